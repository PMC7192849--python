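"""Score genes against a literature evidence database (CFG prioritization).

Builds a small evidence database with a known per-cell probability,
computes each gene's external score (a cell contributes its full weight
when any significant finding exists there; max 12), combines it with
internal discovery points (max 6) and applies the carry-forward cutoff
of 6/18 — one third of the maximum, which keeps novel genes that earned
a maximal internal score but have no literature yet.
"""

import pandas as pd

from stressmark import CfgWeights, external_score, generate_evidence_db
from stressmark.cfg_prioritization import carry_forward_validation, score_cfg
from stressmark.io_core import evidence_by_gene

genes = [f"GENE{i:02d}" for i in range(12)]
records = generate_evidence_db(genes, category_probabilities=0.5, seed=7)
grouped = evidence_by_gene(records)
weights = CfgWeights()

print("external evidence scores (max 12):")
for gene in genes[:5]:
    cells = {(r.species, r.category) for r in grouped.get(gene, [])}
    score = external_score(gene, grouped.get(gene, []), weights)
    print(f"  {gene}: {len(cells)} evidence cells -> {score:g} points")

# combine with internal discovery points and apply the >= 6 cutoff
discovery = pd.DataFrame(
    {"internal_points": [6, 4, 2, 0, 0, 2, 4, 6, 0, 2, 4, 0],
     "gene_symbol": genes},
    index=[f"ps{i:02d}" for i in range(12)],
)
cfg = score_cfg(discovery, records, weights)
kept = carry_forward_validation(cfg)
print(f"\n{len(kept)} of {len(cfg)} probesets reach total CFG >= 6 and are "
      "carried into validation:")
print(cfg.loc[kept].sort_values("total_cfg", ascending=False).head(8))
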