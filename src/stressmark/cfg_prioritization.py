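"""Convergent Functional Genomics prioritization (Step 2).

Each candidate gene is scored against a curated literature evidence
database partitioned into six cells: {human, nonhuman} x {genetic,
brain_expression, peripheral_expression}.  A cell contributes its full
weight if at least one significant finding exists there (binary, not
count-proportional), for a maximum of 12 external points.  Combined with
the 0-6 internal discovery points this gives a total CFG score out of 18;
probesets with total >= 6 are carried into validation — a cutoff of one
third of the maximum, which deliberately admits novel genes with a
maximal internal score but no prior literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_core import EvidenceRecord, evidence_by_gene

logger = logging.getLogger("stressmark")

#: default cell weights (sum = 12): human and brain evidence weighted above
#: animal and peripheral evidence
DEFAULT_WEIGHTS = {
    ("human", "genetic"): 2.0,
    ("human", "brain_expression"): 4.0,
    ("human", "peripheral_expression"): 2.0,
    ("nonhuman", "genetic"): 1.0,
    ("nonhuman", "brain_expression"): 2.0,
    ("nonhuman", "peripheral_expression"): 1.0,
}

CARRY_FORWARD_TOTAL = 6.0
TOP_DISCOVERY_PCT = 90.0
TOP_CFG_TOTAL = 13.0
NOMINAL_P = 0.05


@dataclass
class CfgWeights:
    """Per-cell external weights; must sum to the 12-point maximum."""

    weights: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 12.0) > 1e-9:
            raise ValueError(f"external weights sum to {total}, expected 12")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("external weights must be nonnegative")

    @property
    def maximum(self) -> float:
        return sum(self.weights.values())


def external_score(
    gene_symbol: str,
    evidence: list[EvidenceRecord],
    weights: CfgWeights | None = None,
) -> float:
    """External evidence points for one gene (0-12).

    Each of the six (species, category) cells contributes its full weight
    when at least one record for the gene falls in it; duplicate records in
    a cell do not add points.
    """
    weights = weights or CfgWeights()
    cells = {
        (r.species, r.category)
        for r in evidence
        if r.gene_symbol == gene_symbol
    }
    return float(sum(weights.weights[c] for c in cells))


def total_cfg(internal_points: float, external_points: float) -> float:
    """Combined CFG score: internal (0-6) + external (0-12), max 18."""
    return float(internal_points) + float(external_points)


def score_cfg(
    discovery: pd.DataFrame,
    evidence: list[EvidenceRecord],
    weights: CfgWeights | None = None,
) -> pd.DataFrame:
    """Score every probeset in the discovery table against the evidence DB.

    ``discovery`` must carry ``internal_points`` and ``gene_symbol``
    columns (the output of :func:`stressmark.discovery.score_discovery`).
    """
    weights = weights or CfgWeights()
    grouped = evidence_by_gene(evidence)
    rows = []
    for probeset, row in discovery.iterrows():
        gene = row["gene_symbol"]
        ext = external_score(gene, grouped.get(gene, []), weights)
        rows.append(
            (
                probeset, gene, int(row["internal_points"]), ext,
                total_cfg(row["internal_points"], ext),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probeset_id", "gene_symbol", "internal_points",
            "external_points", "total_cfg",
        ],
    ).set_index("probeset_id")


def carry_forward_validation(
    cfg_scores: pd.DataFrame, threshold: float = CARRY_FORWARD_TOTAL
) -> pd.Index:
    """Probesets with total CFG score >= 6, carried into validation."""
    kept = cfg_scores.index[cfg_scores["total_cfg"] >= threshold]
    if len(kept) == 0:
        logger.warning("no probeset reaches total CFG >= %s", threshold)
    return kept


def candidate_union(
    discovery: pd.DataFrame,
    cfg_scores: pd.DataFrame,
    validation: pd.DataFrame,
    top_discovery_pct: float = TOP_DISCOVERY_PCT,
    top_cfg_total: float = TOP_CFG_TOTAL,
    nominal_p: float = NOMINAL_P,
) -> pd.DataFrame:
    """Union of the three testing-candidate routes.

    Candidates are the union (by probeset) of the top discovery probesets
    (>= 90% of the maximum raw score), the top prioritized probesets (CFG
    total >= 13), and the nominally significant validated probesets
    (ANOVA p < 0.05).  Each candidate is tagged with every route it
    qualified by.
    """
    routes = {
        "top_discovery": set(
            discovery.index[discovery["pct_of_max"] >= top_discovery_pct]
        ),
        "top_cfg": set(
            cfg_scores.index[cfg_scores["total_cfg"] >= top_cfg_total]
        ),
        "validated_nominal": set(
            validation.index[
                validation["stepwise"] & (validation["anova_p"] < nominal_p)
            ]
        ),
    }
    all_ids = sorted(set().union(*routes.values()))
    rows = []
    for probeset in all_ids:
        tags = [name for name, ids in routes.items() if probeset in ids]
        rows.append((probeset, ",".join(tags)))
    out = pd.DataFrame(rows, columns=["probeset_id", "routes"]).set_index(
        "probeset_id"
    )
    for name, ids in routes.items():
        out[name] = [p in ids for p in out.index]
    return out
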