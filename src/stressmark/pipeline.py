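"""End-to-end orchestration: discover -> prioritize -> validate ->
candidates -> predict -> CFE -> signature export, with a run manifest.

Each step emits a TSV result table carrying probeset_id, gene_symbol and
every intermediate score, so Table-style scorecards can be assembled by
joining the outputs.  The manifest records the config hash, seeds, input
file digests, per-step output digests, survivor counts and the per-step
fold enrichment (array size / survivors).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    ancillary,
    cfe_scoring,
    cfg_prioritization as cfg,
    discovery,
    io_core,
    synthetic_data,
    validation as validation_mod,
)

logger = logging.getLogger("stressmark")


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    fold_enrichment: dict[str, float] = field(default_factory=dict)
    steps_completed: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _save(df: pd.DataFrame, path: Path, manifest: RunManifest, name: str):
    df.to_csv(path, sep="\t", float_format="%.10g")
    manifest.outputs[name] = str(path)
    manifest.output_digests[name] = _digest(path)


def fold_enrichment(array_size: int, survivors: int) -> float:
    """Array size divided by the number of surviving probesets."""
    if survivors <= 0:
        return float("inf")
    return array_size / survivors


def run_all(
    out_dir,
    sim_config: synthetic_data.SimConfig | None = None,
    input_dir=None,
    evidence_path=None,
    evidence_probability: float = 0.5,
    config: dict | None = None,
) -> RunManifest:
    """Execute the full pipeline on a simulated or on-disk cohort.

    Exactly one of ``sim_config`` (generate the cohort) or ``input_dir``
    (read clinical.csv / expression.tsv / presence.tsv /
    hospitalizations.csv / followup.csv) must be given.  The evidence
    database is read from ``evidence_path`` when provided, otherwise a
    synthetic database with per-cell probability ``evidence_probability``
    is generated for the cohort's genes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or {}
    seed = sim_config.seed if sim_config is not None else config.get("seed")
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(
                {
                    "config": config,
                    "sim": dataclasses.asdict(sim_config)
                    if sim_config
                    else None,
                },
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest(),
        seed=seed,
    )

    if (sim_config is None) == (input_dir is None):
        raise io_core.ConfigError(
            "provide exactly one of sim_config or input_dir"
        )
    if sim_config is not None:
        visits, eset, hosp, followup, truth = synthetic_data.generate_cohort(
            sim_config
        )
        sim_paths = synthetic_data.write_simulation(
            out / "simulated_input", visits, eset, hosp, followup, truth
        )
        for name, path in sim_paths.items():
            manifest.input_digests[name] = _digest(path)
        manifest.steps_completed.append("simulate")
    else:
        input_dir = Path(input_dir)
        presence = input_dir / "presence.tsv"
        visits, eset = io_core.read_cohort(
            input_dir / "clinical.csv",
            input_dir / "expression.tsv",
            presence if presence.exists() else None,
        )
        hosp = io_core.read_hospitalizations(
            input_dir / "hospitalizations.csv"
        )
        followup = io_core.read_followup(input_dir / "followup.csv")
        for f in sorted(input_dir.glob("*.*sv")):
            manifest.input_digests[f.name] = _digest(f)

    array_size = len(eset.probeset_ids)
    manifest.counts["probesets"] = array_size
    manifest.counts["visits"] = len(visits)

    # Step 1: discovery
    disc = discovery.score_discovery(
        visits, eset, config.get("fold_threshold", discovery.FOLD_THRESHOLD)
    )
    _save(disc, out / "discovery_scores.tsv", manifest, "discovery_scores")
    survivors = int((disc["internal_points"] >= 2).sum())
    manifest.counts["discovery_survivors"] = survivors
    manifest.fold_enrichment["discovery"] = fold_enrichment(
        array_size, survivors
    )
    manifest.steps_completed.append("discover")

    # Step 2: prioritization
    if evidence_path is not None:
        evidence = io_core.read_evidence_db(evidence_path)
    else:
        evidence = synthetic_data.generate_evidence_db(
            sorted(set(eset.gene_symbols)),
            evidence_probability,
            seed=(seed or 0) + 1,
        )
        io_core.write_evidence_db(evidence, out / "evidence_db.tsv")
    weights = cfg.CfgWeights(
        {tuple(k.split("|")): v for k, v in config["cfg_weights"].items()}
    ) if "cfg_weights" in config else cfg.CfgWeights()
    cfg_scores = cfg.score_cfg(
        disc[disc["internal_points"] >= 2], evidence, weights
    )
    _save(cfg_scores, out / "cfg_scores.tsv", manifest, "cfg_scores")
    carried = cfg.carry_forward_validation(cfg_scores)
    manifest.counts["cfg_survivors"] = len(carried)
    manifest.fold_enrichment["prioritization"] = fold_enrichment(
        array_size, len(carried)
    )
    manifest.steps_completed.append("prioritize")

    # Step 3: validation
    val = validation_mod.validate(
        eset, visits, disc["direction"], probesets=list(carried)
    )
    _save(val, out / "validation_results.tsv", manifest, "validation_results")
    nominal = int((val["stepwise"] & (val["anova_p"] < 0.05)).sum())
    manifest.counts["validation_nominal"] = nominal
    manifest.fold_enrichment["validation"] = fold_enrichment(
        array_size, nominal
    )
    manifest.steps_completed.append("validate")

    # candidates: union of the three routes
    cand = cfg.candidate_union(disc, cfg_scores, val)
    cand = cand.join(disc[["internal_points", "direction", "gene_symbol"]])
    _save(cand, out / "candidates.tsv", manifest, "candidates")
    manifest.counts["candidates"] = len(cand)
    manifest.steps_completed.append("candidates")

    # Step 4: predictive testing
    from . import prediction

    z_input = eset.values.loc[
        [p for p in cand.index if p in eset.values.index]
    ]
    pred = prediction.stratified_evaluation(
        cand, visits, z_input, hosp, followup,
        min_positives=config.get("min_positives", 2),
    )
    _save(
        pred.set_index("probeset_id"), out / "predictions.tsv",
        manifest, "predictions",
    )
    manifest.counts["prediction_rows"] = len(pred)
    manifest.steps_completed.append("predict")

    # Steps 5-7: CFE tabulation
    cfe = cfe_scoring.tabulate_cfe(cand, cfg_scores, val, pred)
    _save(cfe, out / "cfe_scores.tsv", manifest, "cfe_scores")
    manifest.steps_completed.append("cfe")

    # signature export (validated nominally significant markers)
    validated = val[val["stepwise"] & (val["anova_p"] < 0.05)]
    sig = disc.loc[validated.index, ["direction"]]
    ancillary.export_signature(sig, eset.probeset_ids, out)
    manifest.outputs["signature_up"] = str(out / "signature_up.grp")
    manifest.outputs["signature_down"] = str(out / "signature_down.grp")
    manifest.output_digests["signature_up"] = _digest(out / "signature_up.grp")
    manifest.output_digests["signature_down"] = _digest(
        out / "signature_down.grp"
    )
    manifest.steps_completed.append("export-signature")

    manifest.write(out / "manifest.json")
    return manifest
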