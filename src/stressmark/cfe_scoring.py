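"""Convergent Functional Evidence tabulation (Steps 5-7 bookkeeping).

The CFE score aggregates everything known about a biomarker into a single
number out of 54: discovery (up to 6), prioritization external evidence
(up to 12), validation (up to 6), three predictive-testing outcomes —
state, first-year hospitalization with stress, all-future hospitalization
with stress — at up to 8 points each (8 significant in all subjects, 6 by
gender, 4 by gender/diagnosis), evidence in other psychiatric and related
disorders (3), and drug-modulation evidence (3, requiring modulation
opposite in direction to the stress change).  36 of the 54 points come
from the pipeline's own data (discovery + validation + testing) and 18
from the literature (external CFG + other disorders + drugs), weighting
own data twice as much as the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DISCOVERY_LEVELS = (0, 2, 4, 6)
VALIDATION_LEVELS = (0, 2, 4, 6)
TESTING_LEVELS = (0, 4, 6, 8)
MAX_EXTERNAL = 12.0
MAX_TOTAL = 54.0
MAX_OWN = 36.0
MAX_LITERATURE = 18.0
TESTING_OUTCOMES = ("state_high_stress", "hosp_first_year", "hosp_all_future")


@dataclass
class CfeComponents:
    discovery_points: int = 0
    cfg_external_points: float = 0.0
    validation_points: int = 0
    testing_points: dict[str, int] = field(
        default_factory=lambda: {o: 0 for o in TESTING_OUTCOMES}
    )
    other_disorder_points: int = 0
    drug_points: int = 0

    def validate(self) -> None:
        if self.discovery_points not in DISCOVERY_LEVELS:
            raise ValueError(
                f"discovery_points {self.discovery_points} not in "
                f"{DISCOVERY_LEVELS}"
            )
        if not (0.0 <= self.cfg_external_points <= MAX_EXTERNAL):
            raise ValueError(
                f"cfg_external_points {self.cfg_external_points} outside "
                f"[0, {MAX_EXTERNAL}]"
            )
        if self.validation_points not in VALIDATION_LEVELS:
            raise ValueError(
                f"validation_points {self.validation_points} not in "
                f"{VALIDATION_LEVELS}"
            )
        for outcome in TESTING_OUTCOMES:
            pts = self.testing_points.get(outcome, 0)
            if pts not in TESTING_LEVELS:
                raise ValueError(
                    f"testing points {pts} for {outcome} not in "
                    f"{TESTING_LEVELS}"
                )
        if self.other_disorder_points not in (0, 3):
            raise ValueError("other_disorder_points must be 0 or 3")
        if self.drug_points not in (0, 3):
            raise ValueError("drug_points must be 0 or 3")


@dataclass
class CfeScore:
    probeset_id: str
    components: CfeComponents
    total: float
    own_data_subtotal: float
    literature_subtotal: float


def cfe_total(
    components: CfeComponents, probeset_id: str = ""
) -> CfeScore:
    """Tabulate the CFE score from its components.

    own data = discovery + validation + testing (max 36);
    literature = external CFG + other disorders + drugs (max 18);
    total = own + literature (max 54).
    """
    components.validate()
    testing = sum(
        components.testing_points.get(o, 0) for o in TESTING_OUTCOMES
    )
    own = components.discovery_points + components.validation_points + testing
    literature = (
        components.cfg_external_points
        + components.other_disorder_points
        + components.drug_points
    )
    return CfeScore(
        probeset_id=probeset_id,
        components=components,
        total=float(own + literature),
        own_data_subtotal=float(own),
        literature_subtotal=float(literature),
    )


def rank_by_cfe(scores: list[CfeScore]) -> list[CfeScore]:
    """Descending total; ties broken by own-data subtotal, then probeset id."""
    return sorted(
        scores,
        key=lambda s: (-s.total, -s.own_data_subtotal, s.probeset_id),
    )


def disorder_drug_flags(
    gene_symbol: str,
    stress_direction: str,
    cross_disorder_db: pd.DataFrame | None,
    drug_db: pd.DataFrame | None,
) -> tuple[int, int]:
    """(other-disorder points, drug points) for one gene.

    Any qualifying cross-disorder record earns 3 points.  Drug evidence
    earns 3 points only when the drug modulates the biomarker opposite in
    direction to its stress change; same-direction records do not count.
    Both databases are tables with a ``gene_symbol`` column; the drug
    table also has a ``direction`` column ({increased, decreased}: the
    direction the drug pushes expression).
    """
    disorder_pts = 0
    if cross_disorder_db is not None and len(cross_disorder_db):
        if (cross_disorder_db["gene_symbol"] == gene_symbol).any():
            disorder_pts = 3
    drug_pts = 0
    if drug_db is not None and len(drug_db):
        opposite = {"increased": "decreased", "decreased": "increased"}.get(
            stress_direction
        )
        rows = drug_db[drug_db["gene_symbol"] == gene_symbol]
        if opposite is not None and (rows["direction"] == opposite).any():
            drug_pts = 3
    return disorder_pts, drug_pts


def tabulate_cfe(
    candidates: pd.DataFrame,
    cfg_scores: pd.DataFrame,
    validation: pd.DataFrame,
    prediction_results: pd.DataFrame,
    cross_disorder_db: pd.DataFrame | None = None,
    drug_db: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the full CFE scorecard for the candidate probesets."""
    from .prediction import testing_points

    rows = []
    for probeset in candidates.index:
        discovery_pts = int(
            candidates.loc[probeset].get("internal_points", 0)
        )
        external = (
            float(cfg_scores.loc[probeset, "external_points"])
            if probeset in cfg_scores.index
            else 0.0
        )
        validation_pts = (
            int(validation.loc[probeset, "validation_points"])
            if probeset in validation.index
            else 0
        )
        marker_results = prediction_results[
            prediction_results["probeset_id"] == probeset
        ]
        testing = {
            outcome: testing_points(marker_results, outcome)
            for outcome in TESTING_OUTCOMES
        }
        direction = str(candidates.loc[probeset].get("direction", "none"))
        gene = str(candidates.loc[probeset].get("gene_symbol", probeset))
        disorder_pts, drug_pts = disorder_drug_flags(
            gene, direction, cross_disorder_db, drug_db
        )
        score = cfe_total(
            CfeComponents(
                discovery_points=discovery_pts,
                cfg_external_points=external,
                validation_points=validation_pts,
                testing_points=testing,
                other_disorder_points=disorder_pts,
                drug_points=drug_pts,
            ),
            probeset_id=probeset,
        )
        rows.append(
            {
                "probeset_id": probeset,
                "gene_symbol": gene,
                "discovery_points": discovery_pts,
                "external_points": external,
                "validation_points": validation_pts,
                **{f"testing_{o}": testing[o] for o in TESTING_OUTCOMES},
                "other_disorder_points": disorder_pts,
                "drug_points": drug_pts,
                "own_data_subtotal": score.own_data_subtotal,
                "literature_subtotal": score.literature_subtotal,
                "cfe_total": score.total,
            }
        )
    out = pd.DataFrame(rows).set_index("probeset_id")
    return out.sort_values(
        ["cfe_total", "own_data_subtotal"], ascending=False, kind="stable"
    )
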