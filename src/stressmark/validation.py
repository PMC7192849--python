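"""Validation of prioritized biomarkers in a clinically severe cohort (Step 3).

Expression is first de-logged (2**x, since the matrices are log2 scale)
and Z-scored within each gender x diagnosis stratum; strata are then
pooled.  Three groups are compared: Low Stress and High Stress visits
from the discovery cohort (High excludes clinically severe trait stress,
PCL-C >= 50) and the Clinically Severe validation arm (PCL-C >= 50 with
VAS Life Stress >= 67).  A probeset validates when its group means are
stepwise changed in its discovery direction (strictly monotone low ->
high -> severe); significance is assessed by one-way ANOVA with a
Bonferroni correction across all probesets tested.

Validation points: 6 for stepwise + Bonferroni-significant, 4 for
stepwise + nominally significant (p < 0.05), 2 for stepwise only, 0
otherwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionSet, Visit
from .discovery import _eligible

logger = logging.getLogger("stressmark")

GROUPS = ("LOW", "HIGH", "SEVERE")
SEVERE_PCL = 50
NOMINAL_ALPHA = 0.05


def delog_zscore(
    values: pd.DataFrame, strata: dict[str, tuple[str, str]]
) -> pd.DataFrame:
    """De-log (2**x) then Z-score each probeset within each stratum.

    ``strata`` maps sample id -> (gender, diagnosis).  Z-scores use the
    sample (n-1) standard deviation.  Strata of size 1 or with zero
    variance yield z = 0 for their samples (logged).
    """
    delogged = np.power(2.0, values)
    z = pd.DataFrame(
        np.zeros(values.shape), index=values.index, columns=values.columns
    )
    cells: dict[tuple[str, str], list[str]] = {}
    for sample in values.columns:
        cells.setdefault(strata[sample], []).append(sample)
    for cell, samples in cells.items():
        block = delogged[samples]
        if len(samples) < 2:
            logger.warning("stratum %s has a single sample; z set to 0", cell)
            continue
        sd = block.std(axis=1, ddof=1)
        mean = block.mean(axis=1)
        zero_var = sd == 0
        sd = sd.where(~zero_var, 1.0)
        z[samples] = block.sub(mean, axis=0).div(sd, axis=0)
        z.loc[zero_var, samples] = 0.0
        if zero_var.any():
            logger.warning(
                "%d probeset(s) with zero variance in stratum %s",
                int(zero_var.sum()), cell,
            )
    return z


def assign_validation_groups(visits: list[Visit]) -> dict[str, str]:
    """Map sample id -> LOW / HIGH / SEVERE (ineligible visits omitted).

    LOW and HIGH are discovery-eligible visits; HIGH excludes clinically
    severe trait stress (PCL-C >= 50).  SEVERE requires PCL-C >= 50 and
    VAS Life Stress >= 67.
    """
    groups: dict[str, str] = {}
    for v in visits:
        if v.sample_id is None:
            continue
        severe_trait = v.pcl_c is not None and v.pcl_c >= SEVERE_PCL
        if severe_trait and v.vas_life is not None and v.vas_life >= 67:
            groups[v.sample_id] = "SEVERE"
        elif _eligible(v, "low"):
            groups[v.sample_id] = "LOW"
        elif _eligible(v, "high") and not severe_trait:
            groups[v.sample_id] = "HIGH"
    return groups


def stepwise_flag(
    mean_low: float, mean_high: float, mean_severe: float, direction: str
) -> bool:
    """Strictly monotone progression of group means in the discovery direction."""
    if direction == "increased":
        return mean_low < mean_high < mean_severe
    if direction == "decreased":
        return mean_low > mean_high > mean_severe
    return False


def anova_p(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over the groups: (F, p)."""
    nonempty = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(nonempty) < 2:
        raise ValueError("ANOVA needs at least two nonempty groups")
    f, p = stats.f_oneway(*nonempty)
    if np.isnan(f):  # zero variance everywhere
        return 0.0, 1.0
    return float(f), float(p)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def validation_points(
    stepwise: bool, p: float, bonf_threshold: float,
    nominal_alpha: float = NOMINAL_ALPHA,
) -> int:
    """6 Bonferroni / 4 nominal / 2 stepwise-only / 0 not stepwise."""
    if not stepwise:
        return 0
    if p < bonf_threshold:
        return 6
    if p < nominal_alpha:
        return 4
    return 2


def validate(
    eset: ExpressionSet,
    visits: list[Visit],
    directions: pd.Series,
    probesets=None,
    alpha: float = NOMINAL_ALPHA,
) -> pd.DataFrame:
    """Run Step 3 for the given probesets (default: all with a direction).

    ``directions`` maps probeset id -> discovery direction.  The Bonferroni
    family is the number of probesets tested here.
    """
    groups = assign_validation_groups(visits)
    samples = [s for s in eset.sample_ids if s in groups]
    counts = pd.Series([groups[s] for s in samples]).value_counts()
    logger.info("validation groups: %s", counts.to_dict())
    if probesets is None:
        probesets = [p for p in directions.index if p in eset.values.index]
    z = delog_zscore(
        eset.values.loc[probesets, samples],
        {s: eset.batch_key[s] for s in samples},
    )
    by_group = {
        g: [s for s in samples if groups[s] == g] for g in GROUPS
    }
    n_tests = len(probesets)
    bonf = bonferroni_threshold(alpha, n_tests) if n_tests else np.nan
    rows = []
    for probeset in probesets:
        row = z.loc[probeset]
        means = {g: float(row[by_group[g]].mean()) for g in GROUPS}
        direction = directions.get(probeset, "none")
        step = stepwise_flag(
            means["LOW"], means["HIGH"], means["SEVERE"], direction
        )
        f, p = anova_p([row[by_group[g]].to_numpy() for g in GROUPS])
        pts = validation_points(step, p, bonf, alpha)
        rows.append(
            (
                probeset, means["LOW"], means["HIGH"], means["SEVERE"],
                step, f, p, p < bonf, pts,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probeset_id", "mean_low", "mean_high", "mean_severe",
            "stepwise", "anova_f", "anova_p", "bonferroni_significant",
            "validation_points",
        ],
    ).set_index("probeset_id")
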