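"""Predictive testing of candidate biomarkers in an independent cohort (Step 4).

Markers are evaluated for **state** (is the current visit a high-stress
visit, VAS Life Stress >= 67) and **trait** (future psychiatric
hospitalization with stress as a reason, within the first year and over
all follow-up).  Marker levels are Z-scored by gender and diagnosis so
that markers can be combined into panels and compared across strata.

Two modes are evaluated:

* cross-sectional — the Z-scored level at each visit;
* longitudinal — for subjects with at least two visits, an additive
  combination of four Z-scored features: the level at the most recent
  visit, the slope into it (level ratio divided by inter-visit days),
  the extreme level over all visits so far, and the extreme slope
  (minimum instead of maximum for decreased markers).

Evaluation is repeated for all subjects, by gender, and by gender x
diagnosis (with schizophrenia + schizoaffective pooled as PSYCHOSIS),
reporting ROC AUC with a one-sided rank-sum p, a one-tailed
unequal-variance t-test, a one-tailed Pearson correlation, and — for the
trait outcomes — a univariate Cox proportional-hazards ratio oriented so
that HR > 1 always means increased hospitalization risk, whatever the
marker's expression direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    FollowupRecord,
    HospitalizationRecord,
    PSYCHOSIS_POOL,
    Visit,
)

logger = logging.getLogger("stressmark")

HIGH_STRESS_VAS = 67
FIRST_YEAR_DAYS = 365
SLOPE_EPS = 0.01
SLOPE_CAP = 10.0
OUTCOMES = ("state_high_stress", "hosp_first_year", "hosp_all_future")
#: primary significance metric per outcome (mirrors the scorecard columns:
#: ROC for state and first-year, Cox for all-future)
PRIMARY_METRIC = {
    "state_high_stress": "auc_p",
    "hosp_first_year": "auc_p",
    "hosp_all_future": "hr_p",
}
TESTING_POINTS = {"all": 8, "gender": 6, "gender_dx": 4}


def zscore_by_stratum(
    levels: pd.Series, gender: pd.Series, diagnosis: pd.Series
) -> pd.Series:
    """Z-score levels within each gender x diagnosis cell (sample sd).

    Singleton cells and zero-variance cells yield z = 0.
    """
    z = pd.Series(0.0, index=levels.index)
    frame = pd.DataFrame(
        {"level": levels, "gender": gender, "diagnosis": diagnosis}
    )
    for _, block in frame.groupby(["gender", "diagnosis"], observed=True):
        if len(block) < 2:
            continue
        sd = block["level"].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        z[block.index] = (block["level"] - block["level"].mean()) / sd
    return z


def slope(
    level_curr: float,
    level_prev: float,
    days_between: float,
    eps: float = SLOPE_EPS,
    cap: float = SLOPE_CAP,
) -> float:
    """Level ratio current/previous divided by inter-visit days.

    Previous levels within ``eps`` of zero are replaced by
    ``sign(prev) * eps`` and the result is capped at ``+/- cap`` to keep
    extreme-slope features finite.
    """
    if days_between <= 0:
        raise ValueError("days_between must be >= 1")
    if abs(level_prev) < eps:
        level_prev = eps if level_prev >= 0 else -eps
    value = (level_curr / level_prev) / days_between
    return float(np.clip(value, -cap, cap))


@dataclass
class MarkerSeries:
    """One subject's ordered z-levels of one marker across visits."""

    subject_id: str
    dates: list
    z_levels: list[float]
    direction: str = "increased"


@dataclass
class LongitudinalFeatures:
    level: float
    slope: float
    extreme_level: float
    extreme_slope: float


def longitudinal_features(
    series: MarkerSeries, upto: int | None = None
) -> LongitudinalFeatures:
    """The four raw longitudinal features at visit index ``upto``.

    Requires at least two visits up to and including ``upto``.  Extremes
    are maxima for increased markers and minima for decreased markers.
    """
    n = len(series.z_levels) if upto is None else upto + 1
    if n < 2:
        raise ValueError("longitudinal features need >= 2 visits")
    levels = series.z_levels[:n]
    dates = series.dates[:n]
    slopes = [
        slope(levels[i], levels[i - 1], (dates[i] - dates[i - 1]).days)
        for i in range(1, n)
    ]
    extreme = min if series.direction == "decreased" else max
    return LongitudinalFeatures(
        level=levels[-1],
        slope=slopes[-1],
        extreme_level=float(extreme(levels)),
        extreme_slope=float(extreme(slopes)),
    )


def combine_features(features: pd.DataFrame) -> pd.Series:
    """Z-score each of the four features over the cohort, then sum."""
    z = pd.DataFrame(index=features.index)
    for col in features.columns:
        sd = features[col].std(ddof=1)
        if len(features) < 2 or sd == 0 or np.isnan(sd):
            z[col] = 0.0
        else:
            z[col] = (features[col] - features[col].mean()) / sd
    return z.sum(axis=1)


def panel_score(z_levels: dict[str, float], directions: dict[str, str]) -> float:
    """Sum of increased-marker z-levels minus decreased-marker z-levels."""
    total = 0.0
    for marker, z in z_levels.items():
        if directions.get(marker, "increased") == "decreased":
            total -= z
        else:
            total += z
    return total


def roc_auc(scores, labels) -> tuple[float, float]:
    """ROC AUC and one-sided rank-sum p for positives scoring higher.

    AUC is the pairwise win probability P(score_pos > score_neg) + half
    the tie probability — the Mann-Whitney U statistic normalized by
    n_pos * n_neg.  The p value is the one-sided Wilcoxon rank-sum test
    (exact enumeration for small tie-free samples, normal approximation
    with tie correction otherwise).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("roc_auc needs both classes nonempty")
    u, p = stats.mannwhitneyu(pos, neg, alternative="greater")
    auc = float(u) / (len(pos) * len(neg))
    return auc, float(p)


def state_labels(visits: list[Visit], threshold: int = HIGH_STRESS_VAS):
    """1 iff VAS Life Stress >= 67 at the visit."""
    return [
        1 if (v.vas_life is not None and v.vas_life >= threshold) else 0
        for v in visits
    ]


def _stress_hospitalizations(
    subject_id: str, hospitalizations: list[HospitalizationRecord]
):
    return sorted(
        (
            h.admission_date
            for h in hospitalizations
            if h.subject_id == subject_id and h.stress_reason
        ),
    )


def first_year_outcome(
    visit: Visit, hospitalizations: list[HospitalizationRecord]
) -> tuple[int, int]:
    """Days to first stress hospitalization within 365 days, else (365, 0)."""
    for when in _stress_hospitalizations(visit.subject_id, hospitalizations):
        days = (when - visit.visit_date).days
        if 0 < days <= FIRST_YEAR_DAYS:
            return days, 1
    return FIRST_YEAR_DAYS, 0


def all_future_outcome(
    visit: Visit,
    hospitalizations: list[HospitalizationRecord],
    followup: list[FollowupRecord],
) -> tuple[int, int]:
    """Days to first stress hospitalization at any follow-up, else censor
    at the last medical-record note date."""
    for when in _stress_hospitalizations(visit.subject_id, hospitalizations):
        days = (when - visit.visit_date).days
        if days > 0:
            return days, 1
    last = [
        f.last_note_date for f in followup if f.subject_id == visit.subject_id
    ]
    if not last:
        raise ValueError(f"no follow-up record for {visit.subject_id}")
    days = (max(last) - visit.visit_date).days
    if days <= 0:
        logger.warning(
            "zero follow-up for %s at %s", visit.subject_id, visit.visit_date
        )
        return 0, 0
    return days, 0


def hosp_frequency(
    visit: Visit,
    hospitalizations: list[HospitalizationRecord],
    followup: list[FollowupRecord],
) -> float:
    """Stress hospitalizations after the visit per day of follow-up."""
    last = [
        f.last_note_date for f in followup if f.subject_id == visit.subject_id
    ]
    duration = (max(last) - visit.visit_date).days if last else 0
    if duration <= 0:
        raise ValueError("zero or negative follow-up duration")
    count = sum(
        1
        for when in _stress_hospitalizations(visit.subject_id, hospitalizations)
        if (when - visit.visit_date).days > 0
    )
    return count / duration


def cox_hr(
    times, events, marker_values, direction: str = "increased"
) -> tuple[float, float]:
    """Univariate Cox proportional-hazards fit (Efron ties, Newton).

    Returns (hazard ratio, Wald p).  The ratio is oriented so that HR > 1
    always means increased hospitalization risk: exp(beta) for increased
    markers, exp(-beta) for decreased markers.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("Cox regression needs at least one event")
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": events,
            "marker": np.asarray(marker_values, dtype=float),
        }
    )
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fitter.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            raise ValueError(f"Cox fit did not converge: {exc}") from exc
    beta = float(fitter.params_["marker"])
    p = float(fitter.summary.loc["marker", "p"])
    hr = float(np.exp(beta if direction != "decreased" else -beta))
    return hr, p


def one_tailed_t(pos, neg) -> float:
    """Welch t-test p for positives having higher scores."""
    res = stats.ttest_ind(pos, neg, equal_var=False, alternative="greater")
    return float(res.pvalue)


def one_tailed_pearson(x, y) -> tuple[float, float]:
    """Pearson r and one-tailed p for positive correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def enumerate_strata(visits: list[Visit]) -> list[tuple[str, str, callable]]:
    """(name, level, predicate) for all / gender / gender x diagnosis strata.

    Diagnosis strata include the pooled PSYCHOSIS group (SZ + SZA).
    """
    strata: list[tuple[str, str, callable]] = [
        ("all", "all", lambda v: True)
    ]
    genders = sorted({v.gender for v in visits})
    for g in genders:
        strata.append((g, "gender", lambda v, g=g: v.gender == g))
    diagnoses = sorted({v.diagnosis for v in visits})
    for g in genders:
        for dx in diagnoses:
            strata.append(
                (
                    f"{g}-{dx}", "gender_dx",
                    lambda v, g=g, dx=dx: v.gender == g and v.diagnosis == dx,
                )
            )
        if any(dx in PSYCHOSIS_POOL for dx in diagnoses):
            strata.append(
                (
                    f"{g}-PSYCHOSIS", "gender_dx",
                    lambda v, g=g: v.gender == g
                    and v.diagnosis in PSYCHOSIS_POOL,
                )
            )
    return strata


def _marker_table(
    visits: list[Visit],
    levels: pd.Series,
    direction: str,
    mode: str,
) -> pd.DataFrame:
    """Per-visit score table for one marker within one stratum.

    Levels are Z-scored by gender x diagnosis within the stratum; in
    longitudinal mode the four-feature combination replaces the level and
    visits without a previous visit are dropped.
    """
    frame = pd.DataFrame(
        {
            "subject_id": [v.subject_id for v in visits],
            "date": [v.visit_date for v in visits],
            "gender": [v.gender for v in visits],
            "diagnosis": [v.diagnosis for v in visits],
            "vas_life": [v.vas_life for v in visits],
            "level": levels.to_numpy(),
        },
        index=[v.sample_id for v in visits],
    )
    frame["z"] = zscore_by_stratum(
        frame["level"], frame["gender"], frame["diagnosis"]
    )
    if mode == "cross_sectional":
        frame["score"] = frame["z"]
        return frame
    rows = []
    for sid, block in frame.sort_values("date").groupby("subject_id"):
        if len(block) < 2:
            continue
        series = MarkerSeries(
            sid, list(block["date"]), list(block["z"]), direction
        )
        for k in range(1, len(block)):
            feats = longitudinal_features(series, upto=k)
            rows.append(
                {
                    "sample_id": block.index[k],
                    "level": feats.level,
                    "slope": feats.slope,
                    "extreme_level": feats.extreme_level,
                    "extreme_slope": feats.extreme_slope,
                }
            )
    if not rows:
        return frame.iloc[0:0].assign(score=[])
    feat = pd.DataFrame(rows).set_index("sample_id")
    combined = combine_features(
        feat[["level", "slope", "extreme_level", "extreme_slope"]]
    )
    out = frame.loc[feat.index].copy()
    out["score"] = combined
    return out


def stratified_evaluation(
    markers: pd.DataFrame,
    visits: list[Visit],
    levels: pd.DataFrame,
    hospitalizations: list[HospitalizationRecord] | None = None,
    followup: list[FollowupRecord] | None = None,
    outcomes=OUTCOMES,
    modes=("cross_sectional", "longitudinal"),
    min_positives: int = 2,
) -> pd.DataFrame:
    """Evaluate every candidate marker per stratum, mode, and outcome.

    ``markers`` has one row per candidate probeset with a ``direction``
    column; ``levels`` is the probesets x samples expression matrix of the
    testing cohort.  Decreased-direction marker scores are sign-flipped
    before ROC/t/Pearson so that AUC > 0.5 always means "predicts the
    outcome", matching the Cox orientation rule.
    """
    visits = [v for v in visits if v.sample_id in set(levels.columns)]
    strata = enumerate_strata(visits)
    results = []
    for probeset, marker_row in markers.iterrows():
        direction = marker_row.get("direction", "increased")
        sign = -1.0 if direction == "decreased" else 1.0
        for name, level_kind, predicate in strata:
            sub = [v for v in visits if predicate(v)]
            if len(sub) < 2 * min_positives:
                continue
            for mode in modes:
                table = _marker_table(
                    sub, levels.loc[probeset, [v.sample_id for v in sub]],
                    direction, mode,
                )
                if len(table) < 2 * min_positives:
                    continue
                sub_visits = {v.sample_id: v for v in sub}
                tab_visits = [sub_visits[s] for s in table.index]
                for outcome in outcomes:
                    res = _evaluate_one(
                        probeset, name, level_kind, mode, outcome,
                        table, tab_visits, sign, direction,
                        hospitalizations, followup, min_positives,
                    )
                    if res is not None:
                        results.append(res)
    columns = [
        "probeset_id", "stratum", "stratum_level", "mode", "outcome",
        "n_positive", "n_total", "auc", "auc_p", "t_p",
        "pearson_r", "pearson_p", "hazard_ratio", "hr_p",
    ]
    return pd.DataFrame(results, columns=columns)


def _evaluate_one(
    probeset, stratum, level_kind, mode, outcome, table, tab_visits,
    sign, direction, hospitalizations, followup, min_positives,
):
    scores = sign * table["score"].to_numpy(dtype=float)
    if outcome == "state_high_stress":
        labels = np.array(state_labels(tab_visits))
        target = np.array(
            [v.vas_life if v.vas_life is not None else np.nan
             for v in tab_visits],
            dtype=float,
        )
        times = events = None
    else:
        if hospitalizations is None or followup is None:
            return None
        pairs = [
            first_year_outcome(v, hospitalizations)
            if outcome == "hosp_first_year"
            else all_future_outcome(v, hospitalizations, followup)
            for v in tab_visits
        ]
        times = np.array([t for t, _ in pairs], dtype=float)
        events = np.array([e for _, e in pairs], dtype=int)
        labels = events
        target = np.array(
            [hosp_frequency(v, hospitalizations, followup)
             for v in tab_visits]
        )
    n_pos = int(labels.sum())
    if n_pos < min_positives or n_pos == len(labels):
        return None
    try:
        auc, auc_p = roc_auc(scores, labels)
    except ValueError:
        return None
    t_p = one_tailed_t(scores[labels == 1], scores[labels == 0])
    r, r_p = one_tailed_pearson(scores, target)
    hr = hr_p = float("nan")
    if times is not None:
        try:
            # Cox covariate keeps the raw orientation; HR is re-oriented
            hr, hr_p = cox_hr(
                times, events, table["score"].to_numpy(), direction
            )
        except ValueError:
            pass
    return (
        probeset, stratum, level_kind, mode, outcome,
        n_pos, len(labels), auc, auc_p, t_p, r, r_p, hr, hr_p,
    )


def testing_points(
    results: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> int:
    """Points for the best stratum with a significant prediction.

    8 if the primary metric is significant in all subjects, 6 in any
    gender stratum, 4 in any gender x diagnosis stratum, else 0.  Both
    cross-sectional and longitudinal modes count.
    """
    metric = PRIMARY_METRIC[outcome]
    sub = results[results["outcome"] == outcome]
    sig = sub[sub[metric] < alpha]
    for level in ("all", "gender", "gender_dx"):
        if (sig["stratum_level"] == level).any():
            return TESTING_POINTS[level]
    return 0
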