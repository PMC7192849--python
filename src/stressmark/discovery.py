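"""Within-subject discovery scoring of low- vs high-stress visits (Step 1).

Two complementary scoring methods run over every eligible low/high visit
pair within each subject:

* **DE** (differential expression): a probeset votes +1 when its intensity
  ratio high/low is at least 1.2-fold, -1 when low/high is, else 0;
* **AP** (absent/present): a probeset votes +1 on an absent -> present
  transition with stress and -1 on present -> absent.

Votes are summed across all comparisons and subjects into a signed raw
score per probeset and method.  Raw scores are then converted to internal
points by their percentage of the maximum absolute raw score within the
method: >=33.3% earns 2 points, >50% earns 4, >80% earns 6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_core import ExpressionSet, Visit

logger = logging.getLogger("stressmark")

FOLD_THRESHOLD = 1.2
LOW_CUTOFF = 33
HIGH_CUTOFF = 67
CONCORDANT_ITEMS = ("financial", "health", "social")


@dataclass
class VisitPair:
    subject_id: str
    low: Visit
    high: Visit


def _eligible(visit: Visit, band: str) -> bool:
    """Life Stress in band with at least one concordant second item."""
    life = visit.vas_life
    if life is None:
        return False
    if band == "low":
        if life > LOW_CUTOFF:
            return False
        return any(
            visit.vas.get(i) is not None and visit.vas[i] <= LOW_CUTOFF
            for i in CONCORDANT_ITEMS
        )
    if life < HIGH_CUTOFF:
        return False
    return any(
        visit.vas.get(i) is not None and visit.vas[i] >= HIGH_CUTOFF
        for i in CONCORDANT_ITEMS
    )


def select_discovery_visits(visits: list[Visit]) -> list[VisitPair]:
    """Enumerate all low x high visit pairs within each subject.

    A low visit has VAS Life Stress <= 33, a high visit >= 67, each with at
    least one other VAS item concordant (<= 33 / >= 67 respectively).  Only
    visits with a linked sample participate.  Subjects with no eligible
    pair are excluded (logged).
    """
    by_subject: dict[str, list[Visit]] = {}
    for v in visits:
        if v.sample_id is not None:
            by_subject.setdefault(v.subject_id, []).append(v)
    pairs: list[VisitPair] = []
    for sid, vs in sorted(by_subject.items()):
        lows = [v for v in vs if _eligible(v, "low")]
        highs = [v for v in vs if _eligible(v, "high")]
        if not lows or not highs:
            logger.info("subject %s has no eligible low/high pair", sid)
            continue
        for lo in lows:
            for hi in highs:
                pairs.append(VisitPair(sid, lo, hi))
    return pairs


def de_vote(
    expr_low: float, expr_high: float, fold_threshold: float = FOLD_THRESHOLD
) -> int:
    """Vote for one probeset in one comparison, on log2 values."""
    ratio = 2.0 ** (expr_high - expr_low)
    if ratio >= fold_threshold:
        return 1
    if 1.0 / ratio >= fold_threshold:
        return -1
    return 0


def ap_vote(present_low: bool, present_high: bool) -> int:
    if not present_low and present_high:
        return 1
    if present_low and not present_high:
        return -1
    return 0


def vote_matrix(
    eset: ExpressionSet,
    pairs: list[VisitPair],
    method: str,
    fold_threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Probesets x pairs matrix of votes in {-1, 0, +1}."""
    cols = {}
    for k, pair in enumerate(pairs):
        lo, hi = pair.low.sample_id, pair.high.sample_id
        if method == "DE":
            diff = eset.values[hi].to_numpy() - eset.values[lo].to_numpy()
            up = (2.0 ** diff) >= fold_threshold
            down = (2.0 ** (-diff)) >= fold_threshold
            votes = up.astype(int) - down.astype(int)
        elif method == "AP":
            if eset.presence is None:
                raise ValueError("no presence matrix; AP votes unavailable")
            p_lo = eset.presence[lo].to_numpy()
            p_hi = eset.presence[hi].to_numpy()
            votes = (~p_lo & p_hi).astype(int) - (p_lo & ~p_hi).astype(int)
        else:
            raise ValueError(f"unknown method {method!r}")
        cols[f"pair{k}"] = votes
    return pd.DataFrame(cols, index=eset.values.index)


def sum_raw_scores(votes: pd.DataFrame) -> pd.Series:
    """Sum votes across all comparisons and subjects per probeset."""
    if votes.shape[1] == 0:
        return pd.Series(0, index=votes.index, dtype=int)
    return votes.sum(axis=1).astype(int)


def internal_points(
    raw_score: float, max_abs_raw: float
) -> tuple[float, int]:
    """Percentage of the method's maximum raw score, and the points it earns.

    >80% -> 6 points, >50% -> 4, >=33.3% -> 2, else 0.
    """
    if max_abs_raw <= 0:
        return 0.0, 0
    pct = 100.0 * abs(raw_score) / max_abs_raw
    if pct > 80.0:
        return pct, 6
    if pct > 50.0:
        return pct, 4
    if pct >= 33.3:
        return pct, 2
    return pct, 0


def score_method(raw: pd.Series, method: str) -> pd.DataFrame:
    """Raw scores -> per-probeset percentage, points and direction."""
    max_abs = int(raw.abs().max()) if len(raw) else 0
    if max_abs == 0:
        logger.warning("all %s raw scores are 0; no internal points", method)
    rows = []
    for probeset, r in raw.items():
        pct, pts = internal_points(r, max_abs)
        direction = (
            "increased" if r > 0 else "decreased" if r < 0 else "none"
        )
        rows.append((probeset, method, int(r), pct, pts, direction))
    return pd.DataFrame(
        rows,
        columns=[
            "probeset_id", "method", "raw_score", "pct_of_max",
            "internal_points", "direction",
        ],
    ).set_index("probeset_id")


def combine_methods(
    de: Optional[pd.DataFrame], ap: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Per-probeset combined internal score: max of the DE and AP points.

    When the two methods disagree in direction the higher-scoring method
    wins and the probeset is flagged.
    """
    frames = {m: f for m, f in (("DE", de), ("AP", ap)) if f is not None}
    index = pd.Index(sorted(set().union(*[f.index for f in frames.values()])))
    out = pd.DataFrame(
        index=index,
        columns=[
            "internal_points", "pct_of_max", "direction", "best_method",
            "conflict",
        ],
    )
    out.index.name = "probeset_id"
    for probeset in index:
        best_pts, best_pct, best_dir, best_method = 0, 0.0, "none", ""
        directions = set()
        for method, frame in frames.items():
            if probeset not in frame.index:
                continue
            row = frame.loc[probeset]
            if row.direction != "none":
                directions.add(row.direction)
            key = (row.internal_points, row.pct_of_max)
            if key > (best_pts, best_pct):
                best_pts, best_pct = int(row.internal_points), float(row.pct_of_max)
                best_dir, best_method = row.direction, method
        out.loc[probeset] = [
            best_pts, best_pct, best_dir, best_method, len(directions) > 1,
        ]
    out["internal_points"] = out["internal_points"].astype(int)
    out["pct_of_max"] = out["pct_of_max"].astype(float)
    out["conflict"] = out["conflict"].astype(bool)
    return out


def score_discovery(
    visits: list[Visit],
    eset: ExpressionSet,
    fold_threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Run the full discovery step: pairing, voting, scoring, combining.

    Returns one row per probeset with per-method raw scores and the
    combined internal points/direction.
    """
    pairs = select_discovery_visits(visits)
    logger.info("discovery: %d low/high comparisons", len(pairs))
    de_scores = score_method(
        sum_raw_scores(vote_matrix(eset, pairs, "DE", fold_threshold)), "DE"
    )
    if eset.presence is not None:
        ap_scores = score_method(
            sum_raw_scores(vote_matrix(eset, pairs, "AP")), "AP"
        )
    else:
        logger.warning("no presence matrix; skipping AP scoring")
        ap_scores = None
    combined = combine_methods(de_scores, ap_scores)
    combined["raw_de"] = de_scores["raw_score"]
    combined["pct_de"] = de_scores["pct_of_max"]
    combined["points_de"] = de_scores["internal_points"]
    if ap_scores is not None:
        combined["raw_ap"] = ap_scores["raw_score"]
        combined["pct_ap"] = ap_scores["pct_of_max"]
        combined["points_ap"] = ap_scores["internal_points"]
    combined["gene_symbol"] = [
        eset.gene_of(p) for p in combined.index
    ]
    return combined
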