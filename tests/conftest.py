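from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from stressmark.io_core import ExpressionSet, Visit
from stressmark.synthetic_data import SimConfig, generate_cohort


def make_visit(
    subject_id="s1",
    visit_date=date(2016, 1, 1),
    gender="M",
    diagnosis="BP",
    life=20,
    financial=50,
    health=50,
    social=50,
    pcl_c=30,
    sample_id=None,
    scales=None,
):
    return Visit(
        subject_id=subject_id,
        visit_date=visit_date,
        gender=gender,
        diagnosis=diagnosis,
        vas={
            "life": life, "financial": financial,
            "health": health, "social": social,
        },
        pcl_c=pcl_c,
        scales=scales or {},
        sample_id=sample_id,
    )


@pytest.fixture
def small_cohort():
    """36-subject simulated cohort with a severe arm, small array."""
    config = SimConfig(
        n_subjects=36,
        n_probesets=400,
        n_planted_de=20,
        n_planted_ap=10,
        effect_log2fc=1.0,
        noise_sd=0.25,
        n_severe_subjects=12,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def tiny_eset():
    """2-subject, 4-sample expression set with hand-set values."""
    visits = []
    samples = ["a_lo", "a_hi", "b_lo", "b_hi"]
    specs = [
        ("A", date(2016, 1, 1), 20, 10),
        ("A", date(2016, 6, 1), 80, 90),
        ("B", date(2016, 2, 1), 25, 30),
        ("B", date(2016, 7, 1), 70, 70),
    ]
    for sample, (sid, d, life, other) in zip(samples, specs):
        visits.append(
            make_visit(
                subject_id=sid, visit_date=d, life=life, health=other,
                sample_id=sample,
            )
        )
    values = pd.DataFrame(
        # ps1 up 0.5 log2 in both subjects, ps2 flat, ps3 down 1.0
        [[5.0, 5.5, 6.0, 6.5],
         [7.0, 7.0, 7.0, 7.0],
         [8.0, 7.0, 8.0, 7.0]],
        index=["ps1", "ps2", "ps3"],
        columns=samples,
    )
    presence = pd.DataFrame(
        [[False, True, False, True],
         [True, True, True, True],
         [True, False, True, False]],
        index=values.index,
        columns=samples,
    )
    batch = {s: ("M", "BP") for s in samples}
    return visits, ExpressionSet(values, presence, batch)


def roc_auc_oracle(scores, labels):
    """Brute-force pair enumeration: wins + half ties over all pos x neg."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def cox_loglik(beta, times, events, x):
    """Cox partial log-likelihood (Breslow form; no tied event times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.where(events == 1)[0]:
        at_risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def cox_beta_oracle(times, events, x, lo=-5.0, hi=5.0):
    """Grid-search maximizer of the partial likelihood to ~1e-5."""
    grid = np.linspace(lo, hi, 2001)
    lls = [cox_loglik(b, times, events, x) for b in grid]
    best = grid[int(np.argmax(lls))]
    for _ in range(3):
        span = (grid[1] - grid[0]) * 2
        grid = np.linspace(best - span, best + span, 401)
        lls = [cox_loglik(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(lls))]
    return float(best)
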