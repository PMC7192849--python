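"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a longitudinal psychiatric cohort in which each
discovery subject shows at least one diametric change in self-reported
stress state: a low-stress visit (VAS Life Stress <= 33/100) and a
high-stress visit (>= 67/100), each with at least one concordant second
VAS item.  A separate "clinically severe" arm carries trait stress
(PCL-C >= 50) together with high state stress, providing the third group
for stepwise validation.

Expression is simulated on the log2 scale (RMA-style): per-probeset
baseline + subject random intercept + stress-state effect + Gaussian
noise.  Planted differential-expression probesets shift by
``effect_log2fc`` in high-stress visits (amplified in the severe arm);
planted absent/present probesets flip their detection call with stress
state.  Hospitalizations are drawn from an exponential waiting-time model
whose log-hazard is linear in a designated planted marker, which makes
the Cox hazard ratio analytically recoverable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    ConfigError,
    EvidenceRecord,
    ExpressionSet,
    FollowupRecord,
    HospitalizationRecord,
    Visit,
    EVIDENCE_CELLS,
    write_cohort,
    write_evidence_db,
    write_followup,
    write_hospitalizations,
)

# discovery-cohort composition: 22 subjects with 2 visits, 9 with 3, 5 with 4;
# 28 of 36 male; diagnosis mix BP 14, MDD 7, PSYCH 1, PTSD 6, SZ 6, SZA 2
VISIT_COUNT_WEIGHTS = {2: 22 / 36, 3: 9 / 36, 4: 5 / 36}
MALE_FRACTION = 28 / 36
DIAGNOSIS_WEIGHTS = {
    "BP": 14 / 36, "MDD": 7 / 36, "PSYCH": 1 / 36,
    "PTSD": 6 / 36, "SZ": 6 / 36, "SZA": 2 / 36,
}


@dataclass
class SimConfig:
    """Tunables of the synthetic cohort.

    ``effect_log2fc`` defaults to 0.5 (a 1.41-fold change, above the
    1.2-fold discovery threshold).  ``severe_effect_multiplier`` amplifies
    planted effects in the clinically severe arm so that planted markers
    are stepwise changed low -> high -> severe.
    """

    n_subjects: int = 36
    visits_per_subject: tuple[int, int] = (2, 4)
    n_probesets: int = 1000
    n_planted_de: int = 20
    n_planted_ap: int = 10
    effect_log2fc: float = 0.5
    noise_sd: float = 0.3
    subject_sd: float = 0.3
    p_high_stress_visit: float = 0.5
    n_severe_subjects: int = 48
    severe_effect_multiplier: float = 1.5
    hosp_hazard_base: float = 1.0 / 2000.0
    hosp_hazard_marker_coef: float = 0.5
    followup_days: int = 2000
    male_fraction: float = MALE_FRACTION
    diagnosis_weights: dict = field(
        default_factory=lambda: dict(DIAGNOSIS_WEIGHTS)
    )
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.visits_per_subject
        if lo < 2:
            raise ConfigError("visits_per_subject must allow >= 2 visits")
        if hi < lo:
            raise ConfigError("visits_per_subject range is empty")
        if self.n_planted_de + self.n_planted_ap > self.n_probesets:
            raise ConfigError("more planted probesets than probesets")
        if not (0.0 <= self.p_high_stress_visit <= 1.0):
            raise ConfigError("p_high_stress_visit must be a probability")
        if self.noise_sd < 0 or self.followup_days < 0:
            raise ConfigError("negative noise_sd or followup_days")


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery checks."""

    planted_de: dict[str, int]          # probeset -> +1 / -1
    planted_ap: dict[str, int]
    hazard_marker: str
    hazard_coef: float
    subject_hazard_multiplier: dict[str, float]

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _draw_visit_counts(rng, config: SimConfig) -> np.ndarray:
    lo, hi = config.visits_per_subject
    if (lo, hi) == (2, 4):
        counts = np.array(sorted(VISIT_COUNT_WEIGHTS))
        probs = np.array([VISIT_COUNT_WEIGHTS[c] for c in counts])
    else:
        counts = np.arange(lo, hi + 1)
        probs = np.full(len(counts), 1.0 / len(counts))
    return rng.choice(counts, size=config.n_subjects, p=probs)


def _vas_for_state(rng, state: str) -> dict[str, int]:
    """VAS items with the Life item in-band and one concordant second item."""
    if state == "low":
        life = int(rng.integers(0, 34))
        concordant = int(rng.integers(0, 34))
    elif state in ("high", "severe"):
        life = int(rng.integers(67, 101))
        concordant = int(rng.integers(67, 101))
    else:  # intermediate
        life = int(rng.integers(34, 67))
        concordant = int(rng.integers(0, 101))
    others = [int(x) for x in rng.integers(0, 101, size=2)]
    items = [concordant] + others
    rng.shuffle(items)
    return {
        "life": life,
        "financial": items[0],
        "health": items[1],
        "social": items[2],
    }


def generate_cohort(
    config: SimConfig,
) -> tuple[
    list[Visit], ExpressionSet, list[HospitalizationRecord],
    list[FollowupRecord], GroundTruth,
]:
    """Simulate a discovery + severe-arm cohort with planted markers."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    probesets = [f"ps{i:05d}_at" for i in range(config.n_probesets)]
    genes = pd.Series(
        [f"GENE{i:05d}" for i in range(config.n_probesets)], index=probesets
    )
    de_ids = probesets[: config.n_planted_de]
    ap_ids = probesets[
        config.n_planted_de: config.n_planted_de + config.n_planted_ap
    ]
    de_dir = {
        p: int(d) for p, d in zip(de_ids, rng.choice([1, -1], len(de_ids)))
    }
    ap_dir = {
        p: int(d) for p, d in zip(ap_ids, rng.choice([1, -1], len(ap_ids)))
    }

    baseline = rng.uniform(4.0, 10.0, size=config.n_probesets)

    visits: list[Visit] = []
    sample_states: list[str] = []
    sample_subject_idx: list[int] = []
    subject_ids: list[str] = []
    subject_intercepts: list[np.ndarray] = []
    subject_meta: list[tuple[str, str]] = []

    n_total = config.n_subjects + config.n_severe_subjects
    visit_counts = _draw_visit_counts(rng, config)
    genders = np.where(
        rng.random(n_total) < config.male_fraction, "M", "F"
    )
    dx_names = list(config.diagnosis_weights)
    dx_probs = np.array([config.diagnosis_weights[d] for d in dx_names])
    dx_probs = dx_probs / dx_probs.sum()
    diagnoses = rng.choice(dx_names, size=n_total, p=dx_probs)

    sample_counter = 0
    for j in range(n_total):
        severe_arm = j >= config.n_subjects
        sid = f"subj{j:04d}"
        subject_ids.append(sid)
        subject_meta.append((str(genders[j]), str(diagnoses[j])))
        subject_intercepts.append(
            rng.normal(0.0, config.subject_sd, size=config.n_probesets)
        )
        if severe_arm:
            n_visits = int(rng.integers(1, 3))  # 1-2 visits, all severe
            states = ["severe"] * n_visits
        else:
            n_visits = int(visit_counts[j])
            states = ["low", "high"]
            for _ in range(n_visits - 2):
                states.append(
                    "high"
                    if rng.random() < config.p_high_stress_visit
                    else "low"
                )
            rng.shuffle(states)
        start = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        d = start
        for k, state in enumerate(states):
            sample_id = f"samp{sample_counter:05d}"
            sample_counter += 1
            if state == "severe":
                pcl = int(rng.integers(50, 86))
            else:
                pcl = int(rng.integers(17, 50))
            scales = {
                "anxiety": float(np.round(rng.uniform(0, 100), 1)),
                "mood": float(np.round(rng.uniform(0, 100), 1)),
                "psychosis": float(np.round(rng.uniform(0, 100), 1)),
            }
            visits.append(
                Visit(
                    subject_id=sid,
                    visit_date=d,
                    gender=str(genders[j]),
                    diagnosis=str(diagnoses[j]),
                    vas=_vas_for_state(rng, state),
                    pcl_c=pcl,
                    scales=scales,
                    sample_id=sample_id,
                )
            )
            sample_states.append(state)
            sample_subject_idx.append(j)
            d = d + timedelta(days=int(rng.integers(90, 181)))  # 3-6 months

    n_samples = len(visits)
    sample_ids = [v.sample_id for v in visits]

    # log2 expression: baseline + subject intercept + planted effect + noise
    values = np.empty((config.n_probesets, n_samples))
    effect = np.zeros(config.n_probesets)
    for p, d_ in de_dir.items():
        effect[probesets.index(p)] = d_ * config.effect_log2fc
    for i in range(n_samples):
        state = sample_states[i]
        mult = (
            config.severe_effect_multiplier if state == "severe"
            else 1.0 if state == "high"
            else 0.0
        )
        values[:, i] = (
            baseline
            + subject_intercepts[sample_subject_idx[i]]
            + mult * effect
            + rng.normal(0.0, config.noise_sd, size=config.n_probesets)
        )

    # presence calls: background mostly present; planted AP flip with state
    presence = rng.random((config.n_probesets, n_samples)) < 0.95
    for p, d_ in ap_dir.items():
        row = probesets.index(p)
        for i, state in enumerate(sample_states):
            stressed = state in ("high", "severe")
            presence[row, i] = stressed if d_ > 0 else not stressed

    values_df = pd.DataFrame(values, index=probesets, columns=sample_ids)
    presence_df = pd.DataFrame(presence, index=probesets, columns=sample_ids)
    batch_key = {v.sample_id: v.batch_key for v in visits}
    eset = ExpressionSet(values_df, presence_df, batch_key, genes)

    # hospitalizations: exponential waiting time from each subject's last
    # visit, log-hazard linear in the subject's level of the planted marker
    hazard_marker = de_ids[0] if de_ids else probesets[0]
    marker_row = probesets.index(hazard_marker)
    # risk rises in the marker's stress direction: for decreased markers
    # lower expression means higher hazard
    marker_dir = de_dir.get(hazard_marker, 1)
    hosp: list[HospitalizationRecord] = []
    followup: list[FollowupRecord] = []
    multipliers: dict[str, float] = {}
    for j, sid in enumerate(subject_ids):
        cols = [i for i in range(n_samples) if sample_subject_idx[i] == j]
        last_visit = max(visits[i].visit_date for i in cols)
        # subject-level marker exposure, centered on the probeset baseline
        x = marker_dir * float(
            np.mean(values[marker_row, cols]) - baseline[marker_row]
        )
        mult = float(np.exp(config.hosp_hazard_marker_coef * x))
        multipliers[sid] = mult
        rate = config.hosp_hazard_base * mult
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if wait <= config.followup_days:
            hosp.append(
                HospitalizationRecord(
                    sid, last_visit + timedelta(days=int(np.ceil(wait))), True
                )
            )
        if rng.random() < 0.15:  # unrelated admissions, stress_reason=0
            when = int(rng.integers(1, config.followup_days + 1))
            hosp.append(
                HospitalizationRecord(
                    sid, last_visit + timedelta(days=when), False
                )
            )
        followup.append(
            FollowupRecord(
                sid, last_visit + timedelta(days=config.followup_days)
            )
        )

    truth = GroundTruth(
        planted_de=de_dir,
        planted_ap=ap_dir,
        hazard_marker=hazard_marker,
        hazard_coef=config.hosp_hazard_marker_coef,
        subject_hazard_multiplier=multipliers,
    )
    return visits, eset, hosp, followup, truth


def generate_evidence_db(
    gene_ids,
    category_probabilities,
    seed: int = 0,
) -> list[EvidenceRecord]:
    """Draw per-gene literature evidence independently per (species, category).

    ``category_probabilities`` is either a single probability applied to all
    six cells or a mapping ``{(species, category): p}``.  With binary cell
    scoring and weights ``w``, the expected external score of a gene is the
    closed form ``sum_cell p_cell * w_cell``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(category_probabilities, (int, float)):
        probs = {cell: float(category_probabilities) for cell in EVIDENCE_CELLS}
    else:
        probs = {cell: float(category_probabilities[cell])
                 for cell in EVIDENCE_CELLS}
    for cell, p in probs.items():
        if not (0.0 <= p <= 1.0):
            raise ConfigError(f"probability for {cell} outside [0, 1]")
    records = []
    for gene in gene_ids:
        for (species, category), p in probs.items():
            if rng.random() < p:
                records.append(
                    EvidenceRecord(
                        gene_symbol=str(gene),
                        species=species,
                        category=category,
                        direction=str(rng.choice(["increased", "decreased"])),
                        citation_tag=f"synthetic:{species}:{category}",
                    )
                )
    return records


def write_simulation(out_dir, visits, eset, hosp, followup, truth) -> dict:
    """Emit the exact file formats io_core reads, plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_cohort(visits, eset, out)
    write_hospitalizations(hosp, out / "hospitalizations.csv")
    write_followup(followup, out / "followup.csv")
    import json

    (out / "ground_truth.json").write_text(
        json.dumps(truth.to_json(), indent=1, sort_keys=True)
    )
    paths["hospitalizations"] = out / "hospitalizations.csv"
    paths["followup"] = out / "followup.csv"
    paths["ground_truth"] = out / "ground_truth.json"
    return paths
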