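"""Data model and file I/O for the stress biomarker pipeline.

The pipeline consumes four kinds of tabular inputs:

* a clinical metadata table (CSV) with one row per testing visit — subject
  id, visit date, gender, psychiatric diagnosis, the four visual-analog
  stress items (Life/Financial/Health/Social, 0-100), the PCL-C trait-stress
  score, and anxiety/mood/psychosis rating-scale values;
* a normalized expression matrix (TSV, probesets x samples, log2 scale) with
  an optional matching absent/present call matrix (P/A coded);
* hospitalization and follow-up tables (CSV) from medical records;
* an evidence database (TSV or JSON) of curated literature findings per
  gene, classified by species (human/nonhuman) and tissue category
  (genetic, brain_expression, peripheral_expression).

Dates are ISO-8601 in files; durations are computed in integer days.
Expression values are log2-scale by convention (RMA-style output); the
de-log step in validation assumes this.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger("stressmark")

GENDERS = ("M", "F")
DIAGNOSES = ("BP", "MDD", "SZ", "SZA", "PTSD", "MOOD", "PSYCH")
#: schizophrenia + schizoaffective pooled for per-diagnosis stratification
PSYCHOSIS_POOL = ("SZ", "SZA")

VAS_ITEMS = ("life", "financial", "health", "social")
SCALE_ITEMS = ("anxiety", "mood", "psychosis")

EVIDENCE_SPECIES = ("human", "nonhuman")
EVIDENCE_CATEGORIES = ("genetic", "brain_expression", "peripheral_expression")
#: the six (species, category) cells of the external evidence score
EVIDENCE_CELLS = tuple(
    (sp, cat) for sp in EVIDENCE_SPECIES for cat in EVIDENCE_CATEGORIES
)

CLINICAL_COLUMNS = (
    "subject_id", "visit_date", "gender", "diagnosis",
    "vas_life", "vas_financial", "vas_health", "vas_social",
    "pcl_c", "anxiety", "mood", "psychosis", "sample_id",
)


class SchemaError(ValueError):
    """A file does not match its documented schema."""


class IntegrityError(ValueError):
    """A file violates a cross-record invariant (e.g. duplicate sample id)."""


class ConfigError(ValueError):
    """An invalid or infeasible configuration."""


@dataclass
class Visit:
    """One testing visit: stress scales plus an optional blood-sample link."""

    subject_id: str
    visit_date: date
    gender: str
    diagnosis: str
    vas: dict[str, int]
    pcl_c: Optional[int] = None
    scales: dict[str, Optional[float]] = field(default_factory=dict)
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise SchemaError(f"unknown gender {self.gender!r}")
        if self.diagnosis not in DIAGNOSES:
            raise SchemaError(f"unknown diagnosis {self.diagnosis!r}")
        unknown = set(self.vas) - set(VAS_ITEMS)
        if unknown:
            raise SchemaError(f"unknown VAS item(s) {sorted(unknown)}")
        unknown = set(self.scales) - set(SCALE_ITEMS)
        if unknown:
            raise SchemaError(f"unknown scale(s) {sorted(unknown)}")
        self.vas = {item: self.vas.get(item) for item in VAS_ITEMS}
        self.scales = {item: self.scales.get(item) for item in SCALE_ITEMS}
        for item, value in self.vas.items():
            if value is not None and not (0 <= value <= 100):
                raise SchemaError(
                    f"VAS {item}={value} outside [0, 100] "
                    f"(subject {self.subject_id})"
                )

    @property
    def vas_life(self) -> Optional[int]:
        return self.vas.get("life")

    @property
    def batch_key(self) -> tuple[str, str]:
        return (self.gender, self.diagnosis)


@dataclass
class HospitalizationRecord:
    subject_id: str
    admission_date: date
    stress_reason: bool


@dataclass
class FollowupRecord:
    subject_id: str
    last_note_date: date


@dataclass
class EvidenceRecord:
    """One curated literature finding for a gene."""

    gene_symbol: str
    species: str
    category: str
    direction: str = "na"
    citation_tag: str = ""

    def __post_init__(self) -> None:
        if (self.species, self.category) not in EVIDENCE_CELLS:
            raise SchemaError(
                f"unknown evidence cell ({self.species!r}, {self.category!r})"
            )
        if self.direction not in ("increased", "decreased", "na"):
            raise SchemaError(f"unknown direction {self.direction!r}")


class ExpressionSet:
    """Probesets x samples expression values with optional presence calls.

    ``values`` is a DataFrame (rows = probeset ids, columns = sample ids) of
    log2 normalized intensities.  ``presence`` shares its shape and holds
    boolean detection calls (True = present).  ``batch_key`` maps every
    sample id to its (gender, diagnosis) normalization batch.
    ``gene_symbols`` optionally annotates probesets with gene symbols.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        presence: Optional[pd.DataFrame] = None,
        batch_key: Optional[dict[str, tuple[str, str]]] = None,
        gene_symbols: Optional[pd.Series] = None,
    ):
        if presence is not None:
            if presence.shape != values.shape:
                raise IntegrityError(
                    "values and presence matrices have different shapes"
                )
            presence = presence.loc[values.index, values.columns]
        values.index.name = "probeset_id"
        if presence is not None:
            presence.index.name = "probeset_id"
        self.values = values
        self.presence = presence
        self.batch_key = batch_key or {}
        if gene_symbols is None:
            gene_symbols = pd.Series(values.index, index=values.index)
        self.gene_symbols = gene_symbols

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_of(self, probeset_id: str) -> str:
        return str(self.gene_symbols.get(probeset_id, probeset_id))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionSet":
        presence = (
            self.presence[sample_ids] if self.presence is not None else None
        )
        return ExpressionSet(
            self.values[sample_ids],
            presence,
            {s: self.batch_key[s] for s in sample_ids if s in self.batch_key},
            self.gene_symbols,
        )


def _parse_date(text: str) -> date:
    return datetime.strptime(str(text), "%Y-%m-%d").date()


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(float(value))


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def read_clinical(path) -> list[Visit]:
    """Read the clinical CSV into validated :class:`Visit` records."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"clinical table {path} missing required column(s): "
            + ", ".join(missing)
        )
    visits = []
    for row in df.itertuples(index=False):
        visits.append(
            Visit(
                subject_id=str(row.subject_id),
                visit_date=_parse_date(row.visit_date),
                gender=str(row.gender),
                diagnosis=str(row.diagnosis),
                vas={
                    item: _opt_int(getattr(row, f"vas_{item}"))
                    for item in VAS_ITEMS
                },
                pcl_c=_opt_int(row.pcl_c),
                scales={
                    item: _opt_float(getattr(row, item))
                    for item in SCALE_ITEMS
                },
                sample_id=(
                    None
                    if pd.isna(row.sample_id) or row.sample_id == ""
                    else str(row.sample_id)
                ),
            )
        )
    sample_ids = [v.sample_id for v in visits if v.sample_id is not None]
    dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dupes:
        raise IntegrityError(f"duplicate sample_id(s): {sorted(dupes)}")
    # visit dates must be strictly ordered within subject
    by_subject: dict[str, list[Visit]] = {}
    for v in visits:
        by_subject.setdefault(v.subject_id, []).append(v)
    for sid, vs in by_subject.items():
        dates = [v.visit_date for v in vs]
        if len(set(dates)) != len(dates):
            raise IntegrityError(f"duplicate visit dates for subject {sid}")
    return visits


def read_expression_matrix(path, presence: bool = False) -> pd.DataFrame:
    """Read a probeset x sample TSV; presence matrices are P/A coded."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        raise IntegrityError(f"duplicate probeset ids in {path}")
    if presence:
        bad = set(df.values.ravel()) - {"P", "A"}
        if bad:
            raise SchemaError(
                f"presence matrix {path} has codes other than P/A: {sorted(bad)}"
            )
        return df == "P"
    return df.astype(float)


def read_cohort(
    clinical_path, expression_path, presence_path=None
) -> tuple[list[Visit], ExpressionSet]:
    """Join the clinical table with the expression (and presence) matrices.

    Samples present in the expression matrix but absent from the clinical
    table are dropped with a warning; a missing presence matrix is permitted
    (absent/present scoring is then skipped downstream).
    """
    visits = read_clinical(clinical_path)
    values = read_expression_matrix(expression_path)
    presence = (
        read_expression_matrix(presence_path, presence=True)
        if presence_path is not None
        else None
    )
    by_sample = {v.sample_id: v for v in visits if v.sample_id is not None}
    matched = [s for s in values.columns if s in by_sample]
    unmatched = [s for s in values.columns if s not in by_sample]
    if unmatched:
        logger.warning(
            "dropping %d expression sample(s) with no clinical record: %s",
            len(unmatched), unmatched,
        )
    values = values[matched]
    if presence is not None:
        presence = presence[matched]
    batch_key = {s: by_sample[s].batch_key for s in matched}
    return visits, ExpressionSet(values, presence, batch_key)


def write_cohort(visits: list[Visit], eset: ExpressionSet, out_dir) -> dict:
    """Write clinical/expression/presence files in the formats read_cohort reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in visits:
        rows.append({
            "subject_id": v.subject_id,
            "visit_date": v.visit_date.isoformat(),
            "gender": v.gender,
            "diagnosis": v.diagnosis,
            **{f"vas_{item}": v.vas.get(item) for item in VAS_ITEMS},
            "pcl_c": v.pcl_c,
            **{item: v.scales.get(item) for item in SCALE_ITEMS},
            "sample_id": v.sample_id,
        })
    clinical = out / "clinical.csv"
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(clinical, index=False)
    expression = out / "expression.tsv"
    eset.values.to_csv(expression, sep="\t", index_label="probeset_id")
    paths = {"clinical": clinical, "expression": expression}
    if eset.presence is not None:
        presence = out / "presence.tsv"
        eset.presence.replace({True: "P", False: "A"}).to_csv(
            presence, sep="\t", index_label="probeset_id"
        )
        paths["presence"] = presence
    return paths


def read_hospitalizations(path) -> list[HospitalizationRecord]:
    df = pd.read_csv(path, dtype=str)
    for col in ("subject_id", "admission_date", "stress_reason"):
        if col not in df.columns:
            raise SchemaError(f"hospitalization table missing column {col!r}")
    return [
        HospitalizationRecord(
            str(r.subject_id), _parse_date(r.admission_date),
            bool(int(r.stress_reason)),
        )
        for r in df.itertuples(index=False)
    ]


def read_followup(path) -> list[FollowupRecord]:
    df = pd.read_csv(path, dtype=str)
    for col in ("subject_id", "last_note_date"):
        if col not in df.columns:
            raise SchemaError(f"follow-up table missing column {col!r}")
    return [
        FollowupRecord(str(r.subject_id), _parse_date(r.last_note_date))
        for r in df.itertuples(index=False)
    ]


def write_hospitalizations(records, path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "admission_date": r.admission_date.isoformat(),
                "stress_reason": int(r.stress_reason),
            }
            for r in records
        ],
        columns=["subject_id", "admission_date", "stress_reason"],
    ).to_csv(path, index=False)


def write_followup(records, path) -> None:
    pd.DataFrame(
        [
            {"subject_id": r.subject_id,
             "last_note_date": r.last_note_date.isoformat()}
            for r in records
        ],
        columns=["subject_id", "last_note_date"],
    ).to_csv(path, index=False)


def read_evidence_db(path) -> list[EvidenceRecord]:
    """Read an evidence database from TSV or JSON (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text() or "[]")
        rows = raw
    else:
        try:
            df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        except pd.errors.EmptyDataError:
            return []
        rows = df.to_dict("records")
    records = []
    for row in rows:
        records.append(
            EvidenceRecord(
                gene_symbol=str(row["gene_symbol"]),
                species=str(row["species"]),
                category=str(row["category"]),
                direction=str(row.get("direction") or "na"),
                citation_tag=str(row.get("citation_tag") or ""),
            )
        )
    return records


def write_evidence_db(records: list[EvidenceRecord], path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(r) for r in records],
        columns=["gene_symbol", "species", "category", "direction",
                 "citation_tag"],
    ).to_csv(path, sep="\t", index=False)


def evidence_by_gene(records) -> dict[str, list[EvidenceRecord]]:
    grouped: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        grouped.setdefault(r.gene_symbol, []).append(r)
    return grouped


def load_config(path) -> dict:
    """Load the JSON config of tunables (thresholds, weights, seeds)."""
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON config {path}: {exc}") from exc
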