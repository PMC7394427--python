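"""Clinical cohort table parsing and demographic/lesion summaries.

The cohort file is a TSV with one row per lesion (patients with multiple
lesions repeat their id) and columns ``patient_id, age_yrs, sex,
handedness, tumor_location, tumor_size_mL, pathology``.  Summaries follow
the conventions of clinical case-series tables: age sd with the n − 1
denominator, tumor volume statistics over per-patient totals, handedness
counts over patients with handedness recorded, and bilateral
left-dominant lesions counted as left-hemisphere-involving.

A fixture table for a 35-patient brain-tumor cohort ships with the package
(``langmap.cohort.packaged_cohort_path``).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import FormatError

COLUMNS = (
    "patient_id",
    "age_yrs",
    "sex",
    "handedness",
    "tumor_location",
    "tumor_size_mL",
    "pathology",
)


@dataclass
class CohortRecord:
    patient_id: str
    age_yrs: int
    sex: str  # "M" | "F"
    handedness: str  # "R" | "L" | "NA"
    lesions: list[tuple[str, float]]  # (location text, volume mL)
    pathology: str

    def __post_init__(self) -> None:
        if self.age_yrs <= 0:
            raise ValueError(f"{self.patient_id}: age must be positive")
        if not self.lesions:
            raise ValueError(f"{self.patient_id}: at least one lesion required")
        if any(v < 0 for _, v in self.lesions):
            raise ValueError(f"{self.patient_id}: lesion volumes must be >= 0")


def packaged_cohort_path() -> Path:
    """Path of the packaged 35-patient cohort fixture."""
    return Path(resources.files("langmap") / "data" / "cohort_table1.tsv")


def load_cohort(table_path) -> list[CohortRecord]:
    """Parse a cohort TSV into per-patient records.

    Rows sharing a patient id are grouped into one record with multiple
    lesions; demographic fields are taken from the patient's first row.
    """
    try:
        df = pd.read_csv(table_path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise FormatError(f"could not read cohort table {table_path}: {exc}") from exc
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"cohort table missing columns: {sorted(missing)}")

    records: dict[str, CohortRecord] = {}
    for i, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        try:
            volume = float(row["tumor_size_mL"])
        except (TypeError, ValueError):
            raise FormatError(
                f"row {i + 2} (patient {pid}): unparsable tumor volume "
                f"{row['tumor_size_mL']!r}"
            ) from None
        lesion = (str(row["tumor_location"]).strip(), volume)
        if pid in records:
            records[pid].lesions.append(lesion)
            continue
        try:
            age = int(row["age_yrs"])
        except (TypeError, ValueError):
            raise FormatError(
                f"row {i + 2} (patient {pid}): unparsable age {row['age_yrs']!r}"
            ) from None
        records[pid] = CohortRecord(
            patient_id=pid,
            age_yrs=age,
            sex=str(row["sex"]).strip(),
            handedness=str(row["handedness"]).strip(),
            lesions=[lesion],
            pathology=str(row["pathology"]).strip(),
        )
    return list(records.values())


def write_cohort(records: list[CohortRecord], path) -> None:
    """Write records back to the one-row-per-lesion TSV format."""
    rows = []
    for rec in records:
        for loc, vol in rec.lesions:
            rows.append(
                dict(
                    patient_id=rec.patient_id,
                    age_yrs=rec.age_yrs,
                    sex=rec.sex,
                    handedness=rec.handedness,
                    tumor_location=loc,
                    tumor_size_mL=vol,
                    pathology=rec.pathology,
                )
            )
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, sep="\t", index=False)


def total_lesion_volume(record: CohortRecord) -> float:
    """Per-patient tumor burden: sum of the patient's lesion volumes (mL)."""
    return float(sum(v for _, v in record.lesions))


def classify_hemisphere(location_text: str) -> str:
    """Keyword rule mapping a lesion-location string to a hemisphere class.

    Returns ``left``, ``right``, ``bilateral_left_dominant`` (counted as
    left-involving in summaries) or ``other``.
    """
    if not location_text or not location_text.strip():
        raise ValueError("location text must be nonempty")
    text = location_text.lower()
    has_left = "left" in text
    has_right = "right" in text
    if "bilateral" in text and "left>right" in text.replace(" ", ""):
        return "bilateral_left_dominant"
    if has_left and not has_right:
        return "left"
    if has_right and not has_left:
        return "right"
    return "other"


def _involves_left(record: CohortRecord) -> bool:
    return any(
        classify_hemisphere(loc) in ("left", "bilateral_left_dominant")
        for loc, _ in record.lesions
    )


def round1(x: float) -> float:
    """Round half-up to one decimal, the convention of printed tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n: int
    age_mean: float
    age_sd: float  # n - 1 denominator
    volume_mean: float  # over per-patient totals
    volume_min: float
    volume_max: float
    n_female: int
    n_right_handed: int
    n_handedness_recorded: int
    n_left_hemisphere: int

    def rounded(self) -> dict:
        """Summary dict with means/sds rounded to 1 decimal for reporting."""
        return dict(
            n=self.n,
            age_mean=round1(self.age_mean),
            age_sd=round1(self.age_sd),
            volume_mean=round1(self.volume_mean),
            volume_min=round1(self.volume_min),
            volume_max=round1(self.volume_max),
            n_female=self.n_female,
            n_right_handed=self.n_right_handed,
            n_handedness_recorded=self.n_handedness_recorded,
            n_left_hemisphere=self.n_left_hemisphere,
        )


def summarize(records: list[CohortRecord]) -> CohortSummary:
    """Demographic and lesion summary statistics of a cohort."""
    import numpy as np

    if len(records) < 2:
        raise ValueError("need at least 2 records to summarize")
    ages = np.array([r.age_yrs for r in records], dtype=float)
    totals = np.array([total_lesion_volume(r) for r in records])
    recorded = [r for r in records if r.handedness in ("R", "L")]
    return CohortSummary(
        n=len(records),
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=1)),
        volume_mean=float(totals.mean()),
        volume_min=float(totals.min()),
        volume_max=float(totals.max()),
        n_female=sum(r.sex == "F" for r in records),
        n_right_handed=sum(r.handedness == "R" for r in recorded),
        n_handedness_recorded=len(recorded),
        n_left_hemisphere=sum(_involves_left(r) for r in records),
    )
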