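"""Clinical data model, treatment-response formulas and cohort summaries.

Staging follows TNM v7 conventions: ``cT``/``cN``/``cM`` are pre-treatment
clinical stages, ``yT``/``yN`` the re-stage after induction chemotherapy.
Sub-stage letters (2a/2b/2c) are preserved as text but ordered within the
same numeric major stage; stage differences (cT-yT, cN-yN) are computed on
the major numeric component.

Radiological response is the percentage of tumour regression,
``100 - post_volume * 100 / pre_volume``; values can be negative
(progression) and are capped above by 100 (complete disappearance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

_STAGE_RE = re.compile(r"^([0-4])([a-c]?)$")

#: TNM v7 stage-group labels used in summaries.
STAGE_GROUPS = ("I", "II", "III", "IVa", "IVb", "IVc")


def parse_stage(stage: str | int) -> tuple[int, str]:
    """Split a stage like ``"2b"`` into (major=2, sub="b")."""
    text = str(stage).strip()
    m = _STAGE_RE.match(text)
    if not m:
        raise ValueError(f"unparseable TNM stage: {stage!r}")
    return int(m.group(1)), m.group(2)


@dataclass
class ClinicalRecord:
    """One patient's clinical data (volumes in cm^3, age in years)."""

    patient_id: str
    sex: str  # "M" | "F"
    age: int
    site: str = ""
    cT: str = ""
    cN: str = ""
    cM: str = "0"
    yT: str | None = None
    yN: str | None = None
    tnm_group: str = ""
    pre_volume_cm3: float | None = None
    post_volume_cm3: float | None = None
    regimen: str = ""
    cycles: int | None = None
    ctcae: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.patient_id}: sex must be 'M' or 'F'")
        for vol in (self.pre_volume_cm3, self.post_volume_cm3):
            if vol is not None and vol < 0:
                raise ValueError(f"{self.patient_id}: tumour volume must be >= 0")


def tumor_regression_pct(pre_volume: float, post_volume: float) -> float:
    """Radiological regression percentage, ``100 - post*100/pre``.

    Negative values indicate progression; 100 is a complete response.
    """
    if pre_volume <= 0:
        raise ValueError("pre-treatment volume must be > 0")
    if post_volume < 0:
        raise ValueError("post-treatment volume must be >= 0")
    return 100.0 - post_volume * 100.0 / pre_volume


def clinical_response(record: ClinicalRecord) -> tuple[int | None, int | None]:
    """Stage differences (cT - yT, cN - yN) on the numeric major stage.

    Returns ``None`` for a component whose post-treatment stage is missing
    (unevaluable); negative values indicate progression.
    """
    def diff(c: str, y: str | None) -> int | None:
        if y is None or str(y).strip() == "":
            return None
        return parse_stage(c)[0] - parse_stage(y)[0]

    return diff(record.cT, record.yT), diff(record.cN, record.yN)


def _round1(value: float) -> float:
    """Half-up rounding to one decimal (matching tabular rendering)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"),
                                               rounding=ROUND_HALF_UP))


def records_from_frame(clinical: pd.DataFrame) -> list[ClinicalRecord]:
    """Build records from a clinical table (CSV schema of the generator)."""
    records = []
    for pid, row in clinical.iterrows():
        ctcae = {c.removeprefix("ctcae_"): int(row[c])
                 for c in clinical.columns if c.startswith("ctcae_")}
        records.append(ClinicalRecord(
            patient_id=str(pid), sex=row["sex"], age=int(row["age"]),
            site=row.get("site", ""), cT=str(row["cT"]), cN=str(row["cN"]),
            cM=str(row.get("cM", "0")),
            yT=str(row["yT"]) if pd.notna(row.get("yT")) else None,
            yN=str(row["yN"]) if pd.notna(row.get("yN")) else None,
            tnm_group=row.get("tnm_group", ""),
            pre_volume_cm3=row.get("pre_volume_cm3"),
            post_volume_cm3=row.get("post_volume_cm3"),
            regimen=row.get("regimen", ""), cycles=row.get("cycles"),
            ctcae=ctcae,
        ))
    return records


def cohort_summary(records: Sequence[ClinicalRecord] | pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by site, stage and sex, plus age summaries.

    Percentages are half-up rounded to one decimal.  Stage groups III, IVa
    and IVb are reported individually and as a combined IV row.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    records = list(records)
    if not records:
        raise ValueError("cohort_summary requires a nonempty cohort")
    n = len(records)

    rows: list[dict] = []

    def add(category: str, level: str, count: int) -> None:
        rows.append({"category": category, "level": level, "count": count,
                     "percent": _round1(100.0 * count / n)})

    ages = sorted(r.age for r in records)
    rows.append({"category": "age", "level": "median",
                 "count": n, "percent": float(pd.Series(ages).median())})
    rows.append({"category": "age", "level": "range",
                 "count": n, "percent": float(ages[-1] - ages[0])})
    for sex in ("M", "F"):
        add("sex", sex, sum(r.sex == sex for r in records))
    for site in sorted({r.site for r in records if r.site}):
        add("site", site, sum(r.site == site for r in records))
    for cat, attr in (("cT", "cT"), ("cN", "cN")):
        for level in sorted({getattr(r, attr) for r in records if getattr(r, attr)}):
            add(cat, level, sum(getattr(r, attr) == level for r in records))
    groups = [r.tnm_group for r in records if r.tnm_group]
    if groups:
        for level in [g for g in STAGE_GROUPS if g in set(groups)]:
            add("tnm_group", level, sum(g == level for g in groups))
        add("tnm_group", "IV",
            sum(g.startswith("IV") for g in groups))
    return pd.DataFrame(rows)


def summary_text(summary: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`cohort_summary`."""
    lines = []
    for cat, chunk in summary.groupby("category", sort=False):
        lines.append(f"{cat}:")
        for _, row in chunk.iterrows():
            if cat == "age":
                lines.append(f"  {row['level']}: {row['percent']:g}")
            else:
                lines.append(f"  {row['level']}: {row['count']} ({row['percent']}%)")
    return "\n".join(lines)


def write_clinical(records: Iterable[ClinicalRecord] | pd.DataFrame,
                   path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        records.to_csv(path)
        return
    rows = []
    for r in records:
        d = {k: v for k, v in r.__dict__.items() if k != "ctcae"}
        d.update({f"ctcae_{k}": v for k, v in r.ctcae.items()})
        rows.append(d)
    pd.DataFrame(rows).set_index("patient_id").to_csv(path)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id",
                       dtype={"cT": str, "cN": str, "cM": str,
                              "yT": str, "yN": str})
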