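"""Tabular I/O: the cohort CSV fixture dialect and score-table round trips.

The fixture dialect is UTF-8 comma-separated CSV with a header row and one
row per athlete; a missing value is an empty field. Writing is
column-order-stable and float formatting uses the shortest lossless
representation, so write -> read -> write is byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .schemes import ALL_SNPS, DOMAINS, SEXES, SPORTS, SQUAD_LEVELS

GENOTYPE_COLUMNS = tuple(f"geno_{snp}" for snp in ALL_SNPS)

COHORT_COLUMNS: tuple[str, ...] = (
    "athlete_id", "sex", "age", "sport", "squad_level",
    "body_mass", "grip_strength",
    "tapping", "sprint_10m", "cmj_height", "drop_jump_rsi", "sergeant_height",
    *GENOTYPE_COLUMNS,
    "vitamin_b12", "vitamin_d", "folic_acid", "ferritin",
    "zvt_mean", "d2r_correct", "d2r_wrong",
    *(f"phq4_{i}" for i in range(1, 5)),
    *(f"pss4_{i}" for i in range(1, 5)),
    *(f"passq_{i}" for i in range(1, 17)),
    *(f"mspss_{i}" for i in range(1, 13)),
    "train_cond_1", "train_cond_2",
    "level_code", "success_code", "years_highest", "years_international_senior",
)

_INT_COLUMNS = (*GENOTYPE_COLUMNS, "level_code", "success_code")
_STR_COLUMNS = ("athlete_id", "sex", "sport", "squad_level")

SCORE_COLUMNS: tuple[str, ...] = (
    "athlete_id", "sex", "age", "sport", "squad_level", *DOMAINS,
    "micronutrient_raw", "expertise", "elite",
)


@dataclass
class RowErrorReport:
    """Per-row validation problems collected while reading a cohort CSV."""

    errors: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["row", "column", "message"]
    ))

    def __len__(self) -> int:
        return len(self.errors)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort frame to the fixture CSV dialect."""
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort frame lacks column(s): {missing}")
    out = cohort[list(COHORT_COLUMNS)].copy()
    for col in _INT_COLUMNS:
        out[col] = out[col].astype("Int64")
    try:
        out.to_csv(path, index=False, na_rep="")
    except OSError as exc:
        raise OSError(f"cannot write cohort fixture to {path}: {exc}") from exc


def read_cohort(path, max_invalid_fraction: float = 0.05
                ) -> tuple[pd.DataFrame, RowErrorReport]:
    """Read and validate a cohort fixture.

    Returns the valid rows plus a report of malformed rows (1-based data
    row numbers). Raises if mandatory columns are missing, the file is
    empty, or more than ``max_invalid_fraction`` of rows are invalid.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={c: "string" for c in _STR_COLUMNS},
                            float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"cohort file {path} is empty") from None
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"cohort file {path} is missing mandatory column(s): {missing}"
        )
    frame = frame[list(COHORT_COLUMNS)]
    for col in _INT_COLUMNS:
        frame[col] = frame[col].astype("Int64")
    for col in _STR_COLUMNS:
        frame[col] = frame[col].astype(object)
    if len(frame) == 0:
        raise ValidationError(f"cohort file {path} contains no athlete rows")

    problems: list[tuple[int, str, str]] = []
    checks = [
        ("sex", ~frame["sex"].isin(SEXES), "sex not in {female, male}"),
        ("sport", ~frame["sport"].isin(SPORTS), "unknown sport"),
        ("squad_level", ~frame["squad_level"].isin(SQUAD_LEVELS),
         "squad_level not in {junior, senior}"),
        ("age", ~(frame["age"] > 0), "age must be > 0"),
        ("body_mass", frame["body_mass"].notna() & ~(frame["body_mass"] > 0),
         "body_mass must be > 0"),
    ]
    for snp_col in GENOTYPE_COLUMNS:
        checks.append((
            snp_col,
            frame[snp_col].notna() & ~frame[snp_col].isin([0, 1, 2]),
            "genotype not in {0, 1, 2}",
        ))
    for col, bad, message in checks:
        for row in frame.index[bad.fillna(True) if col in ("sex", "sport",
                                                           "squad_level", "age")
                               else bad.fillna(False)]:
            problems.append((int(row) + 1, col, message))

    report = RowErrorReport(errors=pd.DataFrame(
        problems, columns=["row", "column", "message"]
    ))
    bad_rows = {p[0] - 1 for p in problems}
    if len(bad_rows) / len(frame) > max_invalid_fraction:
        raise ValidationError(
            f"{len(bad_rows)} of {len(frame)} rows are invalid "
            f"(> {max_invalid_fraction:.0%}); first problems:\n"
            f"{report.errors.head()}"
        )
    valid = frame.drop(index=sorted(bad_rows)).reset_index(drop=True)
    return valid, report


def write_score_table(frame: pd.DataFrame, path) -> None:
    """Write a score table (one row per athlete) to CSV."""
    frame[list(SCORE_COLUMNS)].to_csv(path, index=False, na_rep="")


def read_score_table(path) -> pd.DataFrame:
    """Read a score table CSV written by :func:`write_score_table`."""
    frame = pd.read_csv(Path(path))
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"score table missing column(s): {missing}")
    frame["elite"] = frame["elite"].astype(bool)
    frame["expertise"] = frame["expertise"].astype(int)
    return frame
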