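"""Reading, writing and validation of on-disk pipeline artifacts.

The central in-memory containers are plain :class:`pandas.DataFrame` objects:

* **beta matrix** — probes x samples, values in ``[0, 1]``, ``NaN`` for
  missing; the index holds probe ids (``index.name == "probe_id"``) and the
  columns hold sample ids.
* **sample sheet** — one row per sample with columns ``sample_id``,
  ``group``, ``age``, ``sex`` and optionally ``batch``.
* **probe manifest** — columns ``probe_id`` and ``chromosome``.

On disk, beta matrices are tab-separated (probe rows, sample columns,
missing cells written as ``NA``) and sample sheets are comma-separated,
matching common methylation-array exports.  Sample order in the matrix is
authoritative; the sample sheet is joined by id, never by position.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

REQUIRED_SHEET_COLUMNS = ("sample_id", "group", "age", "sex")
VALID_SEXES = ("F", "M")


class ValidationError(ValueError):
    """A file or frame violates one of the container invariants."""


# ---------------------------------------------------------------------------
# beta matrix


def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    """Check beta-matrix invariants, returning the frame unchanged.

    Raises :class:`ValidationError` naming the offending probe/sample on
    duplicate ids or out-of-range values.  ``NaN`` cells are allowed.
    """
    if beta.index.has_duplicates:
        dups = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids: {dups[:5]}")
    if beta.columns.has_duplicates:
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    values = beta.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    bad &= ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {values[i, j]!r} outside [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    return beta


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta matrix from TSV and validate it."""
    path = Path(path)
    beta = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False
    )
    if beta.index.name != "probe_id":
        raise ValidationError(
            f"{path}: first column header must be 'probe_id', got {beta.index.name!r}"
        )
    beta.index = beta.index.astype(str)
    beta.columns = beta.columns.astype(str)
    try:
        beta = beta.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric beta value ({exc})") from exc
    return validate_beta_matrix(beta)


def write_beta_matrix(beta: pd.DataFrame, path: str | Path) -> None:
    """Write a beta matrix as TSV, preserving >= 12 significant digits."""
    validate_beta_matrix(beta)
    out = beta.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.15g")


# ---------------------------------------------------------------------------
# sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_SHEET_COLUMNS:
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing required column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    bad_sex = ~sheet["sex"].isin(VALID_SEXES)
    if bad_sex.any():
        offender = sheet.loc[bad_sex].iloc[0]
        raise ValidationError(
            f"sex {offender['sex']!r} for sample {offender['sample_id']!r} "
            f"not in {VALID_SEXES}"
        )
    ages = pd.to_numeric(sheet["age"], errors="coerce")
    if ages.isna().any() or (ages < 0).any():
        offender = sheet.loc[ages.isna() | (ages < 0)].iloc[0]
        raise ValidationError(
            f"invalid age {offender['age']!r} for sample {offender['sample_id']!r}"
        )
    empty_group = sheet["group"].isna() | (
        sheet["group"].astype(str).str.strip() == "")
    if empty_group.any():
        offender = sheet.loc[empty_group].iloc[0]
        raise ValidationError(f"empty group for sample {offender['sample_id']!r}")
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "group": str, "sex": str})
    sheet = validate_sample_sheet(sheet)
    sheet["age"] = sheet["age"].astype(float)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, index=False)


def check_matrix_sheet_consistency(beta: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Require identical sample-id sets in matrix columns and sheet rows."""
    matrix_ids = set(beta.columns)
    sheet_ids = set(sheet["sample_id"])
    if matrix_ids != sheet_ids:
        only_matrix = sorted(matrix_ids - sheet_ids)
        only_sheet = sorted(sheet_ids - matrix_ids)
        raise ValidationError(
            "sample ids differ between beta matrix and sample sheet; "
            f"matrix-only: {only_matrix[:10]}, sheet-only: {only_sheet[:10]}"
        )


# ---------------------------------------------------------------------------
# probe manifest


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "chromosome"):
        if col not in manifest.columns:
            raise ValidationError(f"probe manifest missing column {col!r}")
    if manifest["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe ids in manifest")
    return manifest


# ---------------------------------------------------------------------------
# signature probe lists and reports

SIGNATURE_COLUMNS = ("probe_id", "delta_beta", "t_moderated", "p_value", "p_adjusted", "rank")


def write_signature(signature: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked probe list as TSV with the standard stat columns."""
    missing = [c for c in SIGNATURE_COLUMNS if c not in signature.columns]
    if missing:
        raise ValidationError(f"signature frame missing columns {missing}")
    signature.loc[:, SIGNATURE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.15g"
    )


def read_signature(path: str | Path) -> pd.DataFrame:
    signature = pd.read_csv(path, sep="\t")
    missing = [c for c in SIGNATURE_COLUMNS if c not in signature.columns]
    if missing:
        raise ValidationError(f"{path}: signature file missing columns {missing}")
    signature["probe_id"] = signature["probe_id"].astype(str)
    return signature


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_json_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
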