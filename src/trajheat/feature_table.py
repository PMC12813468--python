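"""Canonical session-level feature table: schema, labels, I/O.

One row per scan session.  Rows carry a hierarchical label
``group.subject.scan`` (e.g. ``0.1.1`` = first scan of the first AD
subject; AD=0, CN=1, MCI=2, EMCI=3, LMCI=4), months from the subject's
baseline scan, total intracranial volume (TIV), absolute tissue
volumes (ml), mean cortical thickness (mm), WMH volume (ml), and the
TIV-normalized percentage columns.  Cortical thickness is kept in mm,
un-normalized: a thickness is not a volume fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from trajheat.profiles import GROUP_NAMES

__all__ = [
    "COLUMNS",
    "PCT_FEATURES",
    "pct_of_tiv",
    "assign_delta_t",
    "make_label",
    "parse_label",
    "build_table",
    "validate_table",
    "read_table",
    "write_table",
]

#: Canonical CSV column order.
COLUMNS = [
    "label", "group_code", "subject_num", "scan_num", "delta_t_months",
    "tiv_ml", "gm_ml", "wm_ml", "csf_ml", "ct_mm", "wmh_ml",
    "gm_pct", "wm_pct", "csf_pct", "wmh_pct",
]

#: volume column -> derived %TIV column
PCT_FEATURES = {"gm_ml": "gm_pct", "wm_ml": "wm_pct", "csf_ml": "csf_pct",
                "wmh_ml": "wmh_pct"}

#: Tolerance for the stored-vs-recomputed %TIV consistency check.
_PCT_TOL = 1e-9


class TableSchemaError(ValueError):
    """Raised when a feature table violates the canonical schema."""


def pct_of_tiv(volume_ml, tiv_ml):
    """Express a volume as a percentage of total intracranial volume."""
    volume_ml = np.asarray(volume_ml, dtype=float)
    tiv_ml = np.asarray(tiv_ml, dtype=float)
    if np.any(tiv_ml <= 0):
        raise ValueError("tiv_ml must be positive")
    out = 100.0 * volume_ml / tiv_ml
    return float(out) if out.ndim == 0 else out


def assign_delta_t(months):
    """Months-from-baseline for one subject's sessions.

    The earliest session becomes the baseline (0); every other session
    gets its offset in months from that baseline.  Input is sorted
    before assignment, so callers may pass sessions in any order.
    """
    m = np.sort(np.asarray(months, dtype=float))
    if m.size == 0:
        raise ValueError("at least one session required")
    out = m - m[0]
    if np.any(out < 0):
        raise ValueError("negative interval after baseline assignment")
    return out


def make_label(group_code: int, subject_num: int, scan_num: int) -> str:
    """Hierarchical ``group.subject.scan`` label, e.g. ``0.1.1``."""
    if group_code not in GROUP_NAMES:
        raise ValueError(f"group_code must be in 0..4, got {group_code}")
    if subject_num < 1 or scan_num < 1:
        raise ValueError("subject_num and scan_num are 1-based")
    return f"{group_code}.{subject_num}.{scan_num}"


def parse_label(label: str) -> tuple[int, int, int]:
    """Inverse of :func:`make_label`; round-trip identity holds."""
    parts = str(label).split(".")
    if len(parts) != 3:
        raise ValueError(f"malformed label {label!r}: expected g.s.k")
    try:
        g, s, k = (int(p) for p in parts)
    except ValueError as e:
        raise ValueError(f"malformed label {label!r}: non-integer field") from e
    if g not in GROUP_NAMES:
        raise ValueError(f"unknown group code {g} in label {label!r}")
    if s < 1 or k < 1:
        raise ValueError(f"indices in label {label!r} must be >= 1")
    return g, s, k


def build_table(df: pd.DataFrame) -> pd.DataFrame:
    """Derive labels and %TIV columns, order columns, validate.

    Expects the raw columns (group_code, subject_num, scan_num,
    delta_t_months, tiv_ml, gm_ml, wm_ml, csf_ml, ct_mm, wmh_ml).
    """
    df = df.copy()
    df["label"] = [
        make_label(g, s, k)
        for g, s, k in zip(df["group_code"], df["subject_num"], df["scan_num"])
    ]
    for vol, pct in PCT_FEATURES.items():
        df[pct] = pct_of_tiv(df[vol].to_numpy(), df["tiv_ml"].to_numpy())
    df = df[COLUMNS].reset_index(drop=True)
    validate_table(df)
    return df


def validate_table(df: pd.DataFrame) -> None:
    """Check the schema invariants; raise :class:`TableSchemaError`."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing columns: {missing}")
    if df["label"].duplicated().any():
        dup = df.loc[df["label"].duplicated(), "label"].iloc[0]
        raise TableSchemaError(f"duplicate label {dup!r}")
    if (df["tiv_ml"] <= 0).any():
        raise TableSchemaError("tiv_ml must be positive")
    if (df["delta_t_months"] < 0).any():
        raise TableSchemaError("delta_t_months must be >= 0")
    if (df["ct_mm"] <= 0).any():
        raise TableSchemaError("ct_mm must be positive")
    for col in ("gm_ml", "wm_ml", "csf_ml", "wmh_ml"):
        if (df[col] < 0).any():
            raise TableSchemaError(f"{col} must be >= 0")
    parsed = df["label"].map(parse_label)  # raises on malformed entries
    lbl = pd.DataFrame(parsed.tolist(), columns=["g", "s", "k"], index=df.index)
    if ((lbl["g"] != df["group_code"]) | (lbl["s"] != df["subject_num"])
            | (lbl["k"] != df["scan_num"])).any():
        raise TableSchemaError("label fields disagree with index columns")
    for vol, pct in PCT_FEATURES.items():
        err = np.abs(df[pct] - 100.0 * df[vol] / df["tiv_ml"])
        if (err > _PCT_TOL).any():
            raise TableSchemaError(f"{pct} inconsistent with {vol}/tiv_ml")
    for (g, s), sub in df.groupby(["group_code", "subject_num"]):
        first = sub[sub["scan_num"] == 1]
        if len(first) != 1:
            raise TableSchemaError(f"subject {g}.{s} must have exactly one scan_num=1 row")
        if first["delta_t_months"].iloc[0] != 0.0:
            raise TableSchemaError(f"subject {g}.{s} baseline scan has delta_t != 0")
        if sub["scan_num"].duplicated().any():
            raise TableSchemaError(f"subject {g}.{s} has duplicate scan numbers")


def write_table(df: pd.DataFrame, path) -> None:
    """Write the canonical CSV (UTF-8, comma, header, '.' decimal)."""
    validate_table(df)
    df[COLUMNS].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    Round-trips with :func:`write_table` to full float precision
    (floats are written in shortest round-trip representation).
    """
    df = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    validate_table(df)
    return df[COLUMNS].reset_index(drop=True)
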