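"""Reading and writing two-stage survival datasets as delimited text.

Schema: one row per individual with columns

    id, <baseline covariates...>, a1, s1, delta1, eta,
    <stage-2 covariates...>, a2, s2, delta2

Stage-2 fields are empty exactly when eta = 0; observed times are strictly
positive; indicator columns are coded 0/1.  Baseline covariates are the
columns between ``id`` and ``a1``; Stage-2 covariates those between
``eta`` and ``a2``.
"""

from __future__ import annotations

import logging
import sys

import pandas as pd

from .dtr import TwoStageData
from .exceptions import SchemaError

__all__ = ["read_two_stage", "write_two_stage", "validate_two_stage", "infer_roles"]

logger = logging.getLogger("aftbml")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("aftbml: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

STANDARD = ["a1", "s1", "delta1", "eta", "a2", "s2", "delta2"]


def infer_roles(columns: list[str]) -> tuple[list[str], list[str]]:
    cols = list(columns)
    for req in ("a1", "s1", "delta1", "eta"):
        if req not in cols:
            raise SchemaError(f"missing required column {req!r}")
    baseline = [c for c in cols[: cols.index("a1")] if c != "id"]
    if "a2" in cols:
        stage2 = [c for c in cols[cols.index("eta") + 1: cols.index("a2")]]
    else:
        stage2 = []
    return baseline, stage2


def validate_two_stage(frame: pd.DataFrame, baseline_cols: list[str],
                       stage2_cols: list[str]) -> None:
    """Raise :class:`SchemaError` naming offending rows on any violation."""

    def bad_rows(mask):
        return frame.index[mask].tolist()[:10]

    for col in ("delta1", "eta"):
        vals = frame[col]
        mask = ~vals.isin([0, 1])
        if mask.any():
            raise SchemaError(f"column {col!r} must be 0/1; rows {bad_rows(mask)}")
    mask = ~(frame["s1"] > 0)
    if mask.any():
        raise SchemaError(f"s1 must be strictly positive; rows {bad_rows(mask)}")
    ent = frame["eta"] == 1
    stage2_all = [*stage2_cols, "a2", "s2", "delta2"]
    present = [c for c in stage2_all if c in frame.columns]
    if ent.any() and len(present) < len(stage2_all):
        missing = set(stage2_all) - set(present)
        raise SchemaError(f"entrants present but Stage-2 columns missing: {sorted(missing)}")
    for col in present:
        mask = (~ent) & frame[col].notna()
        if mask.any():
            raise SchemaError(
                f"column {col!r} must be empty when eta=0; rows {bad_rows(mask)}")
        mask = ent & frame[col].isna()
        if mask.any():
            raise SchemaError(
                f"column {col!r} missing for entrants; rows {bad_rows(mask)}")
    if ent.any():
        mask = ent & ~(frame["s2"] > 0)
        if mask.any():
            raise SchemaError(f"s2 must be strictly positive; rows {bad_rows(mask)}")
        mask = ent & ~frame["delta2"].isin([0, 1])
        if mask.any():
            raise SchemaError(f"delta2 must be 0/1; rows {bad_rows(mask)}")
        mask = ent & ~frame["a2"].isin([0, 1])
        if mask.any():
            raise SchemaError(f"a2 must be 0/1; rows {bad_rows(mask)}")
    mask = ~frame["a1"].isin([0, 1])
    if mask.any():
        raise SchemaError(f"a1 must be 0/1; rows {bad_rows(mask)}")


def read_two_stage(path, baseline_cols: list[str] | None = None,
                   stage2_cols: list[str] | None = None) -> TwoStageData:
    """Read and validate a two-stage dataset from comma-separated text."""
    frame = pd.read_csv(path)
    if baseline_cols is None or stage2_cols is None:
        inferred = infer_roles(list(frame.columns))
        baseline_cols = baseline_cols if baseline_cols is not None else inferred[0]
        stage2_cols = stage2_cols if stage2_cols is not None else inferred[1]
    validate_two_stage(frame, baseline_cols, stage2_cols)
    n_ent = int((frame["eta"] == 1).sum())
    cens1 = float((frame.loc[frame["eta"] == 0, "delta1"] == 0).mean()) \
        if (frame["eta"] == 0).any() else float("nan")
    logger.info("read %d records (%d Stage-2 entrants, %.1f%% censored "
                "among non-entrants) from %s", len(frame), n_ent,
                100 * cens1 if cens1 == cens1 else float("nan"), path)
    return TwoStageData(frame=frame, baseline_cols=baseline_cols,
                        stage2_cols=stage2_cols)


def write_two_stage(frame: pd.DataFrame, path) -> None:
    """Write records as comma-separated text; missing Stage-2 fields become
    empty cells.  Floats use shortest round-trip formatting, so a
    write/read cycle reproduces values exactly."""
    frame.to_csv(path, index=False)
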