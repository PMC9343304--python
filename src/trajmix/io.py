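"""Reading and validating long-format observation and covariate tables.

Observation CSVs carry one row per (participant, wave):
``pid,fid,wave,age,bin,ia,hi``.  The bin column is optional — it is
recomputed from age when absent and cross-checked when present.  Scores live
on the common 0-30 scale.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortDataset, assign_age_bin

logger = logging.getLogger(__name__)

REQUIRED_COLS = ("pid", "fid", "wave", "age", "ia", "hi")


def read_long_observations(path: str | Path) -> CohortDataset:
    """Load and validate a long-format observation CSV.

    Malformed rows (non-numeric fields, non-positive ages, scores outside
    0-30, bins inconsistent with ages) are rejected with their line numbers.
    Duplicate (pid, bin) pairs are collapsed to the earliest wave with a
    warning, matching the one-score-per-bin convention of the growth model.
    """
    raw = pd.read_csv(path, dtype={"pid": str, "fid": str})
    missing = [c for c in REQUIRED_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    bad_lines: list[str] = []
    for col in ("wave", "age", "ia", "hi"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[vals.isna()]
        for i in bad:
            bad_lines.append(f"line {i + 2}: non-numeric {col}")
        raw[col] = vals
    if not bad_lines:
        bad_age = raw.index[(raw["age"] <= 0) | ~np.isfinite(raw["age"])]
        for i in bad_age:
            bad_lines.append(f"line {i + 2}: non-positive age")
        for col in ("ia", "hi"):
            bad = raw.index[(raw[col] < 0) | (raw[col] > 30)]
            for i in bad:
                bad_lines.append(f"line {i + 2}: {col} outside [0, 30]")
    if bad_lines:
        raise ValueError(f"{path}: malformed rows: " + "; ".join(bad_lines[:20]))

    expected = assign_age_bin(raw["age"].to_numpy())
    if "bin" in raw.columns and raw["bin"].notna().all():
        given = pd.to_numeric(raw["bin"], errors="coerce")
        mismatch = raw.index[given.to_numpy() != expected]
        if len(mismatch):
            lines = "; ".join(f"line {i + 2}" for i in mismatch[:20])
            raise ValueError(
                f"{path}: bin inconsistent with age at {lines} "
                "(bins are recomputed by truncating age to whole years)")
        raw["bin"] = given.astype(int)
    else:
        raw["bin"] = expected

    n_dup = int(raw.duplicated(subset=["pid", "bin"]).sum())
    if n_dup:
        logger.warning("%s: %d duplicate (pid, bin) rows collapsed to the "
                       "earliest wave", path, n_dup)
        raw = (raw.sort_values(["pid", "bin", "wave"], kind="stable")
               .drop_duplicates(subset=["pid", "bin"], keep="first")
               .sort_index())
    raw["wave"] = raw["wave"].astype(int)
    obs = raw[["pid", "fid", "wave", "age", "bin", "ia", "hi"]].reset_index(drop=True)
    return CohortDataset(obs=obs)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Load a wide covariate CSV (empty cells = missing), indexed by pid."""
    table = pd.read_csv(path, dtype={"pid": str}).set_index("pid")
    return table.apply(pd.to_numeric)
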