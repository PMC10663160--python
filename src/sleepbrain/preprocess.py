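"""Analysis-ready table construction.

Sleep-quality scoring, per-participant sleep averaging, model-based
outlier removal and sleep-range restriction.  All filters are idempotent
and every removal is logged so an audit trail can be written next to the
analysis outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Region, RegionRegistry
from . import splines

__all__ = [
    "MissingComponentError", "global_sleep_quality", "ukb_sleep_quality",
    "UKB_RECODE", "average_sleep", "remove_outliers", "restrict_sleep",
    "OutlierLog", "longitudinal_subset",
]

PSQI_DURATION_COMPONENT = 3  # 1-based index of the duration component


class MissingComponentError(ValueError):
    pass


def global_sleep_quality(components) -> int:
    """PSQI global score with the sleep-duration component excluded.

    ``components`` is a sequence of the seven PSQI component scores
    (each 0-3, component 3 being duration).  Returns the sum of the six
    non-duration components, range [0, 18].
    """
    comp = list(components)
    if len(comp) != 7:
        raise MissingComponentError(
            f"expected 7 PSQI components, got {len(comp)}")
    total = 0
    for i, c in enumerate(comp, start=1):
        if i == PSQI_DURATION_COMPONENT:
            continue
        if c is None or (isinstance(c, float) and np.isnan(c)):
            raise MissingComponentError(f"PSQI component {i} is missing")
        c = int(c)
        if not 0 <= c <= 3:
            raise ValueError(f"PSQI component {i} out of range [0, 3]: {c}")
        total += c
    return total


# Recode tables for the five UK Biobank sleep fields.  The survey codings
# are not published alongside the field list, so the mapping below is an
# explicit, editable convention: each field is mapped to 0..2-3 with
# higher = worse sleep quality.  Chronotype is scored by distance from
# the intermediate type.
UKB_RECODE: dict[str, dict[int, int]] = {
    "sleeplessness":   {1: 0, 2: 1, 3: 2},          # never/rarely .. usually
    "getting_up":      {1: 3, 2: 2, 3: 1, 4: 0},    # very easy -> 0
    "daytime_dozing":  {1: 0, 2: 1, 3: 2},
    "snoring":         {1: 1, 2: 0},                # yes/no
    "chronotype":      {1: 1, 2: 0, 3: 0, 4: 1},    # extreme types -> 1
}


def ukb_sleep_quality(fields: dict) -> int:
    """Sum score over the five UKB sleep-related fields (higher = worse)."""
    total = 0
    for name, mapping in UKB_RECODE.items():
        if name not in fields or fields[name] is None:
            raise MissingComponentError(f"UKB field {name!r} is missing")
        code = fields[name]
        if isinstance(code, float) and np.isnan(code):
            raise MissingComponentError(f"UKB field {name!r} is missing")
        code = int(code)
        if code not in mapping:
            raise ValueError(f"unmapped code {code} for UKB field {name!r}")
        total += mapping[code]
    return total


def average_sleep(table: pd.DataFrame, col: str = "sleep",
                  participant: str = "participant") -> pd.DataFrame:
    """Replace per-scan sleep reports by the participant mean.

    Participants with no sleep report at all are dropped (count logged
    via a warning); single reports pass through unchanged.
    """
    out = table.copy()
    means = out.groupby(participant)[col].transform("mean")
    out[col] = means
    missing = out[col].isna()
    if missing.any():
        n_drop = out.loc[missing, participant].nunique()
        warnings.warn(f"dropping {n_drop} participants without sleep data")
        out = out[~missing]
    return out


@dataclass
class OutlierLog:
    region: str
    n_before: int
    n_removed: int
    rse: float
    indices: np.ndarray


def remove_outliers(table: pd.DataFrame, region: Region | str,
                    registry: RegionRegistry | None = None,
                    k: float = 4.0, basis_dim: int = 10,
                    max_fraction: float = 0.05,
                    age_col: str = "age") -> tuple[pd.DataFrame, OutlierLog]:
    """Drop rows far from an age-effect fit for one region.

    A cubic-regression-spline fit of the measure on age (no covariates)
    defines residuals; rows with |residual| strictly greater than
    ``k`` times the residual standard error are removed.  Removing more
    than ``max_fraction`` of the rows triggers a warning, and removing
    everything raises.
    """
    if isinstance(region, Region):
        name = region.name
        col = (registry.column_name(name) if registry is not None
               else name.lower().replace(" ", "_").replace("-", "_"))
    else:
        name, col = region, region
    y = table[col].to_numpy(dtype=float)
    age = table[age_col].to_numpy(dtype=float)
    n = y.size
    k_basis = min(basis_dim, np.unique(age).size)
    if n <= k_basis:
        raise ValueError("too few rows to fit the age-effect model")
    B, _, _ = splines.cr_basis(age, k_basis)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    rse = float(np.sqrt(resid @ resid / max(n - k_basis, 1)))
    keep = np.abs(resid) <= k * rse  # strict ">" removal rule
    if not keep.any():
        raise RuntimeError(f"outlier rule removed every row for {name}")
    removed = int(n - keep.sum())
    if removed > max_fraction * n:
        warnings.warn(
            f"outlier rule removed {removed}/{n} rows for {name} "
            f"(> {max_fraction:.0%})")
    log = OutlierLog(region=name, n_before=n, n_removed=removed, rse=rse,
                     indices=table.index.to_numpy()[~keep])
    return table[keep], log


def restrict_sleep(table: pd.DataFrame, lo: float = 5.0, hi: float = 9.0,
                   col: str = "sleep") -> pd.DataFrame:
    """Keep rows with lo <= sleep <= hi (closed interval)."""
    if lo > hi:
        raise ValueError(f"lo={lo} exceeds hi={hi}")
    s = table[col]
    out = table[(s >= lo) & (s <= hi)]
    if out.empty:
        warnings.warn("sleep-range restriction removed every row")
    return out


def longitudinal_subset(table: pd.DataFrame) -> pd.DataFrame:
    """Rows of participants eligible for the change analysis (>= 2 scans)."""
    if "long_eligible" in table.columns:
        return table[table["long_eligible"]]
    counts = table.groupby("participant")["participant"].transform("size")
    return table[counts >= 2]
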