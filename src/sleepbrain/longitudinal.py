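"""Longitudinal sleep-atrophy battery.

For each regional measure y the change model is

    y_ij = f(age_bl_j) + b1(age_bl_j) * sleep_j + b2(age_bl_j) * time_ij
           + b3(sleep_j) * time_ij + covariates_ij + u_j + e_ij,

with f and the varying coefficients b1, b2, b3 penalized cubic
regression splines, u_j a participant random intercept, and baseline
age, sex, site, follow-up time (and ICV for volumes) as covariates.
The term of interest is b3(sleep) * time: whether the rate of change
depends on sleep duration.  All smooths are mean-centred over the data
and the main linear effects of sleep and time enter as explicit
covariates, so the varying-coefficient terms are identifiable.

``run_battery`` fits the model across regions and covariate-sensitivity
variants (full range, restriction to 5-9 h, extra covariates, per-sex
runs), tests the b3 term, and adjusts p values by Benjamini-Hochberg
within each region family (cortical / subcortical) separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Region, RegionRegistry, default_registry
from .splines import (Linear, Smooth, build_design, fit_gamm, lrt,
                      posterior_draws, smooth_term_test, bh_adjust,
                      design_matrix)

__all__ = ["build_change_model", "run_battery", "sex_interaction_test",
           "VARIANTS", "SLEEP_TREND_TERM"]

SLEEP_TREND_TERM = "s(sleep):time"

VARIANTS = ["full_range", "restricted_5_9", "+SES", "+BMI", "+depression",
            "+sleep_quality", "males_only", "females_only"]

_EXTRA_COVARIATES = {
    "+SES": ["education", "income"],
    "+BMI": ["bmi"],
    "+depression": ["depression"],
    "+sleep_quality": ["sleep_quality"],
}


def build_change_model(region: Region, covariate_set: str = "full_range",
                       k: int = 10, n_sites: int = 2) -> list:
    """Term list for the change model of one region.

    ICV enters iff the region is a volume and not ICV itself; SES/BMI/
    depression/sleep-quality columns are appended for the corresponding
    variants; sex-stratified variants drop the sex covariate.
    """
    if covariate_set not in VARIANTS:
        raise ValueError(f"unknown covariate set {covariate_set!r}")
    # The main sleep smooth absorbs the participant-constant (possibly
    # inverted-U) cross-sectional sleep effect; without it, that curvature
    # aliases onto the sleep x time varying coefficient and inflates the
    # change test.  Its centred basis contains the linear sleep effect, so
    # no separate linear sleep column is needed.
    terms: list = [
        Smooth("age_bl", k=k),
        Smooth("sleep", k=k),
        Smooth("age_bl", k=k, by="sleep"),
        Smooth("age_bl", k=k, by="time"),
        Smooth("sleep", k=k, by="time"),
        Linear("time"),
    ]
    if covariate_set not in ("males_only", "females_only"):
        terms.append(Linear("sex"))
    if n_sites > 1:
        terms.append(Linear("site"))
    if region.uses_icv:
        terms.append(Linear("icv"))
    for cov in _EXTRA_COVARIATES.get(covariate_set, []):
        terms.append(Linear(cov))
    return terms


def _variant_rows(table: pd.DataFrame, variant: str) -> pd.DataFrame:
    if variant == "restricted_5_9":
        return table[(table["sleep"] >= 5.0) & (table["sleep"] <= 9.0)]
    if variant == "males_only":
        return table[table["sex"] == "male"]
    if variant == "females_only":
        return table[table["sex"] == "female"]
    return table


def _direction_arrow(fit, term: str = SLEEP_TREND_TERM) -> str | None:
    """Sign of the fitted b3 curve's average slope for near-linear terms.

    Mirrors reporting direction only when the smooth is effectively
    linear (edf < 1.5): a negative slope means longer sleep goes with
    more negative change (greater loss).
    """
    if fit.edf.get(term, 0.0) >= 1.5:
        return None
    info = fit.design.term(term)
    lo, hi = info.knots[0], info.knots[-1]
    grid = pd.DataFrame({"sleep": np.linspace(lo, hi, 50)})
    from .splines import cr_basis_at
    B = cr_basis_at(grid["sleep"].to_numpy(), info.knots) @ info.Z
    curve = B @ fit.beta[info.sl]
    slope = np.polyfit(grid["sleep"], curve, 1)[0]
    return "down" if slope < 0 else "up"


@dataclass
class BatteryRow:
    region: str
    variant: str
    F: float
    edf: float
    n_obs: int
    p: float
    p_adj: float
    direction: str | None
    family: str
    status: str = "ok"


def run_battery(table: pd.DataFrame, regions=None, variants=("full_range",),
                registry: RegionRegistry | None = None, k: int = 10,
                tol: float = 1e-6) -> pd.DataFrame:
    """Fit the change model over regions x variants and BH-adjust.

    ``table`` should be the longitudinal subset (participants with >= 2
    scans), already averaged/filtered by the preprocessing stage.  Rows
    with missing values in a variant's covariates are dropped for that
    variant only (complete-case per variant).  Returns one row per
    region x variant with the b3-term F, edf, n, raw and adjusted p.
    """
    registry = registry or default_registry()
    if regions is None:
        regions = [r.name for r in registry.volumetric()]
    rows: list[BatteryRow] = []
    for variant in variants:
        sub_all = _variant_rows(table, variant)
        for name in regions:
            region = registry[name]
            col = registry.column_name(name)
            needed = ["age_bl", "time", "sleep", "participant", col]
            if variant not in ("males_only", "females_only"):
                needed.append("sex")
            if region.uses_icv:
                needed.append("icv")
            needed += _EXTRA_COVARIATES.get(variant, [])
            if table["site"].nunique() > 1:
                needed.append("site")
            missing_cols = [c for c in needed if c not in sub_all.columns]
            sub = sub_all.dropna(subset=[c for c in needed if c in sub_all.columns])
            if missing_cols or len(sub) < 5 * k:
                rows.append(BatteryRow(name, variant, np.nan, np.nan,
                                       len(sub), np.nan, np.nan, None,
                                       region.fdr_family, status="skipped"))
                continue
            terms = build_change_model(region, variant, k=k,
                                       n_sites=sub["site"].nunique())
            design = build_design(terms, sub)
            fit = fit_gamm(design, sub[col].to_numpy(dtype=float),
                           groups=sub["participant"].to_numpy(), tol=tol)
            F, edf, p = smooth_term_test(fit, SLEEP_TREND_TERM)
            rows.append(BatteryRow(name, variant, F, edf, len(sub), p,
                                   np.nan, _direction_arrow(fit),
                                   region.fdr_family))
    out = pd.DataFrame([r.__dict__ for r in rows])
    # BH within family x variant
    out["p_adj"] = np.nan
    for (variant, fam), idx in out.groupby(["variant", "family"]).groups.items():
        mask = out.loc[idx, "p"].notna()
        good = [i for i in idx if out.loc[i, "p"] == out.loc[i, "p"]]
        if good:
            out.loc[good, "p_adj"] = bh_adjust(out.loc[good, "p"].to_numpy(),
                                               family=f"{fam}:{variant}")
    return out


def sex_interaction_test(table: pd.DataFrame, region: Region | str,
                         registry: RegionRegistry | None = None,
                         k: int = 10, tol: float = 1e-6):
    """LRT of sex-specific vs shared sleep smooths (cross-sectional form).

    The full model adds a sleep smooth multiplied by a centred sex
    indicator to the shared age and sleep smooths; the reduced model
    drops it.  Returns (statistic, df, p).
    """
    registry = registry or default_registry()
    region = registry[region] if isinstance(region, str) else region
    col = registry.column_name(region.name)
    if table["sex"].nunique() < 2:
        raise ValueError("sex-interaction test requires both sexes")
    sub = table.copy()
    sub["sex_c"] = (sub["sex"] == "male").astype(float)
    sub["sex_c"] -= sub["sex_c"].mean()
    base: list = [Smooth("age", k=k), Smooth("sleep", k=k), Linear("sex")]
    if sub["site"].nunique() > 1:
        base.append(Linear("site"))
    if region.uses_icv:
        base.append(Linear("icv"))
    # the centred by-smooth carries its own linear component, so no extra
    # sex x sleep linear column (it would be exactly collinear)
    full = base + [Smooth("sleep", k=k, by="sex_c")]
    y = sub[col].to_numpy(dtype=float)
    g = sub["participant"].to_numpy()
    fit_full = fit_gamm(build_design(full, sub), y, groups=g, tol=tol)
    fit_red = fit_gamm(build_design(base, sub), y, groups=g, tol=tol)
    stat, df, p, _ = lrt(fit_full, fit_red)
    return stat, df, p
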