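"""Cross-sectional sleep-morphometry models and peak estimation.

For each region y the full model is

    y_ij = f1(age_ij) + f2(sleep_j) + f12(age_ij, sleep_j)
           + covariates_ij + u_j + e_ij,

with f12 a tensor interaction smooth projected orthogonal to the
additive marginals, so the three candidate models (interaction,
additive, no-sleep) are strictly nested and comparable by likelihood
ratio tests.  Covariates are sex, site and (for volumes) ICV; random
intercepts are included because repeat scans of the same participant
enter the cross-sectional sample.

The quantity of interest per region is the sleep duration at maximum
volume or thickness (minimum for ventricles): the constrained argmax
over [4, 10] hours of the fitted sleep profile, with uncertainty from
Monte-Carlo samples of the empirical-Bayes posterior of the
coefficients.  The profile is the fitted surface averaged over the
observed age distribution (variability of the peak across age is small;
a fixed reference age is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Region, RegionRegistry, default_registry
from .splines import (Linear, Smooth, Tensor, DesignInfo, FitResult,
                      build_design, cr_basis_at, fit_gamm, lrt,
                      posterior_draws, smooth_term_test, bh_adjust, _row_kron)

__all__ = ["PeakEstimate", "fit_cross_models", "peak_estimate",
           "sleep_profile_matrix", "cross_region_analysis",
           "sex_stratified_cross", "icv_toggle_run", "FlatProfileError"]

SLEEP_GRID_STEP = 0.01
SLEEP_RANGE = (4.0, 10.0)


class FlatProfileError(RuntimeError):
    pass


@dataclass
class PeakEstimate:
    region: str
    h_max: float
    se: float
    ci: tuple[float, float]
    boundary_flag: bool
    model_choice: str = "interaction"
    p: float = np.nan
    p_adj: float = np.nan
    F: float = np.nan
    edf: float = np.nan
    n_obs: int = 0
    direction: str = "maximize"


def _cross_terms(region: Region, which: str, k_main: int, k_tensor: int,
                 n_sites: int) -> list:
    terms: list = [Smooth("age", k=k_main)]
    if which in ("interaction", "additive"):
        terms.append(Smooth("sleep", k=k_main))
    if which == "interaction":
        terms.append(Tensor("age", "sleep", k1=k_tensor, k2=k_tensor))
    terms.append(Linear("sex"))
    if n_sites > 1:
        terms.append(Linear("site"))
    if region.uses_icv:
        terms.append(Linear("icv"))
    return terms


def fit_cross_models(table: pd.DataFrame, region: Region | str,
                     registry: RegionRegistry | None = None,
                     k_main: int = 10, k_tensor: int = 5,
                     with_icv: bool = True, tol: float = 1e-6
                     ) -> dict[str, FitResult]:
    """Fit the interaction, additive and no-sleep models on identical rows."""
    registry = registry or default_registry()
    region = registry[region] if isinstance(region, str) else region
    col = registry.column_name(region.name)
    needed = ["age", "sleep", "sex", "participant", col]
    if region.uses_icv and with_icv:
        needed.append("icv")
    sub = table.dropna(subset=[c for c in needed if c in table.columns])
    y = sub[col].to_numpy(dtype=float)
    g = sub["participant"].to_numpy()
    n_sites = sub["site"].nunique() if "site" in sub.columns else 1
    if not with_icv:
        region = Region(**{**region.__dict__, "metric": "thickness"}) \
            if region.uses_icv else region
    fits = {}
    for which in ("interaction", "additive", "no_sleep"):
        terms = _cross_terms(region, which, k_main, k_tensor, n_sites)
        design = build_design(terms, sub)
        try:
            fits[which] = fit_gamm(design, y, groups=g, tol=tol)
        except Exception as exc:
            raise RuntimeError(f"model {which!r} failed for region "
                               f"{region.name}: {exc}") from exc
    return fits


def sleep_profile_matrix(fit: FitResult, grid: np.ndarray,
                         ages: np.ndarray | None = None,
                         reference_age: float | None = None) -> np.ndarray:
    """Matrix P with profile(h) = P @ beta for the sleep-dependent terms.

    The profile is averaged over ``ages`` (default: the realized age
    distribution is supplied by the caller) or evaluated at a single
    ``reference_age``.  Terms not involving sleep contribute a constant
    and are omitted: they do not move the argmax.
    """
    info = fit.design
    P = np.zeros((grid.size, info.p))
    if reference_age is not None:
        ages = np.asarray([reference_age], dtype=float)
    elif ages is None:
        raise ValueError("supply ages or reference_age")
    for t in info.terms:
        term = t.term
        if isinstance(term, Smooth) and term.var == "sleep" and term.by is None:
            P[:, t.sl] = cr_basis_at(grid, t.knots) @ t.Z
        elif isinstance(term, Tensor) and {term.var1, term.var2} == {"age", "sleep"}:
            B1m = cr_basis_at(np.asarray(ages, dtype=float), t.knots).mean(axis=0)
            B2 = cr_basis_at(grid, t.knots2)
            # mean_i kron(B1(age_i), B2(h)) = kron(mean B1, B2(h))
            P[:, t.sl] = _row_kron(np.tile(B1m, (grid.size, 1)), B2) @ t.Z
    return P


def peak_estimate(fit: FitResult, region: Region | str = "region",
                  ages: np.ndarray | None = None,
                  n_draws: int = 5000, seed: int = 0,
                  grid_step: float = SLEEP_GRID_STEP,
                  sleep_range: tuple[float, float] = SLEEP_RANGE,
                  reference_age: float | None = None,
                  direction: str | None = None) -> PeakEstimate:
    """Constrained argmax of the fitted sleep profile with Monte-Carlo CI.

    For every posterior coefficient draw the profile is evaluated on a
    grid over the constrained range and its argmax (argmin for
    ventricle-class regions) recorded; the point estimate uses the
    fitted coefficients, the SE/CI the distribution of draw peaks.  The
    boundary flag marks regions whose posterior peak mass piles up at
    the range limits (effectively monotone profiles).
    """
    if isinstance(region, Region):
        name = region.name
        direction = direction or region.direction
    else:
        name = region
        direction = direction or "maximize"
    lo, hi = sleep_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    P = sleep_profile_matrix(fit, grid, ages=ages, reference_age=reference_age)
    sgn = 1.0 if direction == "maximize" else -1.0

    profile = sgn * (P @ fit.beta)
    if profile.max() - profile.min() < 1e-10:
        raise FlatProfileError(f"flat sleep profile for {name}")

    def argmax_mid(vals: np.ndarray) -> float:
        # ties broken toward the grid midpoint (7 h) to avoid boundary bias
        best = np.flatnonzero(vals >= vals.max() - 1e-12)
        mid = (lo + hi) / 2.0
        return float(grid[best[np.argmin(np.abs(grid[best] - mid))]])

    h_max = argmax_mid(profile)
    draws = posterior_draws(fit, n_draws, seed)
    prof_draws = sgn * (draws @ P.T)             # n_draws x grid
    idx = np.argmax(prof_draws, axis=1)
    peaks = grid[idx]
    se = float(peaks.std())
    ci = (float(np.percentile(peaks, 2.5)), float(np.percentile(peaks, 97.5)))
    at_edge = (peaks <= lo + grid_step / 2) | (peaks >= hi - grid_step / 2)
    boundary = bool(at_edge.mean() > 0.5)
    return PeakEstimate(region=name, h_max=h_max, se=se, ci=ci,
                        boundary_flag=boundary, n_obs=fit.n,
                        direction=direction)


def cross_region_analysis(table: pd.DataFrame, regions=None,
                          registry: RegionRegistry | None = None,
                          n_draws: int = 5000, seed: int = 0,
                          with_icv: bool = True, k_main: int = 10,
                          k_tensor: int = 5, tol: float = 1e-6,
                          grid_step: float = SLEEP_GRID_STEP,
                          reference_age: float | None = None
                          ) -> list[PeakEstimate]:
    """Full per-region cross-sectional analysis (Table-3 analogue).

    Per region: fit the three nested models, select by LRT at 5%, test
    overall sleep relevance (selected vs no-sleep LRT), estimate the
    constrained peak from the selected sleep model, and BH-adjust the
    sleep p values within each FDR family.
    """
    registry = registry or default_registry()
    if regions is None:
        regions = [r.name for r in registry.volumetric()]
    out: list[PeakEstimate] = []
    for name in regions:
        region = registry[name]
        fits = fit_cross_models(table, region, registry, k_main=k_main,
                                k_tensor=k_tensor, with_icv=with_icv, tol=tol)
        _, _, p_int, _ = lrt(fits["interaction"], fits["additive"])
        choice = "interaction" if p_int < 0.05 else "additive"
        _, _, p_sleep, _ = lrt(fits[choice], fits["no_sleep"])
        F, edf, _ = smooth_term_test(fits["additive"], "s(sleep)")
        ages = table["age"].to_numpy(dtype=float)
        if ages.size > 500:
            ages = ages[:: max(1, ages.size // 500)]
        try:
            pk = peak_estimate(fits[choice], region, ages=ages,
                               n_draws=n_draws, seed=seed,
                               grid_step=grid_step,
                               reference_age=reference_age)
        except FlatProfileError:
            pk = PeakEstimate(region=name, h_max=np.nan, se=np.nan,
                              ci=(np.nan, np.nan), boundary_flag=True,
                              direction=region.direction)
        pk.model_choice = choice if p_sleep < 0.05 else "no_sleep"
        pk.p = p_sleep
        pk.F, pk.edf = F, edf
        pk.n_obs = fits[choice].n
        out.append(pk)
    # BH within FDR family
    fams: dict[str, list[int]] = {}
    for i, pk in enumerate(out):
        fams.setdefault(registry[pk.region].fdr_family, []).append(i)
    for fam, idxs in fams.items():
        ps = np.array([out[i].p for i in idxs])
        ok = np.isfinite(ps)
        if ok.any():
            adj = bh_adjust(ps[ok], family=fam)
            for j, i in enumerate(np.array(idxs)[ok]):
                out[i].p_adj = float(adj[j])
    return out


def sex_stratified_cross(table: pd.DataFrame, regions=None,
                         registry: RegionRegistry | None = None,
                         n_draws: int = 2000, seed: int = 0, **kw):
    """Per-sex cross-sectional peaks plus the sex-interaction LRT."""
    from .longitudinal import sex_interaction_test
    registry = registry or default_registry()
    if table["sex"].nunique() < 2:
        raise ValueError("sex-stratified analysis requires both sexes")
    if regions is None:
        regions = [r.name for r in registry.volumetric()]
    peaks = []
    interactions = {}
    for sex in ("female", "male"):
        sub = table[table["sex"] == sex].copy()
        sub["sex"] = "constant"  # degenerate column, dropped by dummy coding
        res = cross_region_analysis(sub, regions=regions, registry=registry,
                                    n_draws=n_draws, seed=seed, **kw)
        for pk in res:
            pk.region = pk.region
            peaks.append((sex, pk))
    for name in regions:
        interactions[name] = sex_interaction_test(table, name, registry)
    return peaks, interactions


def icv_toggle_run(table: pd.DataFrame, regions=None,
                   registry: RegionRegistry | None = None,
                   with_icv: bool = True, **kw) -> list[PeakEstimate]:
    """The cross-sectional analysis with the ICV covariate toggled.

    The toggle only affects volume regions; thickness models never
    include ICV.
    """
    if "icv" not in table.columns:
        raise ValueError("ICV column missing")
    return cross_region_analysis(table, regions=regions, registry=registry,
                                 with_icv=with_icv, **kw)
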