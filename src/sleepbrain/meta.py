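"""Random-effects meta-analysis of regional peaks, curve clustering, and
the mega- vs meta-analytic comparison.

``pool_peaks`` pools the per-region sleep-at-peak estimates with a
DerSimonian-Laird random-effects model, after applying the exclusion
rules (composite regions such as total grey volume, corpus-callosum
segments and any region whose peak is undefined or piled on the range
boundary).  Inverse-variance weights are rescaled so the cortical and
the subcortical block contribute equal total weight to the pooled fit.

``kmeans_curves`` clusters normalized regional sleep profiles (percent
of each region's own maximum) with k-means; ``mega_vs_meta`` compares a
pooled-data ("mega") fit with per-cohort fits pooled afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import RegionRegistry, default_registry
from .crosssectional import PeakEstimate, fit_cross_models, peak_estimate

__all__ = ["MetaResult", "ClusterResult", "dersimonian_laird", "pool_peaks",
           "kmeans_curves", "mega_vs_meta"]


@dataclass
class MetaResult:
    pooled_h: float
    se: float
    ci: tuple[float, float]
    tau2: float
    weights: dict[str, float]
    included: list[str]
    excluded: dict[str, str]
    q: float = np.nan


@dataclass
class ClusterResult:
    assignments: dict[str, int]
    centroids: np.ndarray
    k: int
    inertia: float


def dersimonian_laird(estimates: np.ndarray, ses: np.ndarray
                      ) -> tuple[float, float]:
    """DerSimonian-Laird between-study variance and heterogeneity Q.

    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-
    effect weights w = 1/se^2.
    """
    w = 1.0 / ses ** 2
    mu_fe = np.sum(w * estimates) / np.sum(w)
    q = float(np.sum(w * (estimates - mu_fe) ** 2))
    k = estimates.size
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return tau2, q


def tau2_reml(estimates: np.ndarray, ses: np.ndarray,
              max_iter: int = 200, tol: float = 1e-10) -> float:
    """REML estimate of the between-study variance (iterative)."""
    est = np.asarray(estimates, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    t2 = max(dersimonian_laird(est, ses)[0], 0.0)
    for _ in range(max_iter):
        w = 1.0 / (v + t2)
        mu = np.sum(w * est) / np.sum(w)
        num = np.sum(w ** 2 * ((est - mu) ** 2 - v)) + np.sum(w ** 2) / np.sum(w) * t2
        new = max(0.0, num / np.sum(w ** 2))
        if abs(new - t2) < tol:
            t2 = new
            break
        t2 = new
    return float(t2)


def pool_peaks(peaks: list[PeakEstimate],
               registry: RegionRegistry | None = None,
               tau2: float | None = None,
               method: str = "dl",
               equal_blocks: bool = True) -> MetaResult:
    """Equal-block random-effects pooling of regional peak estimates.

    Exclusions: composite regions, registry-excluded regions (corpus
    callosum, ICV), boundary-flagged or undefined peaks, and peaks with
    non-finite SE.  ``tau2=0`` forces fixed-effect inverse-variance
    pooling.
    """
    registry = registry or default_registry()
    included: list[PeakEstimate] = []
    excluded: dict[str, str] = {}
    for pk in peaks:
        reg = registry[pk.region] if pk.region in registry else None
        if reg is not None and (reg.composite or not reg.meta_include):
            excluded[pk.region] = reg.exclude_reason or "registry exclusion"
        elif pk.boundary_flag or not np.isfinite(pk.h_max):
            excluded[pk.region] = "peak undefined (boundary/monotone profile)"
        elif not (np.isfinite(pk.se) and pk.se > 0):
            excluded[pk.region] = "non-positive peak SE"
        else:
            included.append(pk)
    if len(included) < 2:
        raise ValueError("fewer than 2 regions available for pooling")

    est = np.array([pk.h_max for pk in included])
    ses = np.array([pk.se for pk in included])
    if tau2 is None:
        if method == "reml":
            tau2 = tau2_reml(est, ses)
            _, q = dersimonian_laird(est, ses)
        elif method == "dl":
            tau2, q = dersimonian_laird(est, ses)
        else:
            raise ValueError(f"unknown tau2 method {method!r}")
    else:
        _, q = dersimonian_laird(est, ses)
    w = 1.0 / (ses ** 2 + tau2)

    blocks = []
    for pk in included:
        reg = registry[pk.region] if pk.region in registry else None
        blocks.append((reg.meta_block or "subcortical") if reg else "subcortical")
    blocks = np.asarray(blocks)
    if equal_blocks and np.unique(blocks).size > 1:
        # rescale so each block's total weight is equal
        for b in np.unique(blocks):
            mask = blocks == b
            w[mask] = w[mask] / w[mask].sum() / np.unique(blocks).size
    wn = w / w.sum()
    pooled = float(np.sum(wn * est))
    var = float(np.sum(wn ** 2 * (ses ** 2 + tau2)))
    se = float(np.sqrt(var))
    ci = (pooled - 1.96 * se, pooled + 1.96 * se)
    return MetaResult(pooled_h=pooled, se=se, ci=ci, tau2=float(tau2),
                      weights={pk.region: float(x) for pk, x in zip(included, wn)},
                      included=[pk.region for pk in included],
                      excluded=excluded, q=q)


def kmeans_curves(curves: pd.DataFrame, k: int = 3, seed: int = 0,
                  n_init: int = 50, normalized: bool = False) -> ClusterResult:
    """K-means clustering of regional sleep-profile curves.

    ``curves``: rows = regions, columns = grid points.  Each curve is
    first normalized to percent of its own maximum (pass
    ``normalized=True`` if already done).  Cluster ids are relabelled by
    descending cluster size so the labelling is stable across runs.
    """
    from sklearn.cluster import KMeans
    if k > len(curves):
        raise ValueError(f"k={k} exceeds number of regions {len(curves)}")
    M = curves.to_numpy(dtype=float)
    if not normalized:
        M = 100.0 * M / M.max(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(M)
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centroids = km.cluster_centers_[order]
    return ClusterResult(
        assignments=dict(zip(curves.index, (int(x) for x in labels))),
        centroids=centroids, k=k, inertia=float(km.inertia_))


def mega_vs_meta(table: pd.DataFrame, region: str,
                 registry: RegionRegistry | None = None,
                 min_cohort_n: int = 100, n_draws: int = 2000,
                 seed: int = 0, **fit_kw) -> dict:
    """Pooled-data fit vs per-cohort fits pooled by meta-analysis.

    Cohorts with fewer than ``min_cohort_n`` rows are excluded from the
    meta arm (logged).  Returns both peak estimates and their absolute
    difference.
    """
    registry = registry or default_registry()
    reg = registry[region]
    ages = table["age"].to_numpy(dtype=float)
    if ages.size > 500:
        ages = ages[:: max(1, ages.size // 500)]

    fits = fit_cross_models(table, reg, registry, **fit_kw)
    mega = peak_estimate(fits["additive"], reg, ages=ages,
                         n_draws=n_draws, seed=seed)

    cohort_peaks: list[PeakEstimate] = []
    skipped: dict[str, str] = {}
    for name, sub in table.groupby("cohort"):
        if len(sub) < min_cohort_n:
            skipped[str(name)] = f"n={len(sub)} below threshold {min_cohort_n}"
            continue
        cfits = fit_cross_models(sub, reg, registry, **fit_kw)
        a = sub["age"].to_numpy(dtype=float)
        if a.size > 500:
            a = a[:: max(1, a.size // 500)]
        pk = peak_estimate(cfits["additive"], reg, ages=a,
                           n_draws=n_draws, seed=seed)
        pk.region = f"{region}@{name}"
        cohort_peaks.append(pk)
    if len(cohort_peaks) == 1:
        meta_h = cohort_peaks[0].h_max
        meta = None
    else:
        usable = [pk for pk in cohort_peaks
                  if not pk.boundary_flag and np.isfinite(pk.se) and pk.se > 0]
        meta = pool_peaks_simple(usable)
        meta_h = meta.pooled_h
    return {
        "mega_h": mega.h_max,
        "meta_h": meta_h,
        "abs_diff": abs(mega.h_max - meta_h),
        "cohort_peaks": cohort_peaks,
        "meta": meta,
        "mega": mega,
        "skipped_cohorts": skipped,
    }


def pool_peaks_simple(peaks: list[PeakEstimate]) -> MetaResult:
    """Plain DL pooling without registry rules (per-cohort estimates of a
    single region have no block structure)."""
    if len(peaks) < 2:
        raise ValueError("need >= 2 estimates")
    est = np.array([pk.h_max for pk in peaks])
    ses = np.array([pk.se for pk in peaks])
    tau2, q = dersimonian_laird(est, ses)
    w = 1.0 / (ses ** 2 + tau2)
    wn = w / w.sum()
    pooled = float(np.sum(wn * est))
    se = float(np.sqrt(np.sum(wn ** 2 * (ses ** 2 + tau2))))
    return MetaResult(pooled_h=pooled, se=se,
                      ci=(pooled - 1.96 * se, pooled + 1.96 * se),
                      tau2=tau2, weights={pk.region: float(x)
                                          for pk, x in zip(peaks, wn)},
                      included=[pk.region for pk in peaks], excluded={}, q=q)
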