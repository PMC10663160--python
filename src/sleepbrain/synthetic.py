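"""Synthetic multi-cohort brain-structure / sleep data with known truth.

The generator emulates the structure of a multi-site lifespan MRI study:

* several cohorts with their own sample sizes, age ranges, follow-up
  schedules and site offsets (the shipped default configuration mirrors
  the printed per-cohort observation and participant tallies of the
  study design, scalable by a factor for fast tests);
* an inverted-U relationship between self-reported sleep duration and
  each regional measure, with a configurable true peak location
  ``h_star``, region-level heterogeneity of the peak, and inverted sign
  for ventricles (which expand rather than shrink);
* additive smooth age trajectories, cohort/site offsets, participant
  random intercepts and Gaussian residual noise, all in within-region
  standard-deviation units;
* an intracranial-volume column correlated with sleep duration, loading
  on the volumetric measures (head-size scaling);
* longitudinal change (atrophy) at a rate that may depend on sleep
  duration — zero dependence under the study's null;
* stratified GWAS summary statistics (per-SNP effect, SE, P, MAF,
  position) for the Mendelian-randomization module. Only summary
  statistics are simulated, never genotypes.

Sleep durations are drawn from a discretized distribution centred near
seven hours and reported in 0.5-hour increments, mimicking self-report
granularity.  Region-level peak offsets are drawn from N(0, tau^2) and
then centred to mean zero, so the ensemble-mean peak equals ``h_star``
exactly and meta-analytic recovery tests measure estimation error rather
than the luck of a handful of draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .registry import Region, RegionRegistry, default_registry

__all__ = [
    "CohortConfig", "TrueModel", "GwasSimConfig", "table1_configs",
    "generate_cohorts", "true_curve", "region_truth",
    "generate_mr_summary", "generate_strata_pair",
]


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """One cohort of the simulated study.

    ``n_cross``/``n_long`` are participant counts (longitudinal ones are a
    subset); ``n_obs_cross``/``n_obs_long`` are scan counts and default to
    one scan per cross-sectional participant and ``followups`` scans per
    longitudinal participant.  Surplus cross-sectional scans (some real
    tables count repeat scans that never enter longitudinal analysis) are
    assigned to cross-sectional participants flagged ``long_eligible=False``.
    """
    name: str
    n_cross: int
    n_long: int = 0
    age_range: tuple[float, float] = (20.0, 89.0)
    followups: int = 2
    interval_mean: float = 2.5
    interval_sd: float = 1.4
    site_offset: float | None = None   # None -> drawn N(0, 0.2)
    n_obs_cross: int | None = None
    n_obs_long: int | None = None

    def validate(self) -> None:
        if self.n_cross <= 0:
            raise ConfigurationError(f"{self.name}: n_cross must be positive")
        if not 0 <= self.n_long <= self.n_cross:
            raise ConfigurationError(f"{self.name}: n_long must be in [0, n_cross]")
        if self.n_long > 0 and self.followups < 2:
            raise ConfigurationError(f"{self.name}: followups must be >= 2")
        lo, hi = self.age_range
        if not (20.0 <= lo < hi <= 90.0):
            raise ConfigurationError(f"{self.name}: age_range must lie within [20, 90]")
        if self.interval_mean <= 0 or self.interval_sd < 0:
            raise ConfigurationError(f"{self.name}: interval_mean/interval_sd invalid")
        no_l = self.obs_long
        if self.n_long and no_l < 2 * self.n_long:
            raise ConfigurationError(
                f"{self.name}: n_obs_long must allow >= 2 scans per longitudinal participant")
        if self.obs_cross < (self.n_cross - self.n_long) + no_l:
            raise ConfigurationError(f"{self.name}: n_obs_cross below implied minimum")

    @property
    def obs_long(self) -> int:
        return self.n_obs_long if self.n_obs_long is not None else self.followups * self.n_long

    @property
    def obs_cross(self) -> int:
        if self.n_obs_cross is not None:
            return self.n_obs_cross
        return (self.n_cross - self.n_long) + self.obs_long


@dataclass(frozen=True)
class TrueModel:
    """Generative ground truth shared by all cohorts.

    Units: regional measures are in within-region SD units; sleep in
    hours; time in years.  ``curvature`` is the second derivative of the
    sleep curve at its vertex (negative for the inverted U of volumes and
    thickness; the sign is flipped internally for ventricles).
    ``atrophy_rate`` maps sleep hours to additional annual change; None
    means no sleep dependence (the longitudinal null).
    """
    h_star: float = 6.5
    curvature: float = -0.35
    age_slope: float = 0.25          # SD decline per decade at midlife
    atrophy_rate: Callable[[np.ndarray], np.ndarray] | None = None
    atrophy_base: float = -0.05      # SD/year drift (sign flipped for ventricles)
    sigma_resid: float = 1.0
    sigma_intercept: float = 0.5
    tau_region: float = 0.0
    icv_sleep_corr: float = 0.0
    icv_loading: float = 0.3
    sex_effect: float = 0.25
    sleep_mean: float = 7.0
    sleep_sd: float = 1.1

    def validate(self) -> None:
        if self.sigma_resid < 0 or self.sigma_intercept < 0:
            raise ConfigurationError("sigma_resid/sigma_intercept must be >= 0")
        if not 4.0 <= self.h_star <= 10.0:
            raise ConfigurationError("h_star must lie in [4, 10]")
        if self.tau_region < 0:
            raise ConfigurationError("tau_region must be >= 0")
        if not -1.0 < self.icv_sleep_corr < 1.0:
            raise ConfigurationError("icv_sleep_corr must be in (-1, 1)")


@dataclass(frozen=True)
class GwasSimConfig:
    """Stratified GWAS summary-statistic simulation settings."""
    n_snps: int = 5000
    n_causal: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_sd: float = 0.02
    causal_effect: float = 0.0
    strata_flip: bool = False
    se_model: Callable[[np.ndarray, float], np.ndarray] | None = None
    palindromic_frac: float = 0.0
    n_chr: int = 22

    def validate(self) -> None:
        if not 0 <= self.n_causal <= self.n_snps:
            raise ConfigurationError("n_causal must be in [0, n_snps]")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.n_causal == 0 and self.causal_effect != 0.0:
            raise ConfigurationError(
                "causal_effect nonzero requires n_causal > 0")


# Per-cohort (observations cross/long, participants cross/long, age range)
# matching the printed sample table of the study design.
_TABLE1 = [
    # name,        obs_c, obs_l, n_c,   n_l,   age lo, age hi, followups
    ("HCP",          974,     0,   974,     0, 22.0, 37.0, 2),
    ("BASE-II",      675,   568,   391,   284, 24.0, 83.0, 2),
    ("Barcelona",    113,   112,    39,    38, 64.0, 81.0, 3),
    ("Cam-CAN",      884,   504,   632,   252, 20.0, 88.0, 2),
    ("LCBC",        1474,  1011,   803,   340, 20.0, 89.0, 3),
    ("UKB",        45983,  5692, 43137,  2846, 45.0, 83.0, 2),
    ("Betula",       423,   266,   284,   133, 25.0, 85.0, 2),
    ("Whitehall-II", 769,     0,   769,     0, 60.0, 85.0, 2),
]


def table1_configs(scale: float = 1.0) -> list[CohortConfig]:
    """The default multi-cohort configuration, scalable for fast tests.

    At ``scale=1`` the generated table reproduces the printed tallies
    exactly: 51,295 scans from 47,029 participants, of which 8,153 scans
    from 3,893 longitudinal participants.
    """
    if scale <= 0:
        raise ConfigurationError("scale must be positive")
    out = []
    for name, oc, ol, nc, nl, lo, hi, fu in _TABLE1:
        n_l = max(int(round(nl * scale)), 1 if nl and scale >= 0.01 else 0)
        n_c = max(int(round(nc * scale)), n_l, 1)
        o_l = max(int(round(ol * scale)), 2 * n_l)
        o_c = max(int(round(oc * scale)), (n_c - n_l) + o_l)
        if n_c == n_l:
            # no cross-only participants to carry surplus repeat scans
            o_c = o_l
        out.append(CohortConfig(
            name=name, n_cross=n_c, n_long=n_l, age_range=(lo, hi),
            followups=max(fu, 2), n_obs_cross=o_c, n_obs_long=o_l))
    return out


# ---------------------------------------------------------------------------
# Ground-truth curves
# ---------------------------------------------------------------------------

def _region_sign(region: Region) -> float:
    return -1.0 if region.direction == "minimize" else 1.0


def _is_monotone(region: Region) -> bool:
    # corpus-callosum-like regions: monotone sleep relation, no interior peak
    return region.name.startswith("CC ")


def _sleep_curve(model: TrueModel, region: Region, h_star_r: float,
                 sleep: np.ndarray) -> np.ndarray:
    if _is_monotone(region):
        return 0.08 * (sleep - model.sleep_mean)
    sgn = _region_sign(region)
    return sgn * 0.5 * model.curvature * (sleep - h_star_r) ** 2


def _age_curve(model: TrueModel, region: Region, age: np.ndarray) -> np.ndarray:
    z = (np.asarray(age, dtype=float) - 50.0) / 10.0
    # cubic curvature scales with the slope so age_slope=0 removes the trend
    decline = -model.age_slope * (z + 0.2 * z ** 3)
    return _region_sign(region) * decline


def true_curve(model: TrueModel, region: Region,
               grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth sleep profile of a region on a grid of hours.

    Returns ``(grid, values)``.  The curve has a single interior optimum
    at ``h_star`` (vertex of the quadratic) except for corpus-callosum-
    like regions, which are monotone by design.
    """
    if grid is None:
        grid = np.arange(4.0, 10.0 + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    return grid, _sleep_curve(model, region, model.h_star, grid)


def region_truth(model: TrueModel, regions: Sequence[Region],
                 seed: int) -> pd.DataFrame:
    """Per-region true peak locations (h_star plus centred heterogeneity)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 911]))
    k = len(regions)
    if model.tau_region > 0 and k > 1:
        d = rng.normal(0.0, model.tau_region, k)
        d -= d.mean()
    else:
        d = np.zeros(k)
    h = np.clip(model.h_star + d, 4.2, 9.8)
    return pd.DataFrame({
        "region": [r.name for r in regions],
        "h_star": h,
        "direction": [r.direction for r in regions],
        "monotone": [_is_monotone(r) for r in regions],
    })


# ---------------------------------------------------------------------------
# Observation-table generator
# ---------------------------------------------------------------------------

_PSQI_P = np.array([
    [0.55, 0.25, 0.15, 0.05],   # subjective quality
    [0.50, 0.30, 0.15, 0.05],   # latency
    [0.00, 0.00, 0.00, 0.00],   # duration (deterministic from hours)
    [0.60, 0.25, 0.10, 0.05],   # efficiency
    [0.45, 0.35, 0.15, 0.05],   # disturbances
    [0.80, 0.10, 0.07, 0.03],   # medication
    [0.55, 0.30, 0.10, 0.05],   # daytime dysfunction
])


def _psqi_duration_component(hours: np.ndarray) -> np.ndarray:
    comp = np.zeros(hours.shape, dtype=int)
    comp[hours < 7] = 1
    comp[hours < 6] = 2
    comp[hours < 5] = 3
    return comp


def generate_cohorts(configs: Sequence[CohortConfig], model: TrueModel,
                     seed: int,
                     registry: RegionRegistry | None = None,
                     regions: Sequence[str] | None = None) -> pd.DataFrame:
    """Generate the long-format observation table (one row per scan).

    Regional measures are ``age trend + sleep curve + atrophy x time +
    site offset + ICV loading + sex effect + participant intercept +
    noise`` in SD units.  The drawn per-region truth is attached as
    ``df.attrs['truth']`` for testing.
    """
    if not configs:
        raise ConfigurationError("configs must be non-empty")
    for c in configs:
        c.validate()
    model.validate()
    if registry is None:
        registry = default_registry()
    region_objs = ([registry[name] for name in regions] if regions is not None
                   else list(registry))
    truth = region_truth(model, region_objs, seed)
    h_star_map = dict(zip(truth["region"], truth["h_star"]))

    ss = np.random.SeedSequence([int(seed), 7001])
    child = ss.spawn(len(configs) + 1)
    site_rng = np.random.default_rng(child[-1])

    frames = []
    for ci, cfg in enumerate(configs):
        rng = np.random.default_rng(child[ci])
        n_part = cfg.n_cross
        n_long = cfg.n_long
        singles = n_part - n_long
        extra = cfg.obs_cross - singles - cfg.obs_long

        # scans per participant: longitudinal first, then cross-sectional
        scans = np.ones(n_part, dtype=int)
        if n_long:
            scans[:n_long] = 2
            # distribute remaining follow-up scans round-robin
            rem = cfg.obs_long - 2 * n_long
            for i in range(rem):
                scans[i % n_long] += 1
        # surplus repeat scans on cross-sectional participants
        if extra > 0 and singles == 0:
            raise ConfigurationError(
                f"{cfg.name}: n_obs_cross implies repeat scans but there "
                "are no cross-sectional-only participants to carry them")
        for j in range(extra):
            scans[n_long + (j % singles)] += 1

        long_flag = np.zeros(n_part, dtype=bool)
        long_flag[:n_long] = True

        offset = (cfg.site_offset if cfg.site_offset is not None
                  else float(site_rng.normal(0.0, 0.2)))

        # participant-level draws
        lo, hi = cfg.age_range
        age_bl = rng.uniform(lo, hi, n_part)
        sex = np.where(rng.random(n_part) < 0.53, "female", "male")
        z_sleep = rng.standard_normal(n_part)
        sleep_cont = model.sleep_mean + model.sleep_sd * z_sleep
        sleep = np.clip(np.round(sleep_cont * 2.0) / 2.0, 3.5, 11.0)
        rho = model.icv_sleep_corr
        z_icv = rho * z_sleep + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n_part)
        icv = z_icv + 0.6 * (sex == "male")
        intercepts = rng.normal(0.0, model.sigma_intercept, n_part)

        # weakly sleep-correlated covariates (SES, BMI, depression)
        def corr_noise(r):
            return r * z_sleep + np.sqrt(1 - r ** 2) * rng.standard_normal(n_part)
        education = np.clip(np.round(12 + 3 * corr_noise(0.02)), 7, 22)
        income = np.clip(np.round(5 + 2 * corr_noise(-0.02)), 1, 10)
        bmi = 26 + 4 * corr_noise(-0.04)
        depression = np.clip(5 + 4 * corr_noise(-0.06), 0, None)

        # PSQI components: six generic + duration-derived component
        psqi = np.zeros((n_part, 7), dtype=int)
        for c_idx in range(7):
            if c_idx == 2:
                psqi[:, c_idx] = _psqi_duration_component(sleep)
            else:
                psqi[:, c_idx] = rng.choice(4, size=n_part, p=_PSQI_P[c_idx])

        # expand to scans
        idx = np.repeat(np.arange(n_part), scans)
        n_obs = idx.size
        t = np.zeros(n_obs)
        order = np.zeros(n_obs, dtype=int)
        pos = 0
        intervals = np.clip(
            rng.normal(cfg.interval_mean, cfg.interval_sd, n_obs), 0.25, None)
        for pi in range(n_part):
            k = scans[pi]
            if k > 1:
                t[pos + 1: pos + k] = np.cumsum(intervals[pos + 1: pos + k])
            order[pos: pos + k] = np.arange(k)
            pos += k

        df = pd.DataFrame({
            "cohort": cfg.name,
            "site": cfg.name,
            "participant": [f"{cfg.name}-{i:06d}" for i in idx],
            "scan": order,
            "long_eligible": long_flag[idx],
            "sex": sex[idx],
            "age_bl": age_bl[idx],
            "time": t,
            "sleep": sleep[idx],
            "education": education[idx],
            "income": income[idx],
            "bmi": bmi[idx],
            "depression": depression[idx],
            "icv": icv[idx],
        })
        df["age"] = df["age_bl"] + df["time"]
        for c_idx in range(7):
            df[f"psqi_c{c_idx + 1}"] = psqi[idx, c_idx]

        # regional measures
        for reg in region_objs:
            sgn = _region_sign(reg)
            val = _age_curve(model, reg, df["age"].to_numpy())
            val = val + _sleep_curve(model, reg, h_star_map[reg.name],
                                     df["sleep"].to_numpy())
            rate = sgn * model.atrophy_base
            if model.atrophy_rate is not None:
                rate = rate + model.atrophy_rate(df["sleep"].to_numpy())
            val = val + rate * t
            val = val + offset + intercepts[idx]
            if reg.uses_icv:
                val = val + model.icv_loading * icv[idx]
            if reg.name == "ICV":
                val = icv[idx] + offset
            val = val + model.sex_effect * sgn * (sex[idx] == "male")
            val = val + rng.normal(0.0, model.sigma_resid, n_obs)
            df[registry.column_name(reg.name)] = val
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    # plain records, not a DataFrame: attrs must stay concat-friendly
    out.attrs["truth"] = truth.to_dict("records")
    out.attrs["seed"] = int(seed)
    return out


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_ALLELES = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("C", "G")]


def _default_se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _snp_frame(rng, cfg: GwasSimConfig):
    n = cfg.n_snps
    chrom = rng.integers(1, cfg.n_chr + 1, n)
    pos = rng.integers(1, 250_000_000, n)
    maf = rng.uniform(*cfg.maf_range, n)
    pal = rng.random(n) < cfg.palindromic_frac
    pairs = [(_PALINDROMIC if p else _ALLELES)[rng.integers(0, 2 if p else 4)]
             for p in pal]
    ea = np.array([a for a, _ in pairs])
    oa = np.array([b for _, b in pairs])
    return pd.DataFrame({
        "snp": [f"rs{i + 1:07d}" for i in range(n)],
        "chr": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "maf": maf,
    })


def _observe(base: pd.DataFrame, beta_true: np.ndarray, n_sample: int,
             cfg: GwasSimConfig, rng) -> pd.DataFrame:
    from scipy import stats
    se_fn = cfg.se_model or _default_se
    se = se_fn(base["maf"].to_numpy(), float(n_sample))
    beta = beta_true + rng.normal(0.0, se)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    out = base.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n_sample
    return out


def generate_mr_summary(config: GwasSimConfig, n_exposure: int, n_outcome: int,
                        seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample GWAS summary statistics for exposure and outcome.

    The exposure and outcome samples use independent random streams
    (non-overlapping samples); causal SNPs act on the outcome only
    through the exposure: beta_out_true = causal_effect * beta_exp_true.
    """
    config.validate()
    ss = np.random.SeedSequence([int(seed), 5107])
    r_map, r_exp, r_out = (np.random.default_rng(c) for c in ss.spawn(3))
    base = _snp_frame(r_map, config)
    beta_true = np.zeros(config.n_snps)
    if config.n_causal:
        causal = r_map.choice(config.n_snps, config.n_causal, replace=False)
        beta_true[causal] = r_map.normal(0.0, config.beta_sd, config.n_causal)
    exp_df = _observe(base, beta_true, n_exposure, config, r_exp)
    out_df = _observe(base, config.causal_effect * beta_true, n_outcome,
                      config, r_out)
    exp_df.attrs["beta_true"] = beta_true
    return exp_df, out_df


def generate_strata_pair(config: GwasSimConfig, n_stratum1: int,
                         n_stratum2: int, seed: int
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure summary statistics in two phenotype strata.

    With ``strata_flip`` the second stratum's true effects have opposite
    signs (genes pushing the phenotype up below the split push it down
    above the split), yielding negatively correlated per-SNP effects.
    """
    config.validate()
    ss = np.random.SeedSequence([int(seed), 5211])
    r_map, r1, r2 = (np.random.default_rng(c) for c in ss.spawn(3))
    base = _snp_frame(r_map, config)
    beta_true = np.zeros(config.n_snps)
    if config.n_causal:
        causal = r_map.choice(config.n_snps, config.n_causal, replace=False)
        beta_true[causal] = r_map.normal(0.0, config.beta_sd, config.n_causal)
    s1 = _observe(base, beta_true, n_stratum1, config, r1)
    sign = -1.0 if config.strata_flip else 1.0
    s2 = _observe(base, sign * beta_true, n_stratum2, config, r2)
    return s1, s2
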