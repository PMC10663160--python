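"""Two-sample Mendelian randomization on GWAS summary statistics.

Instrument selection follows the conventional genome-wide screen:
association P below a threshold (1e-6 by default), minor-allele
frequency at least 0.05, then greedy LD pruning by ascending P — a SNP
is dropped when it lies within a distance window (10 kb) of an already
kept SNP on the same chromosome and their r^2 exceeds 0.1.  Without an
r^2 table, pruning is distance-only (any pair within the window counts
as linked), a conservative fallback for synthetic data without a
realistic LD reference.

The causal estimate is the fixed-effect inverse-variance-weighted (IVW)
combination of per-SNP Wald ratios beta_out/beta_exp with weights
beta_exp^2/se_out^2 — algebraically the weighted regression of outcome
on exposure effects through the origin.  Per-SNP instrument strength is
F = (beta_exp/se_exp)^2.  ``bidirectional_mr`` runs both causal
directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MrResult", "select_instruments", "harmonize", "ivw",
           "bidirectional_mr", "EmptyInstrumentSet"]

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


class EmptyInstrumentSet(RuntimeError):
    pass


@dataclass
class MrResult:
    beta_ivw: float
    se: float
    p: float
    n_instruments: int
    min_F: float
    per_snp_ratios: pd.DataFrame
    direction: str = ""
    status: str = "ok"


def select_instruments(stats_df: pd.DataFrame, p_thresh: float = 1e-6,
                       maf_min: float = 0.05, r2_max: float = 0.1,
                       dist_kb: float = 10.0,
                       ld: pd.DataFrame | None = None) -> pd.DataFrame:
    """Independent instrumental SNPs passing P/MAF filters and LD pruning.

    ``ld``: optional frame with columns snp1, snp2, r2 (pairs absent from
    the table are treated as unlinked).  Result order is by ascending P
    regardless of input order.
    """
    if stats_df.empty:
        raise ValueError("empty summary statistics")
    cand = stats_df[(stats_df["p"] <= p_thresh) &
                    (stats_df["maf"] >= maf_min)].copy()
    cand = cand.sort_values(["p", "snp"], kind="stable")
    if cand.empty:
        out = cand
        out.attrs["status"] = "empty: no SNP passed the P/MAF filters"
        return out

    r2_lookup: dict[frozenset, float] = {}
    if ld is not None:
        for s1, s2, r2 in ld[["snp1", "snp2", "r2"]].itertuples(index=False):
            r2_lookup[frozenset((s1, s2))] = float(r2)

    kept_rows = []
    kept_pos: dict = {}
    for row in cand.itertuples(index=False):
        drop = False
        for other in kept_pos.get(row.chr, []):
            if abs(row.pos - other.pos) <= dist_kb * 1000:
                if ld is None:
                    drop = True  # distance-only fallback
                else:
                    r2 = r2_lookup.get(frozenset((row.snp, other.snp)), 0.0)
                    drop = r2 > r2_max
                if drop:
                    break
        if not drop:
            kept_rows.append(row)
            kept_pos.setdefault(row.chr, []).append(row)
    out = pd.DataFrame(kept_rows, columns=cand.columns)
    out.attrs["status"] = "ok" if len(out) else "empty: all candidates pruned"
    return out


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              drop_palindromic: bool = True) -> pd.DataFrame:
    """Join exposure and outcome rows per SNP with aligned effect alleles.

    When the outcome's effect allele is the exposure's other allele, the
    outcome effect sign is flipped.  SNPs with incompatible allele pairs
    are dropped; palindromic SNPs (A/T, C/G) are dropped by default
    since strand cannot be resolved from summary data alone.
    """
    m = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    rows = []
    for r in m.itertuples(index=False):
        pair_exp = frozenset((r.effect_allele_exp, r.other_allele_exp))
        pair_out = frozenset((r.effect_allele_out, r.other_allele_out))
        if pair_exp != pair_out:
            continue
        if drop_palindromic and pair_exp in _PALINDROMIC:
            continue
        flip = r.effect_allele_out != r.effect_allele_exp
        rows.append({
            "snp": r.snp, "chr": r.chr_exp, "pos": r.pos_exp,
            "beta_exp": r.beta_exp, "se_exp": r.se_exp,
            "beta_out": -r.beta_out if flip else r.beta_out,
            "se_out": r.se_out,
        })
    return pd.DataFrame(rows)


def ivw(harmonized: pd.DataFrame, direction: str = "",
        random_effects: bool = False) -> MrResult:
    """Inverse-variance-weighted causal estimate.

    Fixed-effect by default; ``random_effects`` applies the
    multiplicative over-dispersion correction (SE scaled by
    sqrt(max(1, Q/(k-1)))).
    """
    h = harmonized[np.isfinite(harmonized["beta_exp"]) &
                   (harmonized["beta_exp"] != 0.0)].copy()
    n_dropped = len(harmonized) - len(h)
    if n_dropped:
        import warnings
        warnings.warn(f"dropped {n_dropped} instruments with zero exposure effect")
    if h.empty:
        raise EmptyInstrumentSet("no usable instruments for IVW")
    bx = h["beta_exp"].to_numpy(dtype=float)
    by = h["beta_out"].to_numpy(dtype=float)
    so = h["se_out"].to_numpy(dtype=float)
    w = bx ** 2 / so ** 2
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if random_effects and len(h) > 1:
        q = float(np.sum(w * (ratios - beta) ** 2))
        se *= float(np.sqrt(max(1.0, q / (len(h) - 1))))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    h["wald_ratio"] = ratios
    h["F"] = (h["beta_exp"] / h["se_exp"]) ** 2
    return MrResult(beta_ivw=beta, se=se, p=p, n_instruments=len(h),
                    min_F=float(h["F"].min()), per_snp_ratios=h,
                    direction=direction)


def bidirectional_mr(exposure_stats: pd.DataFrame,
                     outcome_stats: pd.DataFrame,
                     labels: tuple[str, str] = ("exposure", "outcome"),
                     p_thresh: float = 1e-6, maf_min: float = 0.05,
                     r2_max: float = 0.1, dist_kb: float = 10.0,
                     ld: pd.DataFrame | None = None,
                     drop_palindromic: bool = True) -> dict[str, MrResult]:
    """IVW in both causal directions.

    Returns a dict with exactly two entries keyed "A->B" and "B->A"
    (A, B from ``labels``); a direction without usable instruments is
    reported with status "not_estimable" rather than raised.
    """
    a, b = labels
    out: dict[str, MrResult] = {}
    for key, exp_df, out_df in ((f"{a}->{b}", exposure_stats, outcome_stats),
                                (f"{b}->{a}", outcome_stats, exposure_stats)):
        inst = select_instruments(exp_df, p_thresh=p_thresh, maf_min=maf_min,
                                  r2_max=r2_max, dist_kb=dist_kb, ld=ld)
        if inst.empty:
            out[key] = MrResult(np.nan, np.nan, np.nan, 0, np.nan,
                                pd.DataFrame(), direction=key,
                                status="not_estimable: " + inst.attrs["status"])
            continue
        h = harmonize(inst, out_df, drop_palindromic=drop_palindromic)
        if h.empty:
            out[key] = MrResult(np.nan, np.nan, np.nan, 0, np.nan,
                                pd.DataFrame(), direction=key,
                                status="not_estimable: no harmonizable instruments")
            continue
        res = ivw(h, direction=key)
        out[key] = res
    return out
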