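#!/usr/bin/env python
"""Meta-analysis of regional peaks, curve clustering, mega vs meta.

Pools the per-region sleep-at-peak estimates with equal cortex/subcortex
weighting (DerSimonian-Laird random effects), with and without the ICV
covariate; clusters the normalized regional curves into three families;
and compares the pooled-data fit with per-cohort fits pooled afterwards.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sleepbrain import meta as meta_mod
from sleepbrain.crosssectional import PeakEstimate
from sleepbrain.registry import default_registry

OUT = Path(__file__).resolve().parents[1] / "results"


def load_peaks(path):
    df = pd.read_csv(path, sep="\t")
    return [PeakEstimate(region=r.region, h_max=r.h_max, se=r.se,
                         ci=(r.ci_low, r.ci_high),
                         boundary_flag=bool(r.boundary))
            for r in df.itertuples(index=False)]


def main() -> None:
    registry = default_registry()
    rows = []
    for label, path in (("with_icv", OUT / "peaks.tsv"),
                        ("without_icv", OUT / "peaks_no_icv.tsv")):
        res = meta_mod.pool_peaks(load_peaks(path), registry)
        rows.append({"analysis": label, "pooled_h": round(res.pooled_h, 3),
                     "se": round(res.se, 3),
                     "ci_low": round(res.ci[0], 3),
                     "ci_high": round(res.ci[1], 3),
                     "tau2": round(res.tau2, 4),
                     "n_included": len(res.included),
                     "excluded": "; ".join(f"{k} ({v})"
                                           for k, v in res.excluded.items())})
        print(f"{label}: pooled peak {res.pooled_h:.2f} h "
              f"(95% CI {res.ci[0]:.2f}-{res.ci[1]:.2f}), "
              f"tau2 {res.tau2:.3f}, {len(res.included)} regions")
    pd.DataFrame(rows).to_csv(OUT / "meta.tsv", sep="\t", index=False)

    curves = pd.read_csv(OUT / "curves.tsv", sep="\t", index_col=0)
    # cluster the cortical thickness curves (volumetric profiles include
    # inverted ventricle and monotone corpus-callosum shapes)
    cortical = [r.name for r in registry.cortical() if r.name in curves.index]
    curves = curves.loc[cortical]
    # percent-of-own-maximum normalization; shift positive before scaling
    M = curves.to_numpy()
    M = M - M.min(axis=1, keepdims=True) + 1.0
    norm = pd.DataFrame(100 * M / M.max(axis=1, keepdims=True),
                        index=curves.index, columns=curves.columns)
    res = meta_mod.kmeans_curves(norm, k=3, seed=0, normalized=True)
    pd.DataFrame({"region": list(res.assignments),
                  "cluster": list(res.assignments.values())}
                 ).to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    sizes = np.bincount(list(res.assignments.values()))
    print(f"3 curve clusters with sizes {sizes.tolist()}, "
          f"inertia {res.inertia:.1f}")

    df = pd.read_csv(OUT / "clean.tsv", sep="\t")
    cmp = meta_mod.mega_vs_meta(df, "Hippocampus", registry,
                                min_cohort_n=60, n_draws=1500, seed=3,
                                tol=1e-4)
    print(f"mega {cmp['mega_h']:.2f} h vs meta {cmp['meta_h']:.2f} h "
          f"(|diff| {cmp['abs_diff']:.3f} h; "
          f"{len(cmp['cohort_peaks'])} cohorts, "
          f"{len(cmp['skipped_cohorts'])} skipped)")
    pd.DataFrame([{"mega_h": cmp["mega_h"], "meta_h": cmp["meta_h"],
                   "abs_diff": cmp["abs_diff"]}]
                 ).to_csv(OUT / "mega_vs_meta.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
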