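#!/usr/bin/env python
"""Build the analysis-ready table.

Computes the global sleep-quality score (duration component excluded),
averages repeated sleep reports per participant, and removes per-region
outliers (|residual| > 4x RSE from an age-effect spline fit).  The
removal log is written as an audit file.
"""

from pathlib import Path

import pandas as pd

from sleepbrain import preprocess as prep
from sleepbrain.pipeline import add_sleep_quality
from sleepbrain.registry import default_registry

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    registry = default_registry()
    df = pd.read_csv(OUT / "observations.tsv", sep="\t")
    df = add_sleep_quality(df)
    df = prep.average_sleep(df)
    logs = []
    for reg in registry:
        col = registry.column_name(reg.name)
        if col not in df.columns:
            continue
        df, log = prep.remove_outliers(df, reg, registry)
        logs.append({"region": log.region, "n_before": log.n_before,
                     "n_removed": log.n_removed, "rse": round(log.rse, 4)})
    audit = pd.DataFrame(logs)
    df.to_csv(OUT / "clean.tsv", sep="\t", index=False)
    audit.to_csv(OUT / "outlier_log.tsv", sep="\t", index=False)
    print(f"clean table: {len(df)} rows; removed "
          f"{audit['n_removed'].sum()} outlier rows across "
          f"{len(audit)} regions")


if __name__ == "__main__":
    main()
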