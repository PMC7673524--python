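#!/usr/bin/env python
"""Group statistics on the extracted feature table.

ROI-averaged contrasts between tinnitus and control subjects: pooled
independent t-tests on seed connectivity (per seed side, ROI and
chromophore) and on auditory/visual evoked window means, a paired
left-vs-right auditory comparison, and OLS severity regressions of the
significant features on THI, age, duration, hearing thresholds,
loudness and annoyance within the tinnitus group.
"""

import warnings
from pathlib import Path

import pandas as pd

from tinnirs.pipeline import roi_summary_features
from tinnirs.stats import group_ttests, severity_regression

OUT = Path(__file__).parent.parent / "results"


def main() -> None:
    table = pd.read_csv(OUT / "features.csv")
    summary = roi_summary_features(table)
    feats = [c for c in summary.columns if c.startswith(("aud_", "vis_", "conn_"))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ttests = group_ttests(
            summary, feats,
            paired_pairs=[("aud_left_vs_right_HbO",
                           "aud_left_temporal_HbO", "aud_right_temporal_HbO")],
        )
        sig = ttests[(ttests.p < 0.05) & (ttests.kind == "independent")]
        reg = severity_regression(summary, list(sig.contrast) or feats[:4])

    ttests.to_csv(OUT / "group_ttests.csv", index=False)
    reg.to_csv(OUT / "severity_regression.csv", index=False)

    print("group contrasts (control minus tinnitus, pooled t):")
    for row in ttests.itertuples():
        flag = " *" if row.p < 0.05 else ""
        print(f"  {row.contrast:32s} t({row.df}) = {row.t:+.3f}, p = {row.p:.3f}{flag}")
    if len(reg):
        print("severity regressions (tinnitus group) with p < 0.1:")
        for row in reg[reg.p < 0.1].itertuples():
            print(f"  {row.feature} ~ {row.covariate}: "
                  f"beta = {row.beta:+.4f} (SE {row.se:.4f}), p = {row.p:.3f}")


if __name__ == "__main__":
    main()
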