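"""Group statistics: t-tests and severity regressions.

Group contrasts use pooled-variance independent-sample t-tests
(df = n1 + n2 - 2); bilateral auditory amplitudes are compared between
hemispheres with paired t-tests.  Relationships between connectivity /
evoked features and tinnitus severity measures (THI, age, duration,
high-frequency hearing thresholds, loudness, annoyance) are estimated
with ordinary least-squares multiple regression within the tinnitus
group.  P-values are reported uncorrected by default; a
Benjamini-Hochberg column can be added on request and is flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

SEVERITY_COVARIATES = (
    "thi", "age", "duration_years", "hearing_4k", "hearing_8k", "loudness", "annoyance"
)


def group_ttests(
    table: pd.DataFrame,
    features: list[str],
    group_col: str = "group",
    positive: str = "tinnitus",
    paired_pairs: list[tuple[str, str, str]] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Pooled independent t-tests per feature, plus optional paired contrasts.

    ``paired_pairs`` entries are ``(contrast_name, column_a, column_b)``
    compared within-subject.  Contrasts are control-minus-positive, so a
    higher value in the positive (tinnitus) group gives a negative t.
    """
    rows = []
    groups = table[group_col]
    a = table[groups != positive]
    b = table[groups == positive]
    for feat in features:
        x = a[feat].dropna().to_numpy()
        y = b[feat].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        if x.std() == 0 and y.std() == 0:
            rows.append({"contrast": feat, "kind": "independent", "t": np.nan,
                         "df": len(x) + len(y) - 2, "p": np.nan, "note": "zero variance"})
            continue
        t, p = ss.ttest_ind(x, y, equal_var=True)
        rows.append({"contrast": feat, "kind": "independent", "t": float(t),
                     "df": len(x) + len(y) - 2, "p": float(p), "note": ""})
    for name, col_a, col_b in paired_pairs or []:
        sub = table[[col_a, col_b]].dropna()
        t, p = ss.ttest_rel(sub[col_a], sub[col_b])
        rows.append({"contrast": name, "kind": "paired", "t": float(t),
                     "df": len(sub) - 1, "p": float(p), "note": ""})
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        ok = out.p.notna()
        out["p_bh"] = np.nan
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out.attrs["correction"] = "benjamini-hochberg"
    return out


def severity_regression(
    table: pd.DataFrame,
    features: list[str],
    covariates: tuple[str, ...] = SEVERITY_COVARIATES,
    group_col: str = "group",
    group: str = "tinnitus",
) -> pd.DataFrame:
    """OLS multiple regression of each feature on the severity covariates.

    Fitted within the tinnitus group only.  Zero-variance covariates are
    excluded with a warning; an ill-conditioned design raises a
    condition-number warning.
    """
    sub = table[table[group_col] == group]
    usable = []
    for cov in covariates:
        if cov not in sub.columns:
            continue
        if sub[cov].std(ddof=0) == 0 or sub[cov].isna().all():
            warnings.warn(f"covariate {cov!r} has zero variance; excluded")
            continue
        usable.append(cov)
    if not usable:
        raise ValueError("no usable covariates")
    rows = []
    for feat in features:
        data = sub[[feat, *usable]].dropna()
        if len(data) <= len(usable) + 1:
            continue
        design = sm.add_constant(data[list(usable)])
        model = sm.OLS(data[feat], design).fit()
        if model.condition_number > 1e6:
            warnings.warn(
                f"ill-conditioned design for {feat} (cond={model.condition_number:.2g})"
            )
        for cov in usable:
            rows.append({
                "feature": feat, "covariate": cov,
                "beta": float(model.params[cov]), "se": float(model.bse[cov]),
                "p": float(model.pvalues[cov]), "n": len(data),
            })
    return pd.DataFrame(rows)
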