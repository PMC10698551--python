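"""Two-rater reliability filtering of radiomics features.

Features are retained when their intraclass correlation across the two
raters' delineations exceeds 0.75 (strict inequality). The default ICC form
is ICC(2,1) — two-way random effects, absolute agreement, single rater —
so a systematic delineation bias between raters penalizes agreement;
ICC(3,1) (consistency) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ICCReport:
    feature_name: str
    icc: float
    retained: bool


def icc_two_rater(values_a, values_b, form: str = "ICC2") -> float:
    """ICC of one feature measured by two raters on the same lesions.

    Computed from the two-way ANOVA mean-squares decomposition with n
    subjects and k=2 raters. Returns NaN when the total variance is zero
    (undefined reliability; treated downstream as "not retained").
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length 1D arrays")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 lesions")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    data = np.stack([a, b], axis=1)  # n x k
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        return float("nan")
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def filter_features(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    threshold: float = 0.75,
                    form: str = "ICC2") -> tuple[pd.DataFrame, list[ICCReport]]:
    """Keep the columns of ``table_a`` whose two-rater ICC exceeds ``threshold``.

    Both tables must share lesions (index) and feature columns; non-feature
    columns (``class``) are carried through. The report covers every
    feature, including dropped ones.
    """
    meta = [c for c in table_a.columns if c == "class"]
    feats_a = [c for c in table_a.columns if c not in meta]
    feats_b = [c for c in table_b.columns if c != "class"]
    if feats_a != feats_b:
        raise ValueError("tables have mismatched feature registries")
    if not table_a.index.equals(table_b.index):
        raise ValueError("tables must cover the same lesions in the same order")
    reports: list[ICCReport] = []
    keep: list[str] = []
    for name in feats_a:
        icc = icc_two_rater(table_a[name].to_numpy(), table_b[name].to_numpy(), form=form)
        # strict inequality; ICC == 1 (bit-identical columns) always passes,
        # which keeps a threshold of exactly 1.0 meaningful
        retained = bool(np.isfinite(icc) and (icc > threshold or icc >= 1.0))
        reports.append(ICCReport(feature_name=name, icc=icc, retained=retained))
        if retained:
            keep.append(name)
    return table_a[meta + keep], reports


def report_frame(reports: list[ICCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature": [r.feature_name for r in reports],
         "icc": [r.icc for r in reports],
         "retained": [r.retained for r in reports]}
    )
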