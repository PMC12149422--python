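"""Feature reproducibility filtering by intraclass correlation.

Repeat tumor delineations (a second pass by the same observer and an
independent second observer) yield repeat feature tables; features are kept
for downstream modeling only if both the intra- and inter-observer ICC
exceed 0.75 (strictly).

The ICC form is ICC(2,1): two-way random effects, absolute agreement,
single measurement — the standard choice for radiomics reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ICCResult", "icc", "filter_features"]


@dataclass
class ICCResult:
    feature: str
    icc_intra: float
    icc_inter: float
    retained: bool


def icc(ratings: np.ndarray) -> float:
    """ICC(2,1) from a subjects x raters table via two-way ANOVA mean squares.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    with MSR/MSC/MSE the row (subject), column (rater) and residual mean
    squares. Zero between-subject variance yields a value <= 0 with a
    warning, never an exception.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a table of >=2 subjects by >=2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        warnings.warn("degenerate ICC denominator (no variance); returning 0")
        return 0.0
    value = (msr - mse) / denom
    if msr <= mse:
        warnings.warn("no between-subject variance beyond error; ICC <= 0")
    return float(value)


def filter_features(
    primary: pd.DataFrame,
    intra: pd.DataFrame,
    inter: pd.DataFrame,
    threshold: float = 0.75,
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature intra-/inter-observer ICC and the retained feature list.

    The three tables are indexed by patient and share feature columns; the
    ICC is computed over their common patients (the re-delineated subset).
    ``icc_intra`` compares the primary delineation against the same
    observer's repeat, ``icc_inter`` against the second observer. A feature
    is retained iff both ICCs are strictly greater than ``threshold``.
    """
    common = primary.index.intersection(intra.index).intersection(inter.index)
    if len(common) < 2:
        raise ValueError("need at least 2 common patients across repeat tables")
    feats = [c for c in primary.columns if c in intra.columns and c in inter.columns]
    records = []
    for f in feats:
        a = primary.loc[common, f].to_numpy(dtype=float)
        b = intra.loc[common, f].to_numpy(dtype=float)
        c = inter.loc[common, f].to_numpy(dtype=float)
        icc_intra = icc(np.column_stack([a, b]))
        icc_inter = icc(np.column_stack([a, c]))
        records.append(
            ICCResult(
                feature=f,
                icc_intra=icc_intra,
                icc_inter=icc_inter,
                retained=bool(icc_intra > threshold and icc_inter > threshold),
            )
        )
    report = pd.DataFrame([r.__dict__ for r in records])
    retained = report.loc[report["retained"], "feature"].tolist()
    return retained, report
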