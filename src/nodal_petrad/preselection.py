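"""Feature pre-selection: test-retest/inter-observer robustness and
lymph-node structure surrogacy.

Robustness keeps a feature only if its intraclass correlation exceeds a
cutoff (default 0.85) in *every* provided replicate context (test-retest
and inter-observer).  Surrogacy keeps a merged-node feature only if it
agrees with the same feature extracted from the largest node and from
the most active node: ICC above the cutoff and Bland-Altman 95% limits
of agreement contained in a +/-10% band of the pair mean.

The ICC is the two-way random-effects, absolute-agreement,
single-measurement form ICC(2,1), computed from the standard ANOVA mean
squares:

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

with n subjects, k raters, MS_R/MS_C/MS_E the row (subject), column
(rater) and residual mean squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "icc",
    "limits_of_agreement",
    "robustness_filter",
    "surrogate_filter",
    "SelectionReport",
]


def icc(pairs: np.ndarray) -> float:
    """ICC(2,1) for an (n_subjects, k_raters) array of measurements."""
    y = np.asarray(pairs, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("pairs must be an (n_subjects, k>=2) array")
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects for ICC")
    if not np.all(np.isfinite(y)):
        raise ValueError("measurements must be finite (no missing sides)")
    grand = y.mean()
    if np.allclose(y, grand):
        raise ValueError("ICC undefined: zero variance across subjects and raters")
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: degenerate variance decomposition")
    return float((msr - mse) / denom)


def limits_of_agreement(a, b) -> tuple[float, float]:
    """Bland-Altman 95% limits of agreement on the percent-difference scale.

    d_i = 100 (a_i - b_i) / ((a_i + b_i)/2); returns mean(d) -/+ 1.96 sd(d).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D arrays of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    means = (a + b) / 2.0
    if np.any(means == 0):
        raise ValueError("zero pair mean: percent difference undefined")
    d = 100.0 * (a - b) / means
    mu = d.mean()
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    return float(mu - 1.96 * sd), float(mu + 1.96 * sd)


@dataclass
class SelectionReport:
    """Per-feature agreement metrics and the retained feature lists."""

    table: pd.DataFrame  # feature, context, icc, loa_low, loa_high, retained
    retained: list[str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _feature_frame(x) -> pd.DataFrame:
    df = pd.DataFrame(x)
    return df.astype(float)


def robustness_filter(candidates: list[str], pairs_by_context: dict[str, tuple],
                      icc_cutoff: float = 0.85) -> SelectionReport:
    """Keep features with ICC above the cutoff in every replicate context.

    ``pairs_by_context`` maps a context name (e.g. ``"retest"``,
    ``"observer"``) to a pair of aligned per-patient feature tables
    (measurement A, measurement B).  Zero-variance features (ICC
    undefined) are dropped rather than erred on.
    """
    rows = []
    keep: dict[str, bool] = {c: True for c in candidates}
    for context, (fa, fb) in pairs_by_context.items():
        fa, fb = _feature_frame(fa), _feature_frame(fb)
        for feat in candidates:
            if feat not in fa.columns or feat not in fb.columns:
                raise KeyError(f"candidate {feat!r} has no pairs in context {context!r}")
            y = np.column_stack([fa[feat].to_numpy(), fb[feat].to_numpy()])
            try:
                val = icc(y)
            except ValueError:
                val = np.nan  # zero-variance feature: ICC undefined, not retained
            ok = bool(np.isfinite(val) and val > icc_cutoff)
            keep[feat] &= ok
            rows.append({"feature": feat, "context": context, "icc": val,
                         "loa_low": np.nan, "loa_high": np.nan, "retained": ok})
    retained = [c for c in candidates if keep[c]] if pairs_by_context else []
    table = pd.DataFrame(rows, columns=["feature", "context", "icc",
                                        "loa_low", "loa_high", "retained"])
    return SelectionReport(table=table, retained=retained)


def surrogate_filter(features_merged, features_largest, features_most_active,
                     icc_cutoff: float = 0.85, loa_bound: float = 10.0,
                     mode: str = "both") -> SelectionReport:
    """Merged-node features surrogated by the largest / most-active node.

    A feature passes one comparator when ICC(merged, comparator) exceeds
    ``icc_cutoff`` AND its limits-of-agreement interval lies within
    ``[-loa_bound, +loa_bound]`` percent.  ``mode="both"`` (default)
    requires passing against both comparators; ``mode="either"`` is the
    disjunctive reading.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    fm = _feature_frame(features_merged)
    comparators = {"largest": _feature_frame(features_largest),
                   "most_active": _feature_frame(features_most_active)}
    for name, fc in comparators.items():
        if len(fc) != len(fm):
            raise ValueError(f"patient tables misaligned for comparator {name!r}")
        if not fm.index.equals(fc.index):
            raise ValueError(f"patient index mismatch for comparator {name!r}")
    rows = []
    retained = []
    for feat in fm.columns:
        passes = []
        for name, fc in comparators.items():
            if feat not in fc.columns:
                raise KeyError(f"feature {feat!r} missing from comparator {name!r}")
            a = fm[feat].to_numpy(float)
            b = fc[feat].to_numpy(float)
            try:
                val = icc(np.column_stack([a, b]))
            except ValueError:
                val = np.nan
            try:
                lo, hi = limits_of_agreement(a, b)
            except ValueError:
                lo = hi = np.nan
            ok = bool(np.isfinite(val) and val > icc_cutoff
                      and np.isfinite(lo) and np.isfinite(hi)
                      and lo >= -loa_bound and hi <= loa_bound)
            passes.append(ok)
            rows.append({"feature": feat, "context": f"surrogacy_{name}",
                         "icc": val, "loa_low": lo, "loa_high": hi, "retained": ok})
        if (all(passes) if mode == "both" else any(passes)):
            retained.append(feat)
    table = pd.DataFrame(rows, columns=["feature", "context", "icc",
                                        "loa_low", "loa_high", "retained"])
    return SelectionReport(table=table, retained=retained)
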