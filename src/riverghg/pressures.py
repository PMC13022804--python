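"""Combined warming x land-use pressure analysis.

Two complementary views of how catchments experience climate and land-use
pressure: (1) a four-quadrant classification by the global median of the
per-catchment water-temperature slope and anthropogenic land-use
(cropland + urban) slope, ties going to "high"; (2) a continuous 0-1
pressure index, the arithmetic mean of min-max-normalized water temperature
and anthropogenic land-use fraction over the global pool of catchment-year
values. Responses are summarised by equal-width binning and fitted with
linear or exponential (log-linear OLS) forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PRESSURE_CLASSES",
    "classify_by_median",
    "pressure_index",
    "binned_response",
    "fit_response_curve",
    "compare_groups",
]

PRESSURE_CLASSES = [
    "lowWT_lowLUC",
    "highWT_lowLUC",
    "lowWT_highLUC",
    "highWT_highLUC",
]


def classify_by_median(wt_slopes: pd.Series, lu_slopes: pd.Series) -> pd.Series:
    """Four-quadrant class per catchment from median-split slopes.

    Both inputs are indexed by catchment and must cover the same catchments;
    the thresholds are the global medians, with slopes equal to the median
    classified as "high". The land-use slope is the trend of cropland% +
    urban% combined.
    """
    wt = pd.Series(wt_slopes).astype(float)
    lu = pd.Series(lu_slopes).astype(float)
    if set(wt.index) != set(lu.index):
        raise ValueError("wt and lu slope sets must cover the same catchments")
    if wt.isna().any() or lu.isna().any():
        missing = sorted(set(wt.index[wt.isna()]) | set(lu.index[lu.isna()]))
        raise ValueError(f"missing slope for catchments: {missing[:5]}")
    lu = lu.reindex(wt.index)
    wt_high = wt >= wt.median()
    lu_high = lu >= lu.median()
    labels = np.where(
        wt_high,
        np.where(lu_high, "highWT_highLUC", "highWT_lowLUC"),
        np.where(lu_high, "lowWT_highLUC", "lowWT_lowLUC"),
    )
    return pd.Series(labels, index=wt.index, name="pressure_class")


def pressure_index(wt_values: pd.Series, lu_values: pd.Series) -> pd.DataFrame:
    """0-1 combined pressure index per catchment-year.

    Min-max normalization over the full pool of values supplied (all
    catchment-years jointly); the combined index is the arithmetic mean of
    the two normalized components, hence itself in [0, 1].
    """
    wt = np.asarray(wt_values, dtype=float)
    lu = np.asarray(lu_values, dtype=float)
    if wt.shape != lu.shape:
        raise ValueError("inputs must be aligned")
    out = {}
    for name, vals in (("wt_norm", wt), ("lu_norm", lu)):
        lo, hi = np.min(vals), np.max(vals)
        if hi == lo:
            raise ValueError(f"cannot normalize a constant variable ({name})")
        out[name] = (vals - lo) / (hi - lo)
    index = getattr(wt_values, "index", pd.RangeIndex(len(wt)))
    frame = pd.DataFrame(out, index=index)
    frame["combined"] = (frame["wt_norm"] + frame["lu_norm"]) / 2.0
    return frame


def binned_response(x, y, n_bins: int = 20) -> pd.DataFrame:
    """Per-bin mean +/- SE of ``y`` over equal-width bins of ``x``.

    Bin edges span [min(x), max(x)]; empty bins are retained as gaps (NaN
    mean), single-point bins report SE as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values to bin")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        n = int(mask.sum())
        yy = y[mask]
        rows.append(
            {
                "bin": b,
                "x_center": (edges[b] + edges[b + 1]) / 2.0,
                "mean": yy.mean() if n else np.nan,
                "se": yy.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ResponseCurveFit:
    form: str  # "linear" or "exponential"
    coefficients: tuple[float, float]  # (intercept-ish, slope/rate)
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def fit_response_curve(bins: pd.DataFrame, form: str = "linear") -> ResponseCurveFit:
    """Fit bin means with a linear or exponential form.

    ``linear``: OLS mean ~ x, returns (intercept, slope). ``exponential``:
    OLS log(mean) ~ x on strictly positive means, returns (amplitude, rate)
    for y = amplitude * exp(rate x). The slope's two-sided p-value gates
    whether the relationship counts as significant (p < 0.05).
    """
    valid = bins.dropna(subset=["mean"])
    if len(valid) < 3:
        raise ValueError("need at least 3 non-missing bins")
    x = valid["x_center"].to_numpy(dtype=float)
    y = valid["mean"].to_numpy(dtype=float)
    if form == "linear":
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        return ResponseCurveFit("linear", (float(fit.params[0]), float(fit.params[1])),
                                float(fit.pvalues[1]))
    if form == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential form requires strictly positive bin means")
        fit = sm.OLS(np.log(y), sm.add_constant(x)).fit()
        return ResponseCurveFit(
            "exponential",
            (float(np.exp(fit.params[0])), float(fit.params[1])),
            float(fit.pvalues[1]),
        )
    raise ValueError(f"unknown form {form!r}")


def compare_groups(
    values: pd.Series, classes: pd.Series, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means and pairwise contrasts across pressure classes.

    Returns ``(group_table, pairwise_table)``. The group table carries each
    class's mean, n, and the percent difference of its mean relative to the
    low/low reference class. Pairwise significance is delegated to Tukey's
    HSD (statsmodels); classes with fewer than 2 members are excluded with a
    warning attribute on the result.
    """
    frame = pd.DataFrame({"value": values, "class": classes}).dropna()
    counts = frame["class"].value_counts()
    small = counts[counts < 2].index.tolist()
    frame = frame[~frame["class"].isin(small)]
    if frame["class"].nunique() < 2:
        raise ValueError("need at least 2 classes with at least 2 members")
    group = (
        frame.groupby("class", observed=True)["value"].agg(["mean", "count"]).reset_index()
    )
    ref_class = "lowWT_lowLUC" if "lowWT_lowLUC" in set(group["class"]) else group["class"].iloc[0]
    ref = float(group.loc[group["class"] == ref_class, "mean"].iloc[0])
    group["pct_vs_reference"] = (
        100.0 * (group["mean"] - ref) / abs(ref) if ref != 0 else np.nan
    )
    tukey = pairwise_tukeyhsd(
        frame["value"].to_numpy(), frame["class"].to_numpy(), alpha=alpha
    )
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    group.attrs["excluded_classes"] = small
    return group, pairwise
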