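"""Annual aggregation, OLS trend estimation and derived nutrient quantities.

Global/regional annual mean series are built across catchments (mean +/- SE),
linear temporal trends are estimated by ordinary least squares of the annual
mean on year (two-sided slope p-value), and rates are reported per decade
(decadal rate = 10 x annual slope, exactly). Land-use trends are windowed to
2002-2019 because the land-use record ends in 2019; gas/water-quality trends
run through 2022.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AnnualSeries",
    "TrendEstimate",
    "annual_aggregate",
    "fit_trend",
    "catchment_slopes",
    "derived_nutrients",
    "regional_table",
    "LANDUSE_WINDOW",
]

#: Years covered by the land-use record; land-use trends never extend past it.
LANDUSE_WINDOW = (2002, 2019)


@dataclass
class AnnualSeries:
    """Annual means (+/- SE across catchments) for one response and scope."""

    scope: str  # "global", a region name, or a catchment id
    response_name: str
    table: pd.DataFrame  # columns: year, mean, se, n

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    @property
    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy()


@dataclass
class TrendEstimate:
    """OLS slope of an annual series, with decadal rate and significance."""

    slope: float  # units per year
    slope_se: float
    p_value: float
    constant: bool = False  # degenerate flat series: slope 0 by contract

    @property
    def decadal_rate(self) -> float:
        return 10.0 * self.slope

    @property
    def significance_flag(self) -> str:
        if self.p_value < 0.05:
            return "p<0.05"
        if self.p_value < 0.1:
            return "p<0.1"
        return "ns"


def annual_aggregate(
    state: pd.DataFrame,
    scope: str = "global",
    value_column: str = "value",
    response_name: str = "",
) -> AnnualSeries | dict[str, AnnualSeries]:
    """Mean and SE (sd/sqrt(n)) across catchments per year.

    ``state`` has one value per (catchment_id, year) in ``value_column``.
    ``scope="global"`` pools every catchment; ``scope="region"`` returns one
    series per region (requires a ``region`` column). Years with a single
    catchment get SE 0; years with none are simply absent (a gap).
    """
    dupes = state.duplicated(["catchment_id", "year"]).any()
    if dupes:
        raise ValueError("state table has duplicate (catchment_id, year) rows")

    def _agg(frame, label):
        grouped = frame.groupby("year")[value_column]
        table = pd.DataFrame(
            {
                "year": grouped.mean().index,
                "mean": grouped.mean().to_numpy(),
                "se": (grouped.std(ddof=1) / np.sqrt(grouped.size()))
                .fillna(0.0)
                .to_numpy(),
                "n": grouped.size().to_numpy(),
            }
        ).reset_index(drop=True)
        return AnnualSeries(scope=label, response_name=response_name, table=table)

    if scope == "global":
        return _agg(state, "global")
    if scope == "region":
        if "region" not in state.columns:
            raise ValueError("region scope requires a 'region' column")
        return {
            str(region): _agg(group, str(region))
            for region, group in state.groupby("region", observed=True)
        }
    raise ValueError(f"unknown scope {scope!r}")


def fit_trend(series: AnnualSeries | pd.DataFrame) -> TrendEstimate:
    """OLS of annual mean on year; two-sided p-value for the slope.

    A perfectly constant series returns slope 0 with p = 1 by contract (its
    slope SE is 0, so the usual t statistic is undefined) and is flagged.
    """
    table = series.table if isinstance(series, AnnualSeries) else series
    years = np.asarray(table["year"], dtype=float)
    means = np.asarray(table["mean"], dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 annual points to fit a trend")
    if np.allclose(means, means[0]):
        return TrendEstimate(slope=0.0, slope_se=0.0, p_value=1.0, constant=True)
    model = sm.OLS(means, sm.add_constant(years)).fit()
    return TrendEstimate(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        p_value=float(model.pvalues[1]),
    )


def catchment_slopes(
    state: pd.DataFrame,
    value_column: str = "value",
    year_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-catchment OLS slope of annual values on year.

    Returns columns catchment_id, slope, slope_se, p_value (decadal rate is
    10 x slope). Used for the median-split pressure classification and the
    binned response analysis.
    """
    frame = state
    if year_window is not None:
        frame = frame[frame["year"].between(*year_window)]
    rows = []
    for cid, group in frame.groupby("catchment_id", observed=True):
        years = group["year"].to_numpy(dtype=float)
        values = group[value_column].to_numpy(dtype=float)
        if len(years) < 3:
            raise ValueError(f"catchment {cid} has fewer than 3 annual values")
        est = fit_trend(pd.DataFrame({"year": years, "mean": values}))
        rows.append(
            {
                "catchment_id": cid,
                "slope": est.slope,
                "slope_se": est.slope_se,
                "p_value": est.p_value,
            }
        )
    return pd.DataFrame(rows)


def derived_nutrients(state: pd.DataFrame) -> pd.DataFrame:
    """DIN, DON and DOC:TN from NH4, NO3, TN, DOC columns (as N units).

    DIN = NH4 + NO3; DON = TN - DIN floored at 0 (flagged where the floor
    bites); DOC:TN is NaN-flagged where TN <= 0.
    """
    required = {"NH4", "NO3", "TN", "DOC"}
    missing = required - set(state.columns)
    if missing:
        raise ValueError(f"missing nutrient columns: {sorted(missing)}")
    out = state.copy()
    out["DIN"] = out["NH4"] + out["NO3"]
    don_raw = out["TN"] - out["DIN"]
    out["DON_floored"] = don_raw < 0
    out["DON"] = don_raw.clip(lower=0.0)
    valid_tn = out["TN"] > 0
    out["DOC_TN_ratio"] = np.where(valid_tn, out["DOC"] / out["TN"], np.nan)
    out["DOC_TN_undefined"] = ~valid_tn
    return out


def regional_table(
    state: pd.DataFrame,
    landuse: pd.DataFrame,
    response_columns: list[str] | None = None,
    mode: str = "region-mean",
) -> pd.DataFrame:
    """Region x variable decadal rates with non-significant cells blanked.

    State variables use the full year range present (through 2022); land-use
    variables are windowed to 2002-2019. Cells with p >= 0.1 are blank (NaN);
    marginal cells (0.05 <= p < 0.1) are reported with a ``*`` marker column.
    ``mode="region-mean"`` fits the trend of the region's annual-mean series;
    ``mode="catchment-mean"`` averages per-catchment slopes instead.
    """
    if "region" not in state.columns:
        raise ValueError("state table requires a 'region' column")
    response_columns = response_columns or [
        c for c in state.columns if c not in ("catchment_id", "region", "year")
    ]
    lu_cols = [c for c in landuse.columns if c.endswith("_pct")]
    region_of = state.drop_duplicates("catchment_id").set_index("catchment_id")["region"]
    landuse = landuse.copy()
    if "region" not in landuse.columns:
        landuse["region"] = landuse["catchment_id"].map(region_of)
    if landuse["region"].isna().any():
        bad = landuse.loc[landuse["region"].isna(), "catchment_id"].unique()
        raise ValueError(f"unknown region for catchments: {list(bad)[:5]}")
    landuse = landuse[landuse["year"].between(*LANDUSE_WINDOW)]

    def _cell(frame, col):
        if mode == "region-mean":
            series = annual_aggregate(
                frame.rename(columns={col: "value"})[["catchment_id", "year", "value"]]
            )
            est = fit_trend(series)
            rate, p = est.decadal_rate, est.p_value
        elif mode == "catchment-mean":
            slopes = catchment_slopes(frame.rename(columns={col: "value"}))
            rate = 10.0 * slopes["slope"].mean()
            n = len(slopes)
            se = slopes["slope"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            from scipy import stats

            t = slopes["slope"].mean() / se if se and se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), n - 1) if np.isfinite(t) else 1.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return rate, p

    rows = []
    for region in sorted(state["region"].unique()):
        row = {"region": region}
        for col in lu_cols:
            rate, p = _cell(landuse[landuse["region"] == region], col)
            row[col] = rate if p < 0.1 else np.nan
            row[f"{col}_marginal"] = bool(0.05 <= p < 0.1)
        for col in response_columns:
            rate, p = _cell(state[state["region"] == region], col)
            row[col] = rate if p < 0.1 else np.nan
            row[f"{col}_marginal"] = bool(0.05 <= p < 0.1)
        rows.append(row)
    return pd.DataFrame(rows)
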