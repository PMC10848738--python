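"""Observation preprocessing and environmental statistics.

Covers the station-sample cleaning and spatial-binning rules, monthly
environmental aggregation, trailing moving averages, the anomaly-vs-
environment correlation screen, and the lag-1 recruit-vs-adult analyses
(including the permuted-anomaly experiment).

Month alignment: anomalies of year Y are screened against factor values over
a 16-month span running September of year Y-1 through December of year Y
(month offsets -4 .. 11 relative to 1 January of year Y), which covers the
larval anomaly window Nov(Y-1)-Oct(Y). The same alignment table is used by
the fused-LASSO design builder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import model as mc
from .errors import InputError, ParameterError

__all__ = [
    "MONTH_OFFSETS",
    "INDEX_FACTORS",
    "LOCAL_FACTORS",
    "month_offset_labels",
    "clean_samples",
    "column_abundance",
    "bin_and_average",
    "moving_average",
    "factor_month_matrix",
    "CorrelationScreen",
    "correlation_screen",
    "recruit_vs_adult",
    "permuted_anomaly_experiment",
]

#: 16-month screen span: Sep of year Y-1 (offset -4) .. Dec of year Y (offset 11)
MONTH_OFFSETS = tuple(range(-4, 12))

#: climate indices enter as 9-month trailing moving averages
INDEX_FACTORS = frozenset({"SAM", "AAO", "SOI", "Nino3.4"})
#: locally measured factors enter as raw monthly means
LOCAL_FACTORS = ("Chl", "T", "Ice")

#: outlier threshold on station densities (ind per 1000 m^3), strict
DENSITY_OUTLIER_THRESHOLD = 5000.0

_MONTH_NAMES = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


def month_offset_labels(offsets=MONTH_OFFSETS) -> list[str]:
    """Human-readable labels; offsets < 0 get a '-1' year tag, >= 12 a '+1'."""
    out = []
    for o in offsets:
        name = _MONTH_NAMES[o % 12]
        if o < 0:
            out.append(f"{name}(Y-1)")
        elif o >= 12:
            out.append(f"{name}(Y+1)")
        else:
            out.append(name)
    return out


def clean_samples(samples: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop stations with density strictly above 5000 ind/1000 m^3.

    Returns the filtered table and the number of removed rows.
    """
    if len(samples) == 0:
        return samples.copy(), 0
    if (samples["density"] < 0).any():
        raise InputError("negative krill density encountered")
    keep = samples["density"] <= DENSITY_OUTLIER_THRESHOLD
    return samples[keep].reset_index(drop=True), int((~keep).sum())


def column_abundance(samples: pd.DataFrame) -> pd.Series:
    """Areal abundance (ind/m^2) = density (ind/1000 m^3) / 1000 x depth (m).

    Rows with missing depth are excluded with a warning; the returned series
    keeps the surviving rows' index.
    """
    depth = samples["depth"]
    missing = depth.isna()
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} rows with missing sampling depth")
    ok = samples[~missing]
    return ok["density"] / 1000.0 * ok["depth"]


def bin_and_average(
    samples: pd.DataFrame, lon_step: float = 0.5, lat_step: float = 0.25
) -> pd.DataFrame:
    """Per-year mean juvenile/adult column abundance, spatially de-clustered.

    Samples are first averaged within (lon_step x lat_step) bins, then the
    bin means are averaged, so stations sampled repeatedly do not dominate.
    The juvenile/adult split uses the per-sample juvenile fraction (body
    length <= 35 mm <=> juvenile). Returns columns (year, J, A).
    """
    df = samples.copy()
    ab = column_abundance(df)
    df = df.loc[ab.index]
    df["_J"] = ab * df["juvenile_fraction"]
    df["_A"] = ab * (1.0 - df["juvenile_fraction"])
    df["_lon_bin"] = np.floor(df["longitude"] / lon_step).astype(int)
    df["_lat_bin"] = np.floor(df["latitude"] / lat_step).astype(int)
    per_bin = (
        df.groupby(["year", "_lon_bin", "_lat_bin"])[["_J", "_A"]].mean().reset_index()
    )
    out = per_bin.groupby("year")[["_J", "_A"]].mean().reset_index()
    return out.rename(columns={"_J": "J", "_A": "A"})


def moving_average(series: pd.Series, window: int = 9, min_present: int | None = None):
    """Trailing moving average: value at t = mean of the last ``window`` months.

    The first window-1 entries are undefined. Missing inputs are tolerated as
    long as at least ``min_present`` (default window-2, i.e. 7 of 9) months
    are present in the window; otherwise the output is missing.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    if min_present is None:
        min_present = max(window - 2, 1)
    return series.rolling(window, min_periods=1).apply(
        lambda w: (
            np.nanmean(w)
            if len(w) == window and np.sum(~np.isnan(w)) >= min_present
            else np.nan
        ),
        raw=True,
    )


def _monthly_series(env: pd.DataFrame, factor: str) -> pd.Series:
    """Continuous monthly series for one factor, indexed by year*12 + month-1."""
    sub = env[env["factor"] == factor]
    if sub.duplicated(["year", "month"]).any():
        raise InputError(f"duplicate (year, month) entries for factor {factor!r}")
    idx = sub["year"].to_numpy() * 12 + (sub["month"].to_numpy() - 1)
    ser = pd.Series(sub["value"].to_numpy(), index=idx).sort_index()
    full = pd.Series(np.nan, index=np.arange(ser.index.min(), ser.index.max() + 1))
    full.loc[ser.index] = ser.to_numpy()
    return full


def factor_month_matrix(
    env: pd.DataFrame,
    factor: str,
    years: np.ndarray,
    offsets=MONTH_OFFSETS,
    smooth: bool | None = None,
) -> np.ndarray:
    """(n_years x n_offsets) matrix of factor values on the screen alignment.

    Entry (Y, i) is the factor value in month offset[i] relative to 1 January
    of calendar year Y. Climate indices (``smooth=None`` auto-detects via
    INDEX_FACTORS) are replaced by their 9-month trailing moving average
    before alignment. Missing months yield NaN.
    """
    if smooth is None:
        smooth = factor in INDEX_FACTORS
    ser = _monthly_series(env, factor)
    if smooth:
        ser = moving_average(ser, window=9)
    years = np.asarray(years, dtype=int)
    out = np.full((len(years), len(offsets)), np.nan)
    for yi, y in enumerate(years):
        base = y * 12
        for oi, o in enumerate(offsets):
            key = base + o
            if key in ser.index:
                out[yi, oi] = ser.loc[key]
    return out


@dataclass
class CorrelationScreen:
    """Pearson r / two-sided p per (month-of-cycle, factor) cell.

    ``significant`` marks p < 0.05 with no multiple-testing correction (an
    exploratory screen); cells with fewer than 5 complete pairs are NaN and
    marked in ``not_assessed``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    not_assessed: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for month in self.r.index:
            for factor in self.r.columns:
                rows.append(
                    {
                        "month_label": month,
                        "factor": factor,
                        "r": self.r.loc[month, factor],
                        "p": self.p.loc[month, factor],
                        "significant": bool(self.significant.loc[month, factor]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def correlation_screen(
    anomaly_values: np.ndarray,
    years: np.ndarray,
    env: pd.DataFrame,
    factors=None,
    offsets=MONTH_OFFSETS,
    alpha: float = 0.05,
    min_pairs: int = 5,
) -> CorrelationScreen:
    """Correlate one anomaly series with each factor at each cycle month.

    ``anomaly_values[i]`` is the loss anomaly of calendar year ``years[i]``.
    Correlations are pairwise-complete Pearson with two-sided p-values.
    """
    anomaly_values = np.asarray(anomaly_values, dtype=float)
    years = np.asarray(years, dtype=int)
    if factors is None:
        factors = sorted(env["factor"].unique())
    labels = month_offset_labels(offsets)
    r = pd.DataFrame(np.nan, index=labels, columns=list(factors))
    p = pd.DataFrame(np.nan, index=labels, columns=list(factors))
    na = pd.DataFrame(False, index=labels, columns=list(factors))
    for factor in factors:
        mat = factor_month_matrix(env, factor, years, offsets)
        for oi, label in enumerate(labels):
            x = mat[:, oi]
            mask = ~(np.isnan(x) | np.isnan(anomaly_values))
            if mask.sum() < min_pairs:
                na.loc[label, factor] = True
                continue
            xi, yi = x[mask], anomaly_values[mask]
            if np.std(xi) == 0 or np.std(yi) == 0:
                na.loc[label, factor] = True
                continue
            rr, pp = stats.pearsonr(xi, yi)
            r.loc[label, factor] = rr
            p.loc[label, factor] = pp
    sig = (p < alpha).fillna(False)
    return CorrelationScreen(r=r, p=p, significant=sig, not_assessed=na)


def recruit_vs_adult(jan1: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Lag-1 pairs (A_Y, J_{Y+1}) and their Pearson r on log abundances.

    Expects columns (year, J, A) sorted by year; with fewer than 3 years or a
    zero-variance series the correlation is undefined (NaN).
    """
    df = jan1.sort_values("year").reset_index(drop=True)
    if len(df) < 3:
        raise InputError("need at least 3 years for the lag-1 analysis")
    pairs = pd.DataFrame(
        {
            "year": df["year"].to_numpy()[:-1],
            "A": df["A"].to_numpy()[:-1],
            "J_next": df["J"].to_numpy()[1:],
        }
    )
    valid = (pairs["A"] > 0) & (pairs["J_next"] > 0)
    sub = pairs[valid]
    la, lj = np.log(sub["A"].to_numpy()), np.log(sub["J_next"].to_numpy())
    if len(sub) < 3 or np.std(la) == 0 or np.std(lj) == 0:
        return pairs, float("nan")
    r, _ = stats.pearsonr(la, lj)
    return pairs, float(r)


def permuted_anomaly_experiment(
    fitted_anomalies,
    fixed_params: mc.ModelParams,
    n_permutations: int = 100,
    seed: int = 0,
    years: int | None = None,
) -> dict:
    """Recruit-vs-adult correlations under year-shuffled loss anomalies.

    Each permutation jointly shuffles the year order of (delta_L, delta_J),
    re-simulates the annually varying model, and records the lag-1
    log-correlation between adults and next-year juveniles. Returns the
    correlation sample and its median; the identity ordering reproduces the
    unpermuted correlation exactly.
    """
    years = years if years is not None else len(fitted_anomalies)
    rng = np.random.default_rng(seed)
    rs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = fitted_anomalies.permuted(rng)
        traj = mc.simulate(fixed_params, anomalies=perm, years=years, method="fast")
        _, rs[i] = recruit_vs_adult(traj.jan1)
    return {"r": rs, "median_r": float(np.nanmedian(rs))}
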