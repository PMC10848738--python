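"""Seeded generators for a complete synthetic krill study.

The generators emulate the statistical structure of the real inputs — a
27-year annual abundance series with multiplicative (lognormal) observation
noise spanning large interannual fluctuations, monthly environmental series
with seasonal cycles plus AR(1) interannual anomalies, loss anomalies driven
by a known sparse linear model on the environment, and overdispersed
station-level sample tables — so that every pipeline stage can be exercised,
and its recovery quantified, without any external data.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import envstats, model as mc
from .anomalies import AnomalySeries
from .errors import ConfigurationError, InputError

__all__ = [
    "FactorSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_factor_specs",
    "gen_environment",
    "gen_anomalies",
    "gen_observations",
    "gen_station_samples",
    "make_study",
]


@dataclass(frozen=True)
class FactorSpec:
    """Monthly generating model for one environmental factor.

    value(year, month) = mean + amplitude * cos(2 pi (month - peak_month)/12)
                         + AR(1) annual anomaly + white monthly noise

    Climate-index-like factors have no seasonal term (amplitude 0).
    """

    mean: float = 0.0
    amplitude: float = 0.0
    peak_month: int = 1  # calendar month (1..12) of the seasonal maximum
    ar_coef: float = 0.5  # lag-1 autocorrelation of the annual anomaly
    ar_sd: float = 0.5  # marginal sd of the annual anomaly
    noise_sd: float = 0.2  # monthly white noise sd

    def __post_init__(self):
        if not (-1.0 < self.ar_coef < 1.0):
            raise ConfigurationError("AR coefficient must lie in (-1, 1)")
        if self.ar_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")


def default_factor_specs() -> dict[str, FactorSpec]:
    """Southern-hemisphere seasonal cycles for the Palmer-grid-like factors.

    Chlorophyll (mg/m^3) peaks in austral summer (January), temperature
    (deg C) in February, ice extent (10^3 km^2) in September; SAM is a
    zero-mean index without seasonality but with interannual persistence.
    """
    return {
        "Chl": FactorSpec(mean=1.5, amplitude=1.2, peak_month=1,
                          ar_coef=0.5, ar_sd=0.5, noise_sd=0.25),
        "T": FactorSpec(mean=-0.5, amplitude=1.5, peak_month=2,
                        ar_coef=0.5, ar_sd=0.4, noise_sd=0.2),
        "Ice": FactorSpec(mean=100.0, amplitude=80.0, peak_month=9,
                          ar_coef=0.5, ar_sd=25.0, noise_sd=10.0),
        "SAM": FactorSpec(mean=0.0, amplitude=0.0, peak_month=1,
                          ar_coef=0.5, ar_sd=1.0, noise_sd=0.6),
        "AAO": FactorSpec(mean=0.0, amplitude=0.0, peak_month=1,
                          ar_coef=0.5, ar_sd=1.0, noise_sd=0.6),
        "SOI": FactorSpec(mean=0.0, amplitude=0.0, peak_month=1,
                          ar_coef=0.6, ar_sd=1.0, noise_sd=0.8),
        "Nino3.4": FactorSpec(mean=0.0, amplitude=0.0, peak_month=1,
                              ar_coef=0.7, ar_sd=0.8, noise_sd=0.4),
    }


#: default generating coefficients for the loss anomalies (factor, month
#: offset relative to 1 January of the anomaly year) -> coefficient on the
#: standardized factor value. Smooth runs over adjacent months exercise the
#: fusion penalty the way the attribution step assumes; larval losses are
#: driven by the SAM-like index over the spawning-to-summer months, juvenile
#: losses by temperature over winter-spring.
DEFAULT_LARVAL_COEFS = {
    ("SAM", -2): 0.08, ("SAM", -1): 0.11, ("SAM", 0): 0.13,
    ("SAM", 1): 0.11, ("SAM", 2): 0.08,
}
DEFAULT_JUVENILE_COEFS = {
    ("T", 5): 0.10, ("T", 6): 0.15, ("T", 7): 0.15, ("T", 8): 0.10,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic pipeline."""

    n_years: int = 27
    start_year: int = 1993
    seed: int = 0
    preset: str = "RK"
    params: mc.ModelParams | None = None  # defaults to the preset parameters
    factors: dict = field(default_factory=default_factor_specs)
    larval_coefs: dict = field(default_factory=lambda: dict(DEFAULT_LARVAL_COEFS))
    juvenile_coefs: dict = field(default_factory=lambda: dict(DEFAULT_JUVENILE_COEFS))
    larval_intercept: float = 0.0
    juvenile_intercept: float = 0.0
    anomaly_noise_sd: float = 0.35  # leaves the environment ~50-70% of variance
    obs_noise_sd: float = 0.3  # lognormal sd on annual abundances

    def __post_init__(self):
        if self.n_years < 5:
            raise ConfigurationError("n_years must be >= 5")
        if self.anomaly_noise_sd < 0 or self.obs_noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")

    def model_params(self) -> mc.ModelParams:
        return self.params if self.params is not None else mc.PRESETS[self.preset]

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth retained alongside the generated tables."""

    anomalies: AnomalySeries
    signal_L: np.ndarray  # anomaly values before noise
    signal_J: np.ndarray
    larval_coefs: dict
    juvenile_coefs: dict


def gen_environment(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Monthly environment table covering start_year-1 .. start_year+n-1.

    One lead year is generated so that 16-month design windows and 9-month
    moving averages are defined for the first anomaly year. Long format:
    (year, month, factor, value).
    """
    seed = config.seed if seed is None else seed
    n_years = config.n_years + 1
    years = np.arange(config.start_year - 1, config.start_year + config.n_years)
    frames = []
    for name, spec in sorted(config.factors.items()):
        # key each factor's stream by its name: adding or removing factors
        # never perturbs the others' realizations
        rng = np.random.default_rng((seed, 7, zlib.crc32(name.encode())))
        annual = np.empty(n_years)
        innov_sd = spec.ar_sd * np.sqrt(1.0 - spec.ar_coef**2)
        annual[0] = rng.normal(0.0, spec.ar_sd)
        for i in range(1, n_years):
            annual[i] = spec.ar_coef * annual[i - 1] + rng.normal(0.0, innov_sd)
        months = np.arange(1, 13)
        seasonal = spec.mean + spec.amplitude * np.cos(
            2.0 * np.pi * (months - spec.peak_month) / 12.0
        )
        noise = rng.normal(0.0, spec.noise_sd, (n_years, 12))
        vals = seasonal[None, :] + annual[:, None] + noise
        frames.append(
            pd.DataFrame(
                {
                    "year": np.repeat(years, 12),
                    "month": np.tile(months, n_years),
                    "factor": name,
                    "value": vals.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _standardized_matrix(env, factor, years):
    mat = envstats.factor_month_matrix(env, factor, years)
    if np.isnan(mat).any():
        raise InputError(
            f"environment table does not cover the 16-month windows for {factor!r}"
        )
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (mat - mu) / sd


def gen_anomalies(
    env: pd.DataFrame, config: SyntheticConfig, seed: int | None = None
) -> SyntheticTruth:
    """Loss anomalies from the linear anomaly model plus Gaussian noise.

    delta_{k,Y} = a0_k + sum_{(F,i)} a_i^{k,F} * standardized factor value in
    month offset i of year Y, with iid N(0, anomaly_noise_sd^2) noise.
    """
    seed = config.seed if seed is None else seed
    years_cal = np.arange(config.start_year, config.start_year + config.n_years)
    offsets = list(envstats.MONTH_OFFSETS)
    mats = {}

    def signal(coefs, intercept):
        out = np.full(config.n_years, intercept)
        for (factor, off), a in coefs.items():
            if factor not in mats:
                mats[factor] = _standardized_matrix(env, factor, years_cal)
            out += a * mats[factor][:, offsets.index(off)]
        return out

    sig_L = signal(config.larval_coefs, config.larval_intercept)
    sig_J = signal(config.juvenile_coefs, config.juvenile_intercept)
    rng = np.random.default_rng((seed, 11))
    delta_L = sig_L + rng.normal(0.0, config.anomaly_noise_sd, config.n_years)
    delta_J = sig_J + rng.normal(0.0, config.anomaly_noise_sd, config.n_years)
    anom = AnomalySeries(np.arange(config.n_years), delta_L, delta_J)
    return SyntheticTruth(
        anomalies=anom, signal_L=sig_L, signal_J=sig_J,
        larval_coefs=dict(config.larval_coefs),
        juvenile_coefs=dict(config.juvenile_coefs),
    )


def gen_observations(
    params: mc.ModelParams,
    true_anomalies: AnomalySeries | None,
    obs_noise_sd: float,
    seed: int,
    n_years: int | None = None,
) -> pd.DataFrame:
    """Annual observed (L', J', A') = simulated 1 January values x lognormal noise."""
    n = n_years if n_years is not None else (
        len(true_anomalies) if true_anomalies is not None else 27
    )
    traj = mc.simulate(params, anomalies=true_anomalies, years=n, method="fast")
    jan1 = traj.jan1[["L", "J", "A"]].to_numpy()
    rng = np.random.default_rng((seed, 13))
    noisy = jan1 * np.exp(rng.normal(0.0, obs_noise_sd, jan1.shape))
    out = pd.DataFrame(noisy, columns=["L", "J", "A"])
    out.insert(0, "year", np.arange(n))
    return out


def gen_station_samples(
    annual_truth: pd.DataFrame,
    stations_per_year: int = 50,
    dispersion: float = 0.6,
    outlier_rate: float = 0.0,
    seed: int = 0,
    depth: float = 120.0,
) -> pd.DataFrame:
    """Station-level sample table consistent with per-year (J, A) truth.

    Station densities (ind per 1000 m^3) are mean-preserving lognormal draws
    around the annual postlarval column abundance divided by the sampling
    depth; a configurable fraction of stations is replaced by extreme
    outliers (> 5000 ind/1000 m^3) emulating swarm hits. The juvenile
    fraction is the annual truth J/(J+A) with dispersion-scaled jitter, so at
    ``dispersion=0`` the two-stage bin averaging recovers the truth exactly.
    """
    rng = np.random.default_rng((seed, 17))
    rows = []
    for _, rec in annual_truth.iterrows():
        total = rec["J"] + rec["A"]
        jf = rec["J"] / total if total > 0 else 0.0
        mean_density = total / depth * 1000.0
        for _ in range(stations_per_year):
            lon = rng.uniform(-67.0, -63.0)
            lat = rng.uniform(-67.5, -64.0)
            if dispersion > 0:
                dens = mean_density * rng.lognormal(-0.5 * dispersion**2, dispersion)
                frac = float(np.clip(jf + 0.1 * dispersion * rng.normal(), 0.0, 1.0))
            else:
                dens = mean_density
                frac = jf
            if outlier_rate > 0 and rng.random() < outlier_rate:
                dens = envstats.DENSITY_OUTLIER_THRESHOLD * (1.0 + rng.exponential(1.0))
            rows.append(
                {
                    "latitude": lat,
                    "longitude": lon,
                    "date": f"{int(rec['year'])}-01-15",
                    "density": dens,
                    "depth": depth,
                    "juvenile_fraction": frac,
                    "year": int(rec["year"]),
                }
            )
    return pd.DataFrame(rows)


def make_study(config: SyntheticConfig, seed: int | None = None) -> dict:
    """Generate a full synthetic study: environment, anomalies, observations.

    Returns a dict with keys env, truth, observations, params.
    """
    seed = config.seed if seed is None else seed
    env = gen_environment(config, seed)
    truth = gen_anomalies(env, config, seed)
    params = config.model_params()
    obs = gen_observations(
        params, truth.anomalies, config.obs_noise_sd, seed, config.n_years
    )
    return {"env": env, "truth": truth, "observations": obs, "params": params}
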