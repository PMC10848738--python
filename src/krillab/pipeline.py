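"""Three-stage analysis pipeline and run configuration.

Stage 1 fits the time-constant model to the annual abundance table; stage 2
estimates the minimal annual loss anomalies under the fitted (fixed)
standard parameters; stage 3 attributes the anomalies to monthly
environmental drivers (correlation screen, fused-LASSO subset selection with
bootstrap bands, anomaly prediction) and runs the permuted-anomaly
recruit-vs-adult experiment. Every stage writes tidy CSVs into the run
directory plus a machine-readable JSON summary; all randomness derives from
the single run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, anomalies as an, envstats, fusedlasso as fl, model as mc
from . import synthetic as syn
from .errors import ConfigurationError

__all__ = ["RunConfig", "run_pipeline", "simulate_only"]

log = logging.getLogger("krillab")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``observations_csv``/``environment_csv`` point at input tables
    (annual cohort abundances; long-format monthly environment), or
    ``synthetic=True`` generates both from the built-in study generator.
    """

    preset: str = "RK"
    seed: int = 0
    synthetic: bool = True
    observations_csv: str | None = None
    environment_csv: str | None = None
    start_year: int = 1993
    n_years: int = 27
    obs_noise_sd: float = 0.3
    # fitting budgets (reduced relative to the full study-scale search;
    # see docs/methods.md)
    n_starts: int = 6
    n_primary_cycles: int = 4
    n_final_cycles: int = 25
    evals_per_cycle: int = 8000
    lambda_reg: float = 0.01
    # attribution
    factors: tuple = fl.DEFAULT_FACTORS
    K: int = 9
    lambda_grid: tuple = tuple(np.logspace(-3, 0, 6))
    tau_grid: tuple = tuple(np.logspace(-3, 0, 4))
    bootstrap_B: int = 200
    n_permutations: int = 100
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.preset not in mc.PRESETS:
            raise ConfigurationError(f"preset must be one of {sorted(mc.PRESETS)}")
        if not self.synthetic:
            for attr in ("observations_csv", "environment_csv"):
                path = getattr(self, attr)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(f"{attr} missing or does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        def plain(v):
            if isinstance(v, (tuple, list)):
                return [plain(x) for x in v]
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v

        d = {k: plain(getattr(self, k)) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# krillab {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_stage_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _load_inputs(config: RunConfig):
    if config.synthetic:
        scfg = syn.SyntheticConfig(
            n_years=config.n_years, start_year=config.start_year, seed=config.seed,
            preset=config.preset, obs_noise_sd=config.obs_noise_sd,
        )
        study = syn.make_study(scfg)
        return study["observations"], study["env"]
    obs = read_stage_csv(config.observations_csv)
    env = read_stage_csv(config.environment_csv)
    obs = obs.copy()
    if obs["year"].min() >= 1000:  # calendar years -> model-year indices
        obs["year"] = obs["year"] - config.start_year
    return obs, env


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages, writing intermediates and a summary into outdir.

    Returns the summary dict (also saved as summary.json). Any stage failure
    raises with the stage name; previously written outputs are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    config.to_yaml(outdir / "config.yaml")
    summary: dict = {"version": __version__, "seed": config.seed, "preset": config.preset}
    stage = "load-inputs"
    try:
        obs, env = _load_inputs(config)
        _write_csv(obs, outdir / "observations.csv", config.seed)
        _write_csv(env, outdir / "environment.csv", config.seed)
        n = len(obs)
        years_cal = obs["year"].to_numpy() + config.start_year

        stage = "fit-timeconstant"
        log.info("stage 1: time-constant %s fit (seed %d)", config.preset, config.seed)
        tc = an.fit_timeconstant(
            obs, preset=config.preset, seed=config.seed, n_starts=config.n_starts
        )
        tc.params.to_yaml(outdir / "fitted_params.yaml")
        summary["timeconstant"] = {
            "cost": tc.cost,
            "params": tc.params.to_dict(),
            "n_evaluations": tc.n_evaluations,
        }

        stage = "fit-anomalies"
        log.info("stage 2: loss-anomaly fit")
        af = an.fit_anomalies(
            obs, tc.params,
            config=an.CostConfig(lambda_reg=config.lambda_reg),
            n_primary_cycles=config.n_primary_cycles,
            n_final_cycles=config.n_final_cycles,
            evals_per_cycle=config.evals_per_cycle,
            seed=config.seed + 1,
        )
        anom = af.anomalies
        _write_csv(anom.to_frame(config.start_year), outdir / "anomalies.csv", config.seed)
        cyc = pd.DataFrame(
            af.cycle_solutions[:, : 2 * n],
            columns=[f"delta_L_{y}" for y in range(n)] + [f"delta_J_{y}" for y in range(n)],
        )
        cyc.insert(0, "cost", af.cycle_costs)
        cyc.insert(1, "retained", af.retained)
        _write_csv(cyc, outdir / "anomaly_cycles.csv", config.seed)
        summary["anomalies"] = {
            "cost": af.cost,
            "n_cycles": int(len(af.cycle_costs)),
            "n_retained": int(af.retained.sum()),
            "initial_conditions": [af.params.L0, af.params.J0, af.params.A0],
        }

        stage = "correlation-screen"
        log.info("stage 3a: correlation screen")
        factors = [f for f in env["factor"].unique()]
        screens = {}
        for cohort, values in (("L", anom.delta_L), ("J", anom.delta_J)):
            scr = envstats.correlation_screen(values, years_cal, env, factors=factors)
            scr.to_csv(outdir / f"screen_{cohort}.csv")
            screens[cohort] = scr
        summary["screen"] = {
            c: int(s.significant.to_numpy().sum()) for c, s in screens.items()
        }

        stage = "fused-lasso"
        log.info("stage 3b: fused LASSO subset selection")
        lasso_summary = {}
        for cohort, values in (("L", anom.delta_L), ("J", anom.delta_J)):
            design = fl.build_design(values, years_cal, env, factors=config.factors)
            sel = fl.subset_model_selection(
                design, K=config.K, lambda_grid=np.asarray(config.lambda_grid),
                tau_grid=np.asarray(config.tau_grid), seed=config.seed + 2,
            )
            _write_csv(sel.report, outdir / f"lasso_selection_{cohort}.csv", config.seed)
            importance = fl.factor_importance(sel.models, config.factors)
            _write_csv(
                importance.rename_axis("factor").reset_index(),
                outdir / f"lasso_importance_{cohort}.csv", config.seed,
            )
            sub_design = design.subset(sel.selected_factors)
            bands = fl.bootstrap_bands(
                sub_design, sel.selected.lambda_l1, sel.selected.tau_fuse,
                B=config.bootstrap_B, seed=config.seed + 3,
            )
            _write_csv(bands, outdir / f"lasso_coefficients_{cohort}.csv", config.seed)
            pred, r2 = fl.predict_and_score(
                sel.selected, fl.design_raw_matrix(sub_design), sub_design.y
            )
            _write_csv(
                pd.DataFrame({"year": years_cal, "observed": sub_design.y, "predicted": pred}),
                outdir / f"lasso_prediction_{cohort}.csv", config.seed,
            )
            lasso_summary[cohort] = {
                "selected_factors": list(sel.selected_factors),
                "cv_error": sel.selected.cv_error,
                "lambda0": sel.selected.lambda_l1,
                "tau0": sel.selected.tau_fuse,
                "r2": r2,
            }
        summary["lasso"] = lasso_summary

        stage = "permutation-experiment"
        log.info("stage 3c: permuted-anomaly experiment")
        perm = envstats.permuted_anomaly_experiment(
            anom, af.params, n_permutations=config.n_permutations,
            seed=config.seed + 4, years=n,
        )
        _write_csv(pd.DataFrame({"r": perm["r"]}), outdir / "permuted_r.csv", config.seed)
        traj = mc.simulate(af.params, anomalies=anom, years=n, method="fast")
        _, r_unperm = envstats.recruit_vs_adult(traj.jan1)
        summary["permutation"] = {
            "median_r": perm["median_r"], "unpermuted_r": r_unperm,
        }
    except Exception:
        log.error("pipeline failed in stage %s", stage)
        raise

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def simulate_only(
    params: mc.ModelParams, years: int, outdir, seed: int = 0, anomalies=None
) -> mc.Trajectory:
    """Run a standalone simulation and export trajectory + 1 January CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = mc.simulate(params, anomalies=anomalies, years=years)
    _write_csv(traj.frame, outdir / "trajectory.csv", seed)
    _write_csv(traj.jan1, outdir / "jan1_samples.csv", seed)
    params.to_yaml(outdir / "params.yaml")
    return traj
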