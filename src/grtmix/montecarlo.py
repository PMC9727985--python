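"""Monte Carlo type I error studies over scenario grids.

A scenario pairs one generating mechanism (design, variance components, null
fixed effects) with a list of analytic models.  For every replication a
dataset is simulated, each analytic model is fitted by unconstrained REML,
the time x condition interaction is tested, and the rejection proportion at
the nominal level estimates the type I error rate.  Replication seeds are
derived deterministically from ``(base_seed, rep)`` so any single flagged fit
can be replayed in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import COHORT, CROSS_SECTIONAL, RM, DesignConfig, FixedEffects, VarianceComponents
from .icc import CorrelationSummary, cac, solve_components, summarize
from .inference import TestUnavailable, test_interaction
from .models import AnalyticModelName, all_model_names, make_spec
from .reml import build_matrices
from .simulate import simulate

__all__ = ["Scenario", "MCResult", "wilson_interval", "replication_seed", "run_scenario", "grid_run", "load_grid_config"]

log = logging.getLogger("grtmix.montecarlo")


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return (max(0.0, centre - half), min(1.0, centre + half))


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation study."""

    design: DesignConfig
    vc: VarianceComponents
    analytic_models: tuple[AnalyticModelName, ...]
    n_reps: int = 300
    alpha: float = 0.05
    base_seed: int = 1
    df_method: str = "KR"
    fx: FixedEffects = field(default_factory=FixedEffects.null)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class MCResult:
    """Rejection-proportion estimate for one (scenario, model) pair."""

    model: AnalyticModelName
    df_method: str
    n_reps: int
    n_converged: int
    n_failed: int
    n_rejected: int
    rejection_rate: float
    ci_low: float
    ci_high: float
    p_values: np.ndarray  # NaN where the fit failed


def replication_seed(base_seed: int, rep: int) -> tuple[int, int]:
    """Seed material for one replication (printable, replayable)."""
    return (int(base_seed), int(rep))


def run_scenario(scenario: Scenario, keep_pvalues: bool = True) -> list[MCResult]:
    """Run the Monte Carlo for one scenario; one result per analytic model."""
    design, vc = scenario.design, scenario.vc
    compiled = []
    for name in scenario.analytic_models:
        spec = make_spec(name, n_periods=design.n_periods, df_method=scenario.df_method)
        compiled.append((name, build_matrices(design, spec)))
    pvals = np.full((len(compiled), scenario.n_reps), np.nan)
    for rep in range(scenario.n_reps):
        seed = replication_seed(scenario.base_seed, rep)
        ds = simulate(design, scenario.fx, vc, np.random.default_rng(list(seed)))
        for mi, (name, dm) in enumerate(compiled):
            fit = dm.fit_dataset(ds)
            try:
                test = test_interaction(fit, scenario.df_method)
            except TestUnavailable as exc:
                log.warning("rep %d model %s failed (%s); replay seed %s", rep, name.label, exc, seed)
                continue
            pvals[mi, rep] = test.p_value
    results = []
    for mi, (name, _) in enumerate(compiled):
        pv = pvals[mi]
        ok = np.isfinite(pv)
        n_conv = int(ok.sum())
        n_rej = int(np.sum(pv[ok] <= scenario.alpha))
        if n_conv == 0:
            raise TestUnavailable(f"all {scenario.n_reps} replications failed for model {name.label}")
        rate = n_rej / n_conv
        lo, hi = wilson_interval(n_rej, n_conv)
        results.append(
            MCResult(
                model=name, df_method=scenario.df_method, n_reps=scenario.n_reps,
                n_converged=n_conv, n_failed=scenario.n_reps - n_conv, n_rejected=n_rej,
                rejection_rate=rate, ci_low=lo, ci_high=hi,
                p_values=pv if keep_pvalues else np.array([]),
            )
        )
    return results


# -- scenario-grid configuration -------------------------------------------

_TOP_KEYS = {"seed", "n_reps", "alpha", "df_method", "design", "scenarios", "models"}
_DESIGN_KEYS = {"groups_per_condition", "members_per_group", "n_periods", "n_conditions", "time_values"}
_SCEN_KEYS = {"mechanism", "structure", "components", "targets", "anchors", "sigma2_tm"}
_MODEL_KEYS = {"family", "timexgroup"}
_TARGET_KEYS = {"wpicc", "cac", "iac"}
_COMP_KEYS = {"sigma2_g", "sigma2_tg", "sigma2_m", "sigma2_tm", "sigma2_e", "cov_g", "cov_m"}


class ConfigError(ValueError):
    """Raised for malformed grid configuration."""


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


def load_grid_config(config) -> dict:
    """Validate a grid config (dict or YAML path) and materialize defaults."""
    if not isinstance(config, dict):
        import yaml
        from pathlib import Path

        with open(Path(config)) as fh:
            config = yaml.safe_load(fh)
    _check_keys(config, _TOP_KEYS, "top level")
    out = {
        "seed": int(config.get("seed", 1)),
        "n_reps": int(config.get("n_reps", 300)),
        "alpha": float(config.get("alpha", 0.05)),
        "df_method": str(config.get("df_method", "KR")).upper(),
    }
    design = dict(config.get("design", {}))
    _check_keys(design, _DESIGN_KEYS, "design")
    gs = design.get("groups_per_condition", [10])
    out["groups_list"] = [int(g) for g in (gs if isinstance(gs, (list, tuple)) else [gs])]
    out["design_base"] = {
        "members_per_group": int(design.get("members_per_group", 40)),
        "n_periods": int(design.get("n_periods", 5)),
        "n_conditions": int(design.get("n_conditions", 2)),
    }
    if "time_values" in design:
        out["design_base"]["time_values"] = tuple(float(v) for v in design["time_values"])
    scens = config.get("scenarios")
    if not scens:
        raise ConfigError("config must list at least one scenario")
    out["scenarios"] = []
    for i, sc in enumerate(scens):
        sc = dict(sc)
        _check_keys(sc, _SCEN_KEYS, f"scenarios[{i}]")
        if ("components" in sc) == ("targets" in sc):
            raise ConfigError(f"scenarios[{i}] must give exactly one of 'components' or 'targets'")
        if "components" in sc:
            _check_keys(dict(sc["components"]), _COMP_KEYS, f"scenarios[{i}].components")
        else:
            _check_keys(dict(sc["targets"]), _TARGET_KEYS, f"scenarios[{i}].targets")
        out["scenarios"].append(sc)
    models = config.get("models")
    if models:
        parsed = []
        for j, mdl in enumerate(models):
            mdl = dict(mdl)
            _check_keys(mdl, _MODEL_KEYS, f"models[{j}]")
            parsed.append((str(mdl["family"]), bool(mdl.get("timexgroup", True))))
        out["models"] = parsed
    else:
        out["models"] = None
    return out


def _scenario_vc(sc: dict, structure: str) -> VarianceComponents:
    mechanism = sc.get("mechanism", RM)
    if "components" in sc:
        comp = dict(sc["components"])
        return VarianceComponents(
            sigma2_g=float(comp.get("sigma2_g", 0.0)),
            sigma2_tg=float(comp.get("sigma2_tg", 0.0)),
            sigma2_m=float(comp.get("sigma2_m", 0.0)),
            sigma2_tm=float(comp.get("sigma2_tm", 0.0)),
            sigma2_e=float(comp.get("sigma2_e", 0.0)),
            cov_g=float(comp.get("cov_g", 0.0)),
            cov_m=float(comp.get("cov_m", 0.0)),
            mechanism=mechanism, structure=structure,
        )
    tg = dict(sc["targets"])
    anchors = tuple(sc.get("anchors", (1.0, 1.0)))
    target = CorrelationSummary(
        wpicc=float(tg["wpicc"]),
        cac=float(tg["cac"]) if "cac" in tg else None,
        iac=float(tg["iac"]) if "iac" in tg else None,
    )
    return solve_components(target, anchors=anchors, structure=structure,
                            mechanism=mechanism, sigma2_tm=sc.get("sigma2_tm"))


def grid_run(config, progress: bool = False) -> pd.DataFrame:
    """Run every (scenario, groups, model) cell of a config; tidy results table."""
    cfg = load_grid_config(config)
    rows = []
    scenario_index = 0
    for sc in cfg["scenarios"]:
        structure = sc.get("structure", CROSS_SECTIONAL)
        for g in cfg["groups_list"]:
            design = DesignConfig(groups_per_condition=g, structure=structure, **cfg["design_base"])
            vc = _scenario_vc(sc, structure)
            if cfg["models"] is None:
                names = tuple(all_model_names(structure))
            else:
                names = tuple(AnalyticModelName(f, tx, structure) for f, tx in cfg["models"])
            base_seed = cfg["seed"] + 1000 * scenario_index
            scenario = Scenario(
                design=design, vc=vc, analytic_models=names, n_reps=cfg["n_reps"],
                alpha=cfg["alpha"], base_seed=base_seed, df_method=cfg["df_method"],
            )
            if progress:
                log.info("scenario %d: %s %s g=%d", scenario_index, vc.mechanism, structure, g)
            summ = summarize(vc)
            try:
                results = run_scenario(scenario, keep_pvalues=False)
            except TestUnavailable as exc:
                log.warning("scenario %d failed entirely: %s", scenario_index, exc)
                scenario_index += 1
                continue
            for res in results:
                rows.append(
                    {
                        "mechanism": vc.mechanism,
                        "structure": structure,
                        "g": g,
                        "wpicc_label": round(summ.wpicc, 6),
                        "cac": round(summ.cac, 6) if summ.cac is not None else np.nan,
                        "model": res.model.family,
                        "timexgroup": res.model.timexgroup,
                        "df_method": res.df_method,
                        "n_reps": res.n_reps,
                        "n_failed": res.n_failed,
                        "rejection_rate": res.rejection_rate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "base_seed": scenario.base_seed,
                    }
                )
            scenario_index += 1
    return pd.DataFrame(rows)
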