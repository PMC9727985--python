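"""Outcome simulation for multiple-period parallel group-randomized trials.

Two generating mechanisms, each with a cross-sectional and a cohort variant:

* repeated-measures ANOVA (RM): categorical time; random intercepts for group,
  time x group, and (cohort) member, plus residual error;
* random coefficients (RC): continuous time; random intercepts and slopes for
  group and (cohort) member, plus residual error.

All random effects are drawn as independent normals at the configured
variances (an optional intercept-slope covariance is supported for RC).
Datasets are generated under any fixed-effect configuration; the type I error
study uses all-zero fixed effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import (
    COHORT,
    CROSS_SECTIONAL,
    RC,
    RM,
    DesignConfig,
    FixedEffects,
    TrialDataset,
    VarianceComponents,
)

__all__ = ["simulate_rm", "simulate_rc", "simulate", "empirical_moments", "MomentEstimates"]


def _check(design: DesignConfig, vc: VarianceComponents, mechanism: str) -> None:
    if vc.mechanism != mechanism:
        raise ValueError(f"variance components are for the {vc.mechanism!r} mechanism")
    if vc.structure != design.structure:
        raise ValueError(
            f"structure mismatch: design is {design.structure!r}, components are {vc.structure!r}"
        )
    vc.validate_for_generation()


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_rm(design: DesignConfig, fx: FixedEffects, vc: VarianceComponents, seed) -> TrialDataset:
    """Simulate one dataset under the repeated-measures ANOVA mechanism."""
    _check(design, vc, RM)
    rng = _rng(seed)
    c, g, m, t = (design.n_conditions, design.groups_per_condition,
                  design.members_per_group, design.n_periods)
    mean = fx.cell_means(design, "categorical")  # (c, t)
    y = np.broadcast_to(mean[:, None, None, :], (c, g, m, t)).copy()
    y += np.sqrt(vc.sigma2_g) * rng.standard_normal((c, g, 1, 1))
    y += np.sqrt(vc.sigma2_tg) * rng.standard_normal((c, g, 1, t))
    if design.structure == COHORT:
        y += np.sqrt(vc.sigma2_m) * rng.standard_normal((c, g, m, 1))
    y += np.sqrt(vc.sigma2_e) * rng.standard_normal((c, g, m, t))
    return TrialDataset.from_tensor(y, design)


def _bivariate(rng: np.random.Generator, shape, v_int: float, v_slo: float, cov: float):
    """Correlated (intercept, slope) draws via the Cholesky factor of the 2x2 cov."""
    z = rng.standard_normal((2,) + shape)
    a = np.sqrt(v_int)
    b = cov / a if a > 0 else 0.0
    c2 = v_slo - b * b
    c = np.sqrt(max(c2, 0.0))
    return a * z[0], b * z[0] + c * z[1]


def simulate_rc(design: DesignConfig, fx: FixedEffects, vc: VarianceComponents, seed) -> TrialDataset:
    """Simulate one dataset under the random-coefficients mechanism."""
    _check(design, vc, RC)
    rng = _rng(seed)
    c, g, m, t = (design.n_conditions, design.groups_per_condition,
                  design.members_per_group, design.n_periods)
    tv = np.asarray(design.time_values)
    mean = fx.cell_means(design, "linear")
    y = np.broadcast_to(mean[:, None, None, :], (c, g, m, t)).copy()
    gi, gs = _bivariate(rng, (c, g), vc.sigma2_g, vc.sigma2_tg, vc.cov_g)
    y += gi[:, :, None, None] + gs[:, :, None, None] * tv
    if design.structure == COHORT:
        mi, ms = _bivariate(rng, (c, g, m), vc.sigma2_m, vc.sigma2_tm, vc.cov_m)
        y += mi[:, :, :, None] + ms[:, :, :, None] * tv
    y += np.sqrt(vc.sigma2_e) * rng.standard_normal((c, g, m, t))
    return TrialDataset.from_tensor(y, design)


def simulate(design: DesignConfig, fx: FixedEffects, vc: VarianceComponents, seed) -> TrialDataset:
    """Dispatch on the mechanism recorded in the variance components."""
    if vc.mechanism == RM:
        return simulate_rm(design, fx, vc, seed)
    return simulate_rc(design, fx, vc, seed)


# -- method-of-moments validation helpers ---------------------------------


@dataclass(frozen=True)
class MomentEstimates:
    """Monte Carlo method-of-moments estimates with standard errors."""

    wpicc: float
    wpicc_se: float
    cac: float
    cac_se: float
    iac: float | None
    iac_se: float | None
    n_datasets: int


def _moments_one(ds: TrialDataset) -> tuple[float, float, float, float]:
    """Unbiased per-dataset estimates of the four moment building blocks.

    Returns ``(b, w, s2_g, s2_m)``: the group-level within-period variance
    ``s2_g + s2_tg``, the member-level variance ``s2_m + s2_tm + s2_e``, the
    group-intercept variance and the member-intercept variance (RM mapping).
    Outcomes are centered per condition x period; cross-period covariance
    estimators carry the exact finite-g / finite-m corrections for that
    centering.
    """
    d = ds.design
    g = d.groups_per_condition
    if g < 2:
        raise ValueError("moment estimation needs at least two groups per condition")
    y, cond = ds.to_tensor()  # (G, m, t)
    G, m, t = y.shape
    yc = y.astype(float).copy()
    for ci in np.unique(cond):
        sel = cond == ci
        yc[sel] -= y[sel].mean(axis=(0, 1), keepdims=True)

    # within group-period variance: E = s2_m + s2_tm + s2_e
    w_hat = float(yc.var(axis=1, ddof=1).mean()) if m > 1 else float("nan")
    gp = yc.mean(axis=1)  # group-period means (G, t)

    b_parts, c_parts = [], []
    for ci in np.unique(cond):
        sub = gp[cond == ci]  # (g, t)
        b_parts.append(sub.var(axis=0, ddof=1))  # E = s2_g + s2_tg + w/m
        cc = (sub.T @ sub) / (sub.shape[0] - 1)
        c_parts.append(float(cc[~np.eye(t, dtype=bool)].mean()))
    b_hat = float(np.mean(b_parts)) - (0.0 if m == 1 else w_hat / m)
    # cross-period covariance of centered group means with 1/(g-1) divisor is
    # unbiased for s2_g + s2_m/m (the centering terms cancel exactly)
    c_g = float(np.mean(c_parts))

    if d.structure == COHORT and m > 1:
        # same-member cross-period products:
        # E = s2_g (1 - 1/g) + s2_m (1 - 1/(g m))
        cm = np.einsum("gij,gik->jk", yc, yc) / (G * m)
        c_m = float(cm[~np.eye(t, dtype=bool)].mean())
        s2_m = (c_m - c_g * (1.0 - 1.0 / g)) / (1.0 - 1.0 / m)
        s2_g = c_g - s2_m / m
    else:
        s2_g, s2_m = c_g, 0.0
    return b_hat, w_hat, s2_g, s2_m


def _ratio_se(num: np.ndarray, den: np.ndarray) -> tuple[float, float]:
    """Delta-method mean and MC standard error of mean(num)/mean(den)."""
    R = len(num)
    nbar, dbar = num.mean(), den.mean()
    est = nbar / dbar
    if R < 2:
        return float(est), float("nan")
    cov = np.cov(num, den, ddof=1)
    var = (cov[0, 0] / dbar**2 - 2 * cov[0, 1] * nbar / dbar**3 + cov[1, 1] * nbar**2 / dbar**4) / R
    return float(est), float(math.sqrt(max(var, 0.0)))


def empirical_moments(datasets) -> MomentEstimates:
    """Pooled moment estimates of WPICC / CAC / IAC over replicate datasets.

    Each summary is a ratio of across-replicate means of unbiased component
    estimators (not a mean of per-dataset ratios, whose small-sample ratio
    bias would not vanish with more replicates); standard errors are
    delta-method Monte Carlo errors, so estimates can be compared to
    configured targets at a stated number of MC standard errors.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("at least one dataset is required")
    comp = np.array([_moments_one(ds) for ds in datasets], dtype=float)
    b, w, s2_g, s2_m = comp.T
    R = len(datasets)
    wp, wp_se = _ratio_se(b, b + w)
    ca, ca_se = _ratio_se(s2_g, b)
    if datasets[0].design.structure == COHORT:
        ia, ia_se = _ratio_se(s2_m, w)
    else:
        ia, ia_se = None, None
    return MomentEstimates(
        wpicc=wp, wpicc_se=wp_se, cac=ca, cac_se=ca_se,
        iac=ia, iac_se=ia_se, n_datasets=R,
    )
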