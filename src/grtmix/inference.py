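"""Small-sample F-tests of the time x condition interaction.

Two denominator-degrees-of-freedom strategies:

* Kenward-Roger: inflate the model-based covariance of the fixed effects for
  the uncertainty in the estimated covariance parameters, then derive a scale
  factor and (possibly fractional) denominator df by matching the first two
  moments of the Wald statistic to a scaled F distribution.  Because every
  covariance structure fitted here is linear in its parameters, the
  second-derivative terms that distinguish the improved ("kr2") adjustment
  from the original first-order one vanish, and the two options coincide.
* Between-within: the classic design-based partition — effects that vary
  within groups (time, time x condition) receive the within-group residual
  df; group-constant effects (condition) receive the between-group df.

The tested null is no time x condition interaction: q = (t-1)(c-1) dummy
contrasts under categorical time coding, q = c-1 slope contrasts under
linear coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reml import FitResult

__all__ = ["InteractionTest", "TestUnavailable", "kr_adjusted_cov", "kr_adjust", "bw_df", "test_interaction"]


class TestUnavailable(RuntimeError):
    """Raised when a test cannot be formed (non-convergence, singular information)."""


@dataclass(frozen=True)
class InteractionTest:
    f_stat: float
    ndf: int
    ddf: float
    p_value: float
    method: str
    note: str = ""


def _interaction_contrast(fit: FitResult) -> np.ndarray:
    q = len(fit.interaction_cols)
    if q == 0:
        raise TestUnavailable("model has no interaction columns (single-period design?)")
    L = np.zeros((q, len(fit.beta_names)))
    for i, c in enumerate(fit.interaction_cols):
        L[i, c] = 1.0
    return L


def kr_adjusted_cov(fit: FitResult) -> np.ndarray:
    """Kenward-Roger small-sample adjusted covariance of the fixed effects."""
    if not fit.converged or fit.theta_cov is None or fit.kr_P is None:
        raise TestUnavailable(f"fit not converged: {fit.message}")
    Phi, P, Q, W = fit.beta_cov, fit.kr_P, fit.kr_Q, fit.theta_cov
    # Lambda = sum_rs W_rs (Q_rs - P_r Phi P_s); second-derivative term is zero
    # for covariance structures linear in theta.
    PPhiP = np.einsum("rij,jk,skl->rsil", P, Phi, P)
    Lam = np.einsum("rs,rsij->ij", W, Q - PPhiP)
    adj = Phi + 2.0 * Phi @ Lam @ Phi
    return 0.5 * (adj + adj.T)


def kr_adjust(fit: FitResult, contrast: np.ndarray | None = None, method: str = "kr2") -> InteractionTest:
    """Kenward-Roger scaled F-test of ``contrast @ beta = 0``.

    ``method`` accepts ``"kr2"`` (default, the improved adjustment) or
    ``"kr"``/``"kr1"``; with covariance structures linear in their parameters
    the adjustments are identical and share one code path.
    """
    if method not in ("kr", "kr1", "kr2"):
        raise ValueError(f"unknown KR method {method!r}")
    L = _interaction_contrast(fit) if contrast is None else np.atleast_2d(np.asarray(contrast, float))
    q = L.shape[0]
    Phi, P, W = fit.beta_cov, fit.kr_P, fit.theta_cov
    if not fit.converged or W is None:
        raise TestUnavailable(f"fit not converged: {fit.message}")
    Phi_A = kr_adjusted_cov(fit)

    M = L @ Phi_A @ L.T
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise TestUnavailable("adjusted contrast covariance is singular") from exc
    Lb = L @ fit.beta
    F_wald = float(Lb @ Minv @ Lb) / q

    # moment matching for the scale and denominator df
    try:
        Theta = L.T @ np.linalg.inv(L @ Phi @ L.T) @ L
    except np.linalg.LinAlgError as exc:
        raise TestUnavailable("contrast covariance is singular") from exc
    C = np.einsum("ij,rjk,kl->ril", Phi, P, Phi)  # dPhi/dtheta_r up to sign
    TC = np.einsum("ij,rjk->rik", Theta, C)
    a_vec = np.einsum("rii->r", TC)
    A1 = float(a_vec @ W @ a_vec)
    A2 = float(np.einsum("rs,rij,sji->", W, TC, TC))

    ols_ddf = float(fit.n_obs - fit.rank_x)
    note = ""
    if A2 <= 0 or not np.isfinite(A1 + A2):
        ddf, lam = ols_ddf, 1.0
        note = "degenerate moment matching; OLS-limit df used"
    else:
        B = (A1 + 6.0 * A2) / (2.0 * q)
        g = ((q + 1.0) * A1 - (q + 4.0) * A2) / ((q + 2.0) * A2)
        den = 3.0 * q + 2.0 * (1.0 - g)
        c1 = g / den
        c2 = (q - g) / den
        c3 = (q + 2.0 - g) / den
        Estar_inv = 1.0 - A2 / q
        if Estar_inv <= 0:
            ddf, lam = ols_ddf, 1.0
            note = "degenerate moment matching; OLS-limit df used"
        else:
            Estar = 1.0 / Estar_inv
            Vstar = (2.0 / q) * (1.0 + c1 * B) / ((1.0 - c2 * B) ** 2 * (1.0 - c3 * B))
            rho = Vstar / (2.0 * Estar**2)
            if q * rho <= 1.0:
                ddf, lam = ols_ddf, 1.0
                note = "degenerate moment matching; OLS-limit df used"
            else:
                ddf = 4.0 + (q + 2.0) / (q * rho - 1.0)
                lam = ddf / (Estar * (ddf - 2.0))
    ddf = min(ddf, ols_ddf)  # KR never exceeds the OLS limit
    f_scaled = lam * F_wald
    p = float(stats.f.sf(f_scaled, q, ddf))
    return InteractionTest(f_stat=f_scaled, ndf=q, ddf=float(ddf), p_value=p,
                           method="KR" if method != "kr2" else "KR2", note=note)


def bw_df(fit: FitResult, contrast: np.ndarray | None = None) -> InteractionTest:
    """Between-within F-test: integer design-based denominator df."""
    if not fit.converged:
        raise TestUnavailable(f"fit not converged: {fit.message}")
    L = _interaction_contrast(fit) if contrast is None else np.atleast_2d(np.asarray(contrast, float))
    q = L.shape[0]
    within_cols = int(np.sum(fit.within_mask))
    between_cols = fit.rank_x - within_cols
    uses_within = bool(np.any(L[:, fit.within_mask] != 0))
    if uses_within:
        ddf = fit.n_obs - fit.n_groups - within_cols
    else:
        ddf = fit.n_groups - between_cols
    if ddf <= 0:
        raise TestUnavailable("nonpositive between-within denominator df")
    M = L @ fit.beta_cov @ L.T
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise TestUnavailable("contrast covariance is singular") from exc
    Lb = L @ fit.beta
    F = float(Lb @ Minv @ Lb) / q
    p = float(stats.f.sf(F, q, float(ddf)))
    return InteractionTest(f_stat=F, ndf=q, ddf=float(ddf), p_value=p, method="BW")


def test_interaction(fit: FitResult, method: str = "KR") -> InteractionTest:
    """Test the time x condition interaction with the requested df method."""
    m = method.lower()
    if m in ("kr", "kr1", "kr2"):
        return kr_adjust(fit, method="kr2" if m in ("kr", "kr2") else "kr1")
    if m == "bw":
        return bw_df(fit)
    raise ValueError(f"unknown df method {method!r}")
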