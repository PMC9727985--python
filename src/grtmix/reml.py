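"""Unconstrained REML estimation for balanced multiple-period GRT mixed models.

The marginal covariance of every analytic model in the registry is *linear*
in its covariance parameters: for one group's stacked outcome vector
(members x periods, member-major),

    V(theta) = sum_r theta_r [ J_m (x) B_r + I_m (x) A_r ]

where ``B_r`` are t x t group-level patterns (shared by all members) and
``A_r`` are t x t within-member patterns (member random effects, residual).
Balance is exploited through an exact orthonormal decomposition of each
group's data into the member-mean series (covariance ``m B + A``, carrying
the fixed effects) and ``m - 1`` member-contrast series (covariance ``A``,
mean zero because fixed effects are constant across members within a
group-period).  The transform is orthogonal, so the REML criterion — and
every Kenward-Roger ingredient — is identical to the individual-level fit
while all dense algebra is t x t.

Estimation is Fisher scoring (expected-information Newton, the natural
algorithm for linear covariance structures) with step-halving, method-of-
moments starting values, and no nonnegativity constraint on the parameters
("nobound"): any theta with positive-definite stratum covariances is
admissible, and negative variance estimates are reported, not truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg

from .data import (
    COHORT,
    CROSS_SECTIONAL,
    DesignConfig,
    TrialDataset,
    BalanceError,
)
from .models import ModelSpec, RandomTerm

__all__ = [
    "DesignError",
    "ConvergenceSettings",
    "FitResult",
    "build_matrices",
    "reml_fit",
    "group_mean_reduce",
    "marginal_covariance",
    "fixed_effects_design",
]

LOG2PI = math.log(2.0 * math.pi)


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable design matrices."""


# -- fixed-effects design --------------------------------------------------


def fixed_effects_design(design: DesignConfig, time_coding: str):
    """Per-condition t x p fixed-effect design matrices with treatment coding.

    Reference levels are condition 1 (control) and period 1, so the columns
    are: intercept, condition dummies (l >= 2), then either period dummies
    (j >= 2) and their condition interactions (categorical coding) or the
    linear time value and its condition interactions (linear coding).

    Returns ``(X_by_condition, names, within_mask, interaction_cols)``.
    """
    c, t = design.n_conditions, design.n_periods
    tv = np.asarray(design.time_values)
    names: list[str] = ["intercept"] + [f"condition[{l}]" for l in range(2, c + 1)]
    within: list[bool] = [False] * (1 + (c - 1))
    interaction_cols: list[int] = []
    if time_coding == "categorical":
        names += [f"period[{j}]" for j in range(2, t + 1)]
        within += [True] * (t - 1)
        for l in range(2, c + 1):
            for j in range(2, t + 1):
                interaction_cols.append(len(names))
                names.append(f"period[{j}]:condition[{l}]")
                within.append(True)
    else:
        names.append("time")
        within.append(True)
        for l in range(2, c + 1):
            interaction_cols.append(len(names))
            names.append(f"time:condition[{l}]")
            within.append(True)
    p = len(names)
    Xs = []
    for l in range(1, c + 1):
        X = np.zeros((t, p))
        X[:, 0] = 1.0
        if l >= 2:
            X[:, l - 1] = 1.0
        col = c
        if time_coding == "categorical":
            for j in range(2, t + 1):
                X[j - 1, col] = 1.0
                col += 1
            for ll in range(2, c + 1):
                for j in range(2, t + 1):
                    if ll == l:
                        X[j - 1, col] = 1.0
                    col += 1
        else:
            X[:, col] = tv
            col += 1
            for ll in range(2, c + 1):
                if ll == l:
                    X[:, col] = tv
                col += 1
        Xs.append(X)
    stacked = np.vstack(Xs)
    if np.linalg.matrix_rank(stacked) < p:
        keep = []
        rank = 0
        aliased = []
        for j in range(p):
            r = np.linalg.matrix_rank(stacked[:, keep + [j]])
            if r > rank:
                keep.append(j)
                rank = r
            else:
                aliased.append(names[j])
        raise DesignError(f"fixed-effects design is rank deficient; aliased column(s): {aliased}")
    return Xs, names, np.array(within), interaction_cols


# -- covariance templates --------------------------------------------------


@dataclass(frozen=True)
class _Param:
    name: str
    is_variance: bool
    B: np.ndarray | None  # group-level t x t pattern
    A: np.ndarray | None  # within-member t x t pattern


def _un_patterns(t: int, prefix: str) -> list[tuple[str, bool, np.ndarray]]:
    out = []
    for j in range(t):
        for k in range(j + 1):
            E = np.zeros((t, t))
            if j == k:
                E[j, j] = 1.0
            else:
                E[j, k] = E[k, j] = 1.0
            out.append((f"{prefix}({j + 1},{k + 1})", j == k, E))
    return out


def _term_params(term: RandomTerm, t: int, tv: np.ndarray) -> list[_Param]:
    J = np.ones((t, t))
    I = np.eye(t)
    w = tv.astype(float)
    ww = np.outer(w, w)
    sym = np.outer(np.ones(t), w)
    sym = sym + sym.T
    grp = term.level == "group"

    def P(name, is_var, M):
        return _Param(name, is_var, B=M if grp else None, A=None if grp else M)

    s = "g" if grp else "m"
    if term.kind == "intercept":
        return [P(f"sigma2_{s}", True, J)]
    if term.kind == "time_categorical":
        return [P(f"sigma2_t{s}", True, I)]
    if term.kind == "time_un":
        pre = "G_un" if grp else "R_un"
        return [P(n, v, E) for n, v, E in _un_patterns(t, pre)]
    if term.kind == "rc_un":
        return [
            P(f"sigma2_{s}", True, J),
            P(f"cov_{s}_ts", False, sym),
            P(f"sigma2_t(lin){s}", True, ww),
        ]
    if term.kind == "rc_vc":
        return [P(f"sigma2_{s}", True, J), P(f"sigma2_t(lin){s}", True, ww)]
    if term.kind == "un1":
        return [P(f"R_un1({j + 1})", True, np.diag(I[j])) for j in range(t)]
    raise ValueError(f"unknown random term kind {term.kind!r}")


def _spec_params(spec: ModelSpec, t: int, tv: np.ndarray) -> list[_Param]:
    params: list[_Param] = []
    for term in spec.terms:
        params.extend(_term_params(term, t, tv))
    if spec.has_residual:
        params.append(_Param("sigma2_e", True, B=None, A=np.eye(t)))
    names = [p.name for p in params]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate covariance parameters in spec: {names}")
    return params


def marginal_covariance(spec: ModelSpec, design: DesignConfig, theta: Sequence[float]) -> np.ndarray:
    """Materialize one group's full (m*t x m*t) marginal covariance, member-major.

    Used for documentation and as the engine's claim in dense-oracle checks;
    the fitting path never forms this matrix.
    """
    t = design.n_periods
    m = design.members_per_group
    tv = np.asarray(design.time_values)
    params = _spec_params(spec, t, tv)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(params),):
        raise ValueError(f"expected {len(params)} parameters, got {theta.shape}")
    B = np.zeros((t, t))
    A = np.zeros((t, t))
    for th, p in zip(theta, params):
        if p.B is not None:
            B = B + th * p.B
        if p.A is not None:
            A = A + th * p.A
    return np.kron(np.ones((m, m)), B) + np.kron(np.eye(m), A)


# -- fit result ------------------------------------------------------------


@dataclass
class FitResult:
    """REML estimates plus the ingredients for small-sample inference."""

    beta: np.ndarray
    beta_names: list[str]
    theta: np.ndarray
    theta_names: list[str]
    variance_flags: np.ndarray
    reml_loglik: float
    beta_cov: np.ndarray  # (X' V^-1 X)^-1 at theta-hat
    converged: bool
    n_iter: int
    gradient_norm: float
    boundary_note: bool  # any variance-type estimate < 0 (nobound)
    message: str
    n_obs: int  # observations at the fitted level
    n_groups: int
    rank_x: int
    interaction_cols: list[int]
    within_mask: np.ndarray
    # Kenward-Roger ingredients (None when not converged)
    kr_P: np.ndarray | None = None  # (k, p, p): d(X'V^-1 X)/dtheta_r
    kr_Q: np.ndarray | None = None  # (k, k, p, p)
    theta_cov: np.ndarray | None = None  # inverse expected information
    spec: ModelSpec | None = None

    @property
    def beta_cov_adjusted(self) -> np.ndarray:
        from .inference import kr_adjusted_cov

        return kr_adjusted_cov(self)

    def beta_series(self) -> dict[str, float]:
        return dict(zip(self.beta_names, self.beta))

    def theta_series(self) -> dict[str, float]:
        return dict(zip(self.theta_names, self.theta))


@dataclass(frozen=True)
class ConvergenceSettings:
    rel_loglik_tol: float = 1e-10
    grad_tol: float = 1e-6
    max_iter: int = 200
    max_halvings: int = 30


# -- the engine ------------------------------------------------------------


class DesignMatrices:
    """Compiled design for fitting one model spec to datasets of one design.

    Building the fixed-effect patterns and covariance templates once lets
    Monte Carlo loops reuse them across replications.
    """

    def __init__(self, design: DesignConfig, spec: ModelSpec):
        self.orig_design = design
        self.orig_spec = spec
        self.reduce_to_means = spec.fitting_level == "group_mean"
        t = design.n_periods
        if self.reduce_to_means:
            eff_design = replace(design, members_per_group=1, structure=COHORT)
            eff_spec = spec.mean_formulation(t)
        else:
            eff_design, eff_spec = design, spec
        self.design = eff_design
        self.spec = eff_spec
        self.t = t
        self.m = eff_design.members_per_group
        self.G = eff_design.n_groups_total
        tv = np.asarray(eff_design.time_values)
        self.params = _spec_params(eff_spec, t, tv)
        self.k = len(self.params)
        Xs, names, within, inter = fixed_effects_design(eff_design, eff_spec.time_coding)
        self.beta_names = names
        self.within_mask = within
        self.interaction_cols = inter
        self.p = len(names)
        sqm = math.sqrt(self.m)
        self.X_mean = [sqm * X for X in Xs]
        self.counts = np.full(eff_design.n_conditions, eff_design.groups_per_condition)
        # stratum templates
        TM = np.zeros((self.k, t, t))
        TC = np.zeros((self.k, t, t))
        for r, prm in enumerate(self.params):
            if prm.B is not None:
                TM[r] += self.m * prm.B
            if prm.A is not None:
                TM[r] += prm.A
                TC[r] += prm.A
        self.TM = TM
        self.has_contrast = self.m > 1
        self.TC = TC if self.has_contrast else None
        self.n_contrast = self.G * (self.m - 1)
        self.n_obs = self.G * self.m * t
        self.L = self._contrast_matrix()

    def _contrast_matrix(self) -> np.ndarray:
        q = len(self.interaction_cols)
        L = np.zeros((q, self.p))
        for i, c in enumerate(self.interaction_cols):
            L[i, c] = 1.0
        return L

    # -- data preparation --------------------------------------------------

    def suffstats(self, dataset: TrialDataset):
        d = dataset.design
        if (d.n_periods, d.members_per_group, d.n_groups_total, d.n_conditions) != (
            self.t, self.m, self.G, self.design.n_conditions
        ):
            raise BalanceError("dataset design does not match the compiled matrices")
        y, cond = dataset.to_tensor()  # (G, m, t)
        sqm = math.sqrt(self.m)
        z = y.sum(axis=1) / sqm  # member-mean series, orthonormal scaling
        nc = self.design.n_conditions
        syy = np.zeros((nc, self.t, self.t))
        sy = np.zeros((nc, self.t))
        for ci in range(nc):
            zz = z[cond == ci]
            syy[ci] = zz.T @ zz
            sy[ci] = zz.sum(axis=0)
        if self.has_contrast:
            syy_con = np.einsum("gmj,gmk->jk", y, y) - z.T @ z
        else:
            syy_con = None
        return _SuffStats(syy=syy, sy=sy, syy_con=syy_con)

    # -- likelihood machinery ---------------------------------------------

    def _eval(self, theta: np.ndarray, ss: "_SuffStats"):
        # degenerate iterates (huge theta, singular V) are rejected through the
        # finiteness guards below, so intermediate overflow is not an error
        with np.errstate(over="ignore", invalid="ignore"):
            return self._eval_inner(theta, ss)

    def _eval_inner(self, theta: np.ndarray, ss: "_SuffStats"):
        t, k = self.t, self.k
        if not np.all(np.isfinite(theta)):
            return None
        try:
            Lm = np.linalg.cholesky(np.einsum("r,rij->ij", theta, self.TM))
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(Lm)):
            return None
        Wm = linalg.cho_solve((Lm, True), np.eye(t))
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(Lm))))
        Am = np.einsum("ij,rjk->rik", Wm, self.TM)
        trA = float(self.G) * np.einsum("rii->r", Am)
        trAA = float(self.G) * np.einsum("rij,sji->rs", Am, Am)

        if self.has_contrast:
            try:
                Lc = np.linalg.cholesky(np.einsum("r,rij->ij", theta, self.TC))
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(Lc)):
                return None
            Wc = linalg.cho_solve((Lc, True), np.eye(t))
            logdet_c = 2.0 * float(np.sum(np.log(np.diag(Lc))))
            Ac = np.einsum("ij,rjk->rik", Wc, self.TC)
            trA = trA + self.n_contrast * np.einsum("rii->r", Ac)
            trAA = trAA + self.n_contrast * np.einsum("rij,sji->rs", Ac, Ac)
        else:
            logdet_c = 0.0

        p = self.p
        T = np.zeros((p, p))
        b = np.zeros(p)
        H = np.zeros((k, p, p))
        Q = np.zeros((k, k, p, p))
        Us = []
        for ci, X in enumerate(self.X_mean):
            g_c = float(self.counts[ci])
            U = Wm @ X
            Us.append(U)
            T += g_c * (X.T @ U)
            b += U.T @ ss.sy[ci]
            P1 = np.einsum("rij,jp->rip", self.TM, U)  # B_r W X
            P2 = np.einsum("ij,rjp->rip", Wm, P1)  # W B_r W X
            H += g_c * np.einsum("iq,rip->rqp", U, P1)
            Q += g_c * np.einsum("riq,sip->rsqp", P1, P2)

        sign, logdet_T = np.linalg.slogdet(T)
        if sign <= 0:
            return None
        Phi = np.linalg.inv(T)
        Phi = 0.5 * (Phi + Phi.T)
        beta = Phi @ b

        Sres = np.zeros((t, t))
        for ci, X in enumerate(self.X_mean):
            mu = X @ beta
            Sres += (
                ss.syy[ci]
                - np.outer(ss.sy[ci], mu)
                - np.outer(mu, ss.sy[ci])
                + float(self.counts[ci]) * np.outer(mu, mu)
            )
        quad = float(np.sum(Wm * Sres))
        Rres = Wm @ Sres @ Wm
        yPBPy = np.einsum("rij,ji->r", self.TM, Rres)
        if self.has_contrast:
            quad += float(np.sum(Wc * ss.syy_con))
            Rc = Wc @ ss.syy_con @ Wc
            yPBPy = yPBPy + np.einsum("rij,ji->r", self.TC, Rc)

        n = self.n_obs
        ll = -0.5 * (
            self.G * logdet_m + self.n_contrast * logdet_c + logdet_T + quad
        ) - 0.5 * (n - p) * LOG2PI

        trPhiH = np.einsum("rij,ji->r", H, Phi)
        score = -0.5 * (trA - trPhiH - yPBPy)
        PhiH = np.einsum("ij,rjk->rik", Phi, H)
        info = 0.5 * (
            trAA - 2.0 * np.einsum("rsqp,pq->rs", Q, Phi) + np.einsum("rij,sji->rs", PhiH, PhiH)
        )
        info = 0.5 * (info + info.T)
        if not (np.isfinite(ll) and np.all(np.isfinite(score)) and np.all(np.isfinite(info))):
            return None
        return _EvalState(ll=ll, score=score, info=info, beta=beta, Phi=Phi, H=H, Q=Q)

    # -- starting values ---------------------------------------------------

    def _start(self, ss: "_SuffStats") -> np.ndarray:
        p = self.p
        T0 = np.zeros((p, p))
        b0 = np.zeros(p)
        for ci, X in enumerate(self.X_mean):
            T0 += float(self.counts[ci]) * (X.T @ X)
            b0 += X.T @ ss.sy[ci]
        beta0 = np.linalg.solve(T0, b0)
        Sres = np.zeros((self.t, self.t))
        for ci, X in enumerate(self.X_mean):
            mu = X @ beta0
            Sres += (
                ss.syy[ci]
                - np.outer(ss.sy[ci], mu)
                - np.outer(mu, ss.sy[ci])
                + float(self.counts[ci]) * np.outer(mu, mu)
            )
        div_m = max(self.G - self.design.n_conditions, 1)
        target_m = Sres / div_m
        rows = [math.sqrt(self.G) * self.TM.reshape(self.k, -1).T]
        rhs = [math.sqrt(self.G) * target_m.reshape(-1)]
        if self.has_contrast:
            target_c = ss.syy_con / self.n_contrast
            rows.append(math.sqrt(self.n_contrast) * self.TC.reshape(self.k, -1).T)
            rhs.append(math.sqrt(self.n_contrast) * target_c.reshape(-1))
        A = np.vstack(rows)
        y = np.concatenate(rhs)
        theta0, *_ = np.linalg.lstsq(A, y, rcond=None)
        return theta0

    def _safe_theta(self, ss: "_SuffStats") -> np.ndarray:
        tr_tot = float(np.trace(ss.syy.sum(axis=0)))
        n_tot = self.G * self.t
        if self.has_contrast:
            tr_tot += float(np.trace(ss.syy_con))
            n_tot += self.n_contrast * self.t
        vbar = max(tr_tot / n_tot, 1e-8)
        theta = np.zeros(self.k)
        names = [prm.name for prm in self.params]
        if self.orig_spec.has_residual or self.spec.has_residual:
            if "sigma2_e" in names:
                theta[names.index("sigma2_e")] = vbar
                return theta
        for r, prm in enumerate(self.params):
            if prm.is_variance and prm.A is not None and np.trace(prm.A) > 0 and prm.B is None:
                theta[r] = vbar
        if not np.any(theta):
            for r, prm in enumerate(self.params):
                if prm.is_variance:
                    theta[r] = vbar
        return theta

    # -- fitting -----------------------------------------------------------

    def fit_suffstats(self, ss: "_SuffStats", start=None,
                      settings: ConvergenceSettings = ConvergenceSettings()) -> FitResult:
        if start is not None:
            theta = np.asarray(start, dtype=float).copy()
            if theta.shape != (self.k,):
                raise ValueError(f"start must have {self.k} entries")
            state = self._eval(theta, ss)
        else:
            theta0 = self._start(ss)
            safe = self._safe_theta(ss)
            state = None
            for a in (0.0, 0.5, 0.8, 0.95, 1.0):
                theta = (1 - a) * theta0 + a * safe
                state = self._eval(theta, ss)
                if state is not None:
                    break
        if state is None:
            return self._failed(theta, "no admissible starting value (covariance not PD)")

        converged = False
        message = "ok"
        it = 0
        for it in range(1, settings.max_iter + 1):
            try:
                delta = np.linalg.solve(state.info, state.score)
            except np.linalg.LinAlgError:
                delta, *_ = np.linalg.lstsq(state.info, state.score, rcond=None)
            new_state = None
            step = 1.0
            for _ in range(settings.max_halvings):
                cand = theta + step * delta
                trial = self._eval(cand, ss)
                if trial is not None and trial.ll >= state.ll - 1e-8 * (1 + abs(state.ll)):
                    new_state = trial
                    break
                step *= 0.5
            if new_state is None:
                if self._grad_small(state, settings):
                    converged = True
                else:
                    message = "step-halving failed to improve the REML criterion"
                break
            dll = new_state.ll - state.ll
            theta = theta + step * delta
            state = new_state
            if abs(dll) <= settings.rel_loglik_tol * (1 + abs(state.ll)) and self._grad_small(
                state, settings
            ):
                converged = True
                break
        else:
            message = "maximum iterations reached"

        if not converged and start is None:
            # single perturbed restart before declaring failure
            safe = self._safe_theta(ss)
            restart = 0.7 * theta + 0.3 * safe + 0.05 * np.abs(safe).max() * np.ones(self.k)
            res2 = self.fit_suffstats(ss, start=restart, settings=settings)
            if res2.converged:
                return res2

        grad_norm = float(np.max(np.abs(state.score)))
        theta_cov = None
        if converged:
            try:
                theta_cov = np.linalg.inv(state.info)
            except np.linalg.LinAlgError:
                theta_cov = np.linalg.pinv(state.info)
        var_flags = np.array([p.is_variance for p in self.params])
        return FitResult(
            beta=state.beta,
            beta_names=self.beta_names,
            theta=theta,
            theta_names=[p.name for p in self.params],
            variance_flags=var_flags,
            reml_loglik=state.ll,
            beta_cov=state.Phi,
            converged=converged,
            n_iter=it,
            gradient_norm=grad_norm,
            boundary_note=bool(np.any(theta[var_flags] < 0)),
            message=message if not converged else "converged",
            n_obs=self.n_obs,
            n_groups=self.G,
            rank_x=self.p,
            interaction_cols=list(self.interaction_cols),
            within_mask=self.within_mask,
            kr_P=-state.H,
            kr_Q=state.Q,
            theta_cov=theta_cov,
            spec=self.orig_spec,
        )

    def _grad_small(self, state, settings) -> bool:
        try:
            nat = float(state.score @ np.linalg.solve(state.info, state.score))
        except np.linalg.LinAlgError:
            nat = float(np.sum(state.score**2))
        return math.sqrt(max(nat, 0.0)) <= settings.grad_tol

    def _failed(self, theta, message) -> FitResult:
        var_flags = np.array([p.is_variance for p in self.params])
        return FitResult(
            beta=np.full(self.p, np.nan),
            beta_names=self.beta_names,
            theta=np.asarray(theta, dtype=float),
            theta_names=[p.name for p in self.params],
            variance_flags=var_flags,
            reml_loglik=float("nan"),
            beta_cov=np.full((self.p, self.p), np.nan),
            converged=False,
            n_iter=0,
            gradient_norm=float("nan"),
            boundary_note=False,
            message=message,
            n_obs=self.n_obs,
            n_groups=self.G,
            rank_x=self.p,
            interaction_cols=list(self.interaction_cols),
            within_mask=self.within_mask,
            spec=self.orig_spec,
        )

    def fit_dataset(self, dataset: TrialDataset, start=None,
                    settings: ConvergenceSettings = ConvergenceSettings()) -> FitResult:
        if self.reduce_to_means:
            dataset = group_mean_reduce(dataset)
        return self.fit_suffstats(self.suffstats(dataset), start=start, settings=settings)


@dataclass
class _SuffStats:
    syy: np.ndarray
    sy: np.ndarray
    syy_con: np.ndarray | None


@dataclass
class _EvalState:
    ll: float
    score: np.ndarray
    info: np.ndarray
    beta: np.ndarray
    Phi: np.ndarray
    H: np.ndarray
    Q: np.ndarray


# -- public operations -----------------------------------------------------


def build_matrices(design: DesignConfig, spec: ModelSpec) -> DesignMatrices:
    """Compile fixed-effect designs and covariance templates for a model."""
    return DesignMatrices(design, spec)


def reml_fit(data: TrialDataset, spec: ModelSpec, start=None,
             settings: ConvergenceSettings = ConvergenceSettings()) -> FitResult:
    """Fit one analytic model to one dataset by unconstrained REML."""
    dm = build_matrices(data.design, spec)
    return dm.fit_dataset(data, start=start, settings=settings)


def group_mean_reduce(data: TrialDataset) -> TrialDataset:
    """Collapse a balanced dataset to one row per group x period (group means)."""
    d = data.design
    y, cond = data.to_tensor()  # (G, m, t)
    means = y.mean(axis=1)  # (G, t)
    c, g = d.n_conditions, d.groups_per_condition
    tensor = means.reshape(c, g, 1, d.n_periods)
    red_design = replace(d, members_per_group=1, structure=COHORT)
    return TrialDataset.from_tensor(tensor, red_design)
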