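"""Correlation algebra for multiple-period group-randomized trials.

Closed-form conversions between variance components and the four correlation
summaries used to parameterize such trials:

* WPICC — within-period intracluster correlation: similarity of two members
  of the same group in the same period,
  ``(s2_g + s2_tg) / (s2_g + s2_tg + s2_m + s2_tm + s2_e)``.
* BPICC — between-period intracluster correlation: similarity of two members
  of the same group in different periods, ``s2_g / total``.
* CAC — cluster autocorrelation, the correlation of a group's mean outcome
  across periods; equals BPICC / WPICC = ``s2_g / (s2_g + s2_tg)``.
* IAC — individual autocorrelation, the correlation of one member's outcomes
  across periods (cohort designs only), ``s2_m / (s2_m + s2_tm + s2_e)``.

Random-coefficients (RC) components are summarized through the same
definitional mapping, with the group and member slope variances occupying the
``sigma2_tg`` / ``sigma2_tm`` slots; the genuinely time-varying between-period
correlation of RC data is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import CROSS_SECTIONAL, COHORT, RC, RM, VarianceComponents, _norm_mechanism, _norm_structure

__all__ = [
    "CorrelationSummary",
    "UndefinedCorrelationError",
    "NotApplicableError",
    "InfeasibleTargetError",
    "wpicc",
    "bpicc",
    "cac",
    "iac",
    "summarize",
    "solve_components",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation's denominator is zero."""


class NotApplicableError(ValueError):
    """Raised when a summary does not exist for the given structure."""


class InfeasibleTargetError(ValueError):
    """Raised when no nonnegative components reproduce the requested targets."""


@dataclass(frozen=True)
class CorrelationSummary:
    """Correlation targets/summaries; ``iac`` is None for cross-sectional data."""

    wpicc: float
    bpicc: float | None = None
    cac: float | None = None
    iac: float | None = None


def wpicc(vc: VarianceComponents) -> float:
    """Within-period intracluster correlation implied by ``vc``."""
    total = vc.total
    if total == 0:
        raise UndefinedCorrelationError("WPICC undefined: total variance is zero")
    return (vc.sigma2_g + vc.sigma2_tg) / total


def bpicc(vc: VarianceComponents) -> float:
    """Between-period intracluster correlation implied by ``vc``."""
    total = vc.total
    if total == 0:
        raise UndefinedCorrelationError("BPICC undefined: total variance is zero")
    return vc.sigma2_g / total


def cac(sigma2_g: float, sigma2_tg: float) -> float:
    """Cluster autocorrelation: group-intercept share of group-level variance."""
    denom = sigma2_g + sigma2_tg
    if denom == 0:
        raise UndefinedCorrelationError("CAC undefined: sigma2_g + sigma2_tg is zero")
    return sigma2_g / denom


def iac(sigma2_m: float, sigma2_tm: float, sigma2_e: float) -> float:
    """Individual autocorrelation (cohort designs)."""
    denom = sigma2_m + sigma2_tm + sigma2_e
    if denom == 0:
        raise UndefinedCorrelationError("IAC undefined: member-level variance is zero")
    return sigma2_m / denom


def summarize(vc: VarianceComponents) -> CorrelationSummary:
    """All four summaries for a set of components (IAC absent cross-sectionally)."""
    w = wpicc(vc)
    b = bpicc(vc)
    a = cac(vc.sigma2_g, vc.sigma2_tg) if (vc.sigma2_g + vc.sigma2_tg) != 0 else None
    if vc.structure == COHORT:
        i = iac(vc.sigma2_m, vc.sigma2_tm, vc.sigma2_e)
    else:
        i = None
    return CorrelationSummary(wpicc=w, bpicc=b, cac=a, iac=i)


def iac_of(vc: VarianceComponents) -> float:
    if vc.structure != COHORT:
        raise NotApplicableError("IAC is defined only for cohort designs")
    return iac(vc.sigma2_m, vc.sigma2_tm, vc.sigma2_e)


def solve_components(
    target: CorrelationSummary,
    anchors: tuple[float, float] = (1.0, 1.0),
    structure: str = CROSS_SECTIONAL,
    mechanism: str = RM,
    sigma2_tm: float | None = None,
) -> VarianceComponents:
    """Invert the correlation formulas for the remaining variance components.

    The group-level variances are fixed by ``anchors = (sigma2_g, sigma2_tg)``
    (slope variance in the ``sigma2_tg`` slot for the RC mechanism).  For
    cross-sectional structure only the residual variance is solved; for cohort
    structure the member and residual variances are solved from the WPICC and
    IAC targets with the time x member variance held fixed (0 under RM, the
    member slope variance — default 1 — under RC).
    """
    structure = _norm_structure(structure)
    mechanism = _norm_mechanism(mechanism)
    s2_g, s2_tg = float(anchors[0]), float(anchors[1])
    if s2_g < 0 or s2_tg < 0:
        raise InfeasibleTargetError("anchor variances must be nonnegative")
    s_group = s2_g + s2_tg
    w = target.wpicc
    if not 0 < w <= 1:
        raise InfeasibleTargetError(f"target WPICC must lie in (0, 1]; got {w}")
    if s_group <= 0:
        raise InfeasibleTargetError("anchors imply zero group-level variance; WPICC target unattainable")
    if target.cac is not None:
        implied = cac(s2_g, s2_tg)
        if abs(implied - target.cac) > 5e-3:
            raise InfeasibleTargetError(
                f"anchors imply CAC = {implied:.6g}, inconsistent with target {target.cac:.6g}"
            )

    total = s_group / w
    rest = total - s_group  # sigma2_m + sigma2_tm + sigma2_e
    if rest < 0:
        raise InfeasibleTargetError("WPICC target exceeds what the anchors allow")

    if structure == CROSS_SECTIONAL:
        if target.iac is not None:
            raise InfeasibleTargetError("IAC target is not applicable to cross-sectional structure")
        return VarianceComponents(s2_g, s2_tg, 0.0, 0.0, rest,
                                  mechanism=mechanism, structure=structure)

    if sigma2_tm is None:
        sigma2_tm = 0.0 if mechanism == RM else 1.0
    if mechanism == RM and sigma2_tm != 0:
        raise InfeasibleTargetError("RM mechanism requires sigma2_tm = 0")
    i = target.iac
    if i is None:
        raise InfeasibleTargetError("cohort structure requires an IAC target")
    if not 0 <= i < 1:
        raise InfeasibleTargetError(f"target IAC must lie in [0, 1); got {i}")
    s2_m = i * rest
    s2_e = rest - sigma2_tm - s2_m
    if s2_e < 0:
        raise InfeasibleTargetError(
            f"targets require negative residual variance ({s2_e:.6g}); "
            "reduce sigma2_tm or the IAC/WPICC targets"
        )
    return VarianceComponents(s2_g, s2_tg, s2_m, sigma2_tm, s2_e,
                              mechanism=mechanism, structure=structure)
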