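"""Registry of the analytic linear mixed models for multiple-period GRTs.

Four families, each with (except Saturated) a "time x group" version and an
"intercept only" version that omits the time-varying group random effect, and
a cross-sectional and a cohort variant:

* ``rm_vc``     — categorical time; group + time x group random intercepts with
  a variance-components (VC) G matrix; cohort adds a compound-symmetric (CS)
  within-member R matrix.  Correctly specified for RM-generated data.
* ``rm_un``     — categorical time; cross-sectionally the time-varying group
  effects carry an unstructured (UN) covariance (the time-invariant group
  variance is absorbed by the UN matrix); cohort keeps a VC G matrix and an
  UN within-member R matrix.
* ``rc``        — linear time; UN(2) intercept/slope covariance at the group
  level and (cohort) at the member level.  Correctly specified for
  RC-generated data.
* ``saturated`` — categorical time; only time-varying random effects, UN at
  the group level, with UN(1) (cross-sectional) or UN (cohort) residual
  structure; fitted on group means by default.

Every structure used here is linear in its covariance parameters, which the
fitting engine exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .data import COHORT, CROSS_SECTIONAL, _norm_structure

__all__ = [
    "CovStructure",
    "RandomTerm",
    "ModelSpec",
    "AnalyticModelName",
    "FAMILIES",
    "make_spec",
    "count_cov_params",
    "all_model_names",
    "table_of_models",
]

FAMILIES = ("rm_vc", "rm_un", "rc", "saturated")


@dataclass(frozen=True)
class CovStructure:
    """Descriptive covariance structure: VC, CS, UN or UN(1) of a given dimension."""

    kind: str  # "VC" | "CS" | "UN" | "UN1"
    dimension: int

    @property
    def n_params(self) -> int:
        if self.kind == "VC":
            return self.dimension
        if self.kind == "CS":
            return 2
        if self.kind == "UN":
            return self.dimension * (self.dimension + 1) // 2
        if self.kind == "UN1":
            return self.dimension
        raise ValueError(f"unknown covariance kind {self.kind!r}")


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term, identified by level and shape.

    kinds: ``intercept`` (J), ``time_categorical`` (same-period indicator, one
    shared variance), ``time_un`` (unstructured over periods), ``rc_un``
    (intercept+slope, unstructured 2x2), ``rc_vc`` (intercept+slope,
    independent), ``un1`` (independent per-period variances).
    """

    level: str  # "group" | "member"
    kind: str

    def n_params(self, t: int) -> int:
        return {
            "intercept": 1,
            "time_categorical": 1,
            "time_un": t * (t + 1) // 2,
            "rc_un": 3,
            "rc_vc": 2,
            "un1": t,
        }[self.kind]


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified analytic model."""

    name: str
    time_coding: str  # "categorical" | "linear"
    structure: str
    terms: tuple[RandomTerm, ...]
    has_residual: bool
    fitting_level: str = "individual"  # "individual" | "group_mean"
    df_method: str = "KR"
    unbounded: bool = True
    g_structure: CovStructure | None = None
    r_structure: CovStructure | None = None
    mean_model_params: int | None = None

    def __post_init__(self) -> None:
        if self.fitting_level not in ("individual", "group_mean"):
            raise ValueError(f"unknown fitting level {self.fitting_level!r}")
        if self.time_coding not in ("categorical", "linear"):
            raise ValueError(f"unknown time coding {self.time_coding!r}")
        member_slope = any(tm.level == "member" and tm.kind in ("rc_un", "rc_vc") for tm in self.terms)
        if member_slope and self.time_coding != "linear":
            raise ValueError("time x member random effects require linear time coding "
                             "with one observation per occasion")

    def mean_formulation(self, t: int) -> "ModelSpec":
        """The group-mean reduced formulation: one UN block per group series."""
        return ModelSpec(
            name=self.name + "@group_mean",
            time_coding=self.time_coding,
            structure=self.structure,
            terms=(RandomTerm("member", "time_un"),),
            has_residual=False,
            fitting_level="individual",
            df_method=self.df_method,
            g_structure=CovStructure("UN", t),
            r_structure=None,
        )


@dataclass(frozen=True)
class AnalyticModelName:
    """Identifier of one analytic model in the study grid."""

    family: str
    timexgroup: bool = True
    structure: str = CROSS_SECTIONAL

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        object.__setattr__(self, "structure", _norm_structure(self.structure))
        if self.family == "saturated" and not self.timexgroup:
            raise ValueError("the saturated model has only time x group random effects; "
                             "an intercept-only variant does not exist")

    @property
    def label(self) -> str:
        kind = "timexgroup" if self.timexgroup else "intercept_only"
        return f"{self.family}:{kind}:{self.structure}"


def make_spec(name: AnalyticModelName, n_periods: int = 5,
              force_individual: bool = False, df_method: str = "KR") -> ModelSpec:
    """Build the analytic-model specification for one registry entry.

    ``force_individual`` fits the group-mean-level models (cross-sectional
    RM-UN and both saturated models) on individual-level data instead, for
    verifying the asserted equivalence of the two formulations.
    """
    fam, tg, structure = name.family, name.timexgroup, name.structure
    t = n_periods
    cohort = structure == COHORT
    level = "individual"
    g_struct = r_struct = None
    mean_params: int | None = None

    if fam == "rm_vc":
        coding = "categorical"
        terms = [RandomTerm("group", "intercept")]
        if tg:
            terms.append(RandomTerm("group", "time_categorical"))
        has_residual = True
        if cohort:
            terms.append(RandomTerm("member", "intercept"))  # with residual => CS R matrix
            r_struct = CovStructure("CS", t)
        g_struct = CovStructure("VC", 2 if tg else 1)
    elif fam == "rm_un":
        coding = "categorical"
        if cohort:
            terms = [RandomTerm("group", "intercept")]
            if tg:
                terms.append(RandomTerm("group", "time_categorical"))
            terms.append(RandomTerm("member", "time_un"))
            has_residual = False
            g_struct = CovStructure("VC", 2 if tg else 1)
            r_struct = CovStructure("UN", t)
        elif tg:
            # time-invariant group variance is aliased with the UN matrix
            terms = [RandomTerm("group", "time_un")]
            has_residual = True
            level = "group_mean"
            g_struct = CovStructure("UN", t)
            mean_params = t * (t + 1) // 2
        else:
            terms = [RandomTerm("group", "intercept")]
            has_residual = True
            g_struct = CovStructure("VC", 1)
    elif fam == "rc":
        coding = "linear"
        if tg:
            terms = [RandomTerm("group", "rc_un")]
            g_struct = CovStructure("UN", 2)
        else:
            terms = [RandomTerm("group", "intercept")]
            g_struct = CovStructure("VC", 1)
        if cohort:
            # intercept-only variant keeps member intercept+slope but as
            # independent components (reproduces the published accounting)
            terms.append(RandomTerm("member", "rc_un" if tg else "rc_vc"))
        has_residual = True
    else:  # saturated
        coding = "categorical"
        terms = [RandomTerm("group", "time_un")]
        if cohort:
            terms.append(RandomTerm("member", "time_un"))
            has_residual = False
            r_struct = CovStructure("UN", t)
        else:
            terms.append(RandomTerm("member", "un1"))
            has_residual = False
            r_struct = CovStructure("UN1", t)
        g_struct = CovStructure("UN", t)
        level = "group_mean"
        mean_params = t * (t + 1) // 2

    if fam == "rm_vc":
        coding = "categorical"
    if force_individual:
        level = "individual"
    return ModelSpec(
        name=name.label,
        time_coding=coding,
        structure=structure,
        terms=tuple(terms),
        has_residual=has_residual,
        fitting_level=level,
        df_method=df_method,
        g_structure=g_struct,
        r_structure=r_struct,
        mean_model_params=mean_params,
    )


def count_cov_params(spec: ModelSpec, n_periods: int = 5) -> int:
    """Number of free covariance parameters of the individual-level formulation.

    Where the model is fitted on group means, ``spec.mean_model_params`` holds
    the (smaller) mean-model count alongside.
    """
    n = sum(tm.n_params(n_periods) for tm in spec.terms)
    return n + (1 if spec.has_residual else 0)


def all_model_names(structure: str) -> list[AnalyticModelName]:
    names = []
    for fam in FAMILIES:
        names.append(AnalyticModelName(fam, True, structure))
        if fam != "saturated":
            names.append(AnalyticModelName(fam, False, structure))
    return names


def table_of_models(n_periods: int = 5) -> str:
    """Human-readable summary of every registered model (G/R structures, counts)."""
    lines = [f"{'model':<42} {'G':>6} {'R':>6} {'params':>10}"]
    for structure in (CROSS_SECTIONAL, COHORT):
        for name in all_model_names(structure):
            spec = make_spec(name, n_periods)
            n = count_cov_params(spec, n_periods)
            extra = f" ({spec.mean_model_params})" if spec.mean_model_params else ""
            gs = spec.g_structure.kind if spec.g_structure else "-"
            rs = spec.r_structure.kind if spec.r_structure else "-"
            lines.append(f"{name.label:<42} {gs:>6} {rs:>6} {str(n) + extra:>10}")
    return "\n".join(lines)
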