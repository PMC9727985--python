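"""Core data structures for multiple-period parallel group-randomized trials.

A trial dataset is a long-format table with one row per member x period
observation.  Designs are balanced and nested: ``c`` conditions, ``g`` groups
per condition, ``m`` members per group, ``t`` time periods.  Cross-sectional
designs draw a fresh set of ``m`` members in every period; cohort designs
follow the same ``m`` members across all periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CROSS_SECTIONAL",
    "COHORT",
    "RM",
    "RC",
    "COLUMNS",
    "SchemaError",
    "BalanceError",
    "VarianceComponents",
    "DesignConfig",
    "FixedEffects",
    "TrialDataset",
    "read_trial_csv",
    "write_trial_csv",
    "write_results",
]

CROSS_SECTIONAL = "cross-sectional"
COHORT = "cohort"
RM = "rm"
RC = "rc"

#: column order of the long-format interchange table
COLUMNS = ("member_id", "group_id", "condition", "period", "time", "y")


class SchemaError(ValueError):
    """Raised when a long-format table violates the trial-data schema."""


class BalanceError(ValueError):
    """Raised when a dataset is not a balanced nested design."""


def _norm_structure(structure: str) -> str:
    s = str(structure).lower().replace("_", "-")
    if s in {"cross", "cross-sectional", "xsec"}:
        return CROSS_SECTIONAL
    if s == "cohort":
        return COHORT
    raise ValueError(f"unknown structure {structure!r}; expected 'cross-sectional' or 'cohort'")


def _norm_mechanism(mechanism: str) -> str:
    m = str(mechanism).lower().replace("-anova", "")
    if m in {"rm", "rc"}:
        return m
    raise ValueError(f"unknown mechanism {mechanism!r}; expected 'rm' or 'rc'")


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of a generating mechanism.

    Under the repeated-measures (RM) mechanism ``sigma2_tg`` and ``sigma2_tm``
    are the time x group and time x member random-intercept variances; under
    the random-coefficients (RC) mechanism the same slots hold the group- and
    member-level random *slope* variances (per unit time squared).  Slope and
    intercept effects may covary at each level through ``cov_g`` / ``cov_m``
    (RC only; the study conditions generate them independently).
    """

    sigma2_g: float
    sigma2_tg: float
    sigma2_m: float
    sigma2_tm: float
    sigma2_e: float
    mechanism: str = RM
    structure: str = CROSS_SECTIONAL
    cov_g: float = 0.0
    cov_m: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", _norm_mechanism(self.mechanism))
        object.__setattr__(self, "structure", _norm_structure(self.structure))
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("variance components must all be finite")
        if self.structure == CROSS_SECTIONAL and (self.sigma2_m != 0 or self.sigma2_tm != 0):
            raise ValueError(
                "cross-sectional structure requires sigma2_m = sigma2_tm = 0 "
                f"(got {self.sigma2_m}, {self.sigma2_tm})"
            )
        if self.mechanism == RM and self.sigma2_tm != 0:
            # one observation per member per occasion: a time x member intercept
            # is indistinguishable from residual error
            raise ValueError("RM mechanism with one observation per occasion requires sigma2_tm = 0")
        if any(v < 0 for v in vals[:5]):
            warnings.warn(
                "negative variance component supplied; correlation formulas pass it through unchanged",
                RuntimeWarning,
                stacklevel=3,
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sigma2_g, self.sigma2_tg, self.sigma2_m, self.sigma2_tm, self.sigma2_e,
             self.cov_g, self.cov_m],
            dtype=float,
        )

    @property
    def total(self) -> float:
        """Total outcome variance implied by the RM definitional mapping."""
        return self.sigma2_g + self.sigma2_tg + self.sigma2_m + self.sigma2_tm + self.sigma2_e

    def validate_for_generation(self) -> None:
        if any(v < 0 for v in self.as_array()[:5]):
            raise ValueError("data generation requires nonnegative variance components")
        for lvl, (v_int, v_slo, cov) in (
            ("group", (self.sigma2_g, self.sigma2_tg, self.cov_g)),
            ("member", (self.sigma2_m, self.sigma2_tm, self.cov_m)),
        ):
            if cov != 0.0:
                if self.mechanism != RC:
                    raise ValueError("intercept-slope covariance applies to the RC mechanism only")
                if cov * cov > v_int * v_slo:
                    raise ValueError(f"{lvl}-level intercept-slope covariance is not positive semi-definite")


def _default_times(n_periods: int) -> tuple[float, ...]:
    return tuple(float(j) for j in range(n_periods))


@dataclass(frozen=True)
class DesignConfig:
    """Balanced nested design for a multiple-period parallel trial."""

    groups_per_condition: int
    members_per_group: int
    n_periods: int = 5
    n_conditions: int = 2
    time_values: tuple[float, ...] = ()
    structure: str = CROSS_SECTIONAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", _norm_structure(self.structure))
        if not self.time_values:
            object.__setattr__(self, "time_values", _default_times(self.n_periods))
        else:
            object.__setattr__(self, "time_values", tuple(float(v) for v in self.time_values))
        for name in ("groups_per_condition", "members_per_group", "n_periods", "n_conditions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.time_values) != self.n_periods:
            raise ValueError("time_values must have length n_periods")
        if np.any(np.diff(self.time_values) <= 0):
            raise ValueError("time_values must be strictly increasing")

    @property
    def n_groups_total(self) -> int:
        return self.n_conditions * self.groups_per_condition

    @property
    def n_obs(self) -> int:
        return self.n_groups_total * self.members_per_group * self.n_periods


@dataclass(frozen=True)
class FixedEffects:
    """Fixed-effect (mean model) parameters.

    Reference-level constraints follow the usual treatment coding: condition 1
    (control) and period 1 are reference levels, so the leading entries of
    ``condition``, ``period``, the first row/column of ``interaction`` and the
    first entry of ``slope_by_condition`` must be zero.  The type I error
    study generates data with every fixed effect equal to zero.
    """

    mu: float = 0.0
    condition: tuple[float, ...] = ()
    period: tuple[float, ...] = ()
    interaction: tuple[tuple[float, ...], ...] = ()  # [condition][period]
    slope: float = 0.0
    slope_by_condition: tuple[float, ...] = ()

    @classmethod
    def null(cls) -> "FixedEffects":
        return cls()

    def cell_means(self, design: DesignConfig, time_coding: str) -> np.ndarray:
        """Mean outcome for each (condition, period) cell."""
        c, t = design.n_conditions, design.n_periods
        cond = np.zeros(c)
        if self.condition:
            cond[: len(self.condition)] = self.condition
        if cond[0] != 0:
            raise ValueError("condition effect for the control condition must be 0")
        means = np.full((c, t), self.mu) + cond[:, None]
        if time_coding == "categorical":
            per = np.zeros(t)
            if self.period:
                per[: len(self.period)] = self.period
            inter = np.zeros((c, t))
            if self.interaction:
                arr = np.asarray(self.interaction, dtype=float)
                inter[: arr.shape[0], : arr.shape[1]] = arr
            if per[0] != 0 or np.any(inter[0] != 0) or np.any(inter[:, 0] != 0):
                raise ValueError("reference-level constraints violated (period 1 / condition 1)")
            means = means + per[None, :] + inter
        elif time_coding == "linear":
            sbc = np.zeros(c)
            if self.slope_by_condition:
                sbc[: len(self.slope_by_condition)] = self.slope_by_condition
            if sbc[0] != 0:
                raise ValueError("slope-by-condition effect for the control condition must be 0")
            tv = np.asarray(design.time_values)
            means = means + (self.slope + sbc)[:, None] * tv[None, :]
        else:
            raise ValueError(f"unknown time coding {time_coding!r}")
        return means


class TrialDataset:
    """Long-format trial outcomes with a validated balanced layout.

    Wraps a :class:`pandas.DataFrame` with columns ``member_id, group_id,
    condition, period, time, y`` and caches the balanced tensor layout
    ``(group, member-slot, period)`` used by the fitting engine.  For
    cross-sectional data the member slot within a period is arbitrary (members
    are exchangeable and appear once); for cohort data member slots are
    consistent across periods.
    """

    def __init__(self, frame: pd.DataFrame, design: DesignConfig,
                 _tensor: np.ndarray | None = None,
                 _group_cond: np.ndarray | None = None) -> None:
        self.frame = frame
        self.design = design
        self._tensor = _tensor
        self._group_cond = _group_cond

    # -- construction -----------------------------------------------------

    @classmethod
    def from_tensor(cls, y: np.ndarray, design: DesignConfig) -> "TrialDataset":
        """Build from a ``(condition, group, member, period)`` outcome array."""
        c, g, m, t = y.shape
        if (c, g, m, t) != (design.n_conditions, design.groups_per_condition,
                            design.members_per_group, design.n_periods):
            raise BalanceError("tensor shape does not match the design")
        cond = np.repeat(np.arange(1, c + 1), g * m * t)
        grp = np.tile(np.repeat(np.arange(1, g + 1), m * t), c)
        mem = np.tile(np.repeat(np.arange(1, m + 1), t), c * g)
        per = np.tile(np.arange(1, t + 1), c * g * m)
        group_id = np.char.add(np.char.add("c", cond.astype(str)), np.char.add("-g", grp.astype(str)))
        if design.structure == COHORT:
            member_id = np.char.add(group_id, np.char.add("-m", np.char.zfill(mem.astype(str), 3)))
        else:
            member_id = np.char.add(
                group_id,
                np.char.add(np.char.add("-p", per.astype(str)),
                            np.char.add("-m", np.char.zfill(mem.astype(str), 3))),
            )
        frame = pd.DataFrame(
            {
                "member_id": member_id,
                "group_id": group_id,
                "condition": cond,
                "period": per,
                "time": np.asarray(design.time_values)[per - 1],
                "y": y.reshape(-1),
            }
        )
        tensor = y.reshape(c * g, m, t)
        group_cond = np.repeat(np.arange(c), g)
        return cls(frame, design, _tensor=tensor, _group_cond=group_cond)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialDataset":
        """Validate an arbitrary long-format table and infer its design."""
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        frame = frame.loc[:, list(COLUMNS)].copy()
        if frame["y"].isna().any() or not np.issubdtype(np.asarray(frame["y"]).dtype, np.number):
            bad = frame.index[pd.to_numeric(frame["y"], errors="coerce").isna()].tolist()[:5]
            raise SchemaError(f"non-numeric or missing outcome at row(s) {bad}")
        dup = frame.duplicated(subset=["member_id", "period"])
        if dup.any():
            rows = frame.index[dup].tolist()[:5]
            raise SchemaError(f"duplicate (member_id, period) row(s) at {rows}")

        periods = np.sort(frame["period"].unique())
        t = len(periods)
        if not np.array_equal(periods, np.arange(1, t + 1)):
            raise SchemaError(f"periods must be 1..t; found {periods.tolist()}")
        tv = frame.sort_values("period").groupby("period")["time"].agg(["min", "max"])
        if not np.allclose(tv["min"], tv["max"]):
            raise SchemaError("time value is not constant within a period")
        time_values = tuple(tv["min"].tolist())

        gmap = frame.groupby("group_id")["condition"].nunique()
        if (gmap > 1).any():
            raise SchemaError(f"group(s) appear in more than one condition: {gmap[gmap > 1].index.tolist()}")
        conditions = np.sort(frame["condition"].unique())
        c = len(conditions)
        groups_per_cond = frame.groupby("condition")["group_id"].nunique()
        if groups_per_cond.nunique() > 1:
            raise BalanceError("unequal numbers of groups per condition")
        g = int(groups_per_cond.iloc[0])

        counts = frame.groupby(["group_id", "period"]).size()
        if counts.nunique() > 1:
            raise BalanceError("unequal group-period cell sizes")
        m = int(counts.iloc[0])

        rows_per_member = frame.groupby("member_id").size()
        if t > 1 and (rows_per_member == t).all():
            structure = COHORT
        elif (rows_per_member == 1).all():
            structure = CROSS_SECTIONAL
        else:
            raise BalanceError(
                "members must appear either in every period (cohort) or exactly once (cross-sectional)"
            )
        design = DesignConfig(
            groups_per_condition=g, members_per_group=m, n_periods=t, n_conditions=c,
            time_values=time_values, structure=structure,
        )
        if len(frame) != design.n_obs:
            raise BalanceError(f"expected {design.n_obs} rows for a balanced design, found {len(frame)}")
        return cls(frame.reset_index(drop=True), design)

    # -- accessors --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def to_tensor(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(y, cond_idx)`` with ``y`` shaped (groups, member-slot, period).

        ``cond_idx`` gives the 0-based condition index per group, groups sorted
        by (condition, group_id).
        """
        if self._tensor is not None:
            return self._tensor, self._group_cond
        d = self.design
        if d.structure == COHORT:
            f = self.frame.sort_values(["condition", "group_id", "member_id", "period"], kind="mergesort")
        else:
            f = self.frame.sort_values(["condition", "group_id", "period", "member_id"], kind="mergesort")
        y = np.asarray(f["y"], dtype=float)
        if d.structure == COHORT:
            tensor = y.reshape(d.n_groups_total, d.members_per_group, d.n_periods)
        else:
            tensor = y.reshape(d.n_groups_total, d.n_periods, d.members_per_group)
            tensor = np.ascontiguousarray(np.swapaxes(tensor, 1, 2))
        cond = np.asarray(
            f.groupby(["condition", "group_id"], sort=True)["condition"].first(), dtype=int
        )
        cond_idx = np.searchsorted(np.sort(np.unique(cond)), cond)
        self._tensor, self._group_cond = tensor, cond_idx
        return tensor, cond_idx


# -- I/O -------------------------------------------------------------------


def read_trial_csv(path: str | Path) -> TrialDataset:
    """Read and validate a long-format trial CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    return TrialDataset.from_frame(frame)


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False, columns=list(COLUMNS))


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy results table with deterministic column order.

    Floats are written at full (round-trip) precision; presentation rounding
    is left to consumers.  An empty table produces a header-only file with a
    warning.
    """
    if len(results) == 0:
        warnings.warn("writing an empty results table (header only)", RuntimeWarning, stacklevel=2)
    results.to_csv(path, index=False)
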