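"""Stepped-wedge allocation matrices and their switch-time summaries.

A stepped-wedge cluster randomized trial (SW-CRT) assigns each of C clusters
a binary intervention indicator in each of P time periods.  Rows are
one-way monotone: once a cluster switches to the intervention it never
returns to control.  Because clusters are exchangeable under the analysis
model, a matrix is summarized without loss by the histogram of its
switch periods, which is the unit this package enumerates and caches on.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

#: Sentinel for a cluster that never enters the intervention condition.
NEVER = "never"

SwitchTime = Union[int, str]


class AllocationError(ValueError):
    """Raised for malformed allocation matrices or continuations."""


class Cohort(str, enum.Enum):
    """Whether each cluster-period samples new participants or re-measures a cohort."""

    CROSS_SECTIONAL = "cross_sectional"
    CLOSED_COHORT = "closed_cohort"


def _switch_sort_key(t: SwitchTime) -> float:
    return float("inf") if t == NEVER else float(t)


@dataclass(frozen=True)
class AllocationMatrix:
    """A validated C x P binary roll-out matrix with monotone rows."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=np.int8)
        if arr.ndim != 2:
            raise AllocationError(f"allocation matrix must be 2-D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise AllocationError(f"allocation matrix entries must be 0/1, found {vals}")
        # no switch-back: a 1 may never be followed by a 0 within a row
        if np.any(np.diff(arr, axis=1) < 0):
            bad = int(np.where(np.any(np.diff(arr, axis=1) < 0, axis=1))[0][0])
            raise AllocationError(f"row {bad} switches back from intervention to control")
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)

    @property
    def C(self) -> int:
        return self.entries.shape[0]

    @property
    def P(self) -> int:
        return self.entries.shape[1]

    @classmethod
    def from_string(cls, s: str) -> "AllocationMatrix":
        """Parse the compact comma-separated row form, e.g. ``"01111,00111"``."""
        rows = [r.strip() for r in s.split(",") if r.strip()]
        if not rows:
            raise AllocationError("empty allocation string")
        if len({len(r) for r in rows}) != 1:
            raise AllocationError("rows of unequal length in allocation string")
        try:
            arr = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
        except ValueError as exc:
            raise AllocationError(f"non-digit character in allocation string: {exc}") from exc
        return cls(arr)

    def to_string(self) -> str:
        return ",".join("".join(str(v) for v in row) for row in self.entries)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "AllocationMatrix":
        arr = np.loadtxt(path, delimiter=",", dtype=np.int8, ndmin=2)
        return cls(arr)

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, self.entries, fmt="%d", delimiter=",")

    def switch_times(self) -> list[SwitchTime]:
        """First intervention period per cluster (1-based), or :data:`NEVER`."""
        out: list[SwitchTime] = []
        for row in self.entries:
            nz = np.flatnonzero(row)
            out.append(NEVER if nz.size == 0 else int(nz[0]) + 1)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AllocationMatrix):
            return NotImplemented
        return self.entries.shape == other.entries.shape and bool(
            np.array_equal(self.entries, other.entries)
        )

    def __hash__(self) -> int:
        return hash((self.entries.shape, self.entries.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AllocationMatrix({self.to_string()!r})"


def validate_allocation(M: Union[np.ndarray, Sequence[Sequence[int]]],
                        C: int | None = None,
                        P: int | None = None) -> AllocationMatrix:
    """Validate a C x P binary array as a monotone roll-out matrix.

    Raises :class:`AllocationError` on shape mismatch, non-binary entries,
    or any row that switches back to control.
    """
    arr = np.asarray(M)
    if arr.ndim != 2:
        raise AllocationError(f"expected a 2-D matrix, got shape {arr.shape}")
    if C is not None and arr.shape[0] != C:
        raise AllocationError(f"expected {C} rows, got {arr.shape[0]}")
    if P is not None and arr.shape[1] != P:
        raise AllocationError(f"expected {P} columns, got {arr.shape[1]}")
    return AllocationMatrix(arr)


@dataclass(frozen=True)
class SwitchTimeHistogram:
    """Counts of clusters per switch period; the exchangeability reduction of a matrix.

    Keys are 1-based periods or :data:`NEVER`.  Two matrices with equal
    histograms are row permutations of one another and share every
    design-level quantity (information, intervention proportion, ...).
    """

    counts: Mapping[SwitchTime, int]

    def __post_init__(self) -> None:
        clean = {}
        for t, n in self.counts.items():
            if n < 0:
                raise AllocationError(f"negative count for switch time {t}")
            if t != NEVER and (not isinstance(t, (int, np.integer)) or t < 1):
                raise AllocationError(f"invalid switch time {t!r}")
            if n:
                clean[int(t) if t != NEVER else NEVER] = int(n)
        object.__setattr__(self, "counts", clean)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def key(self) -> tuple:
        """Hashable canonical key (periods ascending, NEVER last)."""
        return tuple(sorted(self.counts.items(), key=lambda kv: _switch_sort_key(kv[0])))

    @classmethod
    def from_matrix(cls, M: AllocationMatrix) -> "SwitchTimeHistogram":
        return cls(Counter(M.switch_times()))

    def to_matrix(self, P: int) -> AllocationMatrix:
        """Expand to the canonical matrix: rows ordered by ascending switch time."""
        rows = []
        for t, n in self.key():
            row = np.zeros(P, dtype=np.int8)
            if t != NEVER:
                if t > P:
                    raise AllocationError(f"switch time {t} exceeds P={P}")
                row[t - 1:] = 1
            rows.extend([row] * n)
        return AllocationMatrix(np.array(rows, dtype=np.int8))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SwitchTimeHistogram):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())


def switch_time_histogram(M: AllocationMatrix) -> SwitchTimeHistogram:
    """Histogram of first-intervention periods over clusters."""
    return SwitchTimeHistogram.from_matrix(M)


def intervention_proportion(M: AllocationMatrix) -> float:
    """Fraction of the C x P cluster-periods spent in the intervention condition."""
    return float(M.entries.sum()) / M.entries.size


def canonical_form(M: AllocationMatrix) -> AllocationMatrix:
    """Rows permuted so intervention exposure is nonincreasing top to bottom.

    Used to deduplicate enumerated matrices; never applied to relabel
    realized clusters mid-trial.
    """
    order = np.argsort([_switch_sort_key(t) for t in M.switch_times()], kind="stable")
    return AllocationMatrix(M.entries[order])


def build_continuation(X_p: AllocationMatrix, p: int,
                       new_switch_times: Iterable[SwitchTime]) -> AllocationMatrix:
    """Extend the in-force matrix past period ``p`` with new control-cluster switch times.

    Columns 1..p are preserved; clusters already in the intervention at
    period ``p`` remain in it for every later period.  The ``n_control``
    clusters still in control receive the supplied switch times, each of
    which must exceed ``p`` (or be :data:`NEVER`): nondecreasing times are
    assigned to control clusters in ascending cluster-index order, a fixed
    convention that leaves all operating characteristics unchanged because
    clusters are exchangeable.
    """
    if not 1 <= p <= X_p.P:
        raise AllocationError(f"period p={p} outside 1..{X_p.P}")
    times = sorted(new_switch_times, key=_switch_sort_key)
    control = np.flatnonzero(X_p.entries[:, p - 1] == 0)
    if len(times) != len(control):
        raise AllocationError(
            f"got {len(times)} switch times for {len(control)} control clusters")
    out = X_p.entries.copy()
    out[out[:, p - 1] == 1, p:] = 1
    for i, t in zip(control, times):
        out[i, p:] = 0
        if t != NEVER:
            if not isinstance(t, (int, np.integer)) or t <= p:
                raise AllocationError(f"switch time {t!r} must be an integer > p={p}")
            if t > X_p.P:
                raise AllocationError(f"switch time {t} exceeds P={X_p.P}")
            out[i, t - 1:] = 1
    return AllocationMatrix(out)


@dataclass(frozen=True)
class TrialDesign:
    """Static description of the trial: dimensions, planned roll-out, error targets.

    Parameters
    ----------
    C, P, m
        Clusters (>1), periods (>1) and measurements per cluster-period (>0).
    cohort
        Cross-sectional (new participants each period) or closed-cohort.
    X_init
        The initially planned C x P allocation matrix.
    interim_periods
        Strictly increasing periods p in [1, P-1] after which the roll-out
        may be modified.
    alpha, beta
        One-sided type-I error target and type-II error target.
    delta
        Effect size at which power 1 - beta is targeted.
    """

    C: int
    P: int
    m: int
    cohort: Cohort
    X_init: AllocationMatrix
    interim_periods: tuple[int, ...] = ()
    alpha: float = 0.05
    beta: float = 0.2
    delta: float = 0.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.C <= 1 or self.P <= 1:
            raise ValueError("need C > 1 and P > 1")
        if self.m < 1:
            raise ValueError("need m >= 1")
        cohort = Cohort(self.cohort)
        object.__setattr__(self, "cohort", cohort)
        object.__setattr__(self, "interim_periods", tuple(int(p) for p in self.interim_periods))
        validate_allocation(self.X_init.entries, self.C, self.P)
        ip = self.interim_periods
        if any(b <= a for a, b in zip(ip, ip[1:])):
            raise ValueError(f"interim periods must be strictly increasing: {ip}")
        if any(not 1 <= p <= self.P - 1 for p in ip):
            raise ValueError(f"interim periods must lie in [1, P-1]: {ip}")
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
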