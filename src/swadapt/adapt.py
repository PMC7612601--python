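"""Interim adaptation: enumerate, score and select continuation matrices.

At an interim analysis after period p the in-force matrix X_p may be
replaced by any admissible continuation: columns 1..p are frozen and
clusters already in the intervention cannot switch back.  Each candidate
X' is scored by

    s(X') = w * I_{P|X'} / max I  +  (1 - w) * b(X') / max b

where I_{P|X'} is the end-of-trial information and the benefit score
b(X') is the Bin(N, q) probability mass at S, with N the number of
modifiable cluster-periods, S the number of them X' spends in the
intervention, and success probability q = Phi((Z - eta) / (gamma (1 - p/P)))
driven by the interim Wald statistic Z.  Large Z therefore favors fast
roll-out, small Z favors freezing it, and w trades patient benefit
against statistical information.

Candidates are enumerated and scored on switch-time equivalence classes
(multisets of control-cluster switch times); all matrices in a class share
I, S, b and s, so this is exact and turns the largest candidate sets into
cached array lookups.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln, xlog1py, xlogy
from scipy.stats import norm

from .designs import (NEVER, AllocationMatrix, SwitchTime, SwitchTimeHistogram,
                      TrialDesign, build_continuation, switch_time_histogram)
from .lmm import InformationCache, VarianceComponents


@dataclass(frozen=True)
class AdaptationPolicy:
    """Tunables of the interim selection rule.

    Parameters
    ----------
    w
        Weight in [0, 1] on the information term of the combined score;
        1 - w weighs the benefit term.  The endpoints are admissible but
        leave ties between equal-I or equal-b candidates unbroken, so a
        warning is issued.
    eta
        Benefit location: larger eta shrinks the success probability,
        favoring slower roll-out.
    gamma
        Benefit scale (> 0): larger gamma pulls the success probability
        toward 1/2, favoring a steadier roll-out.  The factor 1 - p/P lets
        later interims act on the same Z more decisively.
    restriction
        "none", or "must_complete_rollout" to force every cluster to switch
        by the end of the trial.  ``admissible`` is an optional extra
        predicate applied to each candidate matrix.
    """

    w: float = 0.5
    eta: float = 0.0
    gamma: float = 2.5
    restriction: str = "none"
    admissible: Callable[[AllocationMatrix], bool] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.restriction not in ("none", "must_complete_rollout"):
            raise ValueError(f"unknown restriction {self.restriction!r}")
        if self.w in (0.0, 1.0):
            warnings.warn("w in {0, 1} leaves score ties unbroken and is "
                          "usually best avoided", UserWarning, stacklevel=2)


@dataclass
class ScoredCandidate:
    """One admissible continuation with its scoring ingredients.

    ``S`` counts modifiable cluster-periods the candidate spends in the
    intervention, out of ``N = (P - p) * n_control``.  ``I``, ``b``, ``s``
    and the success probability ``q`` are filled by :func:`combined_scores`.
    """

    X_p: AllocationMatrix
    p: int
    switch_times: tuple[SwitchTime, ...]
    histogram: SwitchTimeHistogram
    S: int
    N: int
    q: float | None = None
    I: float | None = None
    b: float | None = None
    s: float | None = None
    _matrix: AllocationMatrix | None = field(default=None, repr=False)

    @property
    def matrix(self) -> AllocationMatrix:
        if self._matrix is None:
            self._matrix = build_continuation(self.X_p, self.p, self.switch_times)
        return self._matrix


def success_probability(Z: float, p: int, P: int, policy: AdaptationPolicy) -> float:
    """q = Phi((Z - eta) / (gamma (1 - p/P))), the benefit binomial's success rate."""
    if not 1 <= p <= P - 1:
        raise ValueError(f"interim period p={p} must lie in [1, P-1]")
    return float(norm.cdf((Z - policy.eta) / (policy.gamma * (1 - p / P))))


def _log_binom_pmf(S: np.ndarray, N: int, q: float) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    return (gammaln(N + 1) - gammaln(S + 1) - gammaln(N - S + 1)
            + xlogy(S, q) + xlog1py(N - S, -q))


def enumerate_candidates(X_p: AllocationMatrix, p: int,
                         policy: AdaptationPolicy) -> list[ScoredCandidate]:
    """All admissible continuations of X_p after period p, as unscored candidates.

    One candidate per multiset of switch times over {p+1, ..., P, never}
    for the clusters still in control ("never" removed under the
    must_complete_rollout restriction).  Distinct multisets yield distinct
    canonical matrices, so no further deduplication is needed.  The set is
    never empty: freezing the roll-out (all "never") and, in particular,
    the class of X_p itself are always members.
    """
    P = X_p.P
    if not 1 <= p <= P - 1:
        raise ValueError(f"interim period p={p} must lie in [1, P-1]")
    control = np.flatnonzero(X_p.entries[:, p - 1] == 0)
    switched = np.flatnonzero(X_p.entries[:, p - 1] == 1)
    base = [int(np.flatnonzero(X_p.entries[i])[0]) + 1 for i in switched]
    options: list[SwitchTime] = list(range(p + 1, P + 1))
    if policy.restriction != "must_complete_rollout":
        options.append(NEVER)
    out: list[ScoredCandidate] = []
    for times in combinations_with_replacement(options, len(control)):
        S = sum(P - t + 1 for t in times if t != NEVER)
        hist = SwitchTimeHistogram(Counter(base) + Counter(times))
        cand = ScoredCandidate(X_p=X_p, p=p, switch_times=times, histogram=hist,
                               S=int(S), N=(P - p) * len(control))
        if policy.admissible is not None and not policy.admissible(cand.matrix):
            continue
        out.append(cand)
    return out


def benefit_score(cand: ScoredCandidate, Z: float, p: int, P: int,
                  policy: AdaptationPolicy) -> float:
    """Binomial benefit b = P(Bin(N, q) = S); equals 1 when nothing is modifiable."""
    if cand.N == 0:
        return 1.0
    q = success_probability(Z, p, P, policy)
    return float(np.exp(_log_binom_pmf(np.array([cand.S]), cand.N, q)[0]))


def combined_scores(candidates: Sequence[ScoredCandidate], Z: float, p: int,
                    design: TrialDesign, vc: VarianceComponents,
                    policy: AdaptationPolicy,
                    cache: InformationCache | None = None) -> list[ScoredCandidate]:
    """Annotate candidates with I, b and the combined score s in place.

    b is computed in log space and normalized by the candidate-set maximum
    before exponentiation, so the score stays well defined when the
    success probability underflows at extreme Z.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    if cache is None:
        cache = InformationCache(design, vc)
    P = design.P
    N = candidates[0].N
    q = success_probability(Z, p, P, policy)
    S = np.array([c.S for c in candidates])
    info = np.array([cache.information(c.histogram) for c in candidates])
    if N == 0:
        logb = np.zeros(len(candidates))
    else:
        logb = _log_binom_pmf(S, N, q)
    b_norm = np.exp(logb - logb.max())
    s = policy.w * info / info.max() + (1 - policy.w) * b_norm
    for c, qi, Ii, lb, bn, si in zip(candidates, [q] * len(S), info, logb, b_norm, s):
        c.q = qi
        c.I = float(Ii)
        c.b = float(np.exp(lb)) if N else 1.0
        c.s = float(si)
    return list(candidates)


def select_continuation(candidates: Sequence[ScoredCandidate]) -> ScoredCandidate:
    """The s-maximizing candidate; ties go to larger I, then larger S, then order.

    Exact score ties have probability zero in Z, so the tie-break only
    pins down a deterministic choice for degenerate inputs (e.g. w = 0).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    if any(c.s is None for c in candidates):
        raise ValueError("candidates must be scored first (combined_scores)")
    s = np.array([c.s for c in candidates])
    tied = np.flatnonzero(s == s.max())
    if len(tied) > 1:
        I = np.array([candidates[i].I for i in tied])
        tied = tied[I == I.max()]
    if len(tied) > 1:
        S = np.array([candidates[i].S for i in tied])
        tied = tied[S == S.max()]
    return candidates[int(tied[0])]
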