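"""GLS analysis engine for the Hussey-Hughes style linear mixed model.

Model for measurement k in cluster i, period j::

    Y_ijk = beta_j + theta * X_ij + c_i + pi_ij + s_ik + eps_ijk

with independent normal random effects: cluster c_i ~ N(0, sigma2_c),
cluster-period pi_ij ~ N(0, sigma2_pi), individual s_ik ~ N(0, sigma2_s)
(shared across periods only in a closed cohort) and residual
eps_ijk ~ N(0, sigma2_e).  Variance components are treated as known, so
the intervention effect theta is estimated by generalized least squares
and inference uses the normal Wald statistic Z = theta_hat * sqrt(I),
where the information I is the reciprocal GLS variance of theta_hat.

With equal m per cluster-period the cluster-period means are sufficient
for the fixed effects, and their covariance within a cluster is
exchangeable, ``a * J + b * I`` with

    a = sigma2_c (+ sigma2_s / m, closed cohort)
    b = sigma2_pi + (sigma2_e + sigma2_s [cross-sectional]) / m

which admits an analytic inverse.  The collapsed representation is the
default computation path; the observation-level path is retained for
validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .designs import NEVER, AllocationMatrix, Cohort, SwitchTimeHistogram, SwitchTime, TrialDesign

#: Condition-number threshold above which D' Sigma^-1 D is declared singular.
COND_LIMIT = 1e12


class SingularDesignError(np.linalg.LinAlgError):
    """The intervention column is (numerically) collinear with the period effects."""


class InfeasibleDesignError(ValueError):
    """Target power cannot be reached for any per-cluster-period sample size."""


@dataclass(frozen=True)
class VarianceComponents:
    """Known variance components of the mixed model (all on the outcome scale)."""

    sigma2_c: float = 0.0
    sigma2_pi: float = 0.0
    sigma2_s: float = 0.0
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_e <= 0:
            raise ValueError("residual variance sigma2_e must be > 0")
        for name in ("sigma2_c", "sigma2_pi", "sigma2_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def validate_for(self, cohort: Cohort) -> None:
        if Cohort(cohort) is Cohort.CROSS_SECTIONAL and self.sigma2_s != 0:
            raise ValueError("cross-sectional designs require sigma2_s = 0")

    def mean_block_params(self, cohort: Cohort, m: int) -> tuple[float, float]:
        """(a, b) of the collapsed per-cluster covariance a*J + b*I."""
        closed = Cohort(cohort) is Cohort.CLOSED_COHORT
        a = self.sigma2_c + (self.sigma2_s / m if closed else 0.0)
        b = self.sigma2_pi + (self.sigma2_e + (0.0 if closed else self.sigma2_s)) / m
        return a, b


@dataclass
class GLSProblem:
    """A ready-to-solve GLS system, block-diagonal over exchangeable clusters.

    ``D`` stacks per-cluster design blocks (cluster-major row order), each of
    ``rows_per_cluster`` rows; ``sigma_block`` is the shared per-cluster
    covariance; ``Y`` is the matching response vector.
    """

    D: np.ndarray
    sigma_block: np.ndarray
    Y: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.sigma_block = np.asarray(self.sigma_block, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        r = self.sigma_block.shape[0]
        if self.sigma_block.shape != (r, r):
            raise ValueError("sigma_block must be square")
        if self.D.shape[0] != r * self.n_clusters or self.Y.shape[0] != self.D.shape[0]:
            raise ValueError("D/Y rows must equal n_clusters * block size")


@dataclass(frozen=True)
class GLSResult:
    """GLS estimate of the intervention effect and its Wald summary."""

    theta_hat: float
    var_theta: float
    Z: float
    I: float
    beta_hat: np.ndarray


def build_design_matrix(X: AllocationMatrix, p: int, m: int = 1) -> np.ndarray:
    """Fixed-effects design for data through period ``p``.

    One row per observation (cluster-major, then period, then replicate):
    p period indicators followed by the intervention indicator.  There is
    no separate intercept; the period effects absorb it.  ``m = 1`` gives
    the collapsed cluster-period-mean representation.
    """
    if not 1 <= p <= X.P:
        raise ValueError(f"p={p} outside 1..{X.P}")
    block = np.zeros((p, p + 1))
    block[:, :p] = np.eye(p)
    rows = []
    for i in range(X.C):
        b = block.copy()
        b[:, p] = X.entries[i, :p]
        rows.append(np.repeat(b, m, axis=0))
    return np.vstack(rows)


def build_covariance(vc: VarianceComponents, cohort: Cohort, n_periods: int,
                     m: int, collapse: bool = True) -> np.ndarray:
    """Covariance of one cluster's responses over ``n_periods`` periods.

    Collapsed (default): the ``n_periods`` cluster-period means, covariance
    ``a*J + b*I``.  Observation level: all ``n_periods * m`` measurements
    (period-major), distinguishing same-individual covariance in a closed
    cohort from the cross-sectional case where period panels are disjoint.
    """
    vc.validate_for(cohort)
    if collapse:
        a, b = vc.mean_block_params(cohort, m)
        return a * np.ones((n_periods, n_periods)) + b * np.eye(n_periods)
    n = n_periods * m
    closed = Cohort(cohort) is Cohort.CLOSED_COHORT
    S = np.full((n, n), vc.sigma2_c)
    same_period = np.kron(np.eye(n_periods), np.ones((m, m)))
    same_k = np.kron(np.ones((n_periods, n_periods)), np.eye(m))
    S += vc.sigma2_pi * same_period
    if closed:
        S += vc.sigma2_s * same_k  # individual k tracked across periods
    else:
        S += vc.sigma2_s * same_period * same_k  # fresh individuals each period
    S += vc.sigma2_e * same_period * same_k
    return S


def gls_fit(problem: GLSProblem) -> GLSResult:
    """Solve the GLS system; the intervention effect is the last coordinate.

    Uses a Cholesky factorization of the shared per-cluster block (never an
    explicit inverse of the full covariance) and accumulates the normal
    equations cluster by cluster.
    """
    r = problem.sigma_block.shape[0]
    q = problem.D.shape[1]
    try:
        cf = cho_factor(problem.sigma_block, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"covariance block not positive definite: {exc}") from exc
    A = np.zeros((q, q))
    rhs = np.zeros(q)
    for i in range(problem.n_clusters):
        Di = problem.D[i * r:(i + 1) * r]
        yi = problem.Y[i * r:(i + 1) * r]
        SiD = cho_solve(cf, Di)
        A += Di.T @ SiD
        rhs += SiD.T @ yi
    if np.linalg.cond(A) > COND_LIMIT:
        raise SingularDesignError(
            "D' Sigma^-1 D is singular: intervention column collinear with period effects")
    Ainv = np.linalg.inv(A)
    coef = Ainv @ rhs
    theta_hat = float(coef[-1])
    var_theta = float(Ainv[-1, -1])
    info = 1.0 / var_theta
    return GLSResult(theta_hat=theta_hat, var_theta=var_theta,
                     Z=theta_hat * np.sqrt(info), I=info, beta_hat=coef[:-1])


def _mean_block_inverse(a: float, b: float, p: int) -> np.ndarray:
    # (a*J + b*I)^-1 = (I - a/(b + p*a) * J) / b  (Sherman-Morrison)
    return (np.eye(p) - (a / (b + p * a)) * np.ones((p, p))) / b


def _cluster_crossprods(p: int, a: float, b: float) -> dict[SwitchTime, np.ndarray]:
    """G_t = D_t' Sigma^-1 D_t for a single cluster switching at period t.

    Keys: t in 1..p plus NEVER (switch times beyond the analysis period p
    contribute identically to a never-switching cluster).
    """
    Sinv = _mean_block_inverse(a, b, p)
    out: dict[SwitchTime, np.ndarray] = {}
    for t in list(range(1, p + 1)) + [NEVER]:
        D = np.zeros((p, p + 1))
        D[:, :p] = np.eye(p)
        if t != NEVER:
            D[t - 1:, p] = 1.0
        out[t] = D.T @ Sinv @ D
    return out


def _info_from_A(A: np.ndarray) -> float:
    if np.linalg.cond(A) > COND_LIMIT:
        raise SingularDesignError(
            "D' Sigma^-1 D is singular: intervention column collinear with period effects")
    return 1.0 / np.linalg.inv(A)[-1, -1]


def information(X: AllocationMatrix, p: int, design: TrialDesign,
                vc: VarianceComponents) -> float:
    """Information I_{p|X} = 1 / Var(theta_hat) using data through period p.

    Computed from the design alone (no responses), via the collapsed
    cluster-period-mean representation.
    """
    if not 1 <= p <= X.P:
        raise ValueError(f"p={p} outside 1..{X.P}")
    a, b = vc.mean_block_params(design.cohort, design.m)
    G = _cluster_crossprods(p, a, b)
    A = np.zeros((p + 1, p + 1))
    for t in X.switch_times():
        A += G[t if t == NEVER or t <= p else NEVER]
    return _info_from_A(A)


class InformationCache:
    """Memoized information values keyed by switch-time histogram.

    Assembles D' Sigma^-1 D as the histogram-weighted sum of per-switch-time
    single-cluster cross products, exact because clusters are exchangeable
    under the model.  One cache instance is tied to a (cohort, m, variance
    components, P) configuration and is shared across simulation replicates.
    """

    def __init__(self, design: TrialDesign, vc: VarianceComponents):
        self.design = design
        self.vc = vc
        self._G: dict[int, dict[SwitchTime, np.ndarray]] = {}
        self._values: dict[tuple, float] = {}
        self.hits = 0
        self.misses = 0

    def crossprods(self, p: int) -> dict[SwitchTime, np.ndarray]:
        if p not in self._G:
            a, b = self.vc.mean_block_params(self.design.cohort, self.design.m)
            self._G[p] = _cluster_crossprods(p, a, b)
        return self._G[p]

    def information(self, h: SwitchTimeHistogram, p: int | None = None) -> float:
        """I_{p|X} for any matrix X with histogram ``h`` (default p = P)."""
        if h.total != self.design.C:
            raise ValueError(f"histogram total {h.total} != C={self.design.C}")
        p = self.design.P if p is None else p
        key = (p, h.key())
        if key in self._values:
            self.hits += 1
            return self._values[key]
        self.misses += 1
        G = self.crossprods(p)
        A = np.zeros((p + 1, p + 1))
        for t, n in h.counts.items():
            A += n * G[t if t == NEVER or t <= p else NEVER]
        val = _info_from_A(A)
        self._values[key] = val
        return val


def information_from_histogram(h: SwitchTimeHistogram, design: TrialDesign,
                               vc: VarianceComponents,
                               cache: InformationCache | None = None,
                               p: int | None = None) -> float:
    """Histogram-keyed information; equals :func:`information` on the expanded matrix."""
    if cache is None:
        cache = InformationCache(design, vc)
    return cache.information(h, p=p)


def hh_power(design: TrialDesign, vc: VarianceComponents,
             m: int | None = None, theta: float | None = None) -> float:
    """Power of the one-sided Wald test Z_P > z_{1-alpha} under known variances.

    power = Phi(theta * sqrt(I_P) - z_{1-alpha}) with I_P the end-of-trial
    information of the initially planned matrix.
    """
    m = design.m if m is None else m
    theta = design.delta if theta is None else theta
    a, b = vc.mean_block_params(design.cohort, m)
    G = _cluster_crossprods(design.P, a, b)
    A = np.zeros((design.P + 1, design.P + 1))
    for t in design.X_init.switch_times():
        A += G[t]
    info = _info_from_A(A)
    return float(norm.cdf(theta * np.sqrt(info) - norm.ppf(1 - design.alpha)))


def required_m(design: TrialDesign, vc: VarianceComponents, m_max: int = 100_000) -> int:
    """Smallest m with power >= 1 - beta at theta = delta (incremental search).

    Raises :class:`InfeasibleDesignError` when the m -> infinity power limit
    (finite when sigma2_pi > 0 or sigma2_c > 0 bounds the information) falls
    below the target.
    """
    if design.delta <= 0:
        raise ValueError("required_m needs delta > 0")
    target = 1 - design.beta
    if hh_power(design, vc, m=1) >= target:
        return 1
    lo, hi = 1, 2  # power(lo) < target
    while hh_power(design, vc, m=hi) < target:
        lo, hi = hi, hi * 2
        if hi > m_max:
            raise InfeasibleDesignError(
                f"power {hh_power(design, vc, m=m_max):.4f} at m={m_max} "
                f"still below target {target}; information plateaus")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if hh_power(design, vc, m=mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi
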