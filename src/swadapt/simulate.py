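"""Monte-Carlo evaluation of fixed and response-adaptive SW-CRT designs.

Data are generated from the mixed model with period effects set to zero
(the Wald statistic's distribution under known covariance does not depend
on them) at cluster-period-mean granularity, which is exact for equal m.
All random effects for a replicate are drawn before any allocation
decision, so interim adaptation can influence future responses only
through the treatment term theta * X_ij — decisions depend on the data
only through the interim Wald statistics, as in the trial itself.

:class:`TrialEngine` carries the caches that make replicate loops cheap:
per-switch-time cross products, GLS weight vectors keyed by the in-force
allocation, and fully scored candidate tables keyed by (p, frozen columns).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, xlog1py, xlogy
from scipy.stats import norm

from .adapt import AdaptationPolicy, success_probability
from .designs import (NEVER, AllocationMatrix, Cohort, SwitchTime,
                      SwitchTimeHistogram, TrialDesign, build_continuation)
from .lmm import (GLSProblem, InformationCache, SingularDesignError,
                  VarianceComponents, _mean_block_inverse, build_covariance,
                  build_design_matrix, gls_fit)

__all__ = [
    "ScenarioConfig", "RandomEffectsDraw", "TrialResult",
    "OperatingCharacteristics", "TrialEngine", "draw_random_effects",
    "realize_responses", "run_adaptive_trial", "run_fixed_trial",
    "simulate_scenario", "estimate_operating_characteristics",
    "builtin_scenarios",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce one simulation condition."""

    design: TrialDesign
    vc: VarianceComponents
    policy: AdaptationPolicy
    theta_true: float = 0.0
    n_reps: int = 10_000
    seed: int = 1
    analysis_mode: str = "collapsed"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.analysis_mode not in ("collapsed", "observation_level"):
            raise ValueError(f"unknown analysis_mode {self.analysis_mode!r}")
        self.vc.validate_for(self.design.cohort)


@dataclass(frozen=True)
class RandomEffectsDraw:
    """Cluster-period-mean aggregates of one replicate's random effects.

    ``s_bar`` is the per-cluster mean individual effect (variance
    sigma2_s / m, shared across periods in a closed cohort; for
    cross-sectional designs fresh individuals arrive each period, so the
    individual variance is folded into ``eps_bar``).
    """

    c: np.ndarray
    pi: np.ndarray
    s_bar: np.ndarray
    eps_bar: np.ndarray

    def noise(self) -> np.ndarray:
        """Total non-treatment contribution to each cluster-period mean."""
        return (self.c + self.s_bar)[:, None] + self.pi + self.eps_bar


@dataclass(frozen=True)
class TrialResult:
    reject: bool
    theta_hat_final: float
    X_final: AllocationMatrix
    proportion: float
    interim_Z: tuple[float, ...]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Summary of a batch of replicates of one simulation condition."""

    erp: float
    eacp: float
    esdcp: float
    eb: float
    ermse: float
    prop_pmf: dict[float, float]
    mean_X: np.ndarray
    mc_se: dict[str, float]
    n_reps: int
    theta_true: float


def draw_random_effects(config: ScenarioConfig, rng: np.random.Generator) -> RandomEffectsDraw:
    """Draw all of a replicate's random effects up front, at mean granularity."""
    d, vc = config.design, config.vc
    C, P, m = d.C, d.P, d.m
    closed = d.cohort is Cohort.CLOSED_COHORT
    c = rng.normal(0.0, np.sqrt(vc.sigma2_c), C)
    pi = rng.normal(0.0, np.sqrt(vc.sigma2_pi), (C, P))
    if closed:
        s_bar = rng.normal(0.0, np.sqrt(vc.sigma2_s / m), C)
        eps_bar = rng.normal(0.0, np.sqrt(vc.sigma2_e / m), (C, P))
    else:
        s_bar = np.zeros(C)
        eps_bar = rng.normal(0.0, np.sqrt((vc.sigma2_s + vc.sigma2_e) / m), (C, P))
    return RandomEffectsDraw(c=c, pi=pi, s_bar=s_bar, eps_bar=eps_bar)


def realize_responses(draw: RandomEffectsDraw, X: AllocationMatrix,
                      periods: Iterable[int], theta: float) -> np.ndarray:
    """Cluster-period mean responses for the given (1-based) periods under X."""
    cols = np.asarray([p - 1 for p in periods])
    if cols.size and (cols.min() < 0 or cols.max() >= X.P):
        raise ValueError("requested period outside 1..P")
    return theta * X.entries[:, cols] + draw.noise()[:, cols]


class _CandidateTable:
    """Array view of the scored candidate set at one (p, frozen-columns) state.

    Rows are switch-time multisets for the control clusters; ``I`` is the
    end-of-trial information of each continuation, computed once in a
    batched solve and shared across replicates.
    """

    def __init__(self, X_p: AllocationMatrix, p: int, policy: AdaptationPolicy,
                 cache: InformationCache):
        design, P = cache.design, cache.design.P
        self.p = p
        control = np.flatnonzero(X_p.entries[:, p - 1] == 0)
        switched = np.flatnonzero(X_p.entries[:, p - 1] == 1)
        self.n_control = len(control)
        self.N = (P - p) * self.n_control
        self.options: list[SwitchTime] = list(range(p + 1, P + 1))
        if policy.restriction != "must_complete_rollout":
            self.options.append(NEVER)
        K = len(self.options)
        combos = list(combinations_with_replacement(range(K), self.n_control))
        self.idx = np.array(combos, dtype=np.int16).reshape(len(combos), self.n_control)
        counts = np.zeros((len(combos), K), dtype=np.int32)
        for k in range(K):
            counts[:, k] = (self.idx == k).sum(axis=1)
        exposure = np.array([0 if t == NEVER else P - t + 1 for t in self.options])
        self.S = counts @ exposure
        if policy.admissible is not None:
            keep = np.array([policy.admissible(build_continuation(
                X_p, p, tuple(self.options[k] for k in row))) for row in self.idx])
            if not keep.any():
                raise ValueError(f"admissibility predicate left no candidates at p={p}")
            self.idx, counts, self.S = self.idx[keep], counts[keep], self.S[keep]
        # end-of-trial information per candidate: histogram-weighted sum of
        # per-switch-time cross products, then a batched small inverse
        G = cache.crossprods(P)
        A_base = np.zeros((P + 1, P + 1))
        for i in switched:
            t = int(np.flatnonzero(X_p.entries[i])[0]) + 1
            A_base += G[t]
        Gstack = np.stack([G[t] for t in self.options])
        A = A_base[None] + np.tensordot(counts.astype(float), Gstack, axes=(1, 0))
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(f"singular candidate information at p={p}") from exc
        self.I = 1.0 / Ainv[:, -1, -1]
        if not np.all(np.isfinite(self.I)) or np.any(self.I <= 0):
            raise SingularDesignError(f"non-finite candidate information at p={p}")
        self._log_comb = (gammaln(self.N + 1) - gammaln(self.S + 1.0)
                          - gammaln(self.N - self.S + 1.0))
        self._I_norm = self.I / self.I.max()

    def select(self, Z: float, policy: AdaptationPolicy, P: int) -> int:
        """Index of the s-maximizing candidate (ties: larger I, larger S, first)."""
        if self.N == 0:
            return 0
        q = success_probability(Z, self.p, P, policy)
        logb = self._log_comb + xlogy(self.S, q) + xlog1py(self.N - self.S, -q)
        s = policy.w * self._I_norm + (1 - policy.w) * np.exp(logb - logb.max())
        tied = np.flatnonzero(s == s.max())
        if len(tied) > 1:
            tied = tied[self.I[tied] == self.I[tied].max()]
        if len(tied) > 1:
            tied = tied[self.S[tied] == self.S[tied].max()]
        return int(tied[0])

    def times(self, i: int) -> tuple[SwitchTime, ...]:
        return tuple(self.options[k] for k in self.idx[i])


class TrialEngine:
    """Shared caches for simulating one design/policy configuration.

    Safe to reuse across replicates and across values of the true effect:
    every cached quantity depends only on the design, variance components
    and policy, never on responses.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.design = config.design
        self.vc = config.vc
        self.policy = config.policy
        self.info_cache = InformationCache(self.design, self.vc)
        self._weights: dict[bytes, tuple[np.ndarray, float]] = {}
        self._tables: dict[tuple[int, bytes], _CandidateTable] = {}
        self._crit = norm.ppf(1 - self.design.alpha)

    # -- GLS via cached weight vectors -------------------------------------
    def _weights_for(self, X: AllocationMatrix, p: int) -> tuple[np.ndarray, float]:
        """(W, I_p): theta_hat = sum_ij W_ij * Ybar_ij over periods 1..p."""
        sub = np.ascontiguousarray(X.entries[:, :p])
        key = p.to_bytes(2, "little") + sub.tobytes()
        hit = self._weights.get(key)
        if hit is not None:
            return hit
        a, b = self.vc.mean_block_params(self.design.cohort, self.design.m)
        Sinv = _mean_block_inverse(a, b, p)
        C = self.design.C
        A = np.zeros((p + 1, p + 1))
        DtS = np.empty((C, p + 1, p))
        eye = np.eye(p)
        for i in range(C):
            D = np.empty((p, p + 1))
            D[:, :p] = eye
            D[:, p] = sub[i]
            DtS[i] = D.T @ Sinv
            A += DtS[i] @ D
        if np.linalg.cond(A) > 1e12:
            raise SingularDesignError(
                f"no usable intervention contrast at period {p}")
        Ainv = np.linalg.inv(A)
        W = np.einsum("q,iqp->ip", Ainv[-1], DtS)
        out = (W, 1.0 / Ainv[-1, -1])
        self._weights[key] = out
        return out

    def wald(self, X: AllocationMatrix, p: int, ybar: np.ndarray) -> tuple[float, float]:
        """(theta_hat, Z) from cluster-period means ``ybar`` of shape (C, p)."""
        W, info = self._weights_for(X, p)
        theta_hat = float(np.sum(W * ybar))
        return theta_hat, theta_hat * np.sqrt(info)

    def table(self, X_p: AllocationMatrix, p: int) -> _CandidateTable:
        sub = np.ascontiguousarray(X_p.entries[:, :p])
        key = (p, sub.tobytes())
        tab = self._tables.get(key)
        if tab is None:
            tab = _CandidateTable(X_p, p, self.policy, self.info_cache)
            self._tables[key] = tab
        return tab

    # -- trial runs --------------------------------------------------------
    def run_adaptive(self, rng: np.random.Generator, theta: float,
                     z_override: dict[int, float] | None = None) -> TrialResult:
        cfg = self.config
        if cfg.analysis_mode == "observation_level":
            return _run_observation_level(self, rng, theta, adaptive=True,
                                          z_override=z_override)
        d = self.design
        draw = draw_random_effects(cfg, rng)
        noise = draw.noise()
        X = d.X_init
        ybar = np.empty((d.C, d.P))
        filled = 0
        interim_Z = []
        for p in d.interim_periods:
            ybar[:, filled:p] = theta * X.entries[:, filled:p] + noise[:, filled:p]
            filled = p
            _, Z = self.wald(X, p, ybar[:, :p])
            if z_override is not None and p in z_override:
                Z = z_override[p]
            interim_Z.append(Z)
            tab = self.table(X, p)
            X = build_continuation(X, p, tab.times(tab.select(Z, self.policy, d.P)))
        ybar[:, filled:] = theta * X.entries[:, filled:] + noise[:, filled:]
        theta_hat, Z_final = self.wald(X, d.P, ybar)
        return TrialResult(reject=bool(Z_final > self._crit),
                           theta_hat_final=theta_hat, X_final=X,
                           proportion=float(X.entries.sum()) / X.entries.size,
                           interim_Z=tuple(interim_Z))

    def run_fixed(self, rng: np.random.Generator, theta: float) -> TrialResult:
        cfg = self.config
        if cfg.analysis_mode == "observation_level":
            return _run_observation_level(self, rng, theta, adaptive=False)
        d = self.design
        draw = draw_random_effects(cfg, rng)
        ybar = realize_responses(draw, d.X_init, range(1, d.P + 1), theta)
        theta_hat, Z = self.wald(d.X_init, d.P, ybar)
        return TrialResult(reject=bool(Z > self._crit), theta_hat_final=theta_hat,
                           X_final=d.X_init,
                           proportion=float(d.X_init.entries.sum()) / d.X_init.entries.size,
                           interim_Z=())


# -- observation-level validation path ------------------------------------

def _draw_observations(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-treatment part of every Y_ijk, shape (C, P, m)."""
    d, vc = config.design, config.vc
    C, P, m = d.C, d.P, d.m
    c = rng.normal(0.0, np.sqrt(vc.sigma2_c), C)
    pi = rng.normal(0.0, np.sqrt(vc.sigma2_pi), (C, P))
    if d.cohort is Cohort.CLOSED_COHORT:
        s = rng.normal(0.0, np.sqrt(vc.sigma2_s), (C, 1, m))
    else:
        s = rng.normal(0.0, np.sqrt(vc.sigma2_s), (C, P, m))
    eps = rng.normal(0.0, np.sqrt(vc.sigma2_e), (C, P, m))
    return c[:, None, None] + pi[:, :, None] + s + eps


def _obs_fit(engine: TrialEngine, X: AllocationMatrix, p: int, y: np.ndarray):
    d = engine.design
    D = build_design_matrix(X, p, m=d.m)
    block = build_covariance(engine.vc, d.cohort, p, d.m, collapse=False)
    prob = GLSProblem(D=D, sigma_block=block, Y=y[:, :p, :].reshape(-1), n_clusters=d.C)
    return gls_fit(prob)


def _run_observation_level(engine: TrialEngine, rng: np.random.Generator,
                           theta: float, adaptive: bool,
                           z_override: dict[int, float] | None = None) -> TrialResult:
    d = engine.design
    noise = _draw_observations(engine.config, rng)
    X = d.X_init
    interim_Z = []
    if adaptive:
        for p in d.interim_periods:
            y = theta * X.entries[:, :, None] + noise
            res = _obs_fit(engine, X, p, y)
            Z = res.Z
            if z_override is not None and p in z_override:
                Z = z_override[p]
            interim_Z.append(Z)
            tab = engine.table(X, p)
            X = build_continuation(X, p, tab.times(tab.select(Z, engine.policy, d.P)))
    y = theta * X.entries[:, :, None] + noise
    res = _obs_fit(engine, X, d.P, y)
    return TrialResult(reject=bool(res.Z > engine._crit), theta_hat_final=res.theta_hat,
                       X_final=X, proportion=float(X.entries.sum()) / X.entries.size,
                       interim_Z=tuple(interim_Z))


# -- public wrappers -------------------------------------------------------

def run_adaptive_trial(config: ScenarioConfig, rng: np.random.Generator,
                       engine: TrialEngine | None = None,
                       z_override: dict[int, float] | None = None) -> TrialResult:
    """One adaptive replicate: interim GLS, candidate scoring, selection, final test."""
    engine = engine if engine is not None else TrialEngine(config)
    return engine.run_adaptive(rng, config.theta_true, z_override=z_override)


def run_fixed_trial(config: ScenarioConfig, rng: np.random.Generator,
                    engine: TrialEngine | None = None) -> TrialResult:
    """One conventional replicate: the initially planned matrix throughout."""
    engine = engine if engine is not None else TrialEngine(config)
    return engine.run_fixed(rng, config.theta_true)


def estimate_operating_characteristics(results: Sequence[TrialResult],
                                       theta_true: float) -> OperatingCharacteristics:
    """ERP, EACP/ESDCP, EB, ERMSE, proportion pmf and mean final matrix.

    ESDCP and the bias/variance decomposition use the population (1/n)
    convention so that ERMSE^2 = EB^2 + Var(theta_hat) holds exactly.
    """
    if not results:
        raise ValueError("no trial results")
    n = len(results)
    rej = np.array([r.reject for r in results], dtype=float)
    prop = np.array([r.proportion for r in results])
    th = np.array([r.theta_hat_final for r in results])
    erp = float(rej.mean())
    eacp = float(prop.mean())
    esdcp = float(prop.std(ddof=0))
    pmf = {float(k): v / n for k, v in sorted(Counter(prop.tolist()).items())}
    mean_X = np.mean([r.X_final.entries for r in results], axis=0)
    return OperatingCharacteristics(
        erp=erp, eacp=eacp, esdcp=esdcp,
        eb=float(th.mean() - theta_true),
        ermse=float(np.sqrt(np.mean((th - theta_true) ** 2))),
        prop_pmf=pmf, mean_X=mean_X,
        mc_se={"erp": float(np.sqrt(max(erp * (1 - erp), 1e-300) / n)),
               "eacp": esdcp / np.sqrt(n),
               "eb": float(th.std(ddof=0) / np.sqrt(n))},
        n_reps=n, theta_true=theta_true)


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    # independent substreams, invariant to execution order
    return np.random.default_rng(np.random.SeedSequence((seed, rep)))


def simulate_scenario(config: ScenarioConfig, adaptive: bool = True,
                      engine: TrialEngine | None = None,
                      theta: float | None = None) -> OperatingCharacteristics:
    """Run ``config.n_reps`` independent replicates and summarize them.

    Each replicate uses a substream derived from (seed, replicate index),
    so results are bit-reproducible and independent of execution order.
    Pass a shared :class:`TrialEngine` to reuse information caches across
    conditions (they do not depend on theta).
    """
    if theta is not None:
        config = replace(config, theta_true=theta)
    engine = engine if engine is not None else TrialEngine(config)
    run = engine.run_adaptive if adaptive else engine.run_fixed
    results = [run(_replicate_rng(config.seed, r), config.theta_true)
               for r in range(config.n_reps)]
    return estimate_operating_characteristics(results, config.theta_true)


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """The three bundled trial design scenarios (TDS1-TDS3), parsed from YAML."""
    from importlib import resources

    from .config import parse_config
    out = {}
    pkg = resources.files("swadapt.scenarios")
    for name in ("tds1", "tds2", "tds3"):
        with resources.as_file(pkg / f"{name}.yaml") as path:
            out[name.upper()] = parse_config(path)
    return out
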