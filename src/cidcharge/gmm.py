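"""Spherical Gaussian mixture fitted by expectation-maximization.

The model is a K-component mixture in D dimensions with a single scalar
variance per component,

    p(x) = sum_k p_k * N(x; mu_k, sigma_k^2 I),

fitted by maximizing the log-likelihood

    L = sum_n log sum_k p_k * N(x_n; mu_k, sigma_k^2 I)

with the classic EM alternation: the E-step computes responsibilities
p(k|n) proportional to p_k * N(x_n; mu_k, sigma_k^2 I); the M-step sets
each mean to the responsibility-weighted data mean, each variance to the
weighted mean squared deviation per dimension, and each mixing weight to
the average responsibility. All densities are evaluated in the log domain
so the E-step never underflows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

DEFAULT_VAR_FLOOR = 1e-6


@dataclass
class GmmParams:
    """Mixture parameters: means (K, D), spherical variances (K,), mixing (K,)."""

    means: np.ndarray
    variances: np.ndarray
    mixing: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        k = self.means.shape[0]
        if self.variances.shape != (k,) or self.mixing.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if np.any(self.mixing <= 0) or abs(self.mixing.sum() - 1.0) > 1e-12:
            raise ValueError("mixing probabilities must be positive and sum to 1")

    @property
    def n_components(self) -> int:
        return int(self.means.shape[0])

    @property
    def n_dims(self) -> int:
        return int(self.means.shape[1])


def _check_data(data: np.ndarray, params: GmmParams | None = None) -> np.ndarray:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    if params is not None and data.shape[1] != params.n_dims:
        raise ValueError(
            f"data dimension {data.shape[1]} != model dimension {params.n_dims}"
        )
    return data


def _log_component_densities(data: np.ndarray, params: GmmParams) -> np.ndarray:
    """log[p_k * N(x_n; mu_k, sigma_k^2 I)] as an (N, K) matrix."""
    d = params.n_dims
    sq = ((data[:, None, :] - params.means[None, :, :]) ** 2).sum(axis=2)
    log_norm = -0.5 * d * np.log(2.0 * np.pi * params.variances)
    return np.log(params.mixing)[None, :] + log_norm[None, :] - sq / (2.0 * params.variances[None, :])


def log_likelihood(data: np.ndarray, params: GmmParams) -> float:
    """Mixture log-likelihood of the data, computed with log-sum-exp."""
    data = _check_data(data, params)
    return float(logsumexp(_log_component_densities(data, params), axis=1).sum())


def e_step(data: np.ndarray, params: GmmParams) -> np.ndarray:
    """Responsibilities p(k|n); every row sums to 1."""
    data = _check_data(data, params)
    log_joint = _log_component_densities(data, params)
    return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))


def m_step(
    data: np.ndarray,
    responsibilities: np.ndarray,
    var_floor: float = DEFAULT_VAR_FLOOR,
    rng: np.random.Generator | None = None,
) -> GmmParams:
    """Closed-form parameter update from responsibilities.

    A component whose total responsibility collapses below 1e-10 is
    reseeded from a random data point (unit variance, uniform share of
    mixing) rather than propagating a division by zero.
    """
    data = _check_data(data)
    resp = np.asarray(responsibilities, dtype=float)
    n, d = data.shape
    if resp.shape[0] != n:
        raise ValueError("responsibility rows must match data rows")
    if np.any(np.abs(resp.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("responsibility rows must sum to 1")
    weights = resp.sum(axis=0)  # (K,)
    k = resp.shape[1]
    means = np.empty((k, d))
    variances = np.empty(k)
    mixing = weights / n
    rng = rng or np.random.default_rng()
    for c in range(k):
        if weights[c] < 1e-10:
            means[c] = data[rng.integers(n)]
            variances[c] = 1.0
            mixing[c] = 1.0 / n
            continue
        means[c] = resp[:, c] @ data / weights[c]
        sq = ((data - means[c]) ** 2).sum(axis=1)
        variances[c] = (resp[:, c] @ sq) / (d * weights[c])
    variances = np.maximum(variances, var_floor)
    mixing = mixing / mixing.sum()
    return GmmParams(means=means, variances=variances, mixing=mixing)


@dataclass
class FitResult:
    """Converged mixture fit plus its EM trace for reproducibility."""

    params: GmmParams
    responsibilities: np.ndarray
    log_likelihood_trace: list[float]
    n_iter: int
    converged: bool
    seed: int | None = None
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_trace[-1]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "means": self.params.means.tolist(),
            "variances": self.params.variances.tolist(),
            "mixing": self.params.mixing.tolist(),
            "log_likelihood_trace": [float(v) for v in self.log_likelihood_trace],
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
            "feature_names": list(self.feature_names),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _init_median_split(data: np.ndarray, k: int, var_floor: float) -> GmmParams:
    """Deterministic start: split at the median of the first column."""
    n, d = data.shape
    order = np.argsort(data[:, 0], kind="stable")
    chunks = np.array_split(order, k)
    means = np.stack([data[c].mean(axis=0) for c in chunks])
    variances = np.array(
        [max(((data[c] - m) ** 2).sum(axis=1).mean() / d, var_floor) for c, m in zip(chunks, means)]
    )
    mixing = np.full(k, 1.0 / k)
    return GmmParams(means=means, variances=variances, mixing=mixing)


def _init_random(data: np.ndarray, k: int, var_floor: float, rng: np.random.Generator) -> GmmParams:
    """Random start: hard-assign points to components, take M-step stats."""
    n = data.shape[0]
    assignment = rng.integers(k, size=n)
    # guarantee every component owns at least one point
    assignment[rng.choice(n, size=k, replace=False)] = np.arange(k)
    resp = np.zeros((n, k))
    resp[np.arange(n), assignment] = 1.0
    return m_step(data, resp, var_floor, rng)


def _run_em(
    data: np.ndarray,
    params: GmmParams,
    max_iter: int,
    tol_ll: float,
    var_floor: float,
    rng: np.random.Generator,
) -> tuple[GmmParams, np.ndarray, list[float], int, bool]:
    trace = [log_likelihood(data, params)]
    resp = e_step(data, params)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        params = m_step(data, resp, var_floor, rng)
        trace.append(log_likelihood(data, params))
        resp = e_step(data, params)
        prev, curr = trace[-2], trace[-1]
        if abs(curr - prev) <= tol_ll * max(abs(prev), 1.0):
            converged = True
            break
    return params, resp, trace, iteration, converged


def fit(
    data: np.ndarray,
    k: int = 2,
    init: str = "median_split",
    seed: int | None = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol_ll: float = 1e-8,
    var_floor: float = DEFAULT_VAR_FLOOR,
    feature_names: tuple[str, ...] = (),
) -> FitResult:
    """Fit a K-component spherical mixture; best of several EM runs.

    One deterministic median-split start is always run (when ``init`` is
    ``"median_split"``), plus ``n_restarts`` random-assignment restarts
    drawn from ``seed``; the run with the highest final log-likelihood
    wins. Convergence is declared when the relative log-likelihood change
    drops below ``tol_ll``.
    """
    data = _check_data(data)
    n = data.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot fit {k} components to {n} points")
    rng = np.random.default_rng(seed)
    starts: list[GmmParams] = []
    if init == "median_split":
        starts.append(_init_median_split(data, k, var_floor))
    elif init != "random":
        raise ValueError(f"unknown init strategy {init!r}")
    starts.extend(_init_random(data, k, var_floor, rng) for _ in range(n_restarts))
    if not starts:
        raise ValueError("no EM starts configured (init='random' needs n_restarts >= 1)")
    best = None
    for start in starts:
        result = _run_em(data, start, max_iter, tol_ll, var_floor, rng)
        if best is None or result[2][-1] > best[2][-1]:
            best = result
    params, resp, trace, n_iter, converged = best
    return FitResult(
        params=params,
        responsibilities=resp,
        log_likelihood_trace=trace,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        feature_names=tuple(feature_names),
    )
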