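"""Two-Gaussian decomposition of the GM histogram and the WM Gaussian fit.

The decomposition is a 1-D two-component Gaussian mixture fitted by
expectation-maximization, either on raw voxel values or on binned counts
treated as frequency weights at bin centers.  Components are relabeled so
that muG1 <= muG2, and piG2 is the mixing proportion of the higher-mean
component.  Fits whose means nearly coincide are flagged degenerate: the
separation collapses and piG2 becomes unreliable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidInputError
from .histostats import Histogram

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureConfig:
    """EM settings: restarts, tolerance, variance floor, degenerate threshold."""

    n_restarts: int = 5  # 1 deterministic median-split init + (n-1) jittered
    tol: float = 1e-8  # relative log-likelihood change
    max_iter: int = 500
    sigma_floor: float = 0.025  # half the default 0.05 bin width
    seed: int = 0
    degenerate_delta: float = 0.10  # two default bin widths

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MixtureFit:
    muG1: float
    muG2: float
    sigma1: float
    sigma2: float
    piG2: float
    log_likelihood: float
    n_iter: int
    converged: bool
    degenerate: bool = False
    n_restarts_used: int = 0
    trace: Optional[List[float]] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "muG1": self.muG1,
            "muG2": self.muG2,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "piG2": self.piG2,
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_restarts_used": self.n_restarts_used,
        }


@dataclass
class WMFit:
    muW: float
    sigmaW: float
    n: int

    def to_dict(self) -> dict:
        return {"muW": self.muW, "sigmaW": self.sigmaW, "n": self.n}


def _as_weighted(values, histogram: Optional[Histogram]) -> Tuple[np.ndarray, np.ndarray]:
    if histogram is not None:
        keep = histogram.counts > 0
        return histogram.bin_centers[keep], histogram.counts[keep]
    x = np.asarray(values, dtype=float).ravel()
    return x, np.ones_like(x)


def mixture_log_likelihood(
    x: np.ndarray,
    w: np.ndarray,
    mus: np.ndarray,
    sigmas: np.ndarray,
    pis: np.ndarray,
) -> float:
    """Weighted log-likelihood of a two-component Gaussian mixture."""
    log_comp = (
        np.log(pis)[None, :]
        - np.log(sigmas)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[:, None] - mus[None, :]) / sigmas[None, :]) ** 2
    )
    return float(np.sum(w * logsumexp(log_comp, axis=1)))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, q * cw[-1])])


def _median_split_init(x, w, sigma_floor) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    med = _weighted_quantile(x, w, 0.5)
    lo = x <= med
    hi = ~lo
    if not hi.any() or not lo.any():  # all mass in one bin
        m = float(np.average(x, weights=w))
        s = max(float(np.sqrt(np.average((x - m) ** 2, weights=w))), sigma_floor)
        return np.array([m - s, m + s]), np.array([s, s]), np.array([0.5, 0.5])
    mus, sigmas, pis = [], [], []
    for sel in (lo, hi):
        m = float(np.average(x[sel], weights=w[sel]))
        s = float(np.sqrt(np.average((x[sel] - m) ** 2, weights=w[sel])))
        mus.append(m)
        sigmas.append(max(s, sigma_floor))
        pis.append(float(w[sel].sum() / w.sum()))
    return np.array(mus), np.array(sigmas), np.array(pis)


def _em_run(
    x: np.ndarray,
    w: np.ndarray,
    mus: np.ndarray,
    sigmas: np.ndarray,
    pis: np.ndarray,
    config: MixtureConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[float], bool]:
    """One EM run from the given start; returns parameters, trace, converged."""
    n_eff = w.sum()
    trace: List[float] = []
    converged = False
    for _ in range(config.max_iter):
        # E-step
        log_comp = (
            np.log(pis)[None, :]
            - np.log(sigmas)[None, :]
            - 0.5 * _LOG_2PI
            - 0.5 * ((x[:, None] - mus[None, :]) / sigmas[None, :]) ** 2
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(np.sum(w * log_norm))
        trace.append(ll)
        resp = np.exp(log_comp - log_norm[:, None]) * w[:, None]
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        mus = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mus[None, :]) ** 2).sum(axis=0) / nk
        sigmas = np.maximum(np.sqrt(var), config.sigma_floor)
        pis = np.clip(nk / n_eff, 1e-12, 1.0)
        pis = pis / pis.sum()
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= config.tol * max(abs(prev), 1.0):
                converged = True
                break
    return mus, sigmas, pis, trace, converged


def fit_two_gaussians(
    values=None,
    histogram: Optional[Histogram] = None,
    config: MixtureConfig = MixtureConfig(),
) -> MixtureFit:
    """Maximum-likelihood two-component Gaussian mixture via EM.

    Accepts either raw values or a histogram whose counts act as frequency
    weights at bin centers.  Runs a deterministic median-split start plus
    seeded jittered restarts and keeps the best log-likelihood.  Requires at
    least 100 effective observations.
    """
    x, w = _as_weighted(values, histogram)
    if x.size == 0 or w.sum() < 100:
        raise InvalidInputError(
            f"two-Gaussian fit needs >= 100 effective observations, got {w.sum():.0f}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite values in mixture input")

    mus0, sigmas0, pis0 = _median_split_init(x, w, config.sigma_floor)
    rng = np.random.default_rng(config.seed)
    spread = max(float(np.sqrt(np.average((x - np.average(x, weights=w)) ** 2, weights=w))), config.sigma_floor)

    starts = [(mus0.copy(), sigmas0.copy(), pis0.copy())]
    for _ in range(max(config.n_restarts, 1) - 1):
        mus = mus0 + rng.normal(scale=0.5 * spread, size=2)
        sigmas = np.maximum(sigmas0 * rng.uniform(0.5, 1.5, size=2), config.sigma_floor)
        p2 = rng.uniform(0.15, 0.85)
        starts.append((mus, sigmas, np.array([1.0 - p2, p2])))
    # few-support inputs (coarse histograms): the MLE may pin one component at
    # a single support point with sigma at the floor; seed such starts directly
    support = np.unique(x)
    if support.size <= 12:
        for xi in support:
            rest = x != xi
            w_rest = w[rest].sum()
            if w_rest <= 0:
                continue
            m_rest = float(np.average(x[rest], weights=w[rest]))
            s_rest = max(
                float(np.sqrt(np.average((x[rest] - m_rest) ** 2, weights=w[rest]))),
                config.sigma_floor,
            )
            pi_spike = float(w[~rest].sum() / w.sum())
            starts.append(
                (
                    np.array([xi, m_rest]),
                    np.array([config.sigma_floor, s_rest]),
                    np.array([pi_spike, 1.0 - pi_spike]),
                )
            )

    best = None
    for mus, sigmas, pis in starts:
        mus, sigmas, pis, trace, converged = _em_run(x, w, mus, sigmas, pis, config)
        ll = mixture_log_likelihood(x, w, mus, sigmas, pis)
        if best is None or ll > best[0]:
            best = (ll, mus, sigmas, pis, trace, converged)

    ll, mus, sigmas, pis, trace, converged = best
    order = np.argsort(mus)  # enforce muG1 <= muG2
    mus, sigmas, pis = mus[order], sigmas[order], pis[order]
    fit = MixtureFit(
        muG1=float(mus[0]),
        muG2=float(mus[1]),
        sigma1=float(sigmas[0]),
        sigma2=float(sigmas[1]),
        piG2=float(pis[1]),
        log_likelihood=ll,
        n_iter=len(trace),
        converged=bool(converged),
        n_restarts_used=len(starts),
        trace=trace,
    )
    return flag_degenerate(fit, delta=config.degenerate_delta)


def fit_wm_gaussian(values=None, histogram: Optional[Histogram] = None) -> WMFit:
    """Single-Gaussian MLE for the WM histogram: muW = mean, sigmaW = sample SD."""
    x, w = _as_weighted(values, histogram)
    n_eff = float(w.sum())
    if x.size == 0 or n_eff < 10:
        raise InvalidInputError(f"WM fit needs >= 10 observations, got {n_eff:.0f}")
    mu = float(np.average(x, weights=w))
    var = float(np.sum(w * (x - mu) ** 2) / (n_eff - 1))
    return WMFit(muW=mu, sigmaW=float(np.sqrt(var)), n=int(round(n_eff)))


def flag_degenerate(fit: MixtureFit, delta: float = 0.10) -> MixtureFit:
    """Mark the fit degenerate when the component means are closer than ``delta``."""
    return dataclasses.replace(fit, degenerate=bool(fit.muG2 - fit.muG1 < delta))
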