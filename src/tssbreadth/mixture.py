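"""Two-component univariate normal mixtures fitted by EM.

Both decision points of the breadth analysis rest on bimodality of a single
statistic: the TSS-region mean separates H3K4me3-marked from unmarked sites,
and the upstream-TSS / downstream-TSS differences separate "extended" from
"not extended" on each side. A two-normal mixture is fitted to each statistic
and posterior probabilities of the high-mean component drive the calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


class DegenerateMixtureError(RuntimeError):
    """Raised when every EM restart collapses onto a zero-variance component."""


@dataclass
class MixtureFit:
    """Converged 2-component fit; components ordered by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    posterior: np.ndarray  # P(high-mean component | x) for the fitted data
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    def posterior_high(self, x: np.ndarray) -> np.ndarray:
        """P(high-mean component | x) for arbitrary values."""
        x = np.asarray(x, dtype=float)
        log_p = np.stack([
            np.log(self.weights[k]) + norm.logpdf(x, self.means[k], self.sds[k])
            for k in (0, 1)
        ])
        log_p -= log_p.max(axis=0, keepdims=True)
        p = np.exp(log_p)
        return p[1] / p.sum(axis=0)


def _em(x: np.ndarray, resp: np.ndarray, tol: float, max_iter: int,
        sd_floor: float) -> MixtureFit | None:
    n = x.size
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            return None
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if np.any(sd < sd_floor):
            return None
        # E step and log-likelihood
        log_comp = np.log(w) + norm.logpdf(x[:, None], mu, sd)
        m = log_comp.max(axis=1, keepdims=True)
        log_mix = (m + np.log(np.exp(log_comp - m).sum(axis=1, keepdims=True)))
        ll = float(log_mix.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_mix)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = ll
    order = np.argsort(mu)
    resp = resp[:, order]
    return MixtureFit(w[order], mu[order], sd[order], resp[:, 1],
                      np.asarray(trace), converged, it)


def fit_gmm2(values: np.ndarray, seed: int = 0, tol: float = 1e-8,
             max_iter: int = 500, n_restarts: int = 5) -> MixtureFit:
    """Fit a 2-component univariate normal mixture by EM.

    The first attempt initializes responsibilities by a split at the median
    (a k-means-style hard assignment); further restarts draw random soft
    responsibilities from the seeded generator. A fit is rejected as
    degenerate when a component's standard deviation falls below a floor of
    1e-6 times the data range; if every restart degenerates (e.g. all values
    identical) a :class:`DegenerateMixtureError` is raised.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite values to fit a mixture")
    rng = np.random.default_rng(seed)
    scale = max(np.ptp(x), np.abs(x).max(), 1.0)
    sd_floor = 1e-9 * scale
    best = None
    for attempt in range(n_restarts):
        if attempt == 0:
            resp = np.zeros((x.size, 2))
            hi = x > np.median(x)
            resp[hi, 1] = 1.0
            resp[~hi, 0] = 1.0
        else:
            r = rng.uniform(0.05, 0.95, size=x.size)
            resp = np.column_stack([1 - r, r])
        fit = _em(x, resp, tol, max_iter, sd_floor)
        if fit is not None and (best is None
                                or fit.loglik_trace[-1] > best.loglik_trace[-1]):
            best = fit
    if best is None:
        raise DegenerateMixtureError(
            f"all {n_restarts} EM restarts degenerate (sd below floor)")
    return best
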