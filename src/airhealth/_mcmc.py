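"""Small sampling utilities shared by the two MCMC stages."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri


def sample_invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    """Draw from inverse-gamma(shape, scale) with density ∝ x^{-shape-1} e^{-scale/x}.

    Draws are clipped to [1e-12, 1e12]: with the very diffuse shapes used as
    priors (e.g. 0.001) the underlying gamma draw can underflow to zero.
    """
    g = max(float(rng.gamma(shape)), 1e-300)
    return float(np.clip(scale / g, 1e-12, 1e12))


def sample_truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from N(mean, sd^2) truncated to [0, 1] by inverse-CDF sampling."""
    a = ndtr((0.0 - mean) / sd)
    b = ndtr((1.0 - mean) / sd)
    if b - a < 1e-14:  # mass numerically outside [0, 1]: return nearest endpoint
        return float(np.clip(mean, 0.0, 1.0) > 0.5)
    u = rng.uniform(a, b)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return float(mean + sd * ndtri(u))


class AdaptiveScale:
    """Robbins-Monro adaptation of a random-walk step size.

    The log step size is nudged toward a target acceptance rate with a
    decaying gain; adaptation is frozen once :meth:`freeze` is called (at the
    end of burn-in) so the retained chain uses a fixed kernel.
    """

    def __init__(self, init: float = 0.1, target: float = 0.44):
        self.log_s = float(np.log(init))
        self.target = target
        self._n = 0
        self._frozen = False

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_s))

    def update(self, acc_rate: float) -> None:
        if self._frozen:
            return
        self._n += 1
        gain = min(0.25, 10.0 / (self._n + 100.0))
        self.log_s += gain * (acc_rate - self.target)
        self.log_s = float(np.clip(self.log_s, -15.0, 10.0))

    def freeze(self) -> None:
        self._frozen = True


def greedy_coloring(W) -> list[np.ndarray]:
    """Greedy proper colouring of a graph given a (sparse) adjacency matrix.

    Returns index arrays per colour class; vertices in one class are mutually
    non-adjacent, so single-site Markov-blanket updates can run vectorised
    within a class.
    """
    import scipy.sparse as sp

    W = sp.csr_array(W)
    n = W.shape[0]
    order = np.argsort(-np.diff(W.indptr))  # high degree first
    colors = np.full(n, -1, dtype=int)
    for v in order:
        nb = W.indices[W.indptr[v]: W.indptr[v + 1]]
        used = set(colors[nb][colors[nb] >= 0].tolist())
        c = 0
        while c in used:
            c += 1
        colors[v] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]
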