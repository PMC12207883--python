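"""Latent event-time calibration for the couple-track generator.

The imaging window is 15 min at one frame per 20 s, so event times are
observed frame-quantized (nearest frame) and censored at the window end.
Condition presets state the *observed* means — the numbers a per-cell-couple
dot plot would average.  These helpers solve for the latent exponential means
that reproduce those observed means under the observation process, using
closed-form bin probabilities and scalar root finding.

Lamella onset is a single exponential wait from coupling.  Detachment is
modelled as lamella onset plus an additional exponential wait (a
hypoexponential total), which enforces the destabilization ordering
off-interface lamella <= detachment.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

FRAME_S = 20.0
N_FRAMES = 46              # frames 0..45 cover 0..900 s from coupling
HORIZON_S = (N_FRAMES - 1) * FRAME_S


def _exp_cdf(t: np.ndarray, mean: float) -> np.ndarray:
    return 1.0 - np.exp(-np.maximum(t, 0.0) / mean)


def _hypoexp_cdf(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """CDF of the sum of independent Exp(a) + Exp(b) waits (means a, b)."""
    t = np.maximum(np.asarray(t, dtype=float), 0.0)
    if abs(a - b) < 1e-9 * max(a, b):
        # Erlang-2 limit.
        lam = 1.0 / a
        return 1.0 - (1.0 + lam * t) * np.exp(-lam * t)
    return 1.0 - (a * np.exp(-t / a) - b * np.exp(-t / b)) / (a - b)


def _frame_bin_probs(cdf, max_frame: int) -> np.ndarray:
    """P(nearest frame = k) for k = 0..max_frame under the given CDF."""
    k = np.arange(max_frame + 1)
    lo = np.maximum((k - 0.5) * FRAME_S, 0.0)
    hi = (k + 0.5) * FRAME_S
    return cdf(hi) - cdf(lo)


def _observed_mean(cdf, max_frame: int) -> float:
    """Mean frame-quantized time conditional on detection by max_frame."""
    p = _frame_bin_probs(cdf, max_frame)
    tot = p.sum()
    if tot <= 0:
        return np.inf
    return float((np.arange(max_frame + 1) * FRAME_S * p).sum() / tot)


@lru_cache(maxsize=None)
def latent_lamella_mean(observed_mean_s: float,
                        max_frame: int = N_FRAMES - 1) -> float:
    """Latent exponential mean whose censored, quantized mean is as stated."""

    def f(m):
        return _observed_mean(lambda t: _exp_cdf(t, m), max_frame) \
            - observed_mean_s

    return brentq(f, 1.0, 20_000.0, xtol=1e-6)


@lru_cache(maxsize=None)
def latent_detach_wait_mean(observed_detach_mean_s: float,
                            lamella_latent_mean_s: float,
                            max_frame: int) -> float:
    """Latent mean of the post-lamella wait so the observed detach mean fits.

    ``max_frame`` is the last frame at which a detachment can still satisfy
    its persistence requirement within the window.
    """

    def f(b):
        cdf = lambda t: _hypoexp_cdf(t, lamella_latent_mean_s, b)  # noqa: E731
        return _observed_mean(cdf, max_frame) - observed_detach_mean_s

    lo, hi = 0.5, 50_000.0
    if f(lo) > 0:
        # Even an immediate second wait overshoots: the stated detach mean is
        # barely above the lamella mean; fall back to the smallest wait.
        return lo
    return brentq(f, lo, hi, xtol=1e-6)


@lru_cache(maxsize=None)
def detection_prob(lamella_latent_mean_s: float, detach_wait_mean_s: float,
                   max_frame: int) -> float:
    """P(detachment onset falls on a frame <= max_frame)."""
    cdf = lambda t: _hypoexp_cdf(t, lamella_latent_mean_s, detach_wait_mean_s)  # noqa: E731
    return float(_frame_bin_probs(cdf, max_frame).sum())
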