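"""Shared trailing-window stationarity diagnostic.

Both the image-derived density time series and the simulated surface-
fraction trajectories are summarized by the mean and spread of a trailing
window that must look statistically steady.  Steady trajectories of the
recycling process are strongly autocorrelated (the surface fraction
decorrelates on the relaxation time and vesicle-scale delivery makes the
noise batchy), so naive i.i.d. criteria reject genuinely steady windows.

The diagnostic used here is a drift test on batch means, as in Markov-
chain convergence checking: the window is divided into up to eight
contiguous blocks, a line is regressed through the block means, and the
window counts as steady when the fitted drift across the window is
explained by the block-mean noise (within three standard errors), stays
inside the ordinary fluctuation band (within three window standard
deviations — a realized steady path can wander that far when its
correlation time is a sizeable fraction of the window), or is negligible
against the signal level (below 5% of the window mean).  A linear ramp
always fails all three clauses (its drift is large, its regression
residuals tiny, and its window SD is only ~0.29x its drift), while a
converged exponential relaxation passes through the 5% clause.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NoSteadyStateError", "steady_window_stats"]


class NoSteadyStateError(RuntimeError):
    """Raised when a series never settles into a steady window."""


def _drift_and_se(tail: np.ndarray) -> tuple[float, float]:
    """Fitted drift across the window and its standard error, from a
    linear regression through contiguous block means."""
    m = tail.size
    n_blocks = min(8, max(3, m // 4))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    means = np.array([tail[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    x = (edges[:-1] + edges[1:]) / 2.0
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = float(np.sum(xc * (means - means.mean())) / sxx)
    resid = means - means.mean() - slope * xc
    dof = max(n_blocks - 2, 1)
    se_slope = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return slope * m, se_slope * m


def steady_window_stats(
    values: np.ndarray, window_frac: float = 0.25
) -> tuple[np.ndarray, float, float]:
    """Return (window, mean, sd) of the trailing steady window.

    ``window_frac`` is the fraction of the series used as the trailing
    window.

    Raises
    ------
    NoSteadyStateError
        If the trailing window fails the drift diagnostic above.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 8:
        raise NoSteadyStateError("series too short for a steady-window estimate")
    m = max(int(np.ceil(window_frac * n)), 6)
    tail = values[-m:]
    mean = float(tail.mean())
    sd = float(tail.std(ddof=1))
    drift, drift_se = _drift_and_se(tail)
    if abs(drift) > max(3.0 * drift_se, 3.0 * sd, 0.05 * abs(mean)):
        raise NoSteadyStateError(
            "no steady state detected: trailing window is still drifting"
        )
    return tail, mean, sd
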