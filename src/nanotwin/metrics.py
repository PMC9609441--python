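"""Fit-quality metrics shared by the surrogate and milling fits.

Every fit in this package reports ``mse_percent``: the mean squared error of
the predicted D50 profile, with sizes expressed in micrometres, scaled by
100.  Because milled D50 values are of order 1 um, this number reads like a
percentage and is the convention used throughout the reports.  A
scale-invariant alternative, ``relative_mse``, normalised by the mean square
of the observations, is provided for cross-dataset comparisons.
"""

from __future__ import annotations

import numpy as np


def _check_pair(pred, obs):
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs obs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty arrays")
    return pred, obs


def mse_percent(pred, obs) -> float:
    """100 x mean squared error, sizes in micrometres.

    The repo-wide fit metric: ``100 * mean((pred - obs)**2)``.
    """
    pred, obs = _check_pair(pred, obs)
    return float(100.0 * np.mean((pred - obs) ** 2))


def relative_mse(pred, obs) -> float:
    """Scale-invariant MSE in percent: ``100 * mean(err**2) / mean(obs**2)``.

    Invariant under joint rescaling of ``pred`` and ``obs``.
    """
    pred, obs = _check_pair(pred, obs)
    denom = np.mean(obs**2)
    if denom == 0.0:
        raise ValueError("observations are all zero")
    return float(100.0 * np.mean((pred - obs) ** 2) / denom)
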