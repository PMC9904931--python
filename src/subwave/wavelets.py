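"""Haar MODWT scaling coefficients (the denoised channel features).

The maximal overlap discrete wavelet transform is non-decimated: at every
resolution level j it returns a coefficient series of the same length as the
input.  For the Haar basis under mean normalization the level-j scaling
(smooth) coefficient at time t is the 2^j-point moving average

    W_t(j) = 2^{-j} * sum_{l=0}^{2^j - 1} x_{(t - l) mod T}

with a *causal* window (samples at and before t) and circular wrap at the
series start.  Level 0 is the raw signal.  The causal convention matters for
prediction: a feature at time t must not read samples after t; only the
first 2^j - 1 positions touch future samples, via the circular wrap, and the
dataset builder can drop them.

Detail coefficients are not computed — the denoised feature is the smooth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import SignalPanel

__all__ = [
    "BoundaryDominanceWarning",
    "SmoothedPanel",
    "haar_scaling_coefficients",
    "smooth_panel",
    "wrap_prefix_length",
]


class BoundaryDominanceWarning(UserWarning):
    """The smoothing window exceeds the series length; the circular wrap
    dominates every coefficient."""


def wrap_prefix_length(level: int) -> int:
    """Number of leading positions whose window wraps past the series start."""
    return (1 << level) - 1


@dataclass
class SmoothedPanel:
    """Level-j scaling coefficients of one patient's panel (same K x T shape)."""

    patient_id: str
    level: int
    coefficients: np.ndarray  # shape (K, T)

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[1]


def haar_scaling_coefficients(series, level: int) -> np.ndarray:
    """Level-``level`` Haar MODWT smooth of a 1-D series.

    Computed with the pyramid recursion
    ``V_j[t] = (V_{j-1}[t] + V_{j-1}[t - 2^{j-1}]) / 2`` (circular indexing),
    which equals the causal circular 2^j-point moving average in O(T·j).

    Raises
    ------
    ValueError
        If the series is empty or the level negative.

    Warns
    -----
    BoundaryDominanceWarning
        When ``2**level`` exceeds the series length (result still defined via
        the circular wrap).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    if x.size == 0:
        raise ValueError("series must contain at least one sample")
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    if level > 0 and (1 << level) > x.size:
        warnings.warn(
            f"smoothing window 2^{level} = {1 << level} exceeds series length "
            f"{x.size}; coefficients are dominated by the circular wrap",
            BoundaryDominanceWarning,
            stacklevel=2,
        )
    out = x.copy()
    for j in range(level):
        out = 0.5 * (out + np.roll(out, 1 << j))
    return out


def smooth_panel(panel: SignalPanel, level: int) -> SmoothedPanel:
    """Apply :func:`haar_scaling_coefficients` to each channel of a panel.

    The state sequence is untouched (it stays on the source panel); the
    coefficient matrix has the panel's K x T shape.
    """
    if panel.n_times < 1:
        raise ValueError("panel must have at least one time point")
    if level == 0:
        coeffs = panel.channels.copy()
    else:
        coeffs = np.vstack(
            [haar_scaling_coefficients(panel.channels[k], level)
             for k in range(panel.n_channels)]
        )
    return SmoothedPanel(patient_id=panel.patient_id, level=level, coefficients=coeffs)
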