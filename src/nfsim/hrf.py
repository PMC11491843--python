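"""Canonical haemodynamic response function and block regressors.

The BOLD response to a neural event is modelled with the canonical
double-gamma HRF (response peak at 6 s, undershoot at 16 s, undershoot
ratio 1/6), sampled at the repetition time. Block (boxcar) regressors are
convolved with this kernel and scaled so that an isolated 16 s block
reaches a plateau of exactly 1 — a regressor value of 1 then means "full
planted amplitude", which keeps simulated amplitudes, GLM betas and
percent-signal-change numbers on one scale.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "double_gamma_hrf",
    "block_regressor",
    "block_plateau",
    "REFERENCE_BLOCK_S",
]

#: Block duration (s) whose convolved response defines regressor scale 1.
REFERENCE_BLOCK_S = 16.0

# Canonical double-gamma parameters (unit dispersion, gamma shape = delay).
_PEAK_DELAY_S = 6.0
_UNDERSHOOT_DELAY_S = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0
_HRF_DURATION_S = 32.0


def double_gamma_hrf(tr_s: float, duration_s: float = _HRF_DURATION_S) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the repetition time.

    Parameters
    ----------
    tr_s
        Repetition time in seconds (sampling interval of the kernel).
    duration_s
        Kernel support in seconds; the response is effectively zero beyond
        32 s.

    Returns
    -------
    numpy.ndarray
        Kernel samples at t = 0, tr, 2*tr, ..., normalised to peak 1.
    """
    if tr_s <= 0:
        raise ValueError(f"tr_s must be positive, got {tr_s}")
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    h = _gamma.pdf(t, _PEAK_DELAY_S) - _UNDERSHOOT_RATIO * _gamma.pdf(
        t, _UNDERSHOOT_DELAY_S
    )
    return h / h.max()


def _boxcar(onsets_s, duration_s, n_volumes, tr_s) -> np.ndarray:
    box = np.zeros(n_volumes)
    for onset in np.atleast_1d(onsets_s):
        start = math.ceil(onset / tr_s - 1e-9)
        stop = math.ceil((onset + duration_s) / tr_s - 1e-9)
        box[max(start, 0) : min(stop, n_volumes)] = 1.0
    return box


def block_plateau(duration_s: float = REFERENCE_BLOCK_S, tr_s: float = 1.0) -> float:
    """Peak response of an isolated block of the given duration.

    Used as the normalisation constant for :func:`block_regressor`; for a
    16 s block this is the plateau the convolved boxcar settles at.
    """
    n = int(round((duration_s + _HRF_DURATION_S) / tr_s)) + 2
    box = _boxcar([0.0], duration_s, n, tr_s)
    resp = np.convolve(box, double_gamma_hrf(tr_s))[:n]
    return float(resp.max())


def block_regressor(
    onsets_s,
    duration_s: float,
    n_volumes: int,
    tr_s: float,
    *,
    normalize: bool = True,
) -> np.ndarray:
    """HRF-convolved boxcar regressor for a set of equal-duration blocks.

    With ``normalize=True`` (default) the regressor is divided by the
    plateau of an isolated 16 s reference block, so a sustained block of
    that length reaches ~1.0 at steady state.
    """
    box = _boxcar(onsets_s, duration_s, n_volumes, tr_s)
    reg = np.convolve(box, double_gamma_hrf(tr_s))[:n_volumes]
    if normalize:
        reg = reg / block_plateau(REFERENCE_BLOCK_S, tr_s)
    return reg
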