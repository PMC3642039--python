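"""Relative amplitude of the 24-hr discrete-Fourier component (s statistic).

A 12-point window (48 hr at 4-hr sampling) is transformed with the
one-sided DFT, giving a 7-component magnitude vector X whose index k
corresponds to frequency k/48 hr^-1.  The mean term X[0] is zeroed and

    s = X[2] / ||X||_2

so a pure 24-hr cosine attains s = 1 exactly and 0 <= s <= 1 always.
Signals with 13 timepoints are truncated to the first 12 by the runner;
the DFT of 13 points would place bins at k/52 hr^-1 instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rhythmscan.core import Detector, RhythmCall, TimeCourseMatrix

__all__ = ["SpectralResult", "compute_s", "run_dft", "WINDOW_POINTS"]

#: Number of timepoints entering the transform.
WINDOW_POINTS = 12

#: Index of the 24-hr (1/24 hr^-1) frequency bin for the 48-hr window.
BIN_24HR = 2


@dataclass
class SpectralResult:
    probe_id: str
    X: list[np.ndarray]        # one magnitude vector per replicate
    s: list[float]             # per-replicate s
    s_mean: float


def compute_s(signal: np.ndarray) -> tuple[np.ndarray, float]:
    """One-sided DFT magnitudes and the 24-hr relative amplitude.

    Parameters
    ----------
    signal
        Exactly 12 samples (the first 12 of the 13 collected timepoints).

    Returns
    -------
    (X, s)
        ``X`` has 7 nonnegative entries with ``X[0] == 0`` after zeroing
        the mean term; ``s = X[2] / ||X||`` with the 0/0 case mapped to 0.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) != WINDOW_POINTS:
        raise ValueError(
            f"compute_s expects exactly {WINDOW_POINTS} samples "
            f"(got {signal.shape}); truncate or resample the series first"
        )
    X = np.abs(np.fft.rfft(signal))
    X[0] = 0.0
    norm = float(np.linalg.norm(X))
    s = float(X[BIN_24HR] / norm) if norm > 0 else 0.0
    return X, s


def run_dft(tc: TimeCourseMatrix) -> list[RhythmCall]:
    """Per-probe s per replicate plus the replicate mean.

    The period is fixed at 24 hr (the statistic targets the 1/24 hr bin
    only); no period window applies.
    """
    if tc.n_timepoints < WINDOW_POINTS:
        raise ValueError(
            f"need at least {WINDOW_POINTS} timepoints, got {tc.n_timepoints}"
        )
    calls = []
    for i, probe in enumerate(tc.probe_ids):
        s_reps = []
        extras = {}
        for r in range(tc.n_replicates):
            X, s = compute_s(tc.intensities[i, :WINDOW_POINTS, r])
            s_reps.append(s)
            extras[f"s_r{r + 1}"] = s
        calls.append(
            RhythmCall(
                probe_id=probe,
                detector=Detector.DFT,
                statistic=float(np.mean(s_reps)),
                period_hr=24.0,
                peak_phase_hr=None,
                amplitude=None,
                period_ok=True,
                extras=extras,
            )
        )
    return calls


def spectral_result(tc: TimeCourseMatrix, i: int) -> SpectralResult:
    """Full spectral detail for probe row ``i`` (used for reporting)."""
    Xs, ss = [], []
    for r in range(tc.n_replicates):
        X, s = compute_s(tc.intensities[i, :WINDOW_POINTS, r])
        Xs.append(X)
        ss.append(s)
    return SpectralResult(tc.probe_ids[i], Xs, ss, float(np.mean(ss)))
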