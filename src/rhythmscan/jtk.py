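"""Nonparametric rank-correlation rhythm detector with BH q-values.

For every candidate (period, phase) on a lattice, the observed series is
compared by Kendall's tau against a reference cosine sampled at the same
times.  Replicates are concatenated with repeated time labels so a single
statistic is produced per probe.  The one-sided p-value of the Kendall S
statistic comes from the normal approximation with tie correction; the
minimum p across the lattice is Bonferroni-adjusted for the number of
lattice points, and q-values are obtained by Benjamini-Hochberg across
probes.

The amplitude reported for a probe is the median sign-adjusted deviation
from the median, normalized by the reference cosine pattern so that a
perfect cosine of amplitude A yields A/sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from rhythmscan.core import (
    DEFAULT_PERIOD_WINDOW,
    Detector,
    RhythmCall,
    TimeCourseMatrix,
)

__all__ = ["JtkConfig", "jtk_single", "bh_adjust", "run_jtk"]


@dataclass
class JtkConfig:
    """Candidate periods default to sampling-interval steps inside the
    period window (20, 24, 28 hr for the 4-hr study design); the phase
    lattice is every sampling offset within each period."""

    period_grid_hr: tuple[float, ...] | None = None
    period_window_hr: tuple[float, float] | None = None  # None -> regime default
    q_max: float = 0.05

    def periods_for(self, interval_hr: float, window: tuple[float, float]) -> np.ndarray:
        if self.period_grid_hr is not None:
            return np.asarray(self.period_grid_hr, dtype=float)
        lo, hi = window
        k_lo = int(np.ceil(lo / interval_hr - 1e-9))
        k_hi = int(np.floor(hi / interval_hr + 1e-9))
        if k_hi < k_lo:
            raise ValueError(f"no period expressible on the grid within {window}")
        return np.arange(k_lo, k_hi + 1) * interval_hr


# ----------------------------------------------------------------------
# Kendall S with tie-corrected normal p-value
# ----------------------------------------------------------------------

def _tie_stats(values: np.ndarray) -> tuple[float, float, float]:
    """(sum t(t-1), sum t(t-1)(t-2), sum t(t-1)(2t+5)) over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    return (
        float((t * (t - 1)).sum()),
        float((t * (t - 1) * (t - 2)).sum()),
        float((t * (t - 1) * (2 * t + 5)).sum()),
    )


def _var_s(n: int, ties_x, ties_r) -> float:
    t1x, t2x, vtx = ties_x
    t1r, t2r, vtr = ties_r
    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - vtx - vtr) / 18.0
    var += t1x * t1r / (2.0 * n * (n - 1))
    if n > 2:
        var += t2x * t2r / (9.0 * n * (n - 1) * (n - 2))
    return var


def kendall_one_sided(x: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    """One-sided (greater) p-value for Kendall S between ``x`` and ``ref``.

    Returns (p, S, tau_b).  An all-tied series (either side) yields
    (1.0, 0.0, 0.0): tau is undefined, no evidence of rhythm.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = len(x)
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[iu] - x[ju])
    sr = np.sign(ref[iu] - ref[ju])
    S = float(np.dot(sx, sr))
    ties_x = _tie_stats(x)
    ties_r = _tie_stats(ref)
    var = _var_s(n, ties_x, ties_r)
    n0 = n * (n - 1) / 2.0
    denom = np.sqrt((n0 - ties_x[0] / 2.0) * (n0 - ties_r[0] / 2.0))
    if var <= 0 or denom == 0:
        return 1.0, S, 0.0
    tau = S / denom
    z = (S - 1.0) / np.sqrt(var) if S > 0 else (S + 1.0) / np.sqrt(var)
    p = float(norm.sf(z))
    return p, S, tau


# ----------------------------------------------------------------------
# Reference lattice
# ----------------------------------------------------------------------

def _lattice(times: np.ndarray, periods: np.ndarray, interval: float):
    """All (period, phase_offset, reference values) lattice points.

    ``phase_offset`` is the reference peak time in hours since the first
    sample; offsets run over all sampling offsets within each period.
    """
    points = []
    for tau in periods:
        n_phase = max(1, int(round(tau / interval)))
        for k in range(n_phase):
            phi = k * interval
            # quantize so symmetric cosine values tie exactly (float fuzz in
            # cos at equivalent phases would otherwise break rank ties)
            ref = np.round(np.cos(2 * np.pi * (times - phi) / tau), 9)
            points.append((float(tau), float(phi), ref))
    return points


def _amplitude(x: np.ndarray, ref: np.ndarray) -> float:
    """Median sign-adjusted deviation from the median, scaled by the
    reference pattern so a perfect cosine of amplitude A gives A/sqrt(2)."""
    d = x - np.median(x)
    raw = float(np.median(d * np.sign(ref)))
    med_ref = float(np.median(np.abs(ref)))
    if med_ref == 0:
        return raw
    return raw / med_ref / np.sqrt(2.0)


def jtk_single(
    values: np.ndarray,
    times: np.ndarray,
    periods: np.ndarray | None = None,
    sampling_interval_hr: float = 4.0,
):
    """Scan the (period, phase) lattice for one concatenated-replicate series.

    Parameters
    ----------
    values, times
        Concatenated replicate observations and their (repeated) time
        labels, in hours since collection start.

    Returns
    -------
    dict with keys ``p`` (Bonferroni-adjusted min p over the lattice),
    ``p_raw``, ``period_hr``, ``phase_offset_hr`` (reference peak, hours
    since start), ``tau`` and ``amplitude``.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if periods is None:
        periods = np.array([20.0, 24.0, 28.0])
    pts = _lattice(times, np.asarray(periods, dtype=float), sampling_interval_hr)
    best = None
    for tau, phi, ref in pts:
        p, S, t = kendall_one_sided(values, ref)
        if best is None or p < best[0]:
            best = (p, tau, phi, t, ref)
    p_raw, tau_best, phi_best, t_best, ref_best = best
    p_adj = min(1.0, p_raw * len(pts))
    return {
        "p": p_adj,
        "p_raw": p_raw,
        "period_hr": tau_best,
        "phase_offset_hr": phi_best,
        "tau": t_best,
        "amplitude": _amplitude(values, ref_best),
    }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_jtk(tc: TimeCourseMatrix, config: JtkConfig | None = None) -> list[RhythmCall]:
    """Run the detector on every probe of a matrix.

    Replicates are concatenated with duplicated time labels, so one
    statistic (the BH q-value) is produced per probe.  ``period_ok``
    marks probes whose best period lies inside the regime window; the
    default candidate periods already respect the window.
    """
    config = config or JtkConfig()
    window = config.period_window_hr or DEFAULT_PERIOD_WINDOW[tc.regime]
    interval = tc.sampling_interval_hr
    periods = config.periods_for(interval, window)
    times = np.tile(tc.times_hr, tc.n_replicates)
    pts = _lattice(times[: tc.n_timepoints], periods, interval)
    L = len(pts)
    n = tc.n_probes
    N = tc.n_timepoints * tc.n_replicates

    # concatenated series: replicate blocks back to back
    X = np.concatenate([tc.replicate(r) for r in range(tc.n_replicates)], axis=1)
    iu, ju = np.triu_indices(N, k=1)
    signX = np.sign(X[:, iu] - X[:, ju])                     # (n, npairs)
    ties_x = np.array([_tie_stats(row) for row in X])        # (n, 3)

    refs_full = [np.tile(ref, tc.n_replicates) for _, _, ref in pts]
    signR = np.stack([np.sign(r[iu] - r[ju]) for r in refs_full])  # (L, npairs)
    ties_r = np.array([_tie_stats(r) for r in refs_full])          # (L, 3)

    S = signX @ signR.T                                       # (n, L)
    v0 = N * (N - 1) * (2 * N + 5)
    var = (v0 - ties_x[:, 2:3] - ties_r[None, :, 2]) / 18.0
    var = var + ties_x[:, 0:1] * ties_r[None, :, 0] / (2.0 * N * (N - 1))
    var = var + ties_x[:, 1:2] * ties_r[None, :, 1] / (9.0 * N * (N - 1) * (N - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(S > 0, S - 1.0, S + 1.0) / np.sqrt(np.maximum(var, 0.0))
    p = norm.sf(z)
    p[~np.isfinite(z)] = 1.0
    p[var <= 0] = 1.0
    # tau undefined for an all-tied series: no evidence of rhythm
    p[ties_x[:, 0] == N * (N - 1), :] = 1.0

    best_ix = np.argmin(p, axis=1)
    p_raw = p[np.arange(n), best_ix]
    p_adj = np.minimum(1.0, p_raw * L)
    q = bh_adjust(p_adj)

    lo, hi = window
    calls = []
    for i, probe in enumerate(tc.probe_ids):
        tau_best, phi_best, _ = pts[best_ix[i]]
        ref_full = refs_full[best_ix[i]]
        all_tied = ties_x[i, 0] == N * (N - 1)
        if all_tied:
            period = phase = amp = None
            period_ok = False
        else:
            period = tau_best
            phase = float(tc.to_clock_hours(phi_best))
            amp = _amplitude(X[i], ref_full)
            period_ok = lo <= tau_best <= hi
        calls.append(
            RhythmCall(
                probe_id=probe,
                detector=Detector.JTK,
                statistic=float(q[i]),
                period_hr=period,
                peak_phase_hr=phase,
                amplitude=amp,
                period_ok=bool(period_ok),
                extras={"p_adj": float(p_adj[i]), "p_raw": float(p_raw[i])},
            )
        )
    return calls
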