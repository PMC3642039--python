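"""Downstream analysis of rhythm calls: phase distributions, amplitude
measures, LD-vs-DD comparisons, transition typing, clustering, Z-scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from rhythmscan.core import RhythmCall, TimeCourseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseDistribution",
    "AmplitudeMeasure",
    "phase_distribution",
    "peak_nadir_amplitude",
    "ld_dd_fold",
    "classify_ld_dd_type",
    "classify_ld_dd_types",
    "ClusterResult",
    "hierarchical_cluster",
    "zscore_profiles",
]


# ----------------------------------------------------------------------
# Peak-phase distribution
# ----------------------------------------------------------------------

@dataclass
class PhaseDistribution:
    """Percentage of rhythmic genes peaking in each circular phase bin.

    Bins are right-closed and centered on multiples of ``bin_width_hr``:
    with 4-hr bins the bin labelled 0 covers (22, 2] on the 24-hr circle.
    """

    bin_width_hr: float
    bin_centers: np.ndarray
    percentages: np.ndarray
    counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"phase_bin": self.bin_centers, "count": self.counts,
             "percentage": self.percentages}
        )


def phase_distribution(
    calls: Sequence[RhythmCall],
    gene_map: Mapping[str, str] | None = None,
    bin_width_hr: float = 3.0,
    q_max: float = 0.05,
) -> PhaseDistribution:
    """Bin peak phases of rhythmic genes into right-closed circular bins.

    For genes with multiple rhythmic probes only the probe with the
    lowest q (statistic) is kept.  Percentages are over rhythmic genes.
    """
    if 24.0 % bin_width_hr != 0:
        raise ValueError("bin width must divide 24")
    gene_map = gene_map or {}
    best: dict[str, RhythmCall] = {}
    for c in calls:
        if c.peak_phase_hr is None or not (c.statistic < q_max and c.period_ok):
            continue
        gene = gene_map.get(c.probe_id, c.probe_id)
        if gene not in best or c.statistic < best[gene].statistic:
            best[gene] = c
    n_bins = int(round(24.0 / bin_width_hr))
    centers = np.arange(n_bins) * bin_width_hr
    counts = np.zeros(n_bins, dtype=int)
    for c in best.values():
        # right-closed: a phase exactly on a bin's upper edge belongs to it
        k = int(np.ceil((c.peak_phase_hr - bin_width_hr / 2.0) / bin_width_hr - 1e-9))
        counts[k % n_bins] += 1
    total = counts.sum()
    pct = 100.0 * counts / total if total else np.zeros(n_bins)
    return PhaseDistribution(bin_width_hr, centers, pct, counts)


# ----------------------------------------------------------------------
# Peak/nadir amplitude with the 8-16 hr interval rule
# ----------------------------------------------------------------------

@dataclass
class AmplitudeMeasure:
    probe_id: str
    peak: float
    nadir: float
    ratio: float            # peak / nadir (nan when nadir == 0)
    interval_hr: float      # circular separation of peak and nadir times
    valid: bool
    reason: str = ""


def peak_nadir_amplitude(
    signal: np.ndarray,
    times_hr: np.ndarray,
    probe_id: str = "",
    window_hr: tuple[float, float] = (8.0, 16.0),
) -> AmplitudeMeasure:
    """Peak/nadir ratio, valid only when the two are 8-16 hr apart.

    Peak and nadir take the first occurrence of the extreme values; the
    interval is their separation reduced mod 24 (unfolded, so 20 hr apart
    stays 20 and is invalid).
    """
    x = np.asarray(signal, dtype=float)
    t = np.asarray(times_hr, dtype=float)
    i_peak = int(np.argmax(x))
    i_nadir = int(np.argmin(x))
    peak, nadir = float(x[i_peak]), float(x[i_nadir])
    interval = float(np.mod(abs(t[i_peak] - t[i_nadir]), 24.0))
    lo, hi = window_hr
    if nadir == 0:
        return AmplitudeMeasure(probe_id, peak, nadir, float("nan"), interval,
                                False, "zero nadir: ratio undefined")
    ratio = peak / nadir
    ok = lo <= interval <= hi
    reason = "" if ok else f"peak-nadir interval {interval:g} hr outside [{lo}, {hi}]"
    return AmplitudeMeasure(probe_id, peak, nadir, ratio, interval, ok, reason)


# ----------------------------------------------------------------------
# LD vs DD mean-expression fold change
# ----------------------------------------------------------------------

def ld_dd_fold(
    tc_ld: TimeCourseMatrix,
    tc_dd: TimeCourseMatrix,
    probes: Sequence[str] | None = None,
    n_timepoints: int = 12,
) -> tuple[pd.DataFrame, float]:
    """Mean-expression fold change between conditions per probe.

    Means are taken over the first ``n_timepoints`` timepoints and all
    replicates.  Fold is reported symmetrically (max/min >= 1) with a
    direction flag; the summary is the fraction of probes with fold > 2.
    """
    probes = list(probes) if probes is not None else list(tc_ld.probe_ids)
    in_dd = set(tc_dd.probe_ids)
    in_ld = set(tc_ld.probe_ids)
    usable = [p for p in probes if p in in_dd and p in in_ld]
    dropped = [p for p in probes if p not in in_dd or p not in in_ld]
    if dropped:
        logger.warning("ld_dd_fold: %d probe(s) missing in one condition", len(dropped))
    ld = tc_ld.subset(usable).intensities[:, :n_timepoints, :].mean(axis=(1, 2))
    dd = tc_dd.subset(usable).intensities[:, :n_timepoints, :].mean(axis=(1, 2))
    with np.errstate(divide="ignore"):
        fold = np.maximum(ld, dd) / np.minimum(ld, dd)
    direction = np.where(ld >= dd, "LD-high", "DD-high")
    df = pd.DataFrame(
        {"probe_id": usable, "mean_ld": ld, "mean_dd": dd,
         "fold": fold, "direction": direction}
    )
    frac = float((df["fold"] > 2.0).mean()) if len(df) else 0.0
    return df, frac


# ----------------------------------------------------------------------
# LD -> DD transition typing
# ----------------------------------------------------------------------

def _subjective_day_means(dd_profile: np.ndarray, times_hr: np.ndarray,
                          start_phase_hr: float) -> tuple[float, float]:
    ct = np.mod(times_hr + start_phase_hr, 24.0)
    day = ct < 12.0
    first = day & (times_hr < 24.0)
    second = day & (times_hr >= 24.0) & (times_hr < 48.0)
    m1 = float(dd_profile[first].mean()) if first.any() else float("nan")
    m2 = float(dd_profile[second].mean()) if second.any() else float("nan")
    return m1, m2


def classify_ld_dd_type(
    ld_profile: np.ndarray,
    dd_profile: np.ndarray,
    rhythmic_ld: bool,
    rhythmic_dd: bool,
    times_hr: np.ndarray,
    dd_start_phase_hr: float = 0.0,
    type2_factor: float = 1.5,
) -> str:
    """Heuristic LD-to-DD transition type for one probe.

    Returns one of ``"I"``, ``"II"``, ``"III"``, ``"other"``:

    * III — rhythmic in LD, not in DD, DD mean at or below the LD nadir.
    * II  — rhythmic in LD; the first DD cycle's subjective-day mean
      exceeds the second cycle's by ``type2_factor``.
    * I   — rhythmic in both with a smaller DD peak-to-trough amplitude.
    """
    ld = np.asarray(ld_profile, dtype=float)
    dd = np.asarray(dd_profile, dtype=float)
    if not rhythmic_ld:
        return "other"
    if not rhythmic_dd and dd.mean() <= ld.min() + 1e-9:
        return "III"
    m1, m2 = _subjective_day_means(dd, np.asarray(times_hr, dtype=float),
                                   dd_start_phase_hr)
    if np.isfinite(m1) and np.isfinite(m2) and m2 > 0 and m1 > type2_factor * m2:
        return "II"
    if rhythmic_dd and (dd.max() - dd.min()) < (ld.max() - ld.min()):
        return "I"
    return "other"


def classify_ld_dd_types(
    tc_ld: TimeCourseMatrix,
    tc_dd: TimeCourseMatrix,
    calls_ld: Sequence[RhythmCall],
    calls_dd: Sequence[RhythmCall],
    q_max: float = 0.05,
    type2_factor: float = 1.5,
) -> pd.DataFrame:
    """Apply :func:`classify_ld_dd_type` across a paired LD/DD dataset.

    Rhythmicity under each regime is taken from the supplied calls
    (statistic < ``q_max`` with the period window satisfied).  Profiles
    are replicate means.
    """
    rl = {c.probe_id: (c.statistic < q_max and c.period_ok) for c in calls_ld}
    rd = {c.probe_id: (c.statistic < q_max and c.period_ok) for c in calls_dd}
    rows = []
    for i, probe in enumerate(tc_ld.probe_ids):
        if probe not in rl or probe not in rd:
            continue
        j = tc_dd.probe_ids.index(probe)
        ld_prof = tc_ld.intensities[i].mean(axis=1)
        dd_prof = tc_dd.intensities[j].mean(axis=1)
        t = classify_ld_dd_type(
            ld_prof, dd_prof, rl[probe], rd[probe], tc_dd.times_hr,
            dd_start_phase_hr=tc_dd.start_phase_hr, type2_factor=type2_factor,
        )
        rows.append({"probe_id": probe, "ld_dd_type": t,
                     "rhythmic_ld": rl[probe], "rhythmic_dd": rd[probe]})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Hierarchical clustering (log2, mean-center, unit sum of squares,
# centroid linkage)
# ----------------------------------------------------------------------

@dataclass
class ClusterResult:
    probe_ids: list[str]
    normalized: np.ndarray          # (n, T) transformed profiles
    linkage: np.ndarray | None      # scipy linkage matrix (None if n < 2)
    leaf_order: list[int]
    newick: str


def _normalize_profiles(profiles: np.ndarray) -> np.ndarray:
    logged = np.log2(profiles)
    centered = logged - logged.mean(axis=1, keepdims=True)
    ss = np.sqrt((centered ** 2).sum(axis=1, keepdims=True))
    ss[ss == 0] = 1.0
    return centered / ss


def _to_newick(node, names: list[str]) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    dl = max(node.dist - node.get_left().dist, 0.0)
    dr = max(node.dist - node.get_right().dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hierarchical_cluster(
    tc: TimeCourseMatrix,
    intensity_floor: float = 20.0,
) -> ClusterResult:
    """Cluster replicate-mean profiles after log2 / center / unit-SS scaling.

    Probes with overall mean intensity <= ``intensity_floor`` are
    excluded first.  After normalization the profiles have unit norm, so
    Euclidean centroid linkage is monotone in uncentered-correlation
    distance (1 - r = ||u - v||^2 / 2).
    """
    profiles = tc.intensities.mean(axis=2)
    keep = profiles.mean(axis=1) > intensity_floor
    probe_ids = [p for p, k in zip(tc.probe_ids, keep) if k]
    profiles = profiles[keep]
    if (profiles <= 0).any():
        raise ValueError("profiles must be strictly positive for log2 transform")
    norm = _normalize_profiles(profiles)
    if len(probe_ids) < 2:
        nwk = f"{probe_ids[0]};" if probe_ids else ";"
        return ClusterResult(probe_ids, norm, None, list(range(len(probe_ids))), nwk)
    Z = hierarchy.linkage(norm, method="centroid")
    order = hierarchy.leaves_list(Z).tolist()
    tree = hierarchy.to_tree(Z)
    nwk = _to_newick(tree, probe_ids) + ";"
    return ClusterResult(probe_ids, norm, Z, order, nwk)


def zscore_profiles(profiles: np.ndarray) -> np.ndarray:
    """Per-row (x - mean) / sd standardization; constant rows become zeros."""
    x = np.asarray(profiles, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.info("zscore_profiles: %d constant profile(s) set to zeros", flat.sum())
    sd[sd == 0] = 1.0
    return (x - mu) / sd
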