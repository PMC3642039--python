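"""Ground-truth-labelled synthetic data for exercising the pipeline.

Generates expression matrices on the study design (13 timepoints at 4-hr
spacing, 2 replicates), paired LD/DD time courses exhibiting the three
LD-to-DD transition patterns, and random promoter sequences with planted
consensus elements.  Everything is deterministic under a fixed seed.

Signal models
-------------
sinusoidal   ``baseline * (1 + A*cos(2*pi*(clock_t - phase)/period)) * noise``
pulsatile    baseline plus a single elevated timepoint recurring every 24 hr
arrhythmic   ``baseline * noise``

Noise is multiplicative lognormal (``exp(sigma * Z)``), keeping
intensities positive and heteroskedastic like fluorescence data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from rhythmscan.core import Regime, TimeCourseMatrix, DEFAULT_START_PHASE

__all__ = [
    "SimulationSpec",
    "PlantedMotif",
    "simulate_matrix",
    "simulate_ld_dd_pair",
    "simulate_promoters",
    "write_fasta",
]

_CLASSES = ("sinusoidal", "pulsatile", "arrhythmic", "type_I", "type_II", "type_III")


@dataclass
class SimulationSpec:
    """Parameters for one synthetic expression matrix.

    ``period_hr`` and ``phase_hr`` may be a scalar (shared by all probes)
    or a ``(low, high)`` tuple sampled uniformly per probe; ``phase_hr``
    of ``None`` draws uniformly on [0, 24).  Phases are on the ZT/CT
    clock scale.
    """

    n_sinusoidal: int = 0
    n_pulsatile: int = 0
    n_arrhythmic: int = 0
    n_type_I: int = 0
    n_type_II: int = 0
    n_type_III: int = 0
    period_hr: float | tuple[float, float] = 24.0
    phase_hr: float | tuple[float, float] | None = None
    baseline: float = 100.0
    rel_amplitude: float = 0.5
    noise_sigma: float = 0.0
    spike_fold: float = 2.0
    dd_amplitude_scale: float = 0.25
    type3_dd_level_frac: float = 0.5   # of the LD nadir
    background_floor: float = 20.0
    n_timepoints: int = 13
    sampling_interval_hr: float = 4.0
    n_replicates: int = 2
    regime: Regime = Regime.LD
    seed: int = 0

    def __post_init__(self) -> None:
        self.regime = Regime(self.regime)
        for name in ("n_sinusoidal", "n_pulsatile", "n_arrhythmic",
                     "n_type_I", "n_type_II", "n_type_III"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "sinusoidal": self.n_sinusoidal,
            "pulsatile": self.n_pulsatile,
            "arrhythmic": self.n_arrhythmic,
            "type_I": self.n_type_I,
            "type_II": self.n_type_II,
            "type_III": self.n_type_III,
        }


def _draw(rng: np.random.Generator, value, n: int, default_range=None) -> np.ndarray:
    if value is None:
        lo, hi = default_range
        return rng.uniform(lo, hi, size=n)
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return rng.uniform(lo, hi, size=n)
    return np.full(n, float(value))


def _truth_frame(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for klass in _CLASSES:
        for _ in range(spec.class_counts[klass]):
            rows.append(klass)
    n = len(rows)
    periods = _draw(rng, spec.period_hr, n)
    phases = _draw(rng, spec.phase_hr, n, default_range=(0.0, 24.0))
    truth = pd.DataFrame(
        {
            "probe_id": [f"probe_{i:05d}" for i in range(n)],
            "klass": rows,
            "period_hr": periods,
            "phase_hr": np.mod(phases, 24.0),
            "rel_amplitude": spec.rel_amplitude,
            "baseline": spec.baseline,
        }
    )
    # arrhythmic probes carry no rhythm parameters
    flat = truth["klass"] == "arrhythmic"
    truth.loc[flat, ["period_hr", "phase_hr", "rel_amplitude"]] = np.nan
    # pulsatile recurrence is fixed at 24 hr by construction
    truth.loc[truth["klass"] == "pulsatile", "period_hr"] = 24.0
    return truth


def _noise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    if sigma == 0:
        return np.ones(shape)
    return np.exp(sigma * rng.standard_normal(shape))


def _sinus_profile(clock_t: np.ndarray, baseline: float, amp: float,
                   period: float, phase: float) -> np.ndarray:
    return baseline * (1.0 + amp * np.cos(2 * np.pi * (clock_t - phase) / period))


def _pulse_profile(clock_t: np.ndarray, baseline: float, spike_fold: float,
                   phase: float, interval: float) -> np.ndarray:
    """Baseline with one elevated timepoint per 24-hr recurrence of ``phase``."""
    prof = np.full(clock_t.shape, baseline)
    # distance of each grid point to the nearest 24-hr recurrence of phase
    d = np.abs((clock_t - phase + 12.0) % 24.0 - 12.0)
    prof[d <= interval / 2.0 - 1e-9] = baseline * (1.0 + spike_fold)
    # ties exactly halfway between grid points: elevate the earlier point only
    halfway = np.isclose(d, interval / 2.0)
    if halfway.any():
        idx = np.flatnonzero(halfway)
        keep = idx[((clock_t[idx] - phase) % 24.0) < 12.0]
        prof[keep] = baseline * (1.0 + spike_fold)
    return prof


def simulate_matrix(spec: SimulationSpec) -> tuple[TimeCourseMatrix, pd.DataFrame]:
    """Simulate one matrix plus its per-probe truth table.

    Returns
    -------
    (TimeCourseMatrix, DataFrame)
        Truth columns: probe_id, klass, period_hr, phase_hr,
        rel_amplitude, baseline.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_frame(spec, rng)
    n = len(truth)
    t = np.arange(spec.n_timepoints) * spec.sampling_interval_hr
    clock_t = t + DEFAULT_START_PHASE[spec.regime]
    arr = np.empty((n, spec.n_timepoints, spec.n_replicates))
    for i, row in truth.iterrows():
        if row.klass in ("sinusoidal", "type_I", "type_II", "type_III"):
            prof = _sinus_profile(clock_t, spec.baseline, spec.rel_amplitude,
                                  row.period_hr, row.phase_hr)
        elif row.klass == "pulsatile":
            prof = _pulse_profile(clock_t, spec.baseline, spec.spike_fold,
                                  row.phase_hr, spec.sampling_interval_hr)
        else:
            prof = np.full(spec.n_timepoints, spec.baseline)
        arr[i] = prof[:, None]
    arr = arr * _noise(rng, spec.noise_sigma, arr.shape)
    arr = np.maximum(arr, spec.background_floor)
    tc = TimeCourseMatrix(
        probe_ids=truth["probe_id"].tolist(),
        intensities=arr,
        sampling_interval_hr=spec.sampling_interval_hr,
        regime=spec.regime,
    )
    return tc, truth


def simulate_ld_dd_pair(
    spec: SimulationSpec,
) -> tuple[TimeCourseMatrix, TimeCourseMatrix, pd.DataFrame]:
    """Simulate paired LD and DD matrices with LD-to-DD transition types.

    The LD matrix starts at ZT 12 and the DD matrix at CT 0.  Probe
    behaviour by class:

    * ``sinusoidal`` — identical rhythm parameters in both conditions.
    * ``arrhythmic`` — flat baseline in both.
    * ``type_I`` — rhythmic in both; DD amplitude scaled by
      ``dd_amplitude_scale``.
    * ``type_II`` — as type I in DD cycle 2, but held at the LD daytime
      (peak) level during subjective day of the first DD cycle.
    * ``type_III`` — rhythmic in LD only; DD flat at
      ``type3_dd_level_frac`` of the LD nadir.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_frame(spec, rng)
    n = len(truth)
    t = np.arange(spec.n_timepoints) * spec.sampling_interval_hr
    clock_ld = t + DEFAULT_START_PHASE[Regime.LD]
    clock_dd = t + DEFAULT_START_PHASE[Regime.DD]
    ld = np.empty((n, spec.n_timepoints, spec.n_replicates))
    dd = np.empty_like(ld)
    A = spec.rel_amplitude
    B = spec.baseline
    for i, row in truth.iterrows():
        if row.klass == "arrhythmic":
            ld_prof = np.full(spec.n_timepoints, B)
            dd_prof = ld_prof.copy()
        elif row.klass == "pulsatile":
            ld_prof = _pulse_profile(clock_ld, B, spec.spike_fold, row.phase_hr,
                                     spec.sampling_interval_hr)
            dd_prof = _pulse_profile(clock_dd, B, spec.spike_fold, row.phase_hr,
                                     spec.sampling_interval_hr)
        else:
            ld_prof = _sinus_profile(clock_ld, B, A, row.period_hr, row.phase_hr)
            if row.klass in ("type_I", "type_II"):
                dd_prof = _sinus_profile(clock_dd, B, A * spec.dd_amplitude_scale,
                                         row.period_hr, row.phase_hr)
                if row.klass == "type_II":
                    # first DD cycle: subjective day held at the LD daytime level
                    first_day = (t < 24.0) & (np.mod(clock_dd, 24.0) < 12.0)
                    dd_prof = dd_prof.copy()
                    dd_prof[first_day] = B * (1.0 + A)
            elif row.klass == "type_III":
                nadir = ld_prof.min()
                dd_prof = np.full(spec.n_timepoints, spec.type3_dd_level_frac * nadir)
            else:  # plain sinusoidal: same rhythm in both conditions
                dd_prof = _sinus_profile(clock_dd, B, A, row.period_hr, row.phase_hr)
        ld[i] = ld_prof[:, None]
        dd[i] = dd_prof[:, None]
    ld = ld * _noise(rng, spec.noise_sigma, ld.shape)
    dd = dd * _noise(rng, spec.noise_sigma, dd.shape)
    probe_ids = truth["probe_id"].tolist()
    tc_ld = TimeCourseMatrix(probe_ids=list(probe_ids), intensities=ld,
                             sampling_interval_hr=spec.sampling_interval_hr,
                             regime=Regime.LD)
    tc_dd = TimeCourseMatrix(probe_ids=list(probe_ids), intensities=dd,
                             sampling_interval_hr=spec.sampling_interval_hr,
                             regime=Regime.DD)
    return tc_ld, tc_dd, truth


# ----------------------------------------------------------------------
# Promoter sequences with planted motif instances
# ----------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PlantedMotif:
    """One concrete motif instance to embed in a synthetic promoter.

    ``start`` follows the scanner convention: the negative 1-based
    distance of the instance's 5'-most base (on the forward strand)
    upstream of the TSS, which sits at the 3' end of the sequence.
    """

    seq_index: int
    name: str
    sequence: str           # concrete ACGT instance, forward-strand letters
    start: int              # negative upstream coordinate
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= 0:
            raise ValueError("start must be negative (upstream of TSS)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("planted sequence must be concrete ACGT")


def simulate_promoters(
    n: int,
    length: int,
    planted: Sequence[PlantedMotif] = (),
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-random promoter sequences with exact planted motif instances.

    Returns a mapping ``gene_id -> sequence`` (TSS at the 3' end) and a
    truth table with columns gene_id, motif, start, strand, matched.
    """
    rng = np.random.default_rng(seed)
    seqs = {}
    for i in range(n):
        seqs[f"gene_{i:04d}"] = "".join(
            rng.choice(list("ACGT"), size=length)
        )
    rows = []
    for p in planted:
        if p.seq_index >= n:
            raise IndexError(f"seq_index {p.seq_index} out of range for n={n}")
        m = len(p.sequence)
        if m > length:
            raise ValueError(f"motif {p.name!r} longer than sequence ({m} > {length})")
        offset = length + p.start  # 0-based forward index of the 5'-most base
        if offset < 0 or offset + m > length:
            raise ValueError(
                f"planted {p.name!r} at {p.start} does not fit in length {length}"
            )
        gid = f"gene_{p.seq_index:04d}"
        ins = p.sequence if p.strand == "+" else reverse_complement(p.sequence)
        s = seqs[gid]
        seqs[gid] = s[:offset] + ins + s[offset + m:]
        # `matched` is motif-oriented (as the scanner reports it): for a
        # minus-strand plant it is the reverse complement of the forward text
        rows.append(
            {"gene_id": gid, "motif": p.name, "start": p.start,
             "strand": p.strand, "matched": p.sequence}
        )
    truth = pd.DataFrame(rows, columns=["gene_id", "motif", "start", "strand", "matched"])
    return seqs, truth


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path
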