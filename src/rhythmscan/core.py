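"""Domain types, expression-matrix I/O and the shared intensity prefilter.

The central container is :class:`TimeCourseMatrix`: a dense nonnegative
array of fluorescence intensities indexed ``(probe, timepoint, replicate)``
on a uniform sampling grid, together with the collection regime (LD or DD)
and the clock phase at which collection started.  All detectors consume
this type only.

Time conventions
----------------
The internal time axis is hours since collection start
(``t_i = i * sampling_interval_hr``).  Reported peak phases live on the
circular [0, 24) ZT/CT scale and are obtained by adding ``start_phase_hr``
(ZT 12 for the LD design, CT 0 for DD) and reducing mod 24.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Regime(str, enum.Enum):
    """Collection lighting regime: light:dark cycle or constant darkness."""

    LD = "LD"
    DD = "DD"


#: Default collection start phase (ZT/CT hours) per regime.
DEFAULT_START_PHASE = {Regime.LD: 12.0, Regime.DD: 0.0}

#: Default period-eligibility window (hours) per regime.
DEFAULT_PERIOD_WINDOW = {Regime.LD: (20.0, 28.0), Regime.DD: (18.5, 26.5)}


class Detector(str, enum.Enum):
    COSOPT = "COSOPT"
    JTK = "JTK"
    DFT = "DFT"
    PULSE = "PULSE"


@dataclass
class TimeCourseMatrix:
    """Probes x timepoints x replicates intensity array with its time grid.

    Parameters
    ----------
    probe_ids
        Probe identifiers, one per row of ``intensities``.
    intensities
        Nonnegative array of shape ``(n_probes, n_timepoints, n_replicates)``.
    sampling_interval_hr
        Hours between consecutive timepoints (default 4).
    regime
        ``Regime.LD`` or ``Regime.DD``.
    start_phase_hr
        ZT/CT hour of the first timepoint.  Defaults to ZT 12 for LD and
        CT 0 for DD.
    """

    probe_ids: list[str]
    intensities: np.ndarray
    sampling_interval_hr: float = 4.0
    regime: Regime = Regime.LD
    start_phase_hr: float | None = None

    def __post_init__(self) -> None:
        self.regime = Regime(self.regime)
        if self.start_phase_hr is None:
            self.start_phase_hr = DEFAULT_START_PHASE[self.regime]
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError(
                f"intensities must be 3-D (probe, timepoint, replicate); got shape {arr.shape}"
            )
        if arr.shape[0] != len(self.probe_ids):
            raise ValueError(
                f"{len(self.probe_ids)} probe ids but {arr.shape[0]} intensity rows"
            )
        if np.isnan(arr).any():
            bad = [self.probe_ids[i] for i in np.unique(np.argwhere(np.isnan(arr))[:, 0])]
            logger.warning("dropping %d probe(s) with missing values: %s", len(bad), bad)
            keep = ~np.isnan(arr).any(axis=(1, 2))
            self.probe_ids = [p for p, k in zip(self.probe_ids, keep) if k]
            arr = arr[keep]
        if (arr < 0).any():
            i = int(np.argwhere(arr < 0)[0, 0])
            raise ValueError(f"negative intensity for probe {self.probe_ids[i]!r}")
        if self.sampling_interval_hr <= 0:
            raise ValueError("sampling_interval_hr must be positive")
        self.intensities = arr

    # ------------------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[2]

    @property
    def times_hr(self) -> np.ndarray:
        """Hours since collection start for each timepoint."""
        return np.arange(self.n_timepoints) * self.sampling_interval_hr

    @property
    def span_hr(self) -> float:
        """Total span of the sampling grid in hours."""
        return float((self.n_timepoints - 1) * self.sampling_interval_hr)

    def to_clock_hours(self, t_hr: float | np.ndarray) -> np.ndarray:
        """Convert hours-since-start to the [0, 24) ZT/CT scale."""
        return np.mod(np.asarray(t_hr, dtype=float) + self.start_phase_hr, 24.0)

    def subset(self, probe_ids: Iterable[str]) -> "TimeCourseMatrix":
        """Return a new matrix restricted to ``probe_ids`` (input order kept)."""
        wanted = list(probe_ids)
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in wanted if p not in index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        rows = [index[p] for p in wanted]
        return TimeCourseMatrix(
            probe_ids=wanted,
            intensities=self.intensities[rows].copy(),
            sampling_interval_hr=self.sampling_interval_hr,
            regime=self.regime,
            start_phase_hr=self.start_phase_hr,
        )

    def replicate(self, r: int) -> np.ndarray:
        """(probes x timepoints) view of replicate ``r``."""
        return self.intensities[:, :, r]


@dataclass
class RhythmCall:
    """One detector's verdict for one probe."""

    probe_id: str
    detector: Detector
    statistic: float
    period_hr: float | None = None
    peak_phase_hr: float | None = None
    amplitude: float | None = None
    period_ok: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.detector = Detector(self.detector)
        if self.period_hr is not None and self.period_hr <= 0:
            raise ValueError("period_hr must be positive when present")
        if self.peak_phase_hr is not None:
            self.peak_phase_hr = float(np.mod(self.peak_phase_hr, 24.0))


def calls_to_frame(calls: Sequence[RhythmCall]) -> pd.DataFrame:
    """Tabulate rhythm calls as a tidy DataFrame (one row per call)."""
    rows = []
    for c in calls:
        row = {
            "probe_id": c.probe_id,
            "detector": c.detector.value,
            "statistic": c.statistic,
            "period_hr": c.period_hr,
            "peak_phase_hr": c.peak_phase_hr,
            "amplitude": c.amplitude,
            "period_ok": c.period_ok,
        }
        row.update(c.extras)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class Thresholds:
    """Statistical cutoffs used for consensus rhythmicity calling."""

    cosopt_p_max: float = 0.2
    jtk_q_max: float = 0.1
    dft_s_min: float = 0.3
    pulse_c_min: float = 1.6
    pulse_fold_min: float = 1.5
    period_window_hr: tuple[float, float] = (20.0, 28.0)
    intensity_floor: float = 20.0

    def __post_init__(self) -> None:
        lo, hi = self.period_window_hr
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("period window must be finite with low < high")
        for name in ("cosopt_p_max", "jtk_q_max", "dft_s_min", "pulse_c_min",
                     "pulse_fold_min", "intensity_floor"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def for_regime(cls, regime: Regime | str, **kw) -> "Thresholds":
        kw.setdefault("period_window_hr", DEFAULT_PERIOD_WINDOW[Regime(regime)])
        return cls(**kw)


# ----------------------------------------------------------------------
# I/O: wide TSV with columns  probe_id, T<hr>_r<rep>
# ----------------------------------------------------------------------

def _wide_columns(n_timepoints: int, n_replicates: int, interval: float) -> list[str]:
    cols = []
    for i in range(n_timepoints):
        hr = i * interval
        hr_txt = f"{hr:g}"
        for r in range(1, n_replicates + 1):
            cols.append(f"T{hr_txt}_r{r}")
    return cols


def write_time_course(tc: TimeCourseMatrix, path: str | Path) -> Path:
    """Write a matrix in the wide TSV convention (``T<hr>_r<rep>`` columns)."""
    path = Path(path)
    cols = _wide_columns(tc.n_timepoints, tc.n_replicates, tc.sampling_interval_hr)
    flat = tc.intensities.reshape(tc.n_probes, -1)  # timepoint-major, replicate-minor
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "probe_id", tc.probe_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_time_course(
    path: str | Path,
    regime: Regime | str = Regime.LD,
    start_phase_hr: float | None = None,
) -> TimeCourseMatrix:
    """Read a wide TSV/CSV expression table into a :class:`TimeCourseMatrix`.

    The table must carry a ``probe_id`` column plus one ``T<hr>_r<rep>``
    column per (timepoint, replicate).  The time grid is inferred from the
    column names and must be uniform.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if "probe_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'probe_id'")
    data_cols = [c for c in df.columns if c != "probe_id"]
    parsed = []
    for c in data_cols:
        if not c.startswith("T") or "_r" not in c:
            raise ValueError(f"{path}: column {c!r} does not follow 'T<hr>_r<rep>'")
        hr_txt, rep_txt = c[1:].split("_r", 1)
        try:
            parsed.append((float(hr_txt), int(rep_txt), c))
        except ValueError as e:
            raise ValueError(f"{path}: cannot parse column name {c!r}") from e
    hours = sorted({h for h, _, _ in parsed})
    reps = sorted({r for _, r, _ in parsed})
    if len(parsed) != len(hours) * len(reps):
        raise ValueError(f"{path}: ragged (timepoint, replicate) column grid")
    if len(hours) > 1:
        steps = np.diff(hours)
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"{path}: non-uniform time grid {hours}")
        interval = float(steps[0])
    else:
        interval = 4.0
    colmap = {(h, r): c for h, r, c in parsed}
    probe_ids = df["probe_id"].astype(str).tolist()
    arr = np.empty((len(df), len(hours), len(reps)))
    for i, h in enumerate(hours):
        for j, r in enumerate(reps):
            col = df[colmap[(h, r)]]
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() & col.notna()
            if bad.any():
                probe = probe_ids[int(np.argwhere(bad.values)[0, 0])]
                raise ValueError(
                    f"{path}: non-numeric cell in column {colmap[(h, r)]!r}, probe {probe!r}"
                )
            arr[:, i, j] = vals.to_numpy()
    neg = arr < 0
    if neg.any():
        probe = probe_ids[int(np.argwhere(neg)[0, 0])]
        raise ValueError(f"{path}: negative intensity for probe {probe!r}")
    return TimeCourseMatrix(
        probe_ids=probe_ids,
        intensities=arr,
        sampling_interval_hr=interval,
        regime=regime,
        start_phase_hr=start_phase_hr,
    )


def intensity_filter(tc: TimeCourseMatrix, floor: float = 20.0) -> list[str]:
    """Probes whose mean intensity exceeds ``floor`` in every replicate.

    The mean is the arithmetic mean over all timepoints of one replicate;
    a probe is retained only if that mean is strictly above ``floor`` for
    each replicate separately.
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    means = tc.intensities.mean(axis=1)  # (probes, replicates)
    keep = (means > floor).all(axis=1)
    return [p for p, k in zip(tc.probe_ids, keep) if k]
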