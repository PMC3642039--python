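"""Combine detector outputs into consensus rhythmic sets.

Per-probe pass flags at the stated cutoffs (COSOPT mean pMMCbeta with the
period window satisfied in both replicates; JTK q with its period window;
DFT mean s) are combined into the seven Venn regions plus a none-region,
with helpers for "newly rhythmic" lists and threshold sweep tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rhythmscan.core import RhythmCall, Thresholds

__all__ = ["ConsensusResult", "venn_partition", "newly_rhythmic", "threshold_sweep",
           "REGIONS"]

#: Venn region labels, in fixed reporting order.
REGIONS = (
    "COSOPT_only",
    "JTK_only",
    "DFT_only",
    "COSOPT_JTK",
    "COSOPT_DFT",
    "JTK_DFT",
    "all",
    "none",
)


@dataclass
class ConsensusResult:
    probe_id: str
    cosopt_pass: bool
    jtk_pass: bool
    dft_pass: bool
    region: str
    newly_rhythmic: bool = False


def _region(c: bool, j: bool, d: bool) -> str:
    key = (c, j, d)
    return {
        (True, False, False): "COSOPT_only",
        (False, True, False): "JTK_only",
        (False, False, True): "DFT_only",
        (True, True, False): "COSOPT_JTK",
        (True, False, True): "COSOPT_DFT",
        (False, True, True): "JTK_DFT",
        (True, True, True): "all",
        (False, False, False): "none",
    }[key]


def _by_probe(calls: Sequence[RhythmCall]) -> dict[str, RhythmCall]:
    return {c.probe_id: c for c in calls}


def venn_partition(
    cosopt_calls: Sequence[RhythmCall],
    jtk_calls: Sequence[RhythmCall],
    dft_calls: Sequence[RhythmCall],
    thresholds: Thresholds | None = None,
) -> tuple[list[ConsensusResult], dict[str, int]]:
    """Partition the shared probe universe into the 7 Venn regions + none.

    All three call lists must cover exactly the same probes (the
    post-intensity-filter universe).  Pass rules: COSOPT statistic
    (mean pMMCbeta) < ``cosopt_p_max`` with ``period_ok``; JTK statistic
    (q) < ``jtk_q_max`` with ``period_ok``; DFT statistic (mean s)
    > ``dft_s_min`` (no period window: the statistic is pinned to the
    24-hr bin).
    """
    thresholds = thresholds or Thresholds()
    by = [_by_probe(c) for c in (cosopt_calls, jtk_calls, dft_calls)]
    universes = [set(b) for b in by]
    if not (universes[0] == universes[1] == universes[2]):
        sym = sorted(set.union(*universes) - set.intersection(*universes))
        raise ValueError(f"detector call sets cover different probes: {sym}")
    results = []
    counts = {r: 0 for r in REGIONS}
    for probe in sorted(universes[0]):
        c_call, j_call, d_call = (b[probe] for b in by)
        c = c_call.statistic < thresholds.cosopt_p_max and c_call.period_ok
        j = j_call.statistic < thresholds.jtk_q_max and j_call.period_ok
        d = d_call.statistic > thresholds.dft_s_min
        region = _region(c, j, d)
        counts[region] += 1
        results.append(ConsensusResult(probe, c, j, d, region))
    return results, counts


def newly_rhythmic(
    consensus: Sequence[ConsensusResult], prior_set: Iterable[str]
) -> set[str]:
    """Triple-overlap probes absent from a prior rhythmic set.

    Also marks ``newly_rhythmic`` on the consensus records in place.
    """
    prior = set(prior_set)
    new = set()
    for r in consensus:
        r.newly_rhythmic = r.region == "all" and r.probe_id not in prior
        if r.newly_rhythmic:
            new.add(r.probe_id)
    return new


def threshold_sweep(
    cosopt_calls: Sequence[RhythmCall],
    jtk_calls: Sequence[RhythmCall],
    dft_calls: Sequence[RhythmCall],
    cosopt_p_grid: Sequence[float] = (0.05, 0.1, 0.15, 0.2),
    jtk_q_grid: Sequence[float] = (0.05, 0.1),
    dft_s_grid: Sequence[float] = (0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Rhythmic-probe counts per detector per cutoff.

    Counts are monotone in cutoff laxity by construction; the table has
    columns (detector, cutoff, n_rhythmic).
    """
    rows = []
    for p_max in cosopt_p_grid:
        n = sum(1 for c in cosopt_calls if c.statistic < p_max and c.period_ok)
        rows.append({"detector": "COSOPT", "cutoff": p_max, "n_rhythmic": n})
    for q_max in jtk_q_grid:
        n = sum(1 for c in jtk_calls if c.statistic < q_max and c.period_ok)
        rows.append({"detector": "JTK", "cutoff": q_max, "n_rhythmic": n})
    for s_min in dft_s_grid:
        n = sum(1 for c in dft_calls if c.statistic > s_min)
        rows.append({"detector": "DFT", "cutoff": s_min, "n_rhythmic": n})
    return pd.DataFrame(rows)


def consensus_frame(results: Sequence[ConsensusResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "cosopt_pass": [r.cosopt_pass for r in results],
            "jtk_pass": [r.jtk_pass for r in results],
            "dft_pass": [r.dft_pass for r in results],
            "region": [r.region for r in results],
            "newly_rhythmic": [r.newly_rhythmic for r in results],
        }
    )
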