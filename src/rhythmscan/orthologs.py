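"""Two-species comparison of rhythmic gene sets via a homology map.

Species-A probes are collapsed to genes (lowest q per gene).  For every
rhythmic species-A gene, its species-B homologue is the
highest-percent-identity homologue that is itself rhythmic; if none is,
the top-identity homologue is recorded with ``rhythmic_b = False``.
Phases from both species are expressed on the absolute ZT scale before
comparison, so differently phased collection designs line up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rhythmscan.core import RhythmCall

__all__ = [
    "OrthologPair",
    "match_rhythmic_orthologs",
    "category_table",
    "phase_concordance",
]


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str | None          # None when no homologue is listed
    pct_identity: float | None
    rhythmic_a: bool
    rhythmic_b: bool
    phase_a: float | None = None
    phase_b: float | None = None

    def __post_init__(self) -> None:
        if self.pct_identity is not None and not (0 < self.pct_identity <= 100):
            raise ValueError("percent identity must be in (0, 100]")


def _gene_level(
    calls: Sequence[RhythmCall],
    gene_map: Mapping[str, str] | None,
    q_max: float,
) -> dict[str, dict]:
    """Collapse probe calls to genes, keeping the lowest-q probe per gene."""
    gene_map = gene_map or {}
    best: dict[str, RhythmCall] = {}
    for c in calls:
        gene = gene_map.get(c.probe_id, c.probe_id)
        if gene not in best or c.statistic < best[gene].statistic:
            best[gene] = c
    return {
        g: {
            "rhythmic": c.statistic < q_max and c.period_ok,
            "phase": c.peak_phase_hr,
            "q": c.statistic,
        }
        for g, c in best.items()
    }


def match_rhythmic_orthologs(
    calls_a: Sequence[RhythmCall],
    calls_b: Sequence[RhythmCall],
    homology: pd.DataFrame,
    q_max: float = 0.05,
    gene_map_a: Mapping[str, str] | None = None,
    gene_map_b: Mapping[str, str] | None = None,
) -> list[OrthologPair]:
    """Pair each rhythmic species-A gene with its best rhythmic homologue.

    ``homology`` needs columns gene_a, gene_b, pct_identity.  Identity
    ties break lexicographically by gene_b.  Genes without any listed
    homologue yield a pair with ``gene_b = None``.
    """
    for col in ("gene_a", "gene_b", "pct_identity"):
        if col not in homology.columns:
            raise ValueError(f"homology table missing column {col!r}")
    genes_a = _gene_level(calls_a, gene_map_a, q_max)
    genes_b = _gene_level(calls_b, gene_map_b, q_max)
    homs = {
        g: grp.sort_values(["pct_identity", "gene_b"], ascending=[False, True])
        for g, grp in homology.groupby("gene_a")
    }
    pairs = []
    for gene_a in sorted(genes_a):
        info_a = genes_a[gene_a]
        if not info_a["rhythmic"]:
            continue
        grp = homs.get(gene_a)
        if grp is None or grp.empty:
            pairs.append(OrthologPair(gene_a, None, None, True, False,
                                      phase_a=info_a["phase"]))
            continue
        chosen = None
        for _, row in grp.iterrows():
            info_b = genes_b.get(row.gene_b)
            if info_b is not None and info_b["rhythmic"]:
                chosen = (row, info_b)
                break
        if chosen is None:
            row = grp.iloc[0]
            info_b = genes_b.get(row.gene_b)
            pairs.append(OrthologPair(gene_a, str(row.gene_b),
                                      float(row.pct_identity), True, False,
                                      phase_a=info_a["phase"]))
        else:
            row, info_b = chosen
            pairs.append(OrthologPair(gene_a, str(row.gene_b),
                                      float(row.pct_identity), True, True,
                                      phase_a=info_a["phase"],
                                      phase_b=info_b["phase"]))
    return pairs


def category_table(
    pairs: Sequence[OrthologPair],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-category counts of rhythmic genes, homologues, rhythmic homologues.

    Genes absent from ``categories`` fall into "Unknown".  A totals row
    is appended; column inequalities (rhythmic homologues <= homologues
    <= rhythmic genes) hold per row by construction.
    """
    categories = categories or {}
    rows: dict[str, dict[str, int]] = {}
    for p in pairs:
        cat = categories.get(p.gene_a, "Unknown")
        row = rows.setdefault(cat, {"rhythmic_a": 0, "homologues": 0,
                                    "rhythmic_homologues": 0})
        row["rhythmic_a"] += 1
        if p.gene_b is not None:
            row["homologues"] += 1
            if p.rhythmic_b:
                row["rhythmic_homologues"] += 1
    records = [{"category": c, **rows[c]} for c in sorted(rows)]
    totals = {
        "category": "Totals",
        "rhythmic_a": sum(r["rhythmic_a"] for r in rows.values()),
        "homologues": sum(r["homologues"] for r in rows.values()),
        "rhythmic_homologues": sum(r["rhythmic_homologues"] for r in rows.values()),
    }
    records.append(totals)
    return pd.DataFrame(records)


def phase_concordance(pairs: Sequence[OrthologPair]) -> dict:
    """Circular summary of phase differences for doubly-rhythmic pairs.

    Per-pair difference is ``(phase_b - phase_a) mod 24`` folded to
    (-12, 12]; the summary holds the circular mean difference (same
    folding) and the resultant length (concentration in [0, 1]).
    """
    diffs = []
    for p in pairs:
        if p.rhythmic_a and p.rhythmic_b and p.phase_a is not None and p.phase_b is not None:
            d = float(np.mod(p.phase_b - p.phase_a, 24.0))
            if d > 12.0:
                d -= 24.0
            diffs.append(d)
    if not diffs:
        return {"n": 0, "differences_hr": [], "circular_mean_hr": None,
                "concentration": None}
    ang = np.asarray(diffs) / 24.0 * 2 * np.pi
    C, S = np.cos(ang).mean(), np.sin(ang).mean()
    mean = np.arctan2(S, C) / (2 * np.pi) * 24.0
    if mean > 12.0:
        mean -= 24.0
    if mean <= -12.0:
        mean += 24.0
    return {
        "n": len(diffs),
        "differences_hr": diffs,
        "circular_mean_hr": float(mean),
        "concentration": float(np.hypot(C, S)),
    }
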