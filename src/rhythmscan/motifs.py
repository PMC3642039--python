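"""IUPAC consensus-element scanning of upstream promoter regions.

Sequences are supplied with the transcription start site (TSS) at their
3' end.  Both strands are scanned with exact IUPAC-degenerate matching
(an N in the subject never matches); overlapping matches are all
reported, and palindromic matches are deduplicated per position.  Hit
coordinates are negative 1-based distances of the match's 5'-most base
upstream of the TSS.

The default element set (E boxes, W box, CRE, PERR, TER, PDP1 site) ships
as editable YAML (``data/motifs.yaml``); the non-E-box strings are
literature defaults that users should confirm against their own source.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "default_motifs",
    "load_motifs",
    "scan_region",
    "scan_fasta",
    "tabulate_hits",
    "read_fasta",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B",
    "N": "N",
}


def iupac_reverse_complement(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))


def _iupac_regex(pattern: str) -> re.Pattern:
    # N in the subject never matches: classes list concrete bases only
    parts = []
    for c in pattern.upper():
        if c not in IUPAC:
            raise ValueError(f"non-IUPAC character {c!r} in pattern {pattern!r}")
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping matches are all found
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"pattern alphabet must be IUPAC codes; got {bad}")

    def matches(self, seq: str) -> bool:
        return bool(_iupac_regex(self.pattern).match(seq.upper())
                    and len(seq) == len(self.pattern))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    start: int          # negative 1-based distance upstream of the TSS
    strand: str
    matched: str        # motif-oriented matched sequence


def default_motifs() -> list[MotifDefinition]:
    text = resources.files("rhythmscan").joinpath("data/motifs.yaml").read_text()
    return _parse_motifs(yaml.safe_load(text))


def load_motifs(path: str | Path) -> list[MotifDefinition]:
    with open(path) as fh:
        return _parse_motifs(yaml.safe_load(fh))


def _parse_motifs(doc: Mapping) -> list[MotifDefinition]:
    out = []
    for name, patterns in doc["motifs"].items():
        if isinstance(patterns, str):
            patterns = [patterns]
        for pat in patterns:
            out.append(MotifDefinition(name, pat))
    return out


def scan_region(
    sequence: str,
    motifs: Sequence[MotifDefinition],
    gene_id: str = "",
) -> list[MotifHit]:
    """Scan one upstream region (TSS at the 3' end) on both strands.

    A reverse-strand hit is reported with the motif-oriented matched
    sequence (the reverse complement of the forward-strand subsequence).
    When forward and reverse matches of the same motif coincide at a
    position (palindromes), only the forward hit is kept.
    """
    seq = sequence.upper()
    L = len(seq)
    hits: list[MotifHit] = []
    if L == 0:
        return hits
    for m in motifs:
        seen_fwd: set[int] = set()
        for match in _iupac_regex(m.pattern).finditer(seq):
            i = match.start()
            seen_fwd.add(i)
            hits.append(MotifHit(gene_id, m.name, i - L, "+", match.group(1)))
        rc = iupac_reverse_complement(m.pattern)
        for match in _iupac_regex(rc).finditer(seq):
            i = match.start()
            if i in seen_fwd:
                continue  # palindromic duplicate at the same position
            sub = match.group(1)
            rc_sub = "".join(_IUPAC_COMPLEMENT[c] for c in reversed(sub))
            hits.append(MotifHit(gene_id, m.name, i - L, "-", rc_sub))
    hits.sort(key=lambda h: (h.motif, h.start, h.strand))
    return hits


def scan_fasta(
    sequences: Mapping[str, str],
    motifs: Sequence[MotifDefinition] | None = None,
) -> list[MotifHit]:
    motifs = motifs if motifs is not None else default_motifs()
    hits = []
    for gene_id, seq in sequences.items():
        hits.extend(scan_region(seq, motifs, gene_id=gene_id))
    return hits


def tabulate_hits(
    hits: Iterable[MotifHit],
    region_lengths: Mapping[str, int],
    windows: tuple[int, ...] = (1000, 5000),
) -> pd.DataFrame:
    """Per-gene per-motif counts within each upstream window.

    A hit at upstream distance d (= |start|) is counted in window W when
    d <= W.  The available region length is recorded so truncated regions
    (< W bp) can be read with their true denominator.
    """
    rows: dict[tuple[str, str], dict] = {}
    motifs_seen: set[str] = set()
    for h in hits:
        motifs_seen.add(h.motif)
        key = (h.gene_id, h.motif)
        row = rows.setdefault(key, {f"n_within_{w}bp": 0 for w in windows})
        for w in windows:
            if -h.start <= w:
                row[f"n_within_{w}bp"] += 1
    records = []
    for gene_id, length in region_lengths.items():
        for motif in sorted(motifs_seen):
            row = rows.get((gene_id, motif), {f"n_within_{w}bp": 0 for w in windows})
            records.append(
                {"gene_id": gene_id, "motif": motif, "region_bp": length, **row}
            )
    return pd.DataFrame(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning ``{id: sequence}`` (uppercased)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs
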