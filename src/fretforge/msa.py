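"""Alignment scanning for fluorophore-insertion-permissive regions.

Cyclic-nucleotide-binding domains share a conserved eight-stranded beta-barrel,
but the loop between strands 4 and 5 is poorly conserved and carries frequent
insertions across family members — the structural argument for threading a
fluorescent module into that loop without disrupting the fold. This module
makes that argument quantitative: per-column gap fractions and Shannon
entropies over a protein multiple alignment, plus a sliding-window score that
ranks regions by how tolerant they look to insertion (gappy + variable).

The window score is a pragmatic operationalization, not a canonical
conservation statistic: score = mean gap fraction + mean residue entropy
normalized by log2(20). Class entropy over the CLUSTAL physicochemical
partition is reported alongside, since a column can be variable in residue
identity yet conserved in character.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "CLUSTAL_CLASSES",
    "Alignment",
    "ColumnProfile",
    "read_alignment",
    "column_profiles",
    "permissive_windows",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = {"-", "."}
UNKNOWN = "X"

#: CLUSTAL physicochemical classes (the coloring partition of alignment viewers).
CLUSTAL_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AILMFWV"},
    "K": "positive",
    "R": "positive",
    "D": "negative",
    "E": "negative",
    **{aa: "polar" for aa in "NQST"},
    "C": "cysteine",
    "G": "glycine",
    "P": "proline",
    "H": "aromatic",
    "Y": "aromatic",
    UNKNOWN: "unknown",
}

MAX_ENTROPY_BITS = math.log2(20)


@dataclass(frozen=True)
class Alignment:
    """A validated gapped protein alignment (>=2 equal-length rows)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        norm = []
        for rid, row in zip(self.ids, self.rows):
            up = row.upper().replace(".", "-")
            bad = set(up) - AMINO_ACIDS - {"-"} - {UNKNOWN}
            if bad:
                raise ValueError(f"sequence {rid!r} has invalid characters {sorted(bad)}")
            norm.append(up)
        object.__setattr__(self, "rows", tuple(norm))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column statistics: 1-based index, gap fraction, entropies in bits."""

    index: int
    gap_fraction: float
    entropy: float
    class_entropy: float


def read_alignment(path, fmt: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA or Clustal file (format guessed from the suffix)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "clustal" if suffix in (".aln", ".clustal", ".clw") else "fasta"
    msa = AlignIO.read(str(path), fmt)
    return Alignment(
        ids=tuple(rec.id for rec in msa),
        rows=tuple(str(rec.seq) for rec in msa),
    )


def _shannon_bits(counts: dict) -> float:
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def column_profiles(alignment: Alignment) -> list[ColumnProfile]:
    """Gap fraction and residue/class Shannon entropies for every column.

    Gaps are excluded from the entropy (insertions are what ``gap_fraction``
    measures, not a 21st residue type); an all-gap column reports entropy 0
    and gap fraction 1. Class entropy coarsens residues onto the CLUSTAL
    partition, so it can never exceed the residue entropy.
    """
    profiles = []
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        residues = [c for c in col if c not in GAP_CHARS]
        gap_fraction = 1.0 - len(residues) / len(col)
        counts: dict[str, int] = {}
        class_counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
            k = CLUSTAL_CLASSES[c]
            class_counts[k] = class_counts.get(k, 0) + 1
        profiles.append(
            ColumnProfile(
                index=j + 1,
                gap_fraction=gap_fraction,
                entropy=_shannon_bits(counts),
                class_entropy=_shannon_bits(class_counts),
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [p.index for p in profiles],
            "gap_fraction": [p.gap_fraction for p in profiles],
            "entropy_bits": [p.entropy for p in profiles],
            "class_entropy_bits": [p.class_entropy for p in profiles],
        }
    )


def permissive_windows(
    profiles: Sequence[ColumnProfile],
    window: int = 8,
    min_gap: float = 0.25,
    min_entropy: float = 0.5,
) -> list[tuple[int, int, float]]:
    """Rank sliding windows by insertion permissiveness.

    A window of ``window`` consecutive columns qualifies when its mean gap
    fraction exceeds ``min_gap`` *and* its mean residue entropy exceeds
    ``min_entropy`` bits; qualifying windows are scored by
    ``mean_gap + mean_entropy / log2(20)`` and returned as 1-based inclusive
    ``(start, end, score)`` tuples, best first, ties broken by the lower
    start index. A fully conserved, gapless alignment yields no windows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(profiles)
    if window > n:
        raise ValueError(f"window ({window}) longer than alignment ({n} columns)")
    gaps = np.array([p.gap_fraction for p in profiles])
    ents = np.array([p.entropy for p in profiles])
    kernel = np.ones(window) / window
    mean_gap = np.convolve(gaps, kernel, mode="valid")
    mean_ent = np.convolve(ents, kernel, mode="valid")
    score = mean_gap + mean_ent / MAX_ENTROPY_BITS
    out = []
    for i in range(len(score)):
        if mean_gap[i] > min_gap and mean_ent[i] > min_entropy:
            out.append((i + 1, i + window, float(score[i])))
    out.sort(key=lambda t: (-t[2], t[0]))
    return out
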