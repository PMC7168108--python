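"""Count tables, normalized per-family rates, and consensus/conservation.

The consensus of an alignment assigns each column the residue whose
frequency (gap-excluded denominator) strictly exceeds the threshold, and
``z`` where no residue does.  Positions are reported 1-based from the
first alignment column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .classify import CYS_RICH, ScreenResult

#: Output column order of the per-transcriptome count table.
COUNT_COLUMNS = (
    "Defensins",
    "Thionins",
    "Cyclotides",
    "Snakins",
    "Hevein-like",
    "LTP",
    "Cysteine-rich",
    "Unknown",
)

_FAMILY_TO_COLUMN = {
    "defensins": "Defensins",
    "thionins": "Thionins",
    "cyclotides": "Cyclotides",
    "snakins": "Snakins",
    "hevein-like": "Hevein-like",
    "lipid-transfer": "LTP",
    CYS_RICH: "Cysteine-rich",
    "unknown": "Unknown",
}

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-column residue frequencies and the derived consensus string."""

    columns: tuple[Mapping[str, float], ...]
    consensus: str
    threshold: float

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.columns):
            raise ValueError("consensus length must equal column count")


@dataclass(frozen=True)
class ConservationSummary:
    """Counts of conserved columns of a profile (positions 1-based)."""

    fully_conserved_positions: tuple[int, ...]  # non-C residues at frequency 1.0
    n_above_threshold: int
    fraction_of_length: float


def family_count_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """One row per transcriptome plus a totals row, fixed column order."""
    if not results:
        raise ValueError("at least one screen result is required")
    rows = {}
    for res in results:
        row = {col: 0 for col in COUNT_COLUMNS}
        for family, count in res.counts.items():
            col = _FAMILY_TO_COLUMN.get(family)
            if col is not None:
                row[col] += count
        rows[res.transcriptome_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(COUNT_COLUMNS))
    df.loc["Total"] = df.sum(axis=0)
    df.index.name = "transcriptome"
    return df


def normalized_family_counts(
    results: Sequence[ScreenResult],
    family_metadata: Mapping[str, str],
    min_samples: int = 5,
) -> pd.DataFrame:
    """Per plant family: motif counts divided by member transcriptome count.

    Plant families with fewer than *min_samples* transcriptomes are
    excluded.  Every transcriptome must appear in the metadata.
    """
    missing = sorted(
        res.transcriptome_id for res in results if res.transcriptome_id not in family_metadata
    )
    if missing:
        raise KeyError(f"transcriptomes missing from metadata: {', '.join(missing)}")
    groups: dict[str, list[ScreenResult]] = {}
    for res in results:
        groups.setdefault(family_metadata[res.transcriptome_id], []).append(res)
    rows = {}
    for plant_family, members in sorted(groups.items()):
        if len(members) < min_samples:
            continue
        row = {col: 0.0 for col in COUNT_COLUMNS}
        for res in members:
            for family, count in res.counts.items():
                col = _FAMILY_TO_COLUMN.get(family)
                if col is not None:
                    row[col] += count
        for col in COUNT_COLUMNS:
            row[col] /= len(members)
        row["n_transcriptomes"] = len(members)
        rows[plant_family] = row
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(COUNT_COLUMNS) + ["n_transcriptomes"]
    )
    df.index.name = "plant_family"
    return df


def read_alignment_fasta(path: str | Path) -> list[str]:
    """Aligned amino-acid sequences from FASTA; lengths must agree."""
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences in alignment {path}")
    return seqs


def consensus_from_alignment(
    aligned_sequences: Sequence[str], threshold: float = 0.7
) -> ConsensusProfile:
    """Column-wise consensus with 'z' at positions below the threshold.

    Gap characters are excluded from each column's denominator; a column
    of only gaps is a 'z'.  The winning residue's frequency must be
    strictly greater than *threshold*.
    """
    if len(aligned_sequences) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    length = len(aligned_sequences[0])
    for i, seq in enumerate(aligned_sequences):
        if len(seq) != length:
            raise ValueError(
                f"ragged alignment: sequence {i} has length {len(seq)}, expected {length}"
            )
    columns: list[dict[str, float]] = []
    consensus_chars: list[str] = []
    for j in range(length):
        counts: dict[str, int] = {}
        for seq in aligned_sequences:
            ch = seq[j].upper()
            if ch in GAP_CHARS:
                continue
            counts[ch] = counts.get(ch, 0) + 1
        denom = sum(counts.values())
        freqs = {ch: c / denom for ch, c in counts.items()} if denom else {}
        columns.append(freqs)
        letter = "z"
        if freqs:
            top = max(sorted(freqs), key=freqs.get)
            if freqs[top] > threshold:
                letter = top
        consensus_chars.append(letter)
    return ConsensusProfile(tuple(columns), "".join(consensus_chars), threshold)


def conservation_summary(profile: ConsensusProfile) -> ConservationSummary:
    """Fully-conserved non-cysteine positions and above-threshold counts."""
    fully: list[int] = []
    above = 0
    for j, (freqs, letter) in enumerate(zip(profile.columns, profile.consensus)):
        if letter != "z":
            above += 1
        for ch, f in freqs.items():
            if ch != "C" and f == 1.0:
                fully.append(j + 1)  # 1-based
                break
    n = len(profile.columns)
    fraction = above / n if n else 0.0
    return ConservationSummary(tuple(fully), above, fraction)
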