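"""Transcriptome reading, six-frame translation and ORF extraction.

Coordinates are 0-based half-open on the *forward* strand of the source
contig regardless of frame sign.  Frames are labelled +1/+2/+3 (forward
strand, offset 0/1/2) and -1/-2/-3 (reverse complement, offset 0/1/2 on
the reverse-complemented sequence).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

FRAMES = (1, 2, 3, -1, -2, -3)

# IUPAC nucleotide ambiguity codes (post U->T normalization).
_IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


class FastaError(ValueError):
    """Malformed or unusable FASTA input."""


@dataclass(frozen=True)
class NucleotideRecord:
    """One contig: id, normalized sequence (U->T, uppercase), description."""

    seq_id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class OrfCandidate:
    """A Met-initiated open reading frame.

    ``aa_sequence`` starts with M and never contains the stop symbol;
    ``nt_start``/``nt_end`` are 0-based half-open forward-strand
    coordinates covering the codons (and the stop codon when
    ``has_stop``).
    """

    seq_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    has_stop: bool

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if not self.aa_sequence or self.aa_sequence[0] != "M":
            raise ValueError("ORF must start with methionine")
        if "*" in self.aa_sequence:
            raise ValueError("stop symbol inside ORF")
        expect = 3 * len(self.aa_sequence) + (3 if self.has_stop else 0)
        if self.nt_end - self.nt_start != expect:
            raise ValueError("ORF coordinates inconsistent with length")


def _normalize_nt(raw: str, seq_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in _IUPAC_NT:
            raise FastaError(
                f"record {seq_id!r}: non-IUPAC nucleotide {ch!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path) -> list[NucleotideRecord]:
    """Read a nucleotide FASTA into records, validating ids and alphabet."""
    records: list[NucleotideRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_nt(str(rec.seq), rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(NucleotideRecord(rec.id, seq, desc))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FastaError(f"duplicate sequence ids: {', '.join(dups)}")
    return records


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement (delegates to Biopython)."""
    return str(Seq(sequence).reverse_complement())


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    aa = _FORWARD.get(codon)
    if aa is not None:
        return aa
    # ambiguous codon: translate every resolution; agree or 'X'
    try:
        resolutions = {
            ("*" if "".join(c) in _STOPS else _FORWARD["".join(c)])
            for c in itertools.product(*(_IUPAC_NT[b] for b in codon))
        }
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide in codon {codon!r}") from exc
    return resolutions.pop() if len(resolutions) == 1 else "X"


def translate_frame(sequence: str, frame: int) -> str:
    """Translate one reading frame with the standard genetic code.

    Stops are emitted as ``*``; a trailing partial codon is dropped; any
    codon whose IUPAC resolutions disagree translates to ``X``.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame}")
    seq = sequence.upper().replace("U", "T")
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    aas = []
    for i in range(offset, len(seq) - 2, 3):
        aas.append(_translate_codon(seq[i : i + 3]))
    return "".join(aas)


def extract_orfs(
    record: NucleotideRecord,
    min_aa: int = 1,
    max_aa: int = 10**9,
    require_stop: bool = True,
    all_starts: bool = False,
) -> list[OrfCandidate]:
    """Six-frame ORF extraction.

    Each stop-bounded segment of each frame yields one ORF from its first
    in-frame ATG (the longest candidate); with ``all_starts`` every
    in-frame ATG of the segment yields an ORF.  ORFs outside
    ``[min_aa, max_aa]`` amino acids are discarded; with ``require_stop``
    unterminated trailing ORFs are discarded.
    """
    if min_aa < 1 or max_aa < min_aa:
        raise ValueError("require 1 <= min_aa <= max_aa")
    seq = record.sequence
    L = len(seq)
    out: list[OrfCandidate] = []
    for frame in FRAMES:
        aa = translate_frame(seq, frame)
        offset = abs(frame) - 1
        # stop-bounded segments [s, e) in aa coordinates
        s = 0
        for e, ch in enumerate(aa + "*"):
            if ch != "*":
                continue
            has_stop = e < len(aa)
            if require_stop and not has_stop:
                s = e + 1
                continue
            starts = [i for i in range(s, e) if aa[i] == "M"]
            if not all_starts:
                starts = starts[:1]
            for m in starts:
                aa_seq = aa[m:e]
                if not (min_aa <= len(aa_seq) <= max_aa):
                    continue
                w_start = offset + 3 * m
                w_end = offset + 3 * e + (3 if has_stop else 0)
                if frame > 0:
                    nt_start, nt_end = w_start, w_end
                else:
                    nt_start, nt_end = L - w_end, L - w_start
                out.append(
                    OrfCandidate(record.seq_id, frame, nt_start, nt_end, aa_seq, has_stop)
                )
            s = e + 1
    return out


def orf_nucleotides(record: NucleotideRecord, orf: OrfCandidate) -> str:
    """The coding nucleotides of an ORF in reading orientation."""
    chunk = record.sequence[orf.nt_start : orf.nt_end]
    return chunk if orf.frame > 0 else reverse_complement(chunk)


def write_orf_fasta(path: str | Path, orfs: Iterable[OrfCandidate], header_lines: Iterable[str] = ()) -> None:
    """Dump ORFs as amino-acid FASTA, header ``<seq_id>|<frame>|<start>-<end>``."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f";{line}\n")
        for orf in orfs:
            sign = "+" if orf.frame > 0 else ""
            fh.write(f">{orf.seq_id}|{sign}{orf.frame}|{orf.nt_start}-{orf.nt_end}\n")
            fh.write(orf.aa_sequence + "\n")
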