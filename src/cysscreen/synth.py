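"""Synthetic transcriptomes with planted, ground-truthed peptide genes.

Planted precursors are built to pass every default filter: a synthetic
signal peptide satisfying the built-in heuristic (charged n-region,
hydrophobic h-region from L/I/F, A-x-A cleavage), a mature core realized
from a motif, reverse-translated with uniform synonymous codons, framed
by an in-frame upstream stop (so the ORF start is unambiguous) and a
stop codon, embedded in random UTR context on a random strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .classify import MotifDB, load_motif_db, scan_motifs, _specificity_key
from .filters import predict_signal_peptide
from .motifs import CYS, GapSpec, Motif
from .orfs import NucleotideRecord, reverse_complement, _FORWARD

#: Non-cysteine residues used to fill motif gaps.
NON_CYS_AA = "ADEFGHIKLMNPQRSTVWY"

_STOP_CODONS = ("TAA", "TAG", "TGA")

# inverse codon table: aa -> tuple of codons
_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(_FORWARD.items()):
    _CODONS.setdefault(aa, ())
    _CODONS[aa] += (codon,)

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one planted precursor gene."""

    contig_id: str
    motif_id: str
    family: str
    strand: str  # '+' or '-'
    frame: int
    nt_start: int
    nt_end: int
    cleavage_pos: int
    precursor: str
    mature: str


@dataclass
class FixtureManifest:
    seed: int
    n_decoys: int
    genes: list[PlantedGene] = field(default_factory=list)


def sample_motif_realization(motif: Motif, seed: RngLike = 0) -> str:
    """A string matching *motif* exactly: C anchors, random non-C gaps."""
    rng = _rng(seed)
    parts: list[str] = []
    for el in motif.elements:
        if el == CYS:
            parts.append("C")
        else:
            k = int(rng.integers(el.min_len, el.max_len + 1))
            parts.append("".join(rng.choice(list(NON_CYS_AA), size=k)))
    return "".join(parts)


def build_precursor(mature_core: str, seed: RngLike = 0, max_len: int = 150) -> str:
    """Prefix *mature_core* with a signal peptide the heuristic accepts.

    The constructed signal is M + two basic residues + 9-12 hydrophobic
    residues from {L, I, F} (none in the small-residue set, so no early
    cleavage) + A-x-A.  Total precursor length is strictly below
    *max_len*.
    """
    if not mature_core:
        raise ValueError("mature core must be non-empty")
    rng = _rng(seed)
    n_region = "".join(rng.choice(["K", "R"], size=2))
    h_len = int(rng.integers(9, 13))
    h_region = "".join(rng.choice(list("LIF"), size=h_len))
    x = str(rng.choice(list("QNED")))
    signal = "M" + n_region + h_region + "A" + x + "A"
    precursor = signal + mature_core
    if len(precursor) >= max_len:
        raise ValueError(
            f"mature core of {len(mature_core)} aa cannot fit under the "
            f"{max_len}-residue limit with a {len(signal)}-residue signal"
        )
    pred = predict_signal_peptide(precursor)
    assert pred.is_positive and pred.cleavage_pos == len(signal), "signal construction invariant"
    return precursor


def reverse_translate(aa_sequence: str, seed: RngLike = 0) -> str:
    """Uniform synonymous codon choice; no stop codon appended."""
    rng = _rng(seed)
    codons = []
    for aa in aa_sequence:
        options = _CODONS.get(aa)
        if not options:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(str(rng.choice(options)))
    return "".join(codons)


def _best_family(realization: str, db: MotifDB) -> Optional[str]:
    hits = scan_motifs(db, realization)
    if not hits:
        return None
    best = min({mid for mid, _ in hits}, key=lambda mid: _specificity_key(db, mid))
    return db.get(best).family


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_transcriptome(
    n_planted_per_family: Union[int, Mapping[str, int]] = 2,
    n_decoys: int = 20,
    seed: int = 0,
    db: Optional[MotifDB] = None,
    utr_range: tuple[int, int] = (20, 200),
    decoy_length_range: tuple[int, int] = (150, 600),
) -> tuple[list[NucleotideRecord], FixtureManifest]:
    """Build a synthetic transcriptome with planted genes plus random decoys.

    Each planted gene's realization is re-sampled (bounded retries) until
    the most-specific-motif rule assigns it the expected family, so the
    manifest's family labels are guaranteed ground truth.
    """
    if db is None:
        db = load_motif_db()
    rng = np.random.default_rng(seed)
    families = [f for f in db.family_order if any(m.family == f for m in db.motifs)]
    if isinstance(n_planted_per_family, int):
        plan = {fam: n_planted_per_family for fam in families}
    else:
        plan = dict(n_planted_per_family)
    records: list[NucleotideRecord] = []
    manifest = FixtureManifest(seed=seed, n_decoys=n_decoys)
    gene_no = 0
    for family in families:
        family_motifs = [m for m in db.motifs if m.family == family]
        for i in range(plan.get(family, 0)):
            motif = family_motifs[i % len(family_motifs)]
            realization = None
            for _ in range(100):
                cand = sample_motif_realization(motif, rng)
                if _best_family(cand, db) == family:
                    realization = cand
                    break
            if realization is None:  # pragma: no cover - pathological DB
                raise RuntimeError(
                    f"could not realize motif {motif.motif_id} into family {family}"
                )
            precursor = build_precursor(realization, rng)
            cleavage = len(precursor) - len(realization)
            cds = reverse_translate(precursor, rng) + str(rng.choice(_STOP_CODONS))
            utr5 = _random_nt(rng, int(rng.integers(*utr_range))) + "TAA"
            utr3 = _random_nt(rng, int(rng.integers(*utr_range)))
            plus = utr5 + cds + utr3
            nt_start, nt_end = len(utr5), len(utr5) + len(cds)
            strand = "+" if rng.integers(2) == 0 else "-"
            if strand == "+":
                contig = plus
                frame = nt_start % 3 + 1
            else:
                contig = reverse_complement(plus)
                L = len(contig)
                nt_start, nt_end = L - nt_end, L - nt_start
                frame = -((L - nt_end) % 3 + 1)
            gene_no += 1
            contig_id = f"planted{gene_no:03d}_{motif.motif_id}"
            records.append(NucleotideRecord(contig_id, contig))
            manifest.genes.append(
                PlantedGene(
                    contig_id=contig_id,
                    motif_id=motif.motif_id,
                    family=family,
                    strand=strand,
                    frame=frame,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    cleavage_pos=cleavage,
                    precursor=precursor,
                    mature=realization,
                )
            )
    for i in range(n_decoys):
        length = int(rng.integers(*decoy_length_range))
        records.append(NucleotideRecord(f"decoy{i + 1:04d}", _random_nt(rng, length)))
    return records, manifest


def write_fixture_fasta(path: str | Path, records: Iterable[NucleotideRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n{rec.sequence}\n")


def write_manifest_tsv(path: str | Path, manifest: FixtureManifest) -> None:
    cols = (
        "contig_id", "motif_id", "family", "strand", "frame",
        "nt_start", "nt_end", "cleavage_pos", "precursor", "mature",
    )
    with open(path, "w") as fh:
        fh.write(f"# seed={manifest.seed} n_decoys={manifest.n_decoys}\n")
        fh.write("\t".join(cols) + "\n")
        for g in manifest.genes:
            fh.write("\t".join(str(getattr(g, c)) for c in cols) + "\n")
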