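"""Motif database, family assignment and whole-transcriptome screening.

Family assignment uses a most-specific-motif-first rule: among the
qualifying hits the motif with the smallest span range (max_span -
min_span) wins; ties break by the database's family precedence order,
then motif id.  Peptides that pass length and signal filtering but match
no family motif fall into the artificial cysteine-rich group when their
mature region carries at least ``min_cys`` cysteines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .config import PipelineConfig
from .filters import (
    PeptideCandidate,
    Predictor,
    Rejection,
    apply_filters,
    predict_signal_peptide,
)
from .motifs import FAMILIES, MatchSpan, Motif, MotifSyntaxError, find_matches, parse_motif, span_bounds
from .orfs import NucleotideRecord, extract_orfs

#: Artificial group label for cysteine-rich peptides matching no family motif.
CYS_RICH = "cysteine-rich"

#: Default family precedence (roughly increasing motif looseness).
DEFAULT_FAMILY_ORDER = (
    "cyclotides",
    "defensins",
    "hevein-like",
    "thionins",
    "lipid-transfer",
    "snakins",
    "unknown",
)


class MotifDBError(ValueError):
    """Malformed motif database file."""


@dataclass(frozen=True)
class MotifDB:
    motifs: tuple[Motif, ...]
    family_order: tuple[str, ...] = DEFAULT_FAMILY_ORDER

    def __post_init__(self) -> None:
        if not self.motifs:
            raise MotifDBError("motif database must contain at least one motif")
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise MotifDBError(f"duplicate motif ids: {', '.join(dups)}")
        for m in self.motifs:
            if m.family not in self.family_order:
                raise MotifDBError(
                    f"motif {m.motif_id}: family {m.family!r} not in family order"
                )

    def __iter__(self):
        return iter(self.motifs)

    def get(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


@dataclass(frozen=True)
class Classification:
    """Family assignment for one peptide, with the winning motif."""

    family: str
    motif_id: Optional[str]
    qualifying_hits: tuple[tuple[str, MatchSpan], ...]


@dataclass
class ScreenResult:
    """Per-transcriptome outcome of the full screen."""

    transcriptome_id: str
    classified: list[tuple[PeptideCandidate, Classification]] = field(default_factory=list)
    cys_rich: list[PeptideCandidate] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def total_retained(self) -> int:
        return len(self.classified) + len(self.cys_rich)


def _parse_db_lines(lines: Iterable[str], source: str) -> list[Motif]:
    motifs: list[Motif] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise MotifDBError(
                f"{source}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        motif_id, family, pattern = (p.strip() for p in parts)
        try:
            motifs.append(parse_motif(pattern, motif_id=motif_id, family=family))
        except (MotifSyntaxError, ValueError) as exc:
            raise MotifDBError(f"{source}:{lineno}: {exc}") from exc
    return motifs


def load_motif_db(path: Optional[str | Path] = None) -> MotifDB:
    """Load a motif database file, or the shipped default when *path* is None."""
    if path is None:
        text = resources.files("cysscreen.data").joinpath("motifs.tsv").read_text()
        return MotifDB(tuple(_parse_db_lines(text.splitlines(), "builtin")))
    lines = Path(path).read_text().splitlines()
    return MotifDB(tuple(_parse_db_lines(lines, str(path))))


def cys_rich_criterion(mature_sequence: str, min_cys: int = 4) -> bool:
    """True iff the mature sequence carries at least *min_cys* cysteines."""
    if not mature_sequence:
        raise ValueError("empty mature sequence")
    return mature_sequence.upper().count("C") >= min_cys


def scan_motifs(db: MotifDB, aa_sequence: str) -> list[tuple[str, MatchSpan]]:
    """All motif hits on a precursor, in database order then position."""
    hits: list[tuple[str, MatchSpan]] = []
    for motif in db.motifs:
        for span in find_matches(motif, aa_sequence):
            hits.append((motif.motif_id, span))
    return hits


def _specificity_key(db: MotifDB, motif_id: str) -> tuple:
    motif = db.get(motif_id)
    lo, hi = span_bounds(motif)
    return (hi - lo, db.family_order.index(motif.family), motif_id)


def classify_peptide(
    candidate: PeptideCandidate,
    db: MotifDB,
    mature_rule: bool = True,
    min_cys: int = 4,
) -> Classification:
    """Assign a family to a filtered peptide.

    With at least one qualifying motif hit, the most specific motif's
    family is assigned; with none, the peptide goes to the artificial
    cysteine-rich group if :func:`cys_rich_criterion` holds.
    """
    if mature_rule:
        qualifying = tuple(
            h for h in candidate.motif_hits if h[1].start >= candidate.signal.cleavage_pos
        )
    else:
        qualifying = tuple(candidate.motif_hits)
    if qualifying:
        best = min({mid for mid, _ in qualifying}, key=lambda mid: _specificity_key(db, mid))
        return Classification(db.get(best).family, best, qualifying)
    if cys_rich_criterion(candidate.mature_sequence, min_cys):
        return Classification(CYS_RICH, None, ())
    return Classification("unclassified", None, ())


def _empty_counts(db: MotifDB) -> dict[str, int]:
    counts = {fam: 0 for fam in db.family_order}
    counts[CYS_RICH] = 0
    return counts


def screen_transcriptome(
    records: Sequence[NucleotideRecord],
    db: MotifDB,
    config: PipelineConfig = PipelineConfig(),
    predictor: Predictor = predict_signal_peptide,
    transcriptome_id: str = "transcriptome",
) -> ScreenResult:
    """Run the full screen: ORFs -> motif scan -> filters -> classification.

    Deterministic given config and input.  ORFs from one contig yielding
    identical mature peptides are collapsed to the lowest ``nt_start``.
    """
    result = ScreenResult(transcriptome_id=transcriptome_id, counts=_empty_counts(db))
    for record in records:
        orfs = extract_orfs(
            record,
            min_aa=1,
            require_stop=config.require_stop,
            all_starts=config.all_starts,
        )
        retained: list[tuple[PeptideCandidate, Classification]] = []
        for orf in orfs:
            hits = scan_motifs(db, orf.aa_sequence)
            outcome = apply_filters(
                orf,
                hits,
                limit=config.length_limit,
                predictor=predictor,
                mature_rule=config.mature_region_rule,
            )
            if isinstance(outcome, Rejection):
                if outcome.reason == "no_motif":
                    # length+signal passed; cysteine-rich fallback group
                    mature = orf.aa_sequence[outcome.signal.cleavage_pos :]
                    if mature and cys_rich_criterion(mature, config.min_cys):
                        cand = PeptideCandidate(orf, outcome.signal, mature, ())
                        retained.append((cand, Classification(CYS_RICH, None, ())))
                        continue
                result.rejections.append(outcome)
                continue
            cls = classify_peptide(
                outcome, db, mature_rule=config.mature_region_rule, min_cys=config.min_cys
            )
            if cls.family == "unclassified":
                result.rejections.append(Rejection(orf, "no_motif", outcome.signal))
                continue
            retained.append((outcome, cls))
        # per-contig de-duplication on identical mature peptides
        best: dict[str, tuple[PeptideCandidate, Classification]] = {}
        for cand, cls in retained:
            key = cand.mature_sequence
            if key not in best or cand.orf.nt_start < best[key][0].orf.nt_start:
                best[key] = (cand, cls)
        for cand, cls in sorted(
            best.values(), key=lambda t: (t[0].orf.nt_start, t[0].orf.frame)
        ):
            if cls.family == CYS_RICH:
                result.cys_rich.append(cand)
            else:
                result.classified.append((cand, cls))
            result.counts[cls.family] += 1
    return result


def write_classified_fasta(
    path: str | Path, result: ScreenResult, header_lines: Iterable[str] = ()
) -> None:
    """Classified peptides as amino-acid FASTA.

    Header: ``<seq_id>|<family>|<motif_id>|<frame>|<nt_start>-<nt_end>``.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f";{line}\n")
        entries = [(c, cls) for c, cls in result.classified]
        entries += [(c, Classification(CYS_RICH, None, ())) for c in result.cys_rich]
        for cand, cls in entries:
            orf = cand.orf
            sign = "+" if orf.frame > 0 else ""
            motif = cls.motif_id or "-"
            fh.write(
                f">{orf.seq_id}|{cls.family}|{motif}|{sign}{orf.frame}|"
                f"{orf.nt_start}-{orf.nt_end}\n"
            )
            fh.write(cand.orf.aa_sequence + "\n")
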