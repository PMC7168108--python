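"""False-positive calibration on random sequences.

Two modes: amino-acid sequences fed directly to the matcher, or random
nucleotide contigs fed through the entire screen (translation, ORF
extraction, filtering, classification).  Hit fractions carry Wilson 95%
confidence intervals; an exhaustive enumeration oracle provides exact
match probabilities in the small-alphabet regime.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .classify import MotifDB, screen_transcriptome
from .config import PipelineConfig
from .motifs import Motif, matches_anywhere, span_bounds
from .orfs import NucleotideRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

_ENUM_LIMIT = 2_000_000  # max sequences enumerated by the analytic oracle


@dataclass(frozen=True)
class NullConfig:
    """Random-sequence generation parameters."""

    n_sequences: int
    seq_length: int
    alphabet_mode: str = "nucleotide"
    composition: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        if self.alphabet_mode not in ("nucleotide", "amino_acid"):
            raise ValueError("alphabet_mode must be 'nucleotide' or 'amino_acid'")
        if self.composition is not None:
            freqs = list(self.composition.values())
            if any(f < 0 for f in freqs):
                raise ValueError("composition frequencies must be non-negative")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError("composition must sum to 1")

    @property
    def alphabet(self) -> str:
        if self.composition is not None:
            return "".join(self.composition)
        return NT_ALPHABET if self.alphabet_mode == "nucleotide" else AA_ALPHABET

    @property
    def frequencies(self) -> np.ndarray:
        if self.composition is not None:
            return np.array(list(self.composition.values()), dtype=float)
        n = len(self.alphabet)
        return np.full(n, 1.0 / n)


@dataclass(frozen=True)
class FprEstimate:
    """Per-motif hit fraction on random sequences with Wilson 95% CI."""

    motif_id: str
    hit_fraction: float
    ci_low: float
    ci_high: float
    n: int
    hits: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hit_fraction <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def random_sequences(config: NullConfig) -> list[str]:
    """i.i.d. sequences drawn from the configured composition, seeded."""
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(config.alphabet))
    draws = rng.choice(
        letters, size=(config.n_sequences, config.seq_length), p=config.frequencies
    )
    return ["".join(row) for row in draws]


def wilson_interval(hits: int, n: int) -> tuple[float, float]:
    """Wilson 95% interval for a binomial proportion."""
    lo, hi = proportion_confint(hits, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def estimate_fpr(
    db: MotifDB,
    config: NullConfig,
    pipeline_mode: Optional[bool] = None,
    pipeline_config: PipelineConfig = PipelineConfig(),
) -> list[FprEstimate]:
    """Per-motif fraction of random sequences producing a hit.

    In amino-acid mode a hit is any motif match on the sequence; in
    pipeline mode (default for nucleotide sequences) a hit is a retained,
    classified peptide from that contig whose qualifying hits include the
    motif.
    """
    if pipeline_mode is None:
        pipeline_mode = config.alphabet_mode == "nucleotide"
    seqs = random_sequences(config)
    hit_counts = {m.motif_id: 0 for m in db.motifs}
    if pipeline_mode:
        if config.alphabet_mode != "nucleotide":
            raise ValueError("pipeline mode requires nucleotide sequences")
        for i, seq in enumerate(seqs):
            rec = NucleotideRecord(f"rnd{i}", seq)
            res = screen_transcriptome([rec], db, pipeline_config)
            seen = {
                mid
                for _, cls in res.classified
                for mid, _ in cls.qualifying_hits
            }
            for mid in seen:
                hit_counts[mid] += 1
    else:
        for seq in seqs:
            for motif in db.motifs:
                if matches_anywhere(motif, seq):
                    hit_counts[motif.motif_id] += 1
    out = []
    n = config.n_sequences
    for motif in db.motifs:
        hits = hit_counts[motif.motif_id]
        lo, hi = wilson_interval(hits, n)
        out.append(FprEstimate(motif.motif_id, hits / n, lo, hi, n, hits))
    return out


def analytic_match_prob(
    motif: Motif, composition: Mapping[str, float], seq_length: int
) -> float:
    """Exact P(>= 1 match) by exhaustive weighted enumeration.

    Restricted to the small regime (alphabet <= 4, length <= 20, and at
    most ~2e6 sequences); outside it, use :func:`estimate_fpr`.
    """
    letters = list(composition)
    if len(letters) > 4 or seq_length > 20:
        raise ValueError(
            "analytic regime is alphabet <= 4 and length <= 20; use estimate_fpr"
        )
    if len(letters) ** seq_length > _ENUM_LIMIT:
        raise ValueError("enumeration too large; use estimate_fpr")
    freqs = list(composition.values())
    if abs(sum(freqs) - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    lo, _ = span_bounds(motif)
    if lo > seq_length:
        return 0.0
    total = 0.0
    for combo in itertools.product(range(len(letters)), repeat=seq_length):
        seq = "".join(letters[i] for i in combo)
        if matches_anywhere(motif, seq):
            weight = math.prod(freqs[i] for i in combo)
            total += weight
    return total


def composition_from_records(records: Sequence[NucleotideRecord]) -> dict[str, float]:
    """Mono-nucleotide frequencies of a transcriptome (ACGT only; N skipped)."""
    counts = {c: 0 for c in NT_ALPHABET}
    for rec in records:
        for c in rec.sequence:
            if c in counts:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous nucleotides in input")
    return {c: counts[c] / total for c in NT_ALPHABET}
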