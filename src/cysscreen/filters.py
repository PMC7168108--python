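"""Filtration cascade: length limit, signal peptide, mature-region motif.

The signal-peptide predictor is pluggable; the built-in heuristic is a
transparent (-3,-1)-rule test:

* n-region: net charge of residues 2-6 (K/R = +1, D/E = -1) >= 0;
* h-region: best window of 8 within residues 5-25 has mean
  Kyte-Doolittle hydrophobicity >= 1.6;
* cleavage: the first position p in [12, 40] whose -3 and -1 residues
  (1-based) are both small (A, G, S, C, T, V); the first mature residue
  is p, i.e. ``cleavage_pos = p - 1`` (0-based).

All thresholds are keyword-configurable.  Any callable returning a
:class:`SignalPrediction` can replace the built-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

from .motifs import MatchSpan
from .orfs import OrfCandidate

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Small residues admissible at the -3 and -1 positions of a cleavage site.
SMALL_RESIDUES = frozenset("AGSCTV")

REJECTION_REASONS = ("too_long", "no_signal", "motif_in_signal", "no_motif")


@dataclass(frozen=True)
class SignalPrediction:
    """Outcome of a signal-peptide predictor.

    ``cleavage_pos`` is the 0-based index of the first mature residue and
    is meaningful only when ``is_positive``.
    """

    is_positive: bool
    cleavage_pos: int = -1
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.is_positive and not (5 <= self.cleavage_pos <= 40):
            raise ValueError(
                f"implausible cleavage position {self.cleavage_pos} for a positive call"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


Predictor = Callable[[str], SignalPrediction]


@dataclass(frozen=True)
class PeptideCandidate:
    """An ORF that passed filtering, with its mature region and motif hits."""

    orf: OrfCandidate
    signal: SignalPrediction
    mature_sequence: str
    motif_hits: tuple[tuple[str, MatchSpan], ...]

    def __post_init__(self) -> None:
        if not self.signal.is_positive:
            raise ValueError("retained candidate must have a positive signal call")
        if self.mature_sequence != self.orf.aa_sequence[self.signal.cleavage_pos :]:
            raise ValueError("mature_sequence must be the post-cleavage suffix")


@dataclass(frozen=True)
class Rejection:
    """A filtered-out ORF with the (first) reason that disqualified it."""

    orf: OrfCandidate
    reason: str
    signal: Optional[SignalPrediction] = None

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


def check_length(orf: OrfCandidate, limit: int) -> bool:
    """True iff the precursor is strictly shorter than *limit* residues."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    return len(orf.aa_sequence) < limit


def predict_signal_peptide(
    aa_sequence: str,
    *,
    min_charge: float = 0.0,
    min_hydrophobicity: float = 1.6,
    h_window: int = 8,
    cleavage_range: tuple[int, int] = (12, 40),
) -> SignalPrediction:
    """Built-in heuristic signal-peptide call (see module docstring).

    Sequences shorter than 15 residues are negative, not an error.
    """
    seq = aa_sequence.upper()
    if len(seq) < 15:
        return SignalPrediction(False)

    charge = sum(
        1 if c in "KR" else -1 if c in "DE" else 0 for c in seq[1:6]
    )

    region = seq[4:25]
    h_max = -math.inf
    for i in range(len(region) - h_window + 1):
        window = region[i : i + h_window]
        h_max = max(
            h_max,
            sum(KYTE_DOOLITTLE.get(c, 0.0) for c in window) / h_window,
        )
    score = 1.0 / (1.0 + math.exp(-h_max)) if math.isfinite(h_max) else 0.0

    lo, hi = cleavage_range
    cleavage = None
    for p in range(lo, min(hi, len(seq)) + 1):
        if seq[p - 4] in SMALL_RESIDUES and seq[p - 2] in SMALL_RESIDUES:
            cleavage = p - 1  # 0-based first mature residue
            break

    positive = charge >= min_charge and h_max >= min_hydrophobicity and cleavage is not None
    if not positive:
        return SignalPrediction(False, score=score)
    return SignalPrediction(True, cleavage_pos=cleavage, score=score)


def apply_filters(
    orf: OrfCandidate,
    motif_hits: Sequence[tuple[str, MatchSpan]],
    limit: int = 150,
    predictor: Predictor = predict_signal_peptide,
    mature_rule: bool = True,
) -> Union[PeptideCandidate, Rejection]:
    """Run the filtration cascade on one ORF.

    Retained iff the precursor is shorter than *limit*, the predictor is
    positive, and at least one motif hit starts at or after the cleavage
    point (when ``mature_rule``; otherwise any hit qualifies).  The
    retained set is order-independent; the rejection reason reports the
    first failing predicate in the order too_long, no_signal, no_motif,
    motif_in_signal.
    """
    if not check_length(orf, limit):
        return Rejection(orf, "too_long")
    signal = predictor(orf.aa_sequence)
    if not signal.is_positive:
        return Rejection(orf, "no_signal", signal)
    if not motif_hits:
        return Rejection(orf, "no_motif", signal)
    if mature_rule:
        qualifying = [h for h in motif_hits if h[1].start >= signal.cleavage_pos]
    else:
        qualifying = list(motif_hits)
    if not qualifying:
        return Rejection(orf, "motif_in_signal", signal)
    return PeptideCandidate(
        orf=orf,
        signal=signal,
        mature_sequence=orf.aa_sequence[signal.cleavage_pos :],
        motif_hits=tuple(motif_hits),
    )
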