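"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation paths they verify: motif
matching is done by recursive enumeration of gap-length assignments, and
ORF discovery by walking every codon offset on both strands.
"""

from __future__ import annotations

import itertools

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# minimal standard-code codon table for the oracle (independent of Biopython)
_CODON = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    _CODON[_b1 + _b2 + _b3] = _AA[_i]


def oracle_match_spans(elements, seq):
    """All (start, end) spans matching a motif element list, by backtracking.

    ``elements`` uses 'C' for anchors and (min, max) tuples for gaps.
    """
    spans = set()
    n = len(seq)

    def walk(ei, pos, start):
        if ei == len(elements):
            spans.add((start, pos))
            return
        el = elements[ei]
        if el == "C":
            if pos < n and seq[pos] == "C":
                walk(ei + 1, pos + 1, start)
        else:
            lo, hi = el
            for k in range(lo, hi + 1):
                if pos + k > n:
                    break
                if "C" in seq[pos : pos + k]:
                    break
                walk(ei + 1, pos + k, start)

    for i in range(n):
        walk(0, i, i)
    return sorted(spans)


def oracle_matches_anywhere(elements, seq):
    return bool(oracle_match_spans(elements, seq))


def motif_words(elements):
    """Every concrete string over {A, C} a motif can match (gaps -> A's)."""
    gap_axes = [range(el[0], el[1] + 1) for el in elements if el != "C"]
    words = set()
    for lens in itertools.product(*gap_axes):
        it = iter(lens)
        words.add("".join("C" if el == "C" else "A" * next(it) for el in elements))
    return words


def oracle_translate(nt):
    return "".join(
        _CODON.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3)
    )


def brute_force_orfs(sequence, require_stop=True, all_starts=True):
    """Every Met-initiated ORF found by scanning all codon offsets/strands.

    Returns a set of (frame, nt_start, nt_end, aa, has_stop) tuples with
    forward-strand half-open coordinates, matching the package convention.
    With ``all_starts=False`` only the first ATG per stop-bounded run is
    kept.
    """
    seq = sequence.upper().replace("U", "T")
    L = len(seq)
    found = set()
    for sign in (1, -1):
        working = seq if sign == 1 else seq.translate(COMPLEMENT)[::-1]
        for i in range(L - 2):
            if working[i : i + 3] != "ATG":
                continue
            if not all_starts:
                # skip if an in-frame ATG precedes with no stop in between
                j, upstream = i - 3, False
                while j >= 0:
                    codon = working[j : j + 3]
                    if _CODON.get(codon) == "*":
                        break
                    if codon == "ATG":
                        upstream = True
                        break
                    j -= 3
                if upstream:
                    continue
            aa = []
            j = i
            has_stop = False
            while j + 3 <= L:
                res = _CODON[working[j : j + 3]]
                j += 3
                if res == "*":
                    has_stop = True
                    break
                aa.append(res)
            if require_stop and not has_stop:
                continue
            w_start, w_end = i, j if has_stop else i + 3 * len(aa)
            if sign == 1:
                frame, nt_start, nt_end = i % 3 + 1, w_start, w_end
            else:
                frame = -(i % 3 + 1)
                nt_start, nt_end = L - w_end, L - w_start
            found.add((frame, nt_start, nt_end, "".join(aa), has_stop))
    return found
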