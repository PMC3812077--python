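"""Fitting alignment of short reads against the reference gene.

A single internal affine-gap aligner stands in for the external mapping
tools typically used for pooled-amplicon data: it computes the best-scoring
*fitting* alignment (the read consumed end to end, placed anywhere inside
the reference) by dynamic programming over three states (match/mismatch,
deletion = ref base absent from the read, insertion = read base absent from
the ref).  The hot DP fill is numba-compiled; an exact-substring fast path
skips the DP for error-free reads.

Conventions
-----------
* reference positions are 1-based inclusive;
* a deletion of length k at position p removes ref bases p..p+k-1;
* an insertion at position p places its payload *before* ref base p;
* indels are canonicalized by left-shifting within homopolymer/tandem
  context (``left_align_indel``), so every equivalent gap placement inside a
  repeat collapses to one call at the repeat's first position.

Reads mapping equally well to two disjoint loci (a repeat of the whole
read) are discarded as unmappable; so are reads exceeding the mismatch cap
or shorter than the minimum alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = -(10**9)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    max_mismatches: int = 6
    min_alignment_length: int = 24


@dataclass
class ReadAlignment:
    """Alignment of one read: 1-based ``ref_start`` and a CIGAR-like list of
    (op, length) with op in {'M', 'I', 'D'} ('M' covers match and mismatch)."""

    read_id: str
    ref_start: int
    cigar: list[tuple[str, int]]
    score: int
    n_mismatches: int

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        """1-based inclusive position of the last consumed reference base."""
        return self.ref_start + self.ref_span - 1


@dataclass
class DiscardCounts:
    too_short: int = 0
    too_many_mismatches: int = 0
    ambiguous: int = 0
    unalignable: int = 0

    @property
    def total(self) -> int:
        return self.too_short + self.too_many_mismatches + self.ambiguous + self.unalignable


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


@njit(cache=True)
def _fill_dp(read, ref, M, D, I, match, mismatch, gap_open, gap_extend):
    m, n = read.shape[0], ref.shape[0]
    for j in range(n + 1):
        M[0, j] = 0      # free start anywhere in the reference
        D[0, j] = NEG    # leading deletions are never useful (free ref skip)
        I[0, j] = NEG
    for i in range(1, m + 1):
        M[i, 0] = NEG
        D[i, 0] = NEG
        I[i, 0] = max(M[i - 1, 0], I[i - 1, 0] + gap_extend - gap_open) + gap_open
        for j in range(1, n + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            best = M[i - 1, j - 1]
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
            M[i, j] = best + s
            d = M[i, j - 1] + gap_open
            d2 = D[i, j - 1] + gap_extend
            D[i, j] = d if d > d2 else d2
            g = M[i - 1, j] + gap_open
            g2 = I[i - 1, j] + gap_extend
            I[i, j] = g if g > g2 else g2


class ReadAligner:
    """Aligns reads to one reference sequence, reusing DP buffers."""

    def __init__(self, ref_seq: str, params: AlignParams | None = None):
        self.ref_seq = ref_seq.upper()
        self.params = params or AlignParams()
        self._ref_codes = encode(self.ref_seq)
        self._bufs: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.discards = DiscardCounts()

    def _buffers(self, m: int):
        if m not in self._bufs:
            shape = (m + 1, len(self.ref_seq) + 1)
            self._bufs[m] = tuple(np.empty(shape, dtype=np.int64) for _ in range(3))
        return self._bufs[m]

    def align(self, read_seq: str, read_id: str = "read") -> ReadAlignment | None:
        """Best fitting alignment, or None when the read is discarded
        (too short, >max mismatches, or ambiguously placed)."""
        p = self.params
        read_seq = read_seq.upper()
        m = len(read_seq)
        if m < p.min_alignment_length:
            self.discards.too_short += 1
            return None

        # fast path: unique exact substring
        idx = self.ref_seq.find(read_seq)
        if idx >= 0:
            if self.ref_seq.find(read_seq, idx + 1) >= 0:
                self.discards.ambiguous += 1
                return None
            return ReadAlignment(read_id, idx + 1, [("M", m)], p.match * m, 0)

        M, D, I = self._buffers(m)
        _fill_dp(
            encode(read_seq), self._ref_codes, M, D, I,
            p.match, p.mismatch, p.gap_open, p.gap_extend,
        )
        final = np.maximum(M[m], I[m])
        best = int(final.max())
        ends = np.flatnonzero(final == best)

        candidates: list[ReadAlignment] = []
        seen: set[tuple[int, tuple]] = set()
        for j_end in ends:
            aln = self._traceback(read_seq, M, D, I, int(j_end), best, read_id)
            key = (aln.ref_start, tuple(aln.cigar))
            if key not in seen:
                seen.add(key)
                candidates.append(aln)
        candidates.sort(key=lambda a: a.ref_start)
        chosen = candidates[0]
        for other in candidates[1:]:
            if other.ref_start > chosen.ref_end:
                # equal best score at a disjoint locus: whole-read repeat
                self.discards.ambiguous += 1
                return None

        if chosen.n_mismatches > p.max_mismatches:
            self.discards.too_many_mismatches += 1
            return None
        if chosen.ref_span < p.min_alignment_length:
            self.discards.unalignable += 1
            return None
        return chosen

    def _traceback(self, read_seq, M, D, I, j_end, best, read_id) -> ReadAlignment:
        p = self.params
        m = len(read_seq)
        i, j = m, j_end
        state = "M" if M[m, j_end] >= I[m, j_end] else "I"
        ops: list[str] = []
        n_mm = 0
        while i > 0:
            if state == "M":
                s = p.match if read_seq[i - 1] == self.ref_seq[j - 1] else p.mismatch
                if read_seq[i - 1] != self.ref_seq[j - 1]:
                    n_mm += 1
                ops.append("M")
                prev = M[i, j] - s
                # deterministic preference at ties: M, then D, then I
                if M[i - 1, j - 1] == prev:
                    state = "M"
                elif D[i - 1, j - 1] == prev:
                    state = "D"
                else:
                    state = "I"
                i, j = i - 1, j - 1
            elif state == "D":
                ops.append("D")
                state = "M" if M[i, j - 1] + p.gap_open == D[i, j] else "D"
                j -= 1
            else:  # I
                ops.append("I")
                state = "M" if M[i - 1, j] + p.gap_open == I[i, j] else "I"
                i -= 1
        ops.reverse()
        cigar: list[tuple[str, int]] = []
        for op in ops:
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + 1)
            else:
                cigar.append((op, 1))
        return ReadAlignment(read_id, j + 1, cigar, best, n_mm)


def left_align_indel(
    ref_seq: str, position: int, kind: str, payload
) -> tuple[int, object]:
    """Canonicalize an indel by shifting it to its leftmost equivalent
    placement; idempotent.

    ``kind`` is 'del' (payload: deleted length, int) or 'ins' (payload:
    inserted bases, str).  Returns the canonical (position, payload); for
    insertions the payload is rotated along with the shift.
    """
    if kind == "del":
        k = int(payload)
        # the deletion window [p, p+k-1] may shift left while the base just
        # left of it equals the last base of the window
        while position > 1 and ref_seq[position - 2] == ref_seq[position + k - 2]:
            position -= 1
        return position, k
    if kind == "ins":
        s = str(payload)
        while position > 1 and ref_seq[position - 2] == s[-1]:
            s = ref_seq[position - 2] + s[:-1]
            position -= 1
        return position, s
    raise ValueError(f"unknown indel kind {kind!r}")
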