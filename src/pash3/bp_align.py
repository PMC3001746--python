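"""Basepair-level stage: skeleton scoring and banded affine-gap alignment.

The skeleton score is a cheap affine estimate of what a run could achieve
at basepair level (coverage reward minus affine gap charges); runs passing
the skeleton filter get a banded local dynamic-programming alignment whose
cells are restricted to a diagonal interval around the run.

Conventions (shared with the test oracles):

* a gap of length L costs ``gap_open + gap_extend * L``;
* alignment is local with soft-clipped read ends (S ops in the CIGAR);
* on score ties the move preference is diagonal (M), then gap-in-read (D),
  then gap-in-reference (I), then local stop; gap states prefer opening a
  fresh gap over extending; among best cells the first one reached scanning
  rows then columns wins;
* in bisulfite mode a read T aligned to a reference C scores and counts as
  a match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .kmer_align import Run

__all__ = [
    "BpScoringParams",
    "Alignment",
    "BandError",
    "skeleton_score",
    "banded_align",
    "cigar_read_length",
    "cigar_ref_length",
    "rescore_cigar",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class BpScoringParams:
    """Basepair scoring; penalties are positive magnitudes."""

    match_reward: int = 1
    mismatch_penalty: int = 2
    gap_open: int = 2
    gap_extend: int = 1
    bisulfite: bool = False

    def substitution(self, read_base: str, ref_base: str) -> int:
        if read_base == ref_base:
            return self.match_reward
        if self.bisulfite and read_base == "T" and ref_base == "C":
            return self.match_reward
        return -self.mismatch_penalty

    def is_match(self, read_base: str, ref_base: str) -> bool:
        return read_base == ref_base or (
            self.bisulfite and read_base == "T" and ref_base == "C"
        )


class BandError(RuntimeError):
    """The diagonal band excludes every cell — an internal bug upstream."""


@dataclass
class Alignment:
    """A local alignment of a read against a reference segment.

    Intervals are 0-based half-open and local to the inputs; ``cigar``
    consumes exactly ``read`` (S/M/I) and ``[ref_start, ref_end)`` (M/D).
    ``nm`` is the edit distance over the aligned region (bisulfite T~C
    counts as a match).
    """

    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    cigar: str
    nm: int


def skeleton_score(run: Optional[Run], params: BpScoringParams, span: int) -> int:
    """Affine estimate of a run's basepair-level potential.

    ``match_reward`` per read position covered by the union of the run's
    k-mer spans, minus ``gap_open`` per diagonal shift and ``gap_extend``
    per drifted base.
    """
    if run is None or not run.matches:
        return 0
    covered: set[int] = set()
    shifts = 0
    drift_total = 0
    prev_diag: Optional[int] = None
    for m in run.matches:
        covered.update(range(m.read_offset, m.read_offset + span))
        if prev_diag is not None and m.diagonal != prev_diag:
            shifts += 1
            drift_total += abs(m.diagonal - prev_diag)
        prev_diag = m.diagonal
    return (
        params.match_reward * len(covered)
        - params.gap_open * shifts
        - params.gap_extend * drift_total
    )


# traceback pointer codes
_STOP, _DIAG, _FROM_E, _FROM_F = 0, 1, 2, 3
_GAP_OPEN, _GAP_EXTEND = 0, 1


def banded_align(
    read: str,
    ref_segment: str,
    band: tuple[int, int],
    params: BpScoringParams = BpScoringParams(),
) -> Alignment:
    """Best local affine-gap alignment restricted to a diagonal band.

    ``band = (lo, hi)`` constrains cells to ``lo <= j - i <= hi`` where
    ``i`` indexes the read and ``j`` the reference segment (both 0-based).
    A band covering ``(-len(read), len(ref_segment))`` is equivalent to an
    unbanded full DP.
    """
    n, mlen = len(read), len(ref_segment)
    lo, hi = band
    if lo > hi or hi < -(n - 1) or lo > mlen - 1 or n == 0 or mlen == 0:
        raise BandError(f"band {band} excludes all cells for {n}x{mlen} matrix")

    # matrices are (n+1) x (m+1); row/col 0 are the local-alignment borders
    width = mlen + 1
    H = [[0.0] * width for _ in range(n + 1)]
    E = [[NEG_INF] * width for _ in range(n + 1)]  # gap in read (D ops)
    F = [[NEG_INF] * width for _ in range(n + 1)]  # gap in ref (I ops)
    ptr = [bytearray(width) for _ in range(n + 1)]
    eptr = [bytearray(width) for _ in range(n + 1)]
    fptr = [bytearray(width) for _ in range(n + 1)]

    open_cost = params.gap_open + params.gap_extend
    ext_cost = params.gap_extend

    best = 0.0
    best_i = best_j = 0
    sub = params.substitution
    for i in range(1, n + 1):
        j_lo = max(1, i + lo)
        j_hi = min(mlen, i + hi)
        if j_lo > j_hi:
            continue
        Hi, Hi1 = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fi1 = F[i], F[i - 1]
        ri = read[i - 1]
        for j in range(j_lo, j_hi + 1):
            diag_in_band = True  # diagonal predecessor shares this diagonal
            # E: gap in read, consuming ref; predecessor cell (i, j-1)
            if j - 1 - i >= lo:
                e_open = Hi[j - 1] - open_cost
                e_ext = Ei[j - 1] - ext_cost
                if e_open >= e_ext:
                    Ei[j] = e_open
                    eptr[i][j] = _GAP_OPEN
                else:
                    Ei[j] = e_ext
                    eptr[i][j] = _GAP_EXTEND
            # F: gap in ref, consuming read; predecessor cell (i-1, j)
            if j - (i - 1) <= hi:
                f_open = Hi1[j] - open_cost
                f_ext = Fi1[j] - ext_cost
                if f_open >= f_ext:
                    Fi[j] = f_open
                    fptr[i][j] = _GAP_OPEN
                else:
                    Fi[j] = f_ext
                    fptr[i][j] = _GAP_EXTEND
            d = Hi1[j - 1] + sub(ri, ref_segment[j - 1])
            # preference on ties: M, then D (E), then I (F), then stop
            h, p = d, _DIAG
            if Ei[j] > h:
                h, p = Ei[j], _FROM_E
            if Fi[j] > h:
                h, p = Fi[j], _FROM_F
            if h <= 0:
                h, p = 0.0, _STOP
            Hi[j] = h
            ptr[i][j] = p
            if h > best:
                best = h
                best_i, best_j = i, j

    if best <= 0:
        return Alignment(0, 0, 0, 0, 0, f"{n}S" if n else "", 0)

    # traceback
    ops: list[str] = []
    nm = 0
    i, j = best_i, best_j
    state = "H"
    while True:
        if state == "H":
            p = ptr[i][j]
            if p == _STOP:
                break
            if p == _DIAG:
                ops.append("M")
                if not params.is_match(read[i - 1], ref_segment[j - 1]):
                    nm += 1
                i -= 1
                j -= 1
            elif p == _FROM_E:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            nm += 1
            if eptr[i][j] == _GAP_OPEN:
                state = "H"
            j -= 1
        else:  # F
            ops.append("I")
            nm += 1
            if fptr[i][j] == _GAP_OPEN:
                state = "H"
            i -= 1

    ops.reverse()
    read_start, read_end = i, best_i
    ref_start, ref_end = j, best_j

    cigar_parts: list[str] = []
    if read_start:
        cigar_parts.append(f"{read_start}S")
    run_len = 0
    run_op = ""
    for op in ops:
        if op == run_op:
            run_len += 1
        else:
            if run_op:
                cigar_parts.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    if run_op:
        cigar_parts.append(f"{run_len}{run_op}")
    if n - read_end:
        cigar_parts.append(f"{n - read_end}S")

    return Alignment(
        score=int(best),
        read_start=read_start,
        read_end=read_end,
        ref_start=ref_start,
        ref_end=ref_end,
        cigar="".join(cigar_parts),
        nm=nm,
    )


_CIGAR_RE = re.compile(r"(\d+)([MIDS])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    parsed = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in parsed) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return parsed


def cigar_read_length(cigar: str) -> int:
    """Read bases consumed (M/I/S)."""
    return sum(n for n, op in parse_cigar(cigar) if op in "MIS")


def cigar_ref_length(cigar: str) -> int:
    """Reference bases consumed (M/D)."""
    return sum(n for n, op in parse_cigar(cigar) if op in "MD")


def rescore_cigar(
    read: str,
    ref: str,
    ref_start: int,
    cigar: str,
    params: BpScoringParams = BpScoringParams(),
) -> int:
    """Re-derive the DP score of an alignment path from its CIGAR.

    Independent of the DP matrices: walks the path, summing substitution
    scores for M columns and affine charges for I/D gaps; S ops are free.
    """
    score = 0
    i, j = 0, ref_start
    for n, op in parse_cigar(cigar):
        if op == "S":
            i += n
        elif op == "M":
            for _ in range(n):
                score += params.substitution(read[i], ref[j])
                i += 1
                j += 1
        elif op == "I":
            score -= params.gap_open + params.gap_extend * n
            i += n
        elif op == "D":
            score -= params.gap_open + params.gap_extend * n
            j += n
    return score
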