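"""K-mer level alignment: greedy chaining of matching k-mers into runs.

Matching k-mers between a read and a genomic window are processed in read
order and chained into collinear *runs*.  Extending a run by a k-mer earns
an overlap-corrected reward ``(t - ovl(d)) * m`` — only the newly matched
sampled positions count — and pays ``g`` per indel base implied by a
diagonal shift.  A k-mer that cannot extend any live run starts a new run
worth ``t * m``.  This operates entirely in k-mer space and serves as a
cheap filter ahead of basepair-level alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["KmerMatch", "KmerScoringParams", "Run", "kmer_align"]


@dataclass(frozen=True)
class KmerMatch:
    """A gapped k-mer shared by the read (at ``read_offset``) and the window
    (at ``window_offset``); both offsets are 0-based bp."""

    read_offset: int
    window_offset: int

    @property
    def diagonal(self) -> int:
        return self.window_offset - self.read_offset


@dataclass(frozen=True)
class KmerScoringParams:
    match_reward: int = 1  # m, per newly matched sampled base
    indel_penalty: int = 2  # g, per indel base between chained k-mers
    max_diagonal_drift: int = 10  # |Δdiagonal| allowed within one run, bp


@dataclass
class Run:
    """A chain of collinear k-mer matches with its k-mer-level score."""

    score: int
    matches: list[KmerMatch] = field(default_factory=list)

    @property
    def read_start(self) -> int:
        return self.matches[0].read_offset

    @property
    def read_end(self) -> int:
        return self.matches[-1].read_offset

    @property
    def window_start(self) -> int:
        return self.matches[0].window_offset

    @property
    def window_end(self) -> int:
        return self.matches[-1].window_offset

    @property
    def min_diagonal(self) -> int:
        return min(m.diagonal for m in self.matches)

    @property
    def max_diagonal(self) -> int:
        return max(m.diagonal for m in self.matches)


def kmer_align(
    matches: Sequence[KmerMatch],
    ovl: Sequence[int],
    params: KmerScoringParams = KmerScoringParams(),
) -> Optional[Run]:
    """Chain ``matches`` (sorted by read offset, ties by window offset) into
    runs and return the best-scoring run.

    ``ovl`` is the pattern self-overlap table (``ovl[d]`` for overlap d,
    indices 0..span); ``t = ovl[span]`` is the pattern weight.

    A match *k* extends a run *r* ending in match *last* iff it advances in
    both coordinates and stays within ``max_diagonal_drift`` diagonals:
    ``k.read_offset > last.read_offset``, ``k.window_offset >
    last.window_offset`` and ``|k.diagonal - last.diagonal| <= drift``.
    Among all extendable runs the best-scoring extension is applied; a
    non-extending match opens a new run.  Ties between final runs go to the
    smallest window offset.  Returns ``None`` for an empty match list.

    Worst case (every k-mer opens its own run) this is quadratic in the
    number of matches; when one run absorbs everything it is linear.
    """
    if not matches:
        return None
    span = len(ovl) - 1
    t = ovl[span]
    m = params.match_reward
    g = params.indel_penalty

    runs: list[Run] = []
    for k in matches:
        best_run: Optional[Run] = None
        best_score = 0
        for r in runs:
            last = r.matches[-1]
            if k.read_offset <= last.read_offset:
                continue
            if k.window_offset <= last.window_offset:
                continue
            drift = abs(k.diagonal - last.diagonal)
            if drift > params.max_diagonal_drift:
                continue
            d = max(0, span - (k.read_offset - last.read_offset))
            new_score = r.score + (t - ovl[d]) * m - g * drift
            if new_score > best_score:
                best_score = new_score
                best_run = r
        if best_run is not None:
            best_run.matches.append(k)
            best_run.score = best_score
        else:
            runs.append(Run(score=t * m, matches=[k]))

    return max(runs, key=lambda r: (r.score, -r.window_start))
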