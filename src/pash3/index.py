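"""Multi-positional hash table over a batch of reads.

One hash table stores sampled k-mers from every read at every sampling
offset; each entry records which read the k-mer came from and at which
offset it was sampled.  In bisulfite mode each sampled k-mer is inserted
under every key obtained by converting its Ts into either Cs or Ts, so that
reads in which unmethylated Cs read out as Ts still hit reference k-mers
containing the original Cs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .patterns import GappedPattern, sample_kmer

__all__ = [
    "KmerEntry",
    "MultiPositionalHashTable",
    "build_index",
    "expand_bisulfite_kmers",
    "sampling_offsets",
]

# k-mers with more sampled Ts than this are skipped in bisulfite mode to
# bound the 2^T key expansion (2^10 = 1024 keys max per k-mer).
DEFAULT_MAX_T_EXPANSION = 10


@dataclass(frozen=True)
class KmerEntry:
    """One occurrence of a k-mer: which read, at which sampling offset.

    ``rc`` marks entries contributed by the reverse complement of the read
    (regular mapping mode indexes both orientations).
    """

    read_id: int
    offset: int
    rc: bool = False


@dataclass
class MultiPositionalHashTable:
    table: dict[str, list[KmerEntry]]
    pattern: GappedPattern
    offset_gap: int
    kept_fraction: float
    bisulfite: bool
    unmappable: set[int] = field(default_factory=set)
    n_entries: int = 0
    n_distinct_before_filter: int = 0

    def lookup(self, key: str) -> list[KmerEntry]:
        """Entries stored under ``key``; empty if absent or filtered out."""
        return self.table.get(key, [])


def sampling_offsets(read_length: int, span: int, gap: int) -> list[int]:
    """Arithmetic sampling offsets 0, G, 2G, ... plus the terminal offset.

    The last admissible offset ``read_length - span`` is always included so
    both read ends are covered.  Empty if the read is shorter than the span.
    """
    last = read_length - span
    if last < 0:
        return []
    offs = list(range(0, last + 1, gap))
    if offs[-1] != last:
        offs.append(last)
    return offs


def expand_bisulfite_kmers(kmer: str, max_t: int = DEFAULT_MAX_T_EXPANSION) -> set[str]:
    """All keys obtained by independently turning each T into C or T.

    Returns ``{kmer}`` unchanged when there is no T, and the empty set when
    the number of Ts exceeds ``max_t`` (expansion cap).
    """
    t_positions = [i for i, ch in enumerate(kmer) if ch == "T"]
    if not t_positions:
        return {kmer}
    if len(t_positions) > max_t:
        return set()
    keys = {kmer}
    for i in t_positions:
        keys |= {k[:i] + "C" + k[i + 1 :] for k in keys}
    return keys


def build_index(
    reads: Sequence[str],
    pattern: GappedPattern,
    offset_gap: int,
    *,
    bisulfite: bool = False,
    kept_fraction: float = 1.0,
    with_reverse_complement: bool = False,
    max_t_expansion: int = DEFAULT_MAX_T_EXPANSION,
) -> MultiPositionalHashTable:
    """Index a read batch into one multi-positional hash table.

    Parameters
    ----------
    reads:
        Uppercase read sequences; reads shorter than the pattern span are
        recorded in ``unmappable`` rather than raising.
    offset_gap:
        G, the spacing in bp between consecutive sampling offsets.
    bisulfite:
        Insert every sampled k-mer under its full T->{C,T} key expansion.
    kept_fraction:
        After insertion, only the lowest-frequency ``kept_fraction`` of
        distinct keys are retained (frequency = number of entries); ties at
        the boundary are broken lexicographically for determinism.
    with_reverse_complement:
        Additionally index the reverse complement of every read (entries
        flagged ``rc=True``).  Used in regular mapping mode.
    """
    if offset_gap < 1:
        raise ValueError("offset_gap must be >= 1")
    if not 0.0 <= kept_fraction <= 1.0:
        raise ValueError("kept_fraction must be in [0, 1]")

    table: dict[str, list[KmerEntry]] = defaultdict(list)
    unmappable: set[int] = set()
    n_entries = 0

    def _insert(seq: str, read_id: int, rc: bool) -> int:
        count = 0
        for off in sampling_offsets(len(seq), pattern.span, offset_gap):
            key = sample_kmer(seq, off, pattern)
            if key is None:
                continue
            if bisulfite:
                for k in expand_bisulfite_kmers(key, max_t_expansion):
                    table[k].append(KmerEntry(read_id, off, rc))
                    count += 1
            else:
                table[key].append(KmerEntry(read_id, off, rc))
                count += 1
        return count

    for read_id, seq in enumerate(reads):
        if len(seq) < pattern.span:
            unmappable.add(read_id)
            continue
        n_entries += _insert(seq, read_id, rc=False)
        if with_reverse_complement:
            n_entries += _insert(reverse_complement(seq), read_id, rc=True)

    n_distinct = len(table)
    if kept_fraction < 1.0 and n_distinct:
        n_remove = int((1.0 - kept_fraction) * n_distinct)
        if n_remove:
            # highest-frequency keys first; lexicographic tie-break
            ranked = sorted(table, key=lambda k: (-len(table[k]), k))
            for key in ranked[:n_remove]:
                n_entries -= len(table[key])
                del table[key]

    return MultiPositionalHashTable(
        table=dict(table),
        pattern=pattern,
        offset_gap=offset_gap,
        kept_fraction=kept_fraction,
        bisulfite=bisulfite,
        unmappable=unmappable,
        n_entries=n_entries,
        n_distinct_before_filter=n_distinct,
    )


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
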