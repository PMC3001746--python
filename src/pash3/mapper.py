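"""Mapping orchestration: stream genome windows against the read index.

The genome is never indexed.  Reads go into one multi-positional hash
table; fixed-size windows (length 2W, stride W, 50% overlap) slide over
every reference sequence and each window position's sampled k-mer is looked
up in the table.  Per read x window the matches are chained at k-mer level;
two running-maximum filters (k-mer score, then skeleton score, both at
``candidate_fraction`` of the per-read best) gate the banded DP.  Candidate
mappings are buffered, deduplicated across overlapping windows, and the
best ones per read are selected at the end.

Regular mode indexes each read in both orientations and streams only the
forward genome.  Bisulfite mode indexes reads forward-only under their
T->{C,T} key expansion and streams both the forward and reverse-complement
strand of every reference sequence.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

from .bp_align import BpScoringParams, banded_align, skeleton_score
from .index import build_index, reverse_complement
from .kmer_align import KmerMatch, KmerScoringParams, kmer_align
from .patterns import GappedPattern, default_pattern, overlap_table, sample_kmer
from .seqio import SequenceRecord

__all__ = [
    "MapperConfig",
    "ReadMapping",
    "MappingResult",
    "preset",
    "PRESETS",
    "stream_windows",
    "map_reads",
    "select_best",
]

logger = logging.getLogger(__name__)

#: preset name -> (read-length divisor for G, kept_fraction)
PRESETS = {
    "high": (16, 0.99),
    "medium": (12, 0.99),
    "low": (8, 0.99),
    "fast": (8, 0.93),
}


@dataclass
class MapperConfig:
    pattern: Optional[GappedPattern] = None
    offset_gap: Optional[int] = None  # G; derived from preset when None
    window_half_length: Optional[int] = None  # W; max(read_len, 500) when None
    kept_fraction: Optional[float] = None  # from preset when None
    candidate_fraction: float = 0.75
    final_score_margin: int = 0
    kmer_params: KmerScoringParams = field(default_factory=KmerScoringParams)
    bp_params: BpScoringParams = field(default_factory=BpScoringParams)
    bisulfite: bool = False
    preset_name: str = "high"
    band_pad: int = 10

    def resolved(self, max_read_length: int) -> "MapperConfig":
        """Fill derived fields for a concrete read batch."""
        cfg = replace(self)
        if cfg.pattern is None:
            cfg.pattern = default_pattern(cfg.bisulfite)
        if cfg.offset_gap is None or cfg.kept_fraction is None:
            p = preset(cfg.preset_name, max_read_length)
            if cfg.offset_gap is None:
                cfg.offset_gap = p.offset_gap
            if cfg.kept_fraction is None:
                cfg.kept_fraction = p.kept_fraction
        if cfg.window_half_length is None:
            cfg.window_half_length = max(max_read_length, 500)
        if cfg.bisulfite:
            cfg.bp_params = replace(cfg.bp_params, bisulfite=True)
        if not 0 < cfg.candidate_fraction <= 1:
            raise ValueError("candidate_fraction must be in (0, 1]")
        return cfg


def preset(name: str, read_length: int) -> MapperConfig:
    """Built-in sensitivity presets.

    Sampling density scales with read length (high G=ceil(L/16), medium
    G=ceil(L/12), low/fast G=ceil(L/8)); high/medium/low keep the 99%
    lowest-frequency k-mers, fast discards the top 7%.
    """
    try:
        divisor, kept = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return MapperConfig(
        offset_gap=max(1, math.ceil(read_length / divisor)),
        kept_fraction=kept,
        preset_name=name,
    )


@dataclass
class ReadMapping:
    """A final mapping for one read, ready for SAM rendering.

    ``pos`` is the 0-based leftmost reference coordinate; ``seq`` is the
    read as it appears on the forward reference strand (reverse-complemented
    for '-' mappings); ``cigar`` is in forward-reference order.
    """

    read_id: int
    read_name: str
    ref_name: str
    pos: int
    strand: str
    score: int
    cigar: str
    seq: str
    nm: int
    mapq: int = 0
    unique: bool = False


@dataclass
class MappingResult:
    mappings: list[ReadMapping]  # all mappings within margin, best-first per read
    n_reads: int
    n_windows: int = 0
    n_candidates: int = 0

    def primary_mappings(self) -> list[ReadMapping]:
        """Best mapping per read (first within-margin candidate)."""
        seen: set[int] = set()
        primary = []
        for m in self.mappings:
            if m.read_id not in seen:
                seen.add(m.read_id)
                primary.append(m)
        return primary

    def by_read(self) -> dict[int, list[ReadMapping]]:
        out: dict[int, list[ReadMapping]] = defaultdict(list)
        for m in self.mappings:
            out[m.read_id].append(m)
        return dict(out)


def stream_windows(
    genome: Sequence[SequenceRecord], half_length: int
) -> Iterator[tuple[str, int, str]]:
    """Yield (reference name, window start, window sequence).

    Windows have length 2*half_length with stride half_length (50% overlap)
    so every alignment of length <= half_length is fully contained in at
    least one window; the final windows are truncated at the sequence end
    and windows never span sequence boundaries.
    """
    for rec in genome:
        seq = rec.seq
        if len(seq) <= 2 * half_length:
            yield rec.name, 0, seq
            continue
        for start in range(0, len(seq), half_length):
            yield rec.name, start, seq[start : start + 2 * half_length]


@dataclass
class _Candidate:
    score: int
    cigar: str
    seq: str
    nm: int


def _lift_rc(
    pos_rc: int, cigar: str, ref_length: int, consumed: int
) -> tuple[int, str]:
    """Map a reverse-complement-strand alignment back to forward coords."""
    from .bp_align import parse_cigar

    fwd_pos = ref_length - (pos_rc + consumed)
    rev = "".join(f"{n}{op}" for n, op in reversed(parse_cigar(cigar)))
    return fwd_pos, rev


def map_reads(
    reads: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord],
    config: MapperConfig = MapperConfig(),
) -> MappingResult:
    """Map single-end reads against a set of reference sequences."""
    if not reads:
        return MappingResult(mappings=[], n_reads=0)
    max_len = max(len(r.seq) for r in reads)
    cfg = config.resolved(max_len)
    pattern = cfg.pattern
    span = pattern.span
    ovl = overlap_table(pattern)
    W = cfg.window_half_length

    read_seqs = [r.seq for r in reads]
    index = build_index(
        read_seqs,
        pattern,
        cfg.offset_gap,
        bisulfite=cfg.bisulfite,
        kept_fraction=cfg.kept_fraction,
        with_reverse_complement=not cfg.bisulfite,
    )
    logger.info(
        "indexed %d reads: %d entries, %d distinct k-mers before filtering",
        len(reads), index.n_entries, index.n_distinct_before_filter,
    )
    oriented = {False: read_seqs}
    if not cfg.bisulfite:
        oriented[True] = [reverse_complement(s) for s in read_seqs]

    if not genome:
        return MappingResult(mappings=[], n_reads=len(reads))

    # (strand_pass, record): bisulfite mode also streams each reference's
    # reverse complement; regular mode handles strand via rc index entries.
    passes: list[tuple[str, SequenceRecord]] = [("+", rec) for rec in genome]
    if cfg.bisulfite:
        passes += [
            ("-", SequenceRecord(rec.name, reverse_complement(rec.seq)))
            for rec in genome
        ]
    ref_lengths = {rec.name: len(rec.seq) for rec in genome}

    best_kmer: dict[int, float] = defaultdict(float)
    best_skel: dict[int, float] = defaultdict(float)
    candidates: dict[int, dict[tuple[str, int, str], _Candidate]] = defaultdict(dict)
    n_windows = 0
    n_dp = 0

    for strand_pass, rec in passes:
        for ref_name, win_start, window in stream_windows([rec], W):
            n_windows += 1
            per_group: dict[tuple[int, bool], list[KmerMatch]] = defaultdict(list)
            table = index.table
            for pos in range(0, len(window) - span + 1):
                key = sample_kmer(window, pos, pattern)
                if key is None:
                    continue
                entries = table.get(key)
                if not entries:
                    continue
                for e in entries:
                    per_group[(e.read_id, e.rc)].append(KmerMatch(e.offset, pos))

            for (read_id, rc), matches in per_group.items():
                matches.sort(key=lambda m: (m.read_offset, m.window_offset))
                run = kmer_align(matches, ovl, cfg.kmer_params)
                if run is None:
                    continue
                if run.score <= cfg.candidate_fraction * best_kmer[read_id]:
                    continue
                best_kmer[read_id] = max(best_kmer[read_id], run.score)
                skel = skeleton_score(run, cfg.bp_params, span)
                if skel <= cfg.candidate_fraction * best_skel[read_id]:
                    continue
                best_skel[read_id] = max(best_skel[read_id], skel)

                read_seq = oriented[rc][read_id]
                n = len(read_seq)
                pad = cfg.band_pad
                seg_start = max(0, run.min_diagonal - pad)
                seg_end = min(len(window), run.max_diagonal + pad + n)
                segment = window[seg_start:seg_end]
                lo = max(run.min_diagonal - pad - seg_start, -(n - 1))
                hi = min(run.max_diagonal + pad - seg_start, len(segment) - 1)
                if lo > hi or not segment:
                    continue
                aln = banded_align(read_seq, segment, (lo, hi), cfg.bp_params)
                if aln.score <= 0:
                    continue
                n_dp += 1

                consumed = aln.ref_end - aln.ref_start
                pos0 = win_start + seg_start + aln.ref_start
                cigar = aln.cigar
                seq = read_seq
                if cfg.bisulfite and strand_pass == "-":
                    pos0, cigar = _lift_rc(
                        pos0, cigar, ref_lengths[ref_name], consumed
                    )
                    strand = "-"
                    seq = reverse_complement(read_seq)
                else:
                    strand = "-" if rc else "+"
                key3 = (ref_name, pos0, strand)
                prev = candidates[read_id].get(key3)
                if prev is None or aln.score > prev.score:
                    candidates[read_id][key3] = _Candidate(
                        aln.score, cigar, seq, aln.nm
                    )

    logger.info(
        "streamed %d windows, ran %d banded alignments, %d reads with candidates",
        n_windows, n_dp, len(candidates),
    )

    mappings: list[ReadMapping] = []
    for read_id in sorted(candidates):
        mappings.extend(
            select_best(
                read_id,
                reads[read_id].name,
                candidates[read_id],
                cfg.final_score_margin,
            )
        )
    return MappingResult(
        mappings=mappings,
        n_reads=len(reads),
        n_windows=n_windows,
        n_candidates=sum(len(c) for c in candidates.values()),
    )


def select_best(
    read_id: int,
    read_name: str,
    cands: dict[tuple[str, int, str], _Candidate],
    final_score_margin: int,
) -> list[ReadMapping]:
    """Keep candidates within ``final_score_margin`` of the read's best DP
    score; the unique flag is set iff exactly one survives.

    Unique mappings get a MAPQ that grows with the score gap to the best
    runner-up (clamped to [1, 40]; 40 when there is no other candidate);
    non-unique mappings get MAPQ 0.
    """
    if not cands:
        return []
    items = sorted(
        cands.items(), key=lambda kv: (-kv[1].score, kv[0][0], kv[0][1], kv[0][2])
    )
    best = items[0][1].score
    kept = [(k, c) for k, c in items if c.score >= best - final_score_margin]
    unique = len(kept) == 1
    if unique:
        if len(items) > 1:
            gap = best - items[1][1].score
            mapq = max(1, min(40, gap))
        else:
            mapq = 40
    else:
        mapq = 0
    return [
        ReadMapping(
            read_id=read_id,
            read_name=read_name,
            ref_name=ref,
            pos=pos,
            strand=strand,
            score=c.score,
            cigar=c.cigar,
            seq=c.seq,
            nm=c.nm,
            mapq=mapq,
            unique=unique,
        )
        for (ref, pos, strand), c in kept
    ]
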