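"""Read simulators and truth-aware TPR/PPV evaluation.

Three generators:

* whole-genome shotgun reads with per-base mutation (substitutions and
  1-10 bp indels) followed by uniform sequencing error;
* the unique/duplicated - coevolution/speciation/divergence (UD-CSD) tag
  model for semi-repetitive genomes;
* bisulfite-converted reads with per-CpG methylation states.

Every generator is bit-reproducible given its seed, and every read carries
a :class:`TruthRecord` whose edits replay against the genome to reproduce
the read exactly (see :func:`reconstruct_read`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .index import reverse_complement
from .mapper import ReadMapping

__all__ = [
    "UDCSDParams",
    "TruthRecord",
    "EvalResult",
    "random_genome",
    "simulate_udcsd",
    "simulate_wgs_reads",
    "simulate_bisulfite_reads",
    "reconstruct_read",
    "evaluate",
]

_BASES = np.array(list("ACGT"))
_BASE_SET = "ACGT"


def random_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """An i.i.d. random sequence at the requested GC content."""
    if length == 0:
        return ""
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.choice(4, size=length, p=[at, gc, gc, at])])


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read.

    ``edits`` replay deterministically against the source genome (see
    :func:`reconstruct_read`): ``("sub", genome_pos, base)`` substitutes,
    ``("del", genome_pos, length)`` skips reference bases, ``("ins",
    genome_pos, seq)`` inserts before the base at genome_pos, and
    ``("err", read_pos, base)`` overwrites a base of the constructed
    (forward-orientation) read.  ``methylation`` maps genome C positions to
    their simulated state for bisulfite reads.
    """

    read_id: str
    ref_name: str
    start: int
    strand: str
    edits: tuple = ()
    methylation: Optional[dict[int, bool]] = None


@dataclass
class EvalResult:
    n_reads: int
    n_unique: int
    n_true_positive: int

    @property
    def tpr(self) -> float:
        return self.n_true_positive / self.n_reads if self.n_reads else 0.0

    @property
    def ppv(self) -> float:
        return self.n_true_positive / self.n_unique if self.n_unique else 0.0


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = _BASE_SET.replace(base, "")
    return choices[rng.integers(0, len(choices))]


# ---------------------------------------------------------------------------
# UD-CSD


@dataclass(frozen=True)
class UDCSDParams:
    """Unique/Duplicated tags with Coevolution, Speciation, Divergence.

    ``coevolution_rate`` (x) is the per-base substitution probability each
    duplicated copy accumulates before speciation; ``divergence_rate`` (y)
    is the per-base substitution probability applied independently to every
    tag in each of the two descendant sets.
    """

    n_unique: int
    n_dup: int
    coevolution_rate: float
    divergence_rate: float
    read_length: int = 200
    seed: int = 0
    indel_rate: float = 0.0  # optional; off by default


def _mutate_tag(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    out: list[str] = []
    for ch in seq:
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # insertion before this base
                out.extend(_BASES[rng.integers(0, 4, size=length)])
                out.append(ch)
            else:  # deletion of this base (length absorbed by skipping emit)
                continue
        elif sub_rate > 0 and rng.random() < sub_rate:
            out.append(_other_base(rng, ch))
        else:
            out.append(ch)
    return "".join(out)


def simulate_udcsd(params: UDCSDParams) -> tuple[list[str], list[str]]:
    """Generate the paired tag sets (r, s); truth pairing is r[i] <-> s[i].

    One ancestral tag is copied ``n_dup`` times and each copy coevolves by
    independent substitutions at rate x; together with ``n_unique`` random
    tags the collection then speciates into sets r and s, each of which
    diverges by independent substitutions at rate y.
    """
    rng = np.random.default_rng(params.seed)
    L = params.read_length
    tags = [
        "".join(_BASES[rng.integers(0, 4, size=L)]) for _ in range(params.n_unique)
    ]
    if params.n_dup:
        ancestor = "".join(_BASES[rng.integers(0, 4, size=L)])
        tags += [
            _mutate_tag(ancestor, params.coevolution_rate, params.indel_rate, rng)
            for _ in range(params.n_dup)
        ]
    r = [_mutate_tag(t, params.divergence_rate, params.indel_rate, rng) for t in tags]
    s = [_mutate_tag(t, params.divergence_rate, params.indel_rate, rng) for t in tags]
    return r, s


# ---------------------------------------------------------------------------
# WGS reads


def _apply_edits_walk(
    genome: str, start: int, read_length: int, edits_at: Mapping[int, tuple]
) -> str:
    """Walk the genome from ``start`` applying at most one edit per consumed
    position until ``read_length`` bases are emitted (or the genome ends)."""
    out: list[str] = []
    pos = start
    glen = len(genome)
    while len(out) < read_length and pos < glen:
        edit = edits_at.get(pos)
        if edit is None:
            out.append(genome[pos])
            pos += 1
        elif edit[0] == "sub":
            out.append(edit[2])
            pos += 1
        elif edit[0] == "del":
            pos += edit[2]
        else:  # ins: inserted sequence, then the unchanged base
            out.extend(edit[2])
            out.append(genome[pos])
            pos += 1
    return "".join(out[:read_length])


def simulate_wgs_reads(
    genome: str,
    n_reads: int,
    read_length: int,
    *,
    mutation_rate: float = 0.001,
    substitution_fraction: float = 0.9,
    indel_max: int = 10,
    error_rate: float = 0.02,
    seed: int = 0,
    ref_name: str = "ref",
    both_strands: bool = True,
) -> tuple[list[str], list[TruthRecord]]:
    """Uniformly sampled reads with mutations, indels and sequencing error.

    Each consumed genome base mutates with ``mutation_rate``; a mutation is
    a substitution with probability ``substitution_fraction``, otherwise an
    indel of uniform length 1..``indel_max`` (insertion or deletion, equal
    odds).  Sequencing error then hits each read base independently at
    ``error_rate``, substituting a uniformly chosen different base.
    """
    if len(genome) < read_length:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(seed)
    slack = min(50, len(genome) - read_length)
    max_start = len(genome) - read_length - slack
    reads: list[str] = []
    truths: list[TruthRecord] = []
    for i in range(n_reads):
        start = int(rng.integers(0, max_start + 1))
        edits_at: dict[int, tuple] = {}
        # draw mutations along the walk the replay will take
        out_len = 0
        pos = start
        while out_len < read_length and pos < len(genome):
            if mutation_rate > 0 and rng.random() < mutation_rate:
                if rng.random() < substitution_fraction:
                    e = ("sub", pos, _other_base(rng, genome[pos]))
                    out_len += 1
                    pos += 1
                else:
                    length = int(rng.integers(1, indel_max + 1))
                    if rng.random() < 0.5:
                        ins = "".join(_BASES[rng.integers(0, 4, size=length)])
                        e = ("ins", pos, ins)
                        out_len += length + 1
                        pos += 1
                    else:
                        e = ("del", pos, length)
                        pos += length
                edits_at[e[1]] = e
            else:
                out_len += 1
                pos += 1
        read = _apply_edits_walk(genome, start, read_length, edits_at)
        edits: list[tuple] = sorted(edits_at.values(), key=lambda e: e[1])
        if error_rate > 0:
            chars = list(read)
            for p in range(len(chars)):
                if rng.random() < error_rate:
                    chars[p] = _other_base(rng, chars[p])
                    edits.append(("err", p, chars[p]))
            read = "".join(chars)
        strand = "-" if (both_strands and rng.random() < 0.5) else "+"
        if strand == "-":
            read = reverse_complement(read)
        reads.append(read)
        truths.append(
            TruthRecord(
                read_id=f"read{i}",
                ref_name=ref_name,
                start=start,
                strand=strand,
                edits=tuple(edits),
            )
        )
    return reads, truths


def reconstruct_read(genome: str, truth: TruthRecord, read_length: int) -> str:
    """Replay a WGS truth record's edits against the genome; the result
    equals the simulated read exactly (round-trip contract).  Bisulfite
    conversion is carried in ``methylation``, not ``edits``, so bisulfite
    reads are not reconstructable by this function."""
    edits_at = {e[1]: e for e in truth.edits if e[0] in ("sub", "del", "ins")}
    read = _apply_edits_walk(genome, truth.start, read_length, edits_at)
    chars = list(read)
    for e in truth.edits:
        if e[0] == "err":
            chars[e[1]] = e[2]
    read = "".join(chars)
    if truth.strand == "-":
        read = reverse_complement(read)
    return read


# ---------------------------------------------------------------------------
# Bisulfite reads


def simulate_bisulfite_reads(
    genome: str,
    n_reads: int,
    read_length: int,
    *,
    cpg_methylation_prob: float = 0.5,
    error_rate: float = 0.0,
    seed: int = 0,
    ref_name: str = "ref",
    both_strands: bool = True,
) -> tuple[list[str], list[TruthRecord]]:
    """Bisulfite-converted reads from either strand.

    Per CpG cytosine the methylation state is Bernoulli
    (``cpg_methylation_prob``); methylated Cs are preserved, unmethylated
    Cs read out as T.  Non-CpG cytosines are fully converted (always T).
    Truth records the per-CpG state keyed by genome position (for '-'
    strand reads, the forward-strand G position of the CpG).
    """
    if len(genome) < read_length:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    truths: list[TruthRecord] = []
    glen = len(genome)
    for i in range(n_reads):
        start = int(rng.integers(0, glen - read_length + 1))
        strand = "-" if (both_strands and rng.random() < 0.5) else "+"
        meth: dict[int, bool] = {}
        if strand == "+":
            frag = list(genome[start : start + read_length])
            for k, ch in enumerate(frag):
                if ch != "C":
                    continue
                gpos = start + k
                if gpos + 1 < glen and genome[gpos + 1] == "G":
                    state = bool(rng.random() < cpg_methylation_prob)
                    meth[gpos] = state
                    if not state:
                        frag[k] = "T"
                else:
                    frag[k] = "T"
        else:
            frag = list(reverse_complement(genome[start : start + read_length]))
            for k, ch in enumerate(frag):
                if ch != "C":
                    continue
                gpos = start + read_length - 1 - k  # a G on the forward strand
                if gpos >= 1 and genome[gpos - 1] == "C":
                    state = bool(rng.random() < cpg_methylation_prob)
                    meth[gpos] = state
                    if not state:
                        frag[k] = "T"
                else:
                    frag[k] = "T"
        edits: list[tuple] = []
        if error_rate > 0:
            for p in range(len(frag)):
                if rng.random() < error_rate:
                    frag[p] = _other_base(rng, frag[p])
                    edits.append(("err", p, frag[p]))
        reads.append("".join(frag))
        truths.append(
            TruthRecord(
                read_id=f"bsread{i}",
                ref_name=ref_name,
                start=start,
                strand=strand,
                edits=tuple(edits),
                methylation=meth,
            )
        )
    return reads, truths


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(
    mappings: Iterable[ReadMapping],
    truth: Mapping[str, TruthRecord],
    position_tolerance: int = 5,
) -> EvalResult:
    """TPR/PPV against simulator ground truth.

    Only uniquely mapped reads are scored; a unique mapping is a true
    positive iff its reference and strand match the truth and its leftmost
    position is within ``position_tolerance`` bp of the true start.  TPR
    divides by the total number of simulated reads, PPV by the number of
    unique mappings reported.
    """
    n_unique = 0
    tp = 0
    for m in mappings:
        if m.read_name not in truth:
            raise ValueError(f"mapping for unknown read id {m.read_name!r}")
        if not m.unique:
            continue
        n_unique += 1
        t = truth[m.read_name]
        if (
            m.ref_name == t.ref_name
            and m.strand == t.strand
            and abs(m.pos - t.start) <= position_tolerance
        ):
            tp += 1
    return EvalResult(n_reads=len(truth), n_unique=n_unique, n_true_positive=tp)
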