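"""Downstream methylome analysis on bisulfite mappings.

Monoclonal (PCR-duplicate) read removal, per-cytosine methylation calling
at a minimum informative coverage, and the agreement-ratio contingency
analysis contrasting methylation concordance at C/C homozygous versus
C/nonC heterozygous sites inside and outside a set of regions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .bp_align import parse_cigar
from .mapper import ReadMapping

__all__ = [
    "MethylCall",
    "AgreementTable",
    "remove_monoclonal",
    "call_methylation",
    "agreement_ratio",
    "build_agreement_table",
]


@dataclass(frozen=True)
class MethylCall:
    """Methylation level at one cytosine.

    ``pos`` is the 0-based forward-strand coordinate of the cytosine (for
    '-' strand calls, the coordinate of the forward-strand G whose
    complement is the cytosine).  ``context`` is CpG/CHG/CHH from the
    reference trinucleotide on the call's strand.
    """

    ref_name: str
    pos: int
    strand: str
    context: str
    methylated: int
    total: int

    @property
    def level(self) -> float:
        return self.methylated / self.total


def _five_prime(m: ReadMapping) -> int:
    from .bp_align import cigar_ref_length

    if m.strand == "+":
        return m.pos
    return m.pos + cigar_ref_length(m.cigar) - 1


def remove_monoclonal(mappings: Sequence[ReadMapping]) -> list[ReadMapping]:
    """Collapse reads sharing identical (reference, 5' position, strand).

    Among clones the highest DP score wins, first-seen on ties.  Opposite
    strands at the same position are distinct.  Idempotent.
    """
    best: dict[tuple[str, int, str], ReadMapping] = {}
    order: list[tuple[str, int, str]] = []
    for m in mappings:
        key = (m.ref_name, _five_prime(m), m.strand)
        prev = best.get(key)
        if prev is None:
            best[key] = m
            order.append(key)
        elif m.score > prev.score:
            best[key] = m
    return [best[k] for k in order]


def _context(genome: str, pos: int, strand: str) -> str:
    glen = len(genome)
    if strand == "+":
        if pos + 1 < glen and genome[pos + 1] == "G":
            return "CpG"
        if pos + 2 < glen and genome[pos + 2] == "G":
            return "CHG"
        return "CHH"
    if pos - 1 >= 0 and genome[pos - 1] == "C":
        return "CpG"
    if pos - 2 >= 0 and genome[pos - 2] == "C":
        return "CHG"
    return "CHH"


def _aligned_pairs(m: ReadMapping) -> Iterable[tuple[int, str]]:
    """(reference position, read base) for every M column of the mapping."""
    i = 0  # position in SAM SEQ (forward-reference orientation)
    j = m.pos
    for n, op in parse_cigar(m.cigar):
        if op == "S" or op == "I":
            i += n
        elif op == "D":
            j += n
        elif op == "M":
            for _ in range(n):
                yield j, m.seq[i]
                i += 1
                j += 1


def call_methylation(
    mappings: Sequence[ReadMapping],
    genome: Mapping[str, str],
    min_coverage: int = 5,
) -> list[MethylCall]:
    """Per-cytosine methylation calls from bisulfite mappings.

    Forward-strand mappings inform cytosines on the forward strand: an
    aligned read C is methylated evidence, a read T unmethylated evidence,
    anything else is ignored.  Reverse-strand mappings inform cytosines on
    the reverse strand, observed through their forward complement: read G
    methylated, read A unmethylated, at forward-strand G positions.  Calls
    are emitted only where informative coverage reaches ``min_coverage``,
    sorted by (reference, position, strand).
    """
    counts: dict[tuple[str, int, str], list[int]] = defaultdict(lambda: [0, 0])
    for m in mappings:
        seq = genome.get(m.ref_name)
        if seq is None:
            raise ValueError(f"mapping references unknown sequence {m.ref_name!r}")
        for ref_pos, read_base in _aligned_pairs(m):
            if ref_pos >= len(seq):
                raise ValueError(
                    f"mapping for read {m.read_name!r} extends past the end of "
                    f"{m.ref_name!r} (position {ref_pos})"
                )
            ref_base = seq[ref_pos]
            if m.strand == "+" and ref_base == "C":
                if read_base == "C":
                    counts[(m.ref_name, ref_pos, "+")][0] += 1
                elif read_base == "T":
                    counts[(m.ref_name, ref_pos, "+")][1] += 1
            elif m.strand == "-" and ref_base == "G":
                if read_base == "G":
                    counts[(m.ref_name, ref_pos, "-")][0] += 1
                elif read_base == "A":
                    counts[(m.ref_name, ref_pos, "-")][1] += 1
    calls = []
    for (ref, pos, strand) in sorted(counts):
        meth, unmeth = counts[(ref, pos, strand)]
        total = meth + unmeth
        if total < min_coverage:
            continue
        calls.append(
            MethylCall(
                ref_name=ref,
                pos=pos,
                strand=strand,
                context=_context(genome[ref], pos, strand),
                methylated=meth,
                total=total,
            )
        )
    return calls


@dataclass(frozen=True)
class AgreementTable:
    """Counts of methylation agreement between two samples, stratified by
    genotype class (C/C homozygous vs C/nonC heterozygous) and by whether
    the site lies inside the regions of interest."""

    inside_cc_diff: int
    inside_cc_same: int
    inside_cnonc_diff: int
    inside_cnonc_same: int
    outside_cc_diff: int
    outside_cc_same: int
    outside_cnonc_diff: int
    outside_cnonc_same: int

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"negative count in cell {name}")


def agreement_ratio(table: AgreementTable) -> dict[str, float]:
    """Agreement ratios inside/outside the regions and their chi-square.

    Per stratum the ratio is (no-difference fraction among C/nonC sites)
    divided by (no-difference fraction among C/C sites); a ratio below 1
    inside imprinted regions indicates heterozygous C/nonC sites agree less
    often than homozygous sites there.  The chi-square contrasts agreement
    at C/nonC sites between the two strata (2x2, Yates-corrected when any
    expected count is below 5).
    """

    def _fraction(same: int, diff: int, cell: str) -> float:
        total = same + diff
        if total == 0:
            raise ZeroDivisionError(f"no sites in stratum {cell!r}")
        return same / total

    def _ratio(cnonc_same, cnonc_diff, cc_same, cc_diff, where: str) -> float:
        num = _fraction(cnonc_same, cnonc_diff, f"{where} C/nonC")
        den = _fraction(cc_same, cc_diff, f"{where} C/C")
        if den == 0:
            raise ZeroDivisionError(f"zero agreement fraction in {where} C/C")
        return num / den

    ratio_inside = _ratio(
        table.inside_cnonc_same,
        table.inside_cnonc_diff,
        table.inside_cc_same,
        table.inside_cc_diff,
        "inside",
    )
    ratio_outside = _ratio(
        table.outside_cnonc_same,
        table.outside_cnonc_diff,
        table.outside_cc_same,
        table.outside_cc_diff,
        "outside",
    )
    contingency = np.array(
        [
            [table.inside_cnonc_same, table.inside_cnonc_diff],
            [table.outside_cnonc_same, table.outside_cnonc_diff],
        ]
    )
    if contingency.sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        expected = stats.contingency.expected_freq(contingency)
        correction = bool((expected < 5).any())
        chi2, p, _, _ = stats.chi2_contingency(contingency, correction=correction)
    return {
        "ratio_inside": ratio_inside,
        "ratio_outside": ratio_outside,
        "chi_square": float(chi2),
        "p_value": float(p),
    }


def build_agreement_table(
    calls_a: Sequence[MethylCall],
    calls_b: Sequence[MethylCall],
    genotype_classes: Mapping[tuple[str, int], str],
    regions: Sequence[tuple[str, int, int]],
    level_tolerance: float = 0.1,
) -> AgreementTable:
    """Cross two call sets into an :class:`AgreementTable`.

    ``genotype_classes`` maps (ref, pos) to "CC" or "CnonC" (sites absent
    from the map are skipped); two calls agree when their levels differ by
    at most ``level_tolerance``.
    """
    by_site_b = {(c.ref_name, c.pos, c.strand): c for c in calls_b}
    cells = defaultdict(int)
    for a in calls_a:
        b = by_site_b.get((a.ref_name, a.pos, a.strand))
        if b is None:
            continue
        cls = genotype_classes.get((a.ref_name, a.pos))
        if cls not in ("CC", "CnonC"):
            continue
        inside = any(
            ref == a.ref_name and start <= a.pos < end for ref, start, end in regions
        )
        same = abs(a.level - b.level) <= level_tolerance
        cells[(inside, cls, same)] += 1
    return AgreementTable(
        inside_cc_diff=cells[(True, "CC", False)],
        inside_cc_same=cells[(True, "CC", True)],
        inside_cnonc_diff=cells[(True, "CnonC", False)],
        inside_cnonc_same=cells[(True, "CnonC", True)],
        outside_cc_diff=cells[(False, "CC", False)],
        outside_cc_same=cells[(False, "CC", True)],
        outside_cnonc_diff=cells[(False, "CnonC", False)],
        outside_cnonc_same=cells[(False, "CnonC", True)],
    )
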