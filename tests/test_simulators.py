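import math

import numpy as np
import pytest
from scipy import stats

from pash3.index import reverse_complement
from pash3.mapper import ReadMapping
from pash3.simulate import (
    TruthRecord,
    UDCSDParams,
    evaluate,
    random_genome,
    reconstruct_read,
    simulate_bisulfite_reads,
    simulate_udcsd,
    simulate_wgs_reads,
)


class TestRandomGenome:
    def test_zero_length(self):
        assert random_genome(0) == ""

    def test_gc_zero_is_at_only(self):
        assert set(random_genome(500, 0.0, seed=1)) <= {"A", "T"}

    def test_gc_one_is_gc_only(self):
        assert set(random_genome(500, 1.0, seed=1)) <= {"C", "G"}

    def test_observed_gc_within_3_sigma(self):
        n, target = 100_000, 0.4
        g = random_genome(n, target, seed=2)
        observed = (g.count("G") + g.count("C")) / n
        sigma = math.sqrt(target * (1 - target) / n)
        assert abs(observed - target) < 3 * sigma

    def test_reproducible(self):
        assert random_genome(1000, 0.5, seed=3) == random_genome(1000, 0.5, seed=3)


class TestUDCSD:
    def test_no_divergence_pairs_identical(self):
        params = UDCSDParams(
            n_unique=20, n_dup=0, coevolution_rate=0.0, divergence_rate=0.0,
            read_length=50, seed=4,
        )
        r, s = simulate_udcsd(params)
        assert r == s

    def test_duplicated_tags_share_ancestry(self):
        params = UDCSDParams(
            n_unique=0, n_dup=10, coevolution_rate=0.0, divergence_rate=0.0,
            read_length=50, seed=5,
        )
        r, _ = simulate_udcsd(params)
        assert len(set(r)) == 1  # x=0: all copies identical

    def test_pairwise_divergence_matches_expectation(self):
        # each base of r_i and s_i mutates independently at rate y from the
        # common tag; P(differ) = 2y(1-y) + (2/3)y^2
        y, L, n = 0.05, 200, 300
        params = UDCSDParams(
            n_unique=n, n_dup=0, coevolution_rate=0.0, divergence_rate=y,
            read_length=L, seed=6,
        )
        r, s = simulate_udcsd(params)
        diffs = sum(
            a != b for ri, si in zip(r, s) for a, b in zip(ri, si)
        )
        total = n * L
        p = 2 * y * (1 - y) + (2 / 3) * y * y
        sigma = math.sqrt(p * (1 - p) / total)
        assert abs(diffs / total - p) < 3 * sigma

    def test_reproducible(self):
        params = UDCSDParams(
            n_unique=10, n_dup=5, coevolution_rate=0.25, divergence_rate=0.01,
            read_length=80, seed=7,
        )
        assert simulate_udcsd(params) == simulate_udcsd(params)


class TestWGSReads:
    def test_zero_rates_give_exact_substrings(self):
        genome = random_genome(5000, seed=8)
        reads, truths = simulate_wgs_reads(
            genome, 50, 60, mutation_rate=0.0, error_rate=0.0, seed=9,
        )
        for read, t in zip(reads, truths):
            expected = genome[t.start : t.start + 60]
            if t.strand == "-":
                expected = reverse_complement(expected)
            assert read == expected

    def test_truth_round_trip(self):
        genome = random_genome(20_000, seed=10)
        reads, truths = simulate_wgs_reads(
            genome, 300, 100, seed=11,
        )
        for read, t in zip(reads, truths):
            assert reconstruct_read(genome, t, 100) == read

    def test_substituted_base_fraction(self):
        # fraction of changed (non-indel) bases ~ mutation*sub_frac + error
        # with double-hit correction; checked within 3 sigma over 1e5 bases
        genome = random_genome(50_000, seed=12)
        n_reads, L = 1000, 100
        reads, truths = simulate_wgs_reads(
            genome, n_reads, L, seed=13, both_strands=False,
        )
        changed = total = 0
        for read, t in zip(reads, truths):
            if any(e[0] in ("ins", "del") for e in t.edits):
                continue
            ref = genome[t.start : t.start + L]
            changed += sum(a != b for a, b in zip(read, ref))
            total += L
        p_sub, p_err = 0.001 * 0.9, 0.02
        p = p_sub * (1 - p_err) + (1 - p_sub) * p_err + p_sub * p_err * (2 / 3)
        sigma = math.sqrt(p * (1 - p) / total)
        assert abs(changed / total - p) < 3 * sigma

    def test_indel_lengths_uniform(self):
        genome = random_genome(200_000, seed=14)
        # high mutation rate, indels only, to harvest many indels quickly
        _, truths = simulate_wgs_reads(
            genome, 1500, 100, mutation_rate=0.02, substitution_fraction=0.0,
            error_rate=0.0, seed=15,
        )
        lengths = []
        for t in truths:
            for e in t.edits:
                if e[0] == "del":
                    lengths.append(e[2])
                elif e[0] == "ins":
                    lengths.append(len(e[2]))
        assert len(lengths) > 1000
        counts = np.bincount(lengths, minlength=11)[1:11]
        _, p_value = stats.chisquare(counts)
        assert p_value > 0.01

    def test_reproducible(self):
        genome = random_genome(5000, seed=16)
        a = simulate_wgs_reads(genome, 20, 60, seed=17)
        b = simulate_wgs_reads(genome, 20, 60, seed=17)
        assert a == b


class TestBisulfiteReads:
    def test_full_methylation_preserves_cpg_cs(self):
        genome = random_genome(5000, seed=18)
        reads, truths = simulate_bisulfite_reads(
            genome, 50, 60, cpg_methylation_prob=1.0, seed=19,
        )
        for read, t in zip(reads, truths):
            assert all(state for state in t.methylation.values())
            # all remaining Cs in the read sit at CpG positions
            frag = genome[t.start : t.start + 60]
            if t.strand == "+":
                for i, ch in enumerate(read):
                    if ch == "C":
                        assert genome[t.start + i] == "C"

    def test_no_methylation_converts_every_c(self):
        genome = random_genome(5000, seed=20)
        reads, truths = simulate_bisulfite_reads(
            genome, 50, 60, cpg_methylation_prob=0.0, seed=21,
        )
        for read in reads:
            assert "C" not in read

    def test_methylated_fraction_near_probability(self):
        genome = random_genome(50_000, seed=22)
        _, truths = simulate_bisulfite_reads(
            genome, 3000, 60, cpg_methylation_prob=0.5, seed=23,
        )
        states = [s for t in truths for s in t.methylation.values()]
        assert len(states) > 10_000
        p_hat = sum(states) / len(states)
        sigma = math.sqrt(0.25 / len(states))
        assert abs(p_hat - 0.5) < 3 * sigma

    def test_reproducible(self):
        genome = random_genome(5000, seed=24)
        a = simulate_bisulfite_reads(genome, 20, 60, seed=25)
        b = simulate_bisulfite_reads(genome, 20, 60, seed=25)
        assert a == b


def mk_mapping(name, ref, pos, strand="+", unique=True):
    return ReadMapping(
        read_id=0, read_name=name, ref_name=ref, pos=pos, strand=strand,
        score=60, cigar="60M", seq="A" * 60, nm=0,
        mapq=40 if unique else 0, unique=unique,
    )


class TestEvaluate:
    def _truth(self, n):
        return {
            f"r{i}": TruthRecord(
                read_id=f"r{i}", ref_name="chr1", start=100 * i, strand="+"
            )
            for i in range(n)
        }

    def test_all_correct(self):
        truth = self._truth(5)
        mappings = [mk_mapping(f"r{i}", "chr1", 100 * i) for i in range(5)]
        result = evaluate(mappings, truth)
        assert result.tpr == 1.0
        assert result.ppv == 1.0

    def test_half_unmapped(self):
        truth = self._truth(10)
        mappings = [mk_mapping(f"r{i}", "chr1", 100 * i) for i in range(5)]
        result = evaluate(mappings, truth)
        assert result.tpr == 0.5
        assert result.ppv == 1.0

    def test_partially_wrong(self):
        truth = self._truth(10)
        mappings = [mk_mapping(f"r{i}", "chr1", 100 * i) for i in range(6)]
        mappings += [
            mk_mapping(f"r{i}", "chr1", 100 * i + 50) for i in range(6, 8)
        ]
        result = evaluate(mappings, truth)
        assert result.tpr == 0.6
        assert result.ppv == 0.75

    def test_position_tolerance(self):
        truth = self._truth(1)
        near = [mk_mapping("r0", "chr1", 4)]
        far = [mk_mapping("r0", "chr1", 7)]
        assert evaluate(near, truth, position_tolerance=5).tpr == 1.0
        assert evaluate(far, truth, position_tolerance=5).tpr == 0.0

    def test_wrong_strand_not_tp(self):
        truth = self._truth(1)
        mappings = [mk_mapping("r0", "chr1", 0, strand="-")]
        assert evaluate(mappings, truth).tpr == 0.0

    def test_non_unique_not_counted(self):
        truth = self._truth(1)
        mappings = [mk_mapping("r0", "chr1", 0, unique=False)]
        result = evaluate(mappings, truth)
        assert result.n_unique == 0
        assert result.tpr == 0.0

    def test_unknown_read_raises(self):
        with pytest.raises(ValueError, match="unknown read"):
            evaluate([mk_mapping("ghost", "chr1", 0)], self._truth(1))

    def test_tpr_anti_monotone_in_error_rate(self):
        from pash3 import SequenceRecord, map_reads, preset

        genome = random_genome(20_000, seed=26)
        tprs = []
        for rate in (0.0, 0.08, 0.2):
            reads, truths = simulate_wgs_reads(
                genome, 80, 80, mutation_rate=0.0, error_rate=rate, seed=27,
            )
            recs = [
                SequenceRecord(t.read_id, s) for s, t in zip(reads, truths)
            ]
            res = map_reads(recs, [SequenceRecord("ref", genome)], preset("high", 80))
            ev = evaluate(
                res.primary_mappings(), {t.read_id: t for t in truths}
            )
            tprs.append(ev.tpr)
        assert tprs[0] >= tprs[1] >= tprs[2]
        assert tprs[0] > tprs[2]
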