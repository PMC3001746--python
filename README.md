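# pash3

A read mapper built on **gapped-pattern multi-positional hashing**: reads
are indexed in a single hash table keyed by spaced-seed k-mers (each entry
recording the read and the sampling offset), the genome is streamed against
the index in overlapping fixed-size windows, matching k-mers are chained by
a greedy **k-mer-level alignment** with overlap-corrected rewards, and only
candidates passing two running-best filters (k-mer score, then an affine
*skeleton* bound) reach banded affine-gap dynamic programming. Bisulfite
mode maps C→T-converted reads by expanding read k-mer Ts into {C,T} keys
and streaming both reference strands, scoring read-T/reference-C as a
match.

The package also ships the simulators used to benchmark the mapper
(uniform WGS reads with substitutions/indels/sequencing error, the UD-CSD
unique/duplicated coevolution-speciation-divergence model, bisulfite reads
with per-CpG methylation states), truth-aware TPR/PPV evaluation, and a
methylome-analysis stage (monoclonal-read removal, per-cytosine methylation
calling at a minimum coverage, and an agreement-ratio contingency
analysis).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(oracle equivalences, closed-form scores, exact/variant/bisulfite recovery
on 100-kb random genomes, simulator statistics). The whole suite runs in
well under a minute on one CPU.

The acceptance report script (the build contract defines no numeric
targets, so it emits an empty JSON object plus diagnostics on stderr):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## CLI

```sh
# simulate reads + truth
pash3 simulate wgs --genome-length 100000 --n-reads 1000 --read-length 100 \
    --seed 1 --out-reads reads.fq --out-truth truth.tsv --out-ref ref.fa

# map (presets: high / medium / low / fast)
pash3 map --reads reads.fq --ref ref.fa --preset high --out out.sam

# evaluate against the truth table
pash3 evaluate --sam out.sam --truth truth.tsv

# bisulfite pipeline
pash3 simulate bisulfite --genome-length 100000 --n-reads 1000 \
    --out-reads bs.fq --out-truth bs_truth.tsv --out-ref ref.fa
pash3 map --reads bs.fq --ref ref.fa --bisulfite --out bs.sam
pash3 methylation --sam bs.sam --ref ref.fa --min-coverage 5 --out meth.tsv

# UD-CSD benchmark (map r against the s tags)
pash3 simulate udcsd --n-unique 900 --n-dup 100 --coevolution 0.25 \
    --divergence 0.01 --out-r r.fq --out-s s.fa --out-truth t.tsv

# index statistics; agreement-ratio analysis of an 8-cell table
pash3 index --reads reads.fq
pash3 agreement --counts 7808 5286 7 4 25170688 16275243 20963 23299
```

`pash3 map` accepts `--pattern` as a literal 0/1 mask, `--offset-gap`,
`--score-margin`, `--kept-fraction`, and `--config file.yaml` (a key-value
file mirroring the flags; explicit flags win).

## Library

```python
from pash3 import SequenceRecord, map_reads, preset, random_genome, evaluate

genome = random_genome(100_000, seed=1)
reads = [SequenceRecord("r0", genome[1000:1100])]
result = map_reads(reads, [SequenceRecord("chr1", genome)], preset("high", 100))
for m in result.primary_mappings():
    print(m.ref_name, m.pos, m.strand, m.cigar, m.score, m.unique)
```

Modules: `patterns` (gapped masks, self-overlap tables), `index`
(multi-positional hash table, bisulfite key expansion, frequency
filtering), `kmer_align` (greedy run chaining), `bp_align` (skeleton score,
banded affine DP, CIGAR utilities), `mapper` (window streaming, filters,
candidate selection, presets), `simulate` (generators + evaluation),
`methylome` (duplicate removal, methylation calling, agreement ratios),
`seqio` (FASTA/FASTQ/SAM/BED), `cli`.

Output SAM is plain text (flags 0/4/16, soft-clipped local alignments,
`NM`/`AS` tags); coordinates are 0-based half-open internally and converted
to 1-based only at SAM emission.
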