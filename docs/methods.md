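# Methods

This note documents the model behind `happhase`, its assumptions and
numerical conventions, what the simulator does and does not emulate, and
the design choices made where the design was genuinely open.

## The phasing model

### Setting

A partially phased diploid assembly provides, per primary contig, an
ordered list of *m* phase blocks. Block *k* is a pair of segments
(*A_k*, *B_k*): the alternate haplotig and the homologous primary-contig
interval. Between blocks lie collapsed segments carrying both haplotypes.
Each block has two possible diploid configurations — *A* to output
haplotype 0 and *B* to haplotype 1, or the reverse — encoded as a binary
state *T[k]*, with state 0 meaning "*B* stays on the phase-0 backbone".
The assembly gives no information about the relative states of
neighbouring blocks; Hi-C does.

### Contact signal

Hi-C ligation joins loci of the same chromosome fibre, so read pairs
spanning two blocks of the same parental chromosome dominate over pairs
joining different homologs. After mapping to the *minced* segments, only
haplotype-specific pairs are kept: both mates primary alignments
(SAM flag mask 2316 removes unmapped/secondary/supplementary records),
map quality strictly greater than 10, edit distance strictly less than 5.
Both thresholds are deliberately strict at the boundary: a mate with MAPQ
exactly 10 or NM exactly 5 is rejected. Retained pairs are counted into a
symmetric matrix *M* over segments, and each entry is normalized by the
restriction-site content of its two segments,

    Mhat[i, j] = M[i, j] / (z_i + z_j),

because the number of ligatable restriction fragments, not length per se,
sets a segment's expected contact budget. `z` counts motif occurrences on
the forward strand, overlapping matches included; a list of motifs
(multi-enzyme kits) is summed. Segment pairs with `z_i + z_j = 0` get
`Mhat = 0` rather than a division error — such segments carry no usable
signal and are effectively muted.

### The sweep

For an ordered block pair (*i*, *j*) the four inter-block entries of
`Mhat` split into two groups: `cis_same = Mhat[A_i,A_j] + Mhat[B_i,B_j]`
supports equal states, `cis_diff = Mhat[A_i,B_j] + Mhat[B_i,A_j]` supports
opposite states, and `beta = cis_same + cis_diff` is the pair's total link
mass. Sweeping the blocks of a contig in coordinate order, the sampler
visits block *i*, hypothesizes state 1, and computes

    phaseFreq(i) = sum_{j<i} [T[j]=1] cis_same(i,j) + [T[j]=0] cis_diff(i,j)
                   -----------------------------------------------------
                               sum_{j<i} beta(i,j)

— the fraction of link mass to *past* blocks consistent with the
hypothesis. It keeps state 1 iff a uniform draw falls below this value.
The conditional deliberately looks backwards only; combined with many
whole-contig sweeps this behaves like a Gibbs-flavoured sampler whose
stationary preference is the assignment maximizing total consistent link
mass (the quantity `exhaustive_phase` maximizes directly by enumeration).

Conventions, in order of appearance:

* **Pinning.** Block 0 is fixed at state 0 and never resampled (for
  *m* ≥ 2): per-contig phase labels are arbitrary, and pinning makes runs
  comparable. A single-block contig draws its state uniformly.
* **Zero denominator.** A block with no links to its past returns
  phaseFreq = 0.5 — an uninformed coin flip, matching the sampler's
  intent.
* **Initialization.** States are randomized once before the first sweep,
  not per sweep.
* **Scoring.** After `b` burn-in sweeps, each of the remaining `n − b`
  sweeps increments a per-block counter when the block sits in state 1
  (one increment per block visit per sweep). The final assignment is the
  majority state; a frequency of exactly 0.5 resolves to 1. The
  frequency itself is reported as `phase1_freq`, a per-block support
  value: values near 0/1 mark confident blocks, values near 0.5
  uninformative ones.
* **Budgets.** Defaults are `n = 1,000,000` sweeps with `b = 100,000`
  burn-in. The validation experiments use `n = 100,000` / `b = 10,000`,
  which is generous for the tens-of-blocks contigs they phase: agreement
  with exhaustive enumeration is already complete at that budget. Block
  counts in the hundreds-to-thousands (whole-genome runs) warrant the
  larger default.
* **Reproducibility.** Every contig gets an independent PCG64 stream
  derived from the master seed and a hash of the contig name, so results
  never depend on contig iteration order. Uniform variates are pre-drawn
  in fixed-size chunks, making results identical with and without the
  numba-compiled inner loop.

The inner loop is JIT-compiled with numba (a pure-Python fallback of the
same function is used if numba is unavailable). Per-contig work is
O(n · m²); memory is dominated by the dense `Mhat`.

### Sweeps conditioned on the past only

Because phaseFreq conditions on *j < i* rather than all *j ≠ i*, the
per-visit update is not a full Gibbs conditional. Empirically this does
not cost accuracy at realistic signal-to-noise (the oracle-equivalence
test holds at 5:1 cis:trans with 99–100% agreement), and it keeps each
visit O(i). The exhaustive oracle provides the reference answer in tests
for up to 16 blocks (2^15 configurations).

## Placement and mincing conventions

* Coordinates are 0-based half-open everywhere; PAF is natively so.
* Chaining requires sub-alignments strictly increasing on both query and
  target (strand-aware), with zero gap penalty; the chain maximizing
  total matched bases defines the placement interval and its score.
* A haplotig whose second-best candidate placement scores more than 0.8×
  its best is discarded as non-uniquely mapped (ratio configurable).
* Placements fully contained in a higher-scoring placement are dropped;
  partial overlaps are resolved by trimming the lower-scoring placement
  (largest surviving piece kept, dropped below 1 kb). Mincing requires
  disjoint intervals, and the filter is idempotent.
* The A segment keeps the full haplotig sequence as assembled — unaligned
  haplotig ends are not trimmed — with the placement strand recorded;
  minus-strand haplotigs are reverse-complemented at emission so both
  outputs read in primary orientation.
* Zero-length collapsed intervals between abutting placements are
  omitted.
* With an all-zero assignment, the phase-0 output reproduces the input
  primary contig byte for byte; this fixes the otherwise arbitrary
  convention of which phase inherits the primary backbone and makes the
  identity case directly testable.

## The simulator

`simulate_assembly` builds, per contig, a uniform-ACGT background with
`n_blocks` blocks of `block_len` bp placed at Dirichlet-random gaps. The
two parental alleles of a block differ at Binomial(block_len,
heterozygosity) SNV positions; the primary contig carries a uniformly
random parent per block (the mosaic real collapsing assemblers produce)
and the haplotig the other, on the minus strand with probability 0.25.
Placements are emitted as exact PAF rows. SNVs only — no indels — so A
and B members have equal length and emission length identities are exact.

`simulate_pairs` emits the haplotype-specific fraction of an
`n_pairs`-pair library (each pair informative with probability
`informative_fraction`; the rest are considered lost to the map-quality
filter upstream). An informative pair picks a parent uniformly, a first
endpoint uniform over the contig's block union, and a second endpoint at
an exponentially distributed distance (scale `decay_scale`, random
direction, redrawn until it lands in a block). Endpoints map to the
segment carrying that parent at their block; with probability
`noise_fraction` the second endpoint is flipped to the wrong haplotype —
the knob that takes the signal from clean (0) to nonexistent (0.5).

Default conditions: 20 contigs × 1 Mb, 10 blocks of 50 kb each (half of
each contig unzipped), heterozygosity 0.005, GATC motif, 800,000 library
pairs with informative fraction 0.25 (the middle of the ~11–44% range
real libraries show), decay scale 150 kb, noise 0.05. The library size
was set so that even the widest random collapsed gap leaves every
adjacent block pair with ≥ 50 informative pairs linking it.

What the simulator does **not** emulate: read-level sequence (pairs are
placed at segment level, so mapping ambiguity inside blocks is abstracted
into `informative_fraction`/`noise_fraction`), indels and structural
variation between haplotypes, PCR duplicates and re-ligation artifacts,
restriction-fragment-level pair placement, chimeric contigs, and
collapsed-region copy-number errors. Passing the recovery tests therefore
demonstrates the correctness of the placement → mince → count → phase →
emit chain under the stated noise model, not robustness to alignment
artifacts in real libraries.

## Scoring phasing accuracy

**Block accuracy** compares the fitted assignment with the simulator's
truth. Per contig, phase labels are identifiable only relative to the
pinned first block, so the comparison applies the global flip that aligns
block 0 with its truth and reports the fraction of matching blocks,
block-weighted across contigs. This anchored flip equals the best-of-two
flip whenever phasing is better than chance, but is unbiased at the null:
a best-of-two flip over *m* coin-flip blocks has expected accuracy
0.5 + E|Bin(m, ½) − m/2|/m ≈ 0.62 for m = 10, whereas anchoring leaves
only the structural 0.5/m bonus of the always-correct anchor block
(≈ 0.53 at the m = 16 null geometry used here).

**Parental k-mer accuracy** is the stringent trio measure: canonical
k-mers (k = 21) specific to one parent (count ≥ `min_count` in one,
absent from the other; `min_count` 1 for assembled parents, default 2 for
reads) are counted in each output sequence; each sequence is assigned its
majority parent and *every* minority marker counts as an error. The
overall value is marker-weighted across sequences. Marker sets are stored
as sorted 2-bit-packed uint64 arrays; counting is pure numpy.

## Validation experiments (scripts/acceptance.py, tests/test_acceptance.py)

* **Oracle equivalence** — 100 random instances of 3–8 blocks; every
  inter-block link weight U(0.5, 1.5) with the two truth-consistent
  entries scaled ×5 (5:1 cis:trans). The sweep (100k/10k, seeded) must
  match exhaustive enumeration in ≥ 99 instances.
* **Clean recovery** — the default conditions above, 10 seeds: mean block
  accuracy and parental k-mer accuracy of the emitted outputs ≥ 0.99.
* **Null** — noise 0.5 at a reduced geometry (8 contigs × 16 blocks of
  5 kb, 80k pairs, decay 15 kb): mean block accuracy over 20 seeds must
  fall in [0.4, 0.6]; expected value ≈ 0.53 from the anchor bonus.
* **Normalization exactness, structural invariants, filter strictness,
  before/after contrast** — as described in their test docstrings; the
  before/after test reuses the clean-recovery runs and applies a
  one-sided sign test to the pre- vs post-phasing k-mer accuracies.

Problem sizes were chosen so the full suite runs in minutes on one CPU
while every experiment retains enough replication to be conclusive.

## Known limitations

* Diploid only: block states are binary; polyploid configurations are out
  of scope.
* The sampler conditions on past blocks only (see above); pathological
  matrices could in principle favour the full conditional, but none arise
  at tested signal levels.
* Inter-contig links are ignored during contig-stage phasing: phaseFreq
  sums run over blocks of the same primary contig only. Scaffold-stage
  phasing is the same operation applied to an index whose "contig" is a
  scaffold's ordered list of phase-block pairs.
* Placement quality is bounded by the input alignments; `happhase` chains
  and filters but never re-aligns.
* A haplotig is emitted exactly as assembled (reverse-complemented if
  minus-strand); no polishing, gap filling, or scaffolding.
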