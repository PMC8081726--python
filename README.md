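# happhase

Extend haplotype phase across a partially phased diploid genome assembly
using Hi-C contact counts.

Long-read assemblers for outbred diploids produce a haploid backbone of
**primary contigs** plus shorter **alternate haplotigs**, each haplotig
covering one heterozygous ("unzipped") region. Within one such phase block
both haplotypes are resolved, but the *relative* phase of neighbouring
blocks along a contig is unknown: the primary contig is a mosaic of
maternal and paternal segments. `happhase` fixes this by exploiting the
fact that Hi-C read pairs overwhelmingly link loci on the *same* parental
chromosome: haplotype-specific Hi-C contacts between blocks reveal which
members belong together.

## Method

1. **Placement** — haplotig-vs-primary alignments (PAF) are chained in one
   dimension per haplotig, then filtered (non-unique mappings discarded,
   contained placements removed, residual overlaps trimmed) into a set of
   disjoint placement intervals per primary contig.
2. **Mincing** — each primary contig is cut at placement boundaries into
   **B** segments (the primary's copy of each phase block), paired with
   their **A** haplotigs, and interleaved **collapsed** segments
   (homozygous sequence). B ∪ collapsed tiles the contig exactly.
3. **Contacts** — Hi-C mate pairs mapped to the minced segments are kept
   only if both mates are primary alignments with map quality > 10 and
   edit distance < 5 (the haplotype-specific set), counted into a
   symmetric matrix *M*, and normalized by restriction-site content:

   *M̂ᵢⱼ = Mᵢⱼ / (zᵢ + zⱼ)*,

   where *zᵢ* is the number of restriction-enzyme motif occurrences in
   segment *i* (entries with *zᵢ + zⱼ = 0* are set to 0).
4. **Phasing** — each block *k* takes a binary configuration
   *T[k] ∈ {0, 1}* (which member goes to which output haplotype). A
   stochastic sweep walks the blocks of each contig in order; at block *i*
   it keeps the hypothesis *T[i] = 1* with probability equal to the
   fraction of normalized link mass to all previous blocks that is
   consistent with it:

   *phaseFreq(i) = Σⱼ₍ⱼ₎ consistent links(i, j) / Σⱼ₍ⱼ₎ all links(i, j)*,
   j < i,

   where the consistent mass is *M̂[Aᵢ,Aⱼ] + M̂[Bᵢ,Bⱼ]* for same-state
   blocks and *M̂[Aᵢ,Bⱼ] + M̂[Bᵢ,Aⱼ]* otherwise. Block 0 is pinned (phase
   labels per contig are arbitrary). After a burn-in the sweeps are
   scored, and each block's final phase is its majority state — with the
   scored-state frequency reported as a per-block support value.
5. **Emission** — the two full-length pseudo-haplotypes per contig are
   rebuilt by traversing segments in order: collapsed sequence goes to
   both outputs, and at each block the A/B members are distributed
   according to the assignment (with all-zero assignments, phase 0
   reproduces the input primary contig exactly).

A simulator (`happhase.simulate`) generates diploid assemblies with known
block-level truth and decay-distributed Hi-C pairs, and an evaluator
(`happhase.evaluate`) scores phased outputs by parent-specific *k*-mers
(canonical, *k* = 21 by default), the standard trio-based phasing measure.

## Worked example

Simulate a small diploid (2 contigs × 200 kb, four 20 kb phase blocks
each, 0.5% heterozygosity, 5% cross-phase noise), then run the pipeline:

```bash
cat > sim.yaml <<EOF
n_contigs: 2
contig_len: 200000
n_blocks: 4
block_len: 20000
heterozygosity: 0.005
n_pairs: 120000
decay_scale: 60000.0
noise_fraction: 0.05
seed: 7
EOF
happhase simulate --config sim.yaml -o simdata
# -> 2 contigs, 8 haplotigs, 29820 informative pairs -> simdata

cat > run.yaml <<EOF
primary_fasta: simdata/primary.fasta
haplotig_fasta: simdata/haplotigs.fasta
paf: simdata/placements.paf
pairs: simdata/pairs.tsv
outdir: run
iterations: 200000
burn_in: 20000
seed: 11
EOF
happhase run --config run.yaml
# -> done: 8 placements, 26 segments, 29820 retained pairs
```

Inspecting the fit (`happhase phase … --seed 11`) prints the per-block
assignment and its sampler support:

```
Contig phasing model
====================================================
contigs:            2
phase blocks:       8
sweeps (burn-in):   200000 (20000)
seed:               11
----------------------------------------------------
primary_id  rank      a_seg                b_seg  phase  phase1_freq
    ctg000     0 ctg000_h00   ctg000:10778-30778      0     0.000000
    ctg000     1 ctg000_h01   ctg000:38521-58521      0     0.048361
    ctg000     2 ctg000_h02   ctg000:68738-88738      1     0.929089
    ctg000     3 ctg000_h03 ctg000:128856-148856      1     0.907456
    ctg001     0 ctg001_h00    ctg001:1226-21226      0     0.000000
    ctg001     1 ctg001_h01   ctg001:53150-73150      1     0.947739
    ctg001     2 ctg001_h02  ctg001:99746-119746      1     0.918333
    ctg001     3 ctg001_h03 ctg001:137460-157460      1     0.889211
```

`phase = 0` means the block keeps the primary's member in the phase-0
output; `phase1_freq` is the fraction of scored sweeps the block spent in
state 1 — values near 0 or 1 mark confidently phased blocks (block 0 is
pinned at 0 by convention). Scoring the emitted outputs against the
simulated parents confirms the phasing:

```bash
happhase evaluate --parent1 simdata/parent1.fasta \
    --parent2 simdata/parent2.fasta --min-count 1 \
    --asm run/emitted/phase0.fasta --asm run/emitted/phase1.fasta \
    -o report.tsv
# -> overall parental k-mer accuracy: 1.0000 (4 sequences)
```

Every emitted sequence carries markers of a single parent: no phase
switches survived.

The same machinery is available as a library, statsmodels-style:

```python
from happhase.model import ContigPhasingModel
model = ContigPhasingModel.from_files("run/matrix.tsv", "run/segments.tsv",
                                      "run/minced/phase_block_index.tsv")
results = model.fit(n_iter=200_000, burn_in=20_000, seed=11)
print(results.summary())
```

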