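# hybvet

Vetting toolkit for target-capture (Hyb-Seq) bait panels.

Designing a phylogenomic target set means betting thousands of
sequencing dollars on a list of loci that must be *present*,
*single-copy*, and *informative* across the study clade. `hybvet`
implements the quality-control half of that bet: it decides, from
cheap genome-scale summaries, which candidate loci to keep, which to
rebuild, and which to throw away — before bait synthesis, and again
after the first capture experiment. It is aimed at plant (and other
non-model) phylogenomics groups building or refining custom panels.

## What it computes

**Depth-based copy-number vetting** (`hybvet.wgs`). Shotgun or
off-target read depth over a candidate target scales with its genomic
copy number. A target whose median depth deviates from the grand mean
across targets by more than `k` sample standard deviations is flagged
(absent loci sit near zero, duplicates near twice the bulk), per
species, failing overall if it fails anywhere. A three-stage
prefilter (breadth ≥ 80%, depth strictly above but within 2 SD of the
grand mean, length ≥ 1,500 bp) screens large mined candidate sets.

**Coverage-based paralogy statistics** (`hybvet.assembly`). After a
capture experiment, contigs assembled per sample are matched back to
the targets; each target site gets a count *c* of the **distinct**
contigs covering it. With *L* the target length, *l₀* the uncovered
sites and *l_{c≥2}* the sites covered twice or more:

    P = l_{c≥2} / (L − l₀)      paralogy
    M = l₀ / L                  missingness
    C = mean c over c ≥ 1       copy-number proxy

Per-sample statistics populate a samples × targets matrix; targets
with mean P > 0.40 (in either of two reference forms) or mean
M > 0.40 are flagged, and samples whose P deviates from the per-target
means by > 0.20 on average (a ploidy signature) are reported.

**Full-gene target extraction** (`hybvet.extract`). Protein-vs-genome
hits place each target on a draft-genome scaffold; targets mapping to
more than one scaffold are rejected, coverage of > 70% of the protein
is required, and the spanned region — exons *and* introns — is
extracted, reverse-complemented as needed, then re-vetted by depth
with fallback to the transcript form.

**Alignment end-trimming and informativeness** (`hybvet.msa`). A
majority-rule consensus is computed once per alignment; each row is
trimmed against it by a 50-column sliding window that recodes
sub-0.8-identity ends to gaps, working inward from both edges.
Parsimony-informative sites (≥ 2 bases each in ≥ 2 rows) are counted
per alignment, and per-gene intron content is summarized.

**Synthetic data** (`hybvet.simulate`). Seeded generators for every
input format — targets with planted copy numbers, Poisson depth
tables, capture-assembly hit tables, exon/intron genes in scaffolds,
alignments with planted terminal junk — so the whole suite is testable
without external data. See `docs/methods.md` for models, parameter
defaults and limitations.

## Worked example

Simulate a panel of 115 candidate targets (100 single-copy, 10
duplicated, 5 absent) with Poisson read depth at 30× per copy, then
vet it:

```console
$ hybvet simulate --preset wgs-vet --seed 7 --out demo
wrote wgs-vet fixture to demo
$ hybvet vet-wgs --targets demo/targets.fasta --depth species1=demo/depth.tsv \
    --out demo/verdicts.tsv
100/115 targets passed depth vetting
$ head -3 demo/verdicts.tsv
target_id   species1_median  species1_mean  species1_breadth  verdict  reason
target0001  0.0              0.0            0.0               fail     depth_outlier
target0002  30.0             29.941         1.0               pass     pass
```

The 15 failures are exactly the 10 planted duplicates (median ≈ 60,
far above the grand mean ≈ 31) and the 5 planted absences (median 0);
all 100 single-copy targets pass. `demo/ground_truth.tsv` holds the
planted copy numbers for comparison.

Trimming a simulated alignment with junk-laden ends:

```console
$ hybvet simulate --preset msa --seed 7 --out demo_msa
$ hybvet trim-msa --in demo_msa/alignment.fasta --out demo_msa/trimmed.fasta \
    --report demo_msa/report.tsv
recoded 201 characters across 8 sequences
$ head -4 demo_msa/report.tsv
seq_id  head_recoded  tail_recoded  forward_stop  reverse_stop
seq1    51            50            2             1
seq2    50            50            1             1
seq3    0             0             0             0
```

Only the two rows carrying planted junk are recoded; the clean rows
stop at the first window. Other subcommands: `prefilter-offtarget`,
`vet-assemblies`, `extract-genes`, `pi-sites`.

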