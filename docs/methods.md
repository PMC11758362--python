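# Methods

`hybvet` vets candidate loci for target-capture (Hyb-Seq) bait panels.
Its four analysis stages share one premise: cheap, unbiased sequence
summaries — per-position read depth from shotgun reads, and per-site
hit coverage from capture assemblies — carry enough copy-number signal
to decide, per locus, whether it is present, single-copy, and worth
the bait footprint. This note records the models, the parameters that
matter, the numerical conventions, and what the synthetic fixtures do
and do not show.

## Depth-based copy-number vetting

Mapped read depth from whole-genome shotgun (or off-target capture)
reads is treated as a per-position count whose expectation scales with
genomic copy number: a missing target has depth near zero, a
duplicated one roughly twice the depth of the single-copy bulk,
because reads from both copies map to the one reference. Two cascades
build on this.

**Median-depth outlier vet** (`wgs.vet_by_median_depth`). Per species,
the grand mean and sample standard deviation (n − 1 denominator; the
panels involved are small) are computed over per-target median depths,
and a target fails iff its median deviates from the grand mean by
strictly more than `k_sd` (default 1.0) standard deviations. A target
failing in *any* tested species fails overall — the panel must work
across the clade, so one species' evidence of duplication or absence
suffices. Absent targets (all-zero depth) stay in the grand
statistics; dropping them would silently shift the threshold for
everything else.

The phrase "median depth vs the mean depth across all targets" admits
two readings (grand statistics over medians or over means). We take
the grand baseline over the *same* statistic being tested — medians
for the median vet, means in the prefilter — because mixing them makes
the test statistic and its baseline incommensurable under skew. The
`grand_statistic` knob switches both together.

The median (even count: mean of the middle two) is the test statistic
because it is insensitive to localized pile-ups (repeats, chimeric
joins) that inflate the mean. Verdicts are scale-invariant: depth
rescaling multiplies deviations and SD alike, so sequencing effort
does not change who fails. Mapping-quality filtering (e.g. MAPQ > 20)
belongs upstream, when the depth table is produced.

**Off-target prefilter** (`wgs.offtarget_prefilter`), for screening
thousands of mined candidates with sparse off-target reads, in order:
(1) breadth — at least 80% of the length covered by ≥ 1 read (absence
test robust to low depth); (2) depth — mean depth strictly above, but
within 2 SD of, the grand mean (below the mean suggests partial
presence; far above suggests multi-copy); (3) length — at least
1,500 bp (bait economics: short loci waste probe tiling). Grand
statistics are computed over all input genes, before the breadth
filter, so stage order cannot silently change the threshold. The
reason code reports the first failed stage. Boundary semantics
throughout: "more than" ⇒ strict `>`, "at least 80%" ⇒ `≥`,
"< 1,500 bp" ⇒ strict `<`.

`wgs.expected_coverage` is the planning arithmetic
`n_pairs × bases_per_pair / footprint`, with a nearest-ten reporter.

## Coverage-based paralogy statistics

After a capture experiment, each sample's assembled contigs are
matched back to the targets (tabular 12-column hits; matches shorter
than 150 bp or below 70% identity are discarded — boundary kept). Each
target site i gets a count c_i = number of **distinct contigs** with at
least one match covering it. Distinctness is the load-bearing choice:
a fragmented or chimeric contig producing several self-overlapping
split hits still counts once, so fragmentation cannot masquerade as
duplication. Strand never matters; only the normalized subject
interval does.

With L the target length, l_0 the uncovered sites and l_{c≥2} the
sites covered twice or more:

    P = l_{c≥2} / (L − l_0)    paralogy (undefined when l_0 = L)
    M = l_0 / L                missingness
    C = mean c_i over c_i ≥ 1  copy-number proxy (undefined when l_0 = L)

P conditions on covered length so that missingness does not dilute
paralogy. Undefined cells are excluded from all means — a fully
missing target is no evidence of single-copy status. Note the
consequence that P is not monotone under added coverage in general:
a new contig covering previously uncovered sites grows the
denominator without touching l_{c≥2}; c_i, l_{c≥2} and (1 − M) are the
monotone quantities, and the property tests assert exactly those.

Across samples these statistics form the samples × targets paralogy
matrix. Targets are flagged as paralogs when mean P across samples is
strictly above 0.40 in either of two hit sets (against the actual
targets and against their CDS forms — running both catches intron-only
artifacts), and as poorly recovered when mean M is strictly above 0.40
on the target-based matrix. Samples whose P deviates from the
per-target mean by more than 0.20 on average (undefined cells excluded
pairwise) are flagged as outliers; a genome-wide shift of that size is
a ploidy signature, not per-locus paralogy. No sample is excluded from
the per-target means by default (`drop_samples` exists): excluding
outliers before flagging them would be circular. The per-sample
length-ratio flag (second-longest contig strictly above 0.75 of the
longest) is provided as the cheaper, less sensitive cross-check.

## Full-gene extraction from a draft genome

To include introns in baits, targets are re-derived from a draft
assembly: protein translations of candidate targets are matched to the
scaffolds, and for each target the gene's genomic span is taken as
`max(end) − min(start)` over qualifying hits (identity ≥ 70%, E-value
strictly < 1e-6) — exons plus everything between them. Scaffolds under
500 bp are dropped up front as assembly noise.

Qualifying hits on two or more scaffolds reject the target outright:
a split mapping may be a truncated assembly or a tandem duplicate, and
a half-gene bait is worse than a transcript bait. Otherwise strictly
more than 70% of the *protein* length must be covered by the union of
query intervals. Coverage is measured on the query because the protein
is the fixed yardstick — subject-side spans inflate with intron
content. The region's strand is that of the highest-bit-score hit;
mixed-strand hit sets warn and use the same rule, with a deterministic
tie-break (bit score desc, then scaffold id, then start) so hit order
never changes the result. Extraction cuts `scaffold[start:end)` and
reverse-complements minus-strand genes.

Two fallback rules keep the panel honest: a supercontig strictly
shorter than 70% of its reference CDS is replaced by the CDS (the
supercontig's internal make-up is not inspected), and extracted
genomic forms are re-vetted by depth — failures revert to their
already-vetted transcript form (`revert_failed_genomic`).

Coordinates are 0-based half-open everywhere inside the package; the
1-based inclusive on-disk conventions of hit and depth tables are
converted exactly once, at the I/O boundary, which is the cheapest way
to keep off-by-one errors out of interval arithmetic. Minus-strand
hits (descending subject coordinates) are normalized on read with an
explicit strand flag; normalization is involutive.

## Consensus-referenced end-trimming ("chomping")

Alignment ends of individual sequences often carry mis-assembled or
misaligned flanking sequence. The chomper computes the majority-rule
consensus once per alignment (per column, the most frequent of
A/C/G/T case-folded, ignoring gaps and ambiguity codes; ties break
A < C < G < T; empty columns give `-`) and trims every row against it
independently: two rounds (forward and reverse), each sliding a
50-column window inward with stride 1, recoding the row's non-gap
characters to `-` in every window whose identity to the consensus is
below 0.8, stopping at the first window that reaches it.

Identity is matches / comparable, over columns where both consensus
and row have an unambiguous base; a window with no comparable column
scores 0, so trimming continues through gap runs rather than stopping
at them. A consequence worth knowing: during the crawl the leading
window is mostly freshly-recoded gaps, so identity can rest on very
few columns, and a chance match there stops the round early inside
residual junk. This is inherent to the windowed local decision; the
synthetic fixtures provide a `mismatch` junk mode (junk guaranteed
below threshold) when exact planted-junk recovery is being asserted.

The consensus is deliberately *not* recomputed between rows or rounds:
it is a fixed reference, which makes the operation idempotent and
row-order-independent. Recoding never deletes columns (an optional
post-step drops columns left all-gap); general gappy-column curation
is out of scope, belonging to dedicated trimming tools.

Site classification: a column is parsimony-informative iff at least
two distinct unambiguous bases each occur in at least two rows;
columns with one base are constant, other variable columns
singleton-variable, base-free columns degenerate — a partition, so the
four counts always sum to the column count. `intron_fraction`
summarizes per-sample intron content per gene, using the maximum
assembled gene length across samples as the proxy for the true length
(a deliberate underestimate for genes whose introns were never fully
recovered).

## Synthetic data: what it shows and what it does not

The generators (`hybvet.simulate`) produce every input format the
suite consumes, with planted ground truth, deterministically per seed.
Defaults encode the study conditions the suite is sized for: 115
targets of 1,500–3,000 bp — 100 single-copy, 10 duplicated, 5 absent —
with Poisson depth at base 30 per copy and 10% divergence between
duplicate copies (typical of reasonably recent plant gene duplicates).
MSA fixtures default to 8 rows × 400 columns at 2% core divergence
with 55–80 columns of terminal junk, deliberately wider than the
50-column window. Hit tables are generated directly with exact
coordinates instead of running a search binary, so the tests exercise
the statistics, not an aligner.

Capture-assembly fixtures tile single-copy targets with 1–3 adjacent
contigs (c = 1 everywhere covered, hence P = 0) and add a
second-copy contig overlapping ≥ 85% of a duplicated target's length
(hence P ≥ 0.85); gene fixtures embed each target's codon-aligned
exons, separated by 200–500 bp introns, in its own scaffold on a
random strand, optionally splitting one gene across two scaffolds.

Passing on these fixtures therefore demonstrates the estimators'
correctness and the filters' discrimination *under the stated model*:
independent Poisson depth with no GC, mappability or repeat structure,
perfect hit coordinates, integer copy numbers, and one sample per
depth table. It does not demonstrate robustness to overdispersed
coverage (a negative-binomial depth option exists to probe this),
mis-mapped reads, collapsed repeats, or partial-length duplicates —
on real data the SD-based thresholds are exactly the knobs to revisit.

## Problem sizes used by the checks

The test suite and the reproduction script run at desk scale, chosen
so the full battery completes in seconds: oracle cross-checks on 200
random coverage instances (L ≤ 500, ≤ 50 hits) and 100 random
alignments (≤ 10 rows, ≤ 260 columns) against naive brute-force
references; parameter recovery over 20 simulated panels at the default
study conditions; 100 planted genes for the extraction round trip; and
engineered fixtures with planted flag counts (e.g. 303 targets with
13 + 5 flags, cascades of 134, 1,021, 114 and 87 candidates) for the
bookkeeping checks.
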