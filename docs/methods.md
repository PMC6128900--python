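# Methods

This note documents the models and procedures implemented in
`pirnakit`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions made
where the design was genuinely open.

## Read processing

Reads are collapsed to unique sequences with aggregated copy counts;
sequences longer than 36 nt (too long for any piRNA) and reads
containing N are rejected. RNA alphabets are normalized to DNA (U→T)
on input.

The low-complexity filter removes a read iff, for some motif length
k ∈ 1..5, the longest contiguous run of perfect tandem repeats of a
single k-mer covers ≥ 75 % of the read. This is a deterministic,
testable contract for the intent of classic "duster"-style filters
(whose exact windows/entropy defaults are not published): homopolymers
and short tandem repeats map promiscuously and carry no positional
information. Lowering the coverage threshold only ever removes more
reads (monotonicity is property-tested), and filtering commutes with
collapsing.

## Mapping and the mismatch-classification filter

piRNAs are enriched for transposon-derived sequences (multimappers)
and both miRNAs and piRNAs are post-transcriptionally edited and
3′-tailed, so the mapper must (a) report *all* placements, not one
best hit, and (b) treat a terminal run of mismatches differently from
internal ones.

`map_reads` reports every placement of a read with ≤ `max_mismatch`
(default 3) mismatches on either strand. It uses disjoint exact seeds
(pigeonhole: m+1 seeds guarantee one exact seed under m mismatches)
over a base-5 rolling-hash index of genomic windows, and verifies
every candidate base-by-base — so its output provably equals an
exhaustive window-by-window scan, which the test suite checks against
an independent brute-force oracle on random genomes. Seed length is
capped at 16 so all read lengths share one index; reads shorter than
m+1 bases fall back to scanning every window. Hash collisions are
harmless (all candidates are verified). Output ordering is
(read, chrom, start, strand)-sorted and byte-reproducible.

Mismatch positions are expressed in 1-based read coordinates from the
5′ end. The *non-template 3′* count is the maximal contiguous mismatch
run anchored at the 3′ terminus — the natural formalization of
untemplated tailing; everything else is internal. `filter_alignments`
discards placements with > 2 non-template 3′ nt or > 1 internal
mismatch, keeps only tied-best placements per read (by total mismatch
count), and never discards equal-quality placements of multimappers.
Downstream, every multimapper's copy count is apportioned 1/n across
its retained placements, which keeps all count-weighted statistics
conservative. We treat the mismatch cap of 3 as the total before
classification; no cap is placed on the number of placements per read.

Coordinates are 0-based half-open internally; GFF3 and RepeatMasker
coordinates (1-based inclusive) are converted at the file boundary.
The minus-strand 5′ end of an alignment `[start, end)` is `end − 1`.

## Annotation hierarchy

Reads are matched against reference classes in priority order
miRNA < tRNA < rRNA < other ncRNA < mRNA (lower rank matched first),
using the same mismatch tolerance as genomic mapping; each read is
assigned to the highest-priority class containing a match, and
remaining reads are "intergenic" — the piRNA candidate pool. This is
deliberately a simplified hierarchical annotator: its downstream role
is only to define the intergenic fraction and the annotated
background, not to reproduce a full annotation suite.

tRNA references are extended with the non-template CCA before
matching, since mature tRNAs (and hence their 3′ fragments) carry it.
A tRNA-matching read is a **3′ tRF** iff it aligns sense within the
CCA-extended tRNA with its 3′ terminus exactly at the extended 3′ end;
the subtype records the isoacceptor.

### Primary-piRNA fraction from 5′U composition

Cluster calling can over- or under-estimate the primary piRNA
content, so an independent arithmetic estimate is computed from the
5′U composition of 24–29 nt reads. The unannotated pool is modelled
as a two-component mixture of genuine primary piRNAs (5′U fraction
`u_ref`, measured from cluster-mapped reads, the best available proxy)
and background (5′U fraction `u_bg`, measured from annotated reads in
the same length window). The observed fraction `u_obs` then gives the
mixing proportion

    f_pi = (u_obs − u_bg) / (u_ref − u_bg),   clamped to [0, 1],

and f_pi × (unannotated 24–29 nt copies) estimates the primary piRNA
count. All fractions are count-weighted. If `u_ref = u_bg` the
estimate is undefined and flagged rather than raised. Recovery of
injected fractions {0, 0.25, 0.5, 0.75, 1} at n = 50 000 reads is
within 0.05 absolute (acceptance-tested; typical error < 0.02). A
per-length refinement (computing the mixture separately per read
length) is possible but not enabled: at desk scale it only adds
variance.

## Ping-pong statistics

With c₊(p), c₋(p) the apportioned counts of 5′ ends at position p on
the two strands, the overlap score is

    S(o) = Σ_chrom Σ_p c₊(p) · c₋(p + o − 1),      o = 1..20,

so o = 10 counts read pairs with the canonical 10 bp 5′ overlap
produced by PIWI slicing. The product form (pair-count
interpretation) is the declared contract; it equals an all-pairs
enumeration, which is property-tested. The Z-score of S(10) uses the
19 other offsets as background with the sample (n−1) standard
deviation, and p = 1 − Φ(z). An all-zero or zero-variance background
returns NaN sentinels instead of raising.

**Bootstrap (pps-mbr / ppr-mbr).** Libraries of different depth are
compared via pseudo-replicates: each replicate draws R reads with
replacement from the count-weighted read distribution (whole reads
with all their placements, preserving multimapping structure; a
single multinomial draw per replicate). Per replicate, pps = S(10)
and ppr = the summed drawn count of reads with at least one placement
participating in a 10 bp-overlap pair (each read counted once,
regardless of how many loci or partner roles). Mean and SD over
replicates are reported (median by flag). With the default
R = 1 000 000 the values are literally "per million bootstrapped
reads"; for smaller R, ppr is scaled by 1e6/R (it is a fraction of
the replicate) and pps by (1e6/R)² (it is a pair count, quadratic in
replicate size). The replicate mean of pps converges to the exact
multinomial expectation E[nᵢnⱼ] = R(R−1)pᵢpⱼ, which is tested in
closed form on a small fixture. Note that ppr/R approaches the true
participating-read fraction only when R is several times the library
size (otherwise pairs whose only partner is a low-copy read drop out
of some replicates); the acceptance runs use R = 5× the library
count.

**Length matrix and base bias.** For every end pair in ping-pong
register, the apportioned weight product is added to the unordered
cell {L₊, L₋}; the mode cell summarizes whether the pairing is
heterotypic (e.g. 25/29 nt, two PIWI paralogs) or homotypic (29/29).
Positional base bias is reported as sequence-logo information
heights: ICᵢ = 2 + Σ_b p_b log₂ p_b and height(b) = p_b·ICᵢ, with the
1U height at position 1 and the 10A height at position 10.

## piRNA cluster prediction

Prediction runs on the intergenic 24–32 nt fraction. A sliding window
(5 kb, step 1 kb) qualifies when all gates pass:

| gate | default | rationale |
|---|---|---|
| 5′-end density | ≥ 5 rpm/kb | read-dense loci at library scale |
| distinct sequences | ≥ 10 | excludes single-sequence piles |
| 1U-or-10A fraction | ≥ 0.75 | piRNA composition signature |
| strand coherence | ≥ 0.75 | single-stranded precursor transcript |
| internal read gap | ≤ 1000 bp | precursor-derived reads tile the locus |
| trimmed span | ≥ 1000 bp | minimum cluster extent |

Strand coherence is computed over **5′U reads** (the putative
primaries): ping-pong responder piRNAs map antisense within a cluster,
so at an appreciable ping-pong rate the all-read main-strand fraction
drops toward (1+ρ·a)/(1+ρ) and would reject genuine mono-directional
clusters; restricting the vote to 5′U reads preserves the gate's
intent — the orientation of the precursor — at any ping-pong rate. A
window failing the mono-directional gate still qualifies if it splits
at a single point into two strand-homogeneous halves (bi-directional
cluster).

The two structural gates suppress transposon-copy artifacts: genuine
clusters derive from a precursor transcript, so reads tile the locus
contiguously, whereas isolated transposon copies attract piles of
multimapping piRNAs a few hundred bp wide separated by empty
sequence. Merged qualifying windows are therefore split wherever more
than 1 kb of internal sequence carries no read, each block is trimmed
to the outermost read termini, and blocks shorter than 1 kb (the
minimum cluster extent — exactly the isolated-copy piles) are
dropped. Candidates from multiple
libraries are condensed by transitively merging intervals that overlap
or lie < 10 kb apart (strictly; a 10 000 bp gap does not merge).
Merging is idempotent and order-independent.

rpm(cluster, library) counts placements whose **5′ end** lies in the
cluster (apportioned, ×1e6 / library total); 5′-end containment
rather than any-overlap keeps each placement attributable to exactly
one cluster. Expression classification takes the top 100 clusters by
maximum rpm, scales each profile to [0, 1] between its own extremes,
clusters rows with average linkage on 1 − Pearson distance, cuts into
k = 4 classes, and renumbers classes by mean peak position. Constant
rows (Pearson undefined) fall back to a scaled Euclidean distance and
are flagged. A validation report flags clusters whose mapped signal
is > 50 % rRNA/tRNA-annotated (guards against ncRNA loci masquerading
as clusters).

## Transposon landscape and enrichment

RepeatMasker `.out` records (3 header lines; column 2 = % divergence;
columns 5–7 = 1-based inclusive query coordinates; 'C' = minus
strand) are parsed into 0-based half-open records; unclassified
repeats are kept under family "Unknown". Landscapes bin each record's
bp overlap with the scope (genome, or the merged cluster intervals)
by floor(% divergence), bins 0–50 with ≥ 50 % collected in the last
bin so per-family bp totals are conserved exactly. Landscapes count
records individually; fractions and enrichment use per-family
*unioned* intervals so nested RepeatMasker hits cannot push a
fraction past 100 %. Enrichment fold = (family bp in clusters /
cluster bp) / (family bp / genome bp); families absent genome-wide
are flagged NaN rather than divided. Gene content is the bp fraction
of each cluster covered by the union of CDS features from a GFF3.

## Synthetic studies (what the generator emulates)

The generator plants, on a random genome (default 2 Mb over 5
chromosomes): 20 strand-coherent piRNA clusters (3–8 kb, ≥ 25 kb
apart); transposon families at target genomic fractions with planted
cluster enrichment folds (copy numbers are deterministic given the
targets — copies = target bp / consensus length, placed without
intra-family overlap, per-copy divergence drawn from a family normal
and realized as point mutations); tRNA loci (with templated CCA so 3′
tRFs map), miRNA loci, and protein-coding genes (uniformly placed, so
a small fraction overlaps clusters by chance, producing realistic
nonzero cluster gene content and an mRNA-subset ping-pong signal).

Reads (default 50 000) comprise primary piRNAs from clusters (lengths
≈ 28–30 nt, 5′U forced with probability 0.8, a 10 % antisense
fraction reflecting imperfect strandedness), secondary piRNAs spawned
by a fraction ρ of primaries on the opposite strand with exactly
10 bp 5′ overlap (lengths ≈ 24–26 nt; the responder 10A is the
complement of the initiator 1U, the same genomic base, forced with
probability 1−(1−p_1U)(1−p_10A)), and background: miRNAs (40 %), 3′
tRFs (12 %), mRNA degradation fragments 18–30 nt sampled sense from
gene loci (6 % — the annotated class that spans the 24–29 nt window,
required for the 5′U estimator's background term), and low-complexity
reads (3 %). Copy counts are geometric (mean 2) to exercise
collapsing. Forced bases are written into the genome *before* read
extraction, so every non-low-complexity read maps with zero
mismatches; untemplated 3′ tails (1–2 random bases appended to the
read only) are available by flag to exercise the alignment filter.
The manifest records cluster coordinates, per-sequence labels, the
realized per-family bp, and the participating-read fraction computed
by an all-pairs 10 bp-overlap oracle on the true coordinates (so
chance pairings count, exactly as the mapped-data statistic sees
them).

What the generator does **not** emulate: sequencing error and quality
variation, realistic transposon sequence evolution (copies are
mutated consensus, not phylogenies), expression heterogeneity across
clusters, RNA secondary-structure-driven biases, and contamination.
Passing recovery tests therefore demonstrates correctness of the
statistics and the recovery machinery under clean conditions, not
robustness to every artifact of real libraries.

## Problem sizes and seeds

The test suite and the acceptance script run at desk scale: mapping
oracle equivalence on fifty 5 kb genomes × 500 reads at ≤ 3
mismatches; ping-pong null/power on one hundred seeded 20 000-read
studies each (400 kb genomes); ppr recovery at ρ ∈ {0.1, 0.3, 0.5}
with 20 replicates of 5× the library count; cluster and enrichment
recovery on the full 2 Mb default. All randomness in the acceptance
script derives from its `--seed`; the pipeline fans a single config
seed out to per-stage seeds via a CRC of the stage name, so stages
are individually reproducible.

## Known limitations

* The annotator matches whole reads against references; it does not
  model precursor processing (e.g. miRNA arm selection) or
  multi-species annotation.
* ppr-mbr is a bootstrap-expected quantity; at replicate sizes near
  or below the library size it underestimates the participating-read
  fraction (see above).
* The cluster predictor is a deterministic gate, not a probabilistic
  density model; its thresholds are configurable but its decisions
  are hard.
* Indels are not modelled in mapping (mismatches only), matching the
  upstream study design.
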