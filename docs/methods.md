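# Methods

## Overview

`vhhscreen` analyses phage-display panning experiments in which one
unselected VHH library (round 0) is split over several whole-cell panning
arms, one per target tumor cell line, and each arm's final round is
sequenced as a 2×300 bp paired-end amplicon library. The pipeline runs in
five stages — read processing, CDR3 annotation, enrichment ranking,
phylogeny/clustering, cross-reactivity grouping — plus a synthetic-data
generator that provides ground-truthed inputs for validation.

## Read processing

**Merging.** Mates are merged on the best ungapped overlap of R1 against
the reverse complement of R2 (both orientations are tried, since sequencer
output strand is not guaranteed). Among overlaps of ≥ `min_overlap` bases
(default 20) with mismatch fraction ≤ `max_mismatch_frac` (default 0.1),
the overlap maximizing matched bases wins, ties going to the longer
overlap. Candidate offsets come from exact 20-mer seeds with an exhaustive
scan as fallback, so the result equals the full scan whenever any seed in
the overlap is error-free. At overlap mismatches the consensus takes the
higher-quality base (quality = difference of the two Phred scores, floor
2); agreeing bases get summed quality capped at 60.

**Filtering.** A merged read passes if its expected error count
Σ 10^(−Q/10) is at most `max_expected_errors` (default 1.0), the standard
amplicon filter. Raising the threshold can only admit more reads
(monotonicity is property-tested).

**Trimming and hinge classification.** The common forward primer
(`GGTGCAGCTCGTGGAGTCTGGGGG`) must start within `primer_window` (default 5)
bases of the 5′ end; the reverse-complemented site of one of the two
hinge-specific reverse primers (IgG2 short hinge
`GGGGTCTTCGCTGTGGTGCGC`, IgG3 long hinge `GTGGTTTTGGTGTCTTGGGTTC`) within
the same window of the 3′ end. Matching is IUPAC-aware (a pattern base
matches when its base set intersects the read's) with up to
`max_primer_mismatches` (default 2) mismatches. The hinge class follows
the better-matching reverse primer; an exact tie is rejected as ambiguous
and counted separately. The insert excludes both primers.

**Translation.** The forward primer's 3′ end anchors the reading frame
(offset configurable, default 0 — the only reconstructible convention when
the amplicon is primer-defined). Translation uses the standard code;
ambiguous codons give `X`, a trailing partial codon is dropped, internal
stops reject the read (`stop_codon`), and products shorter than
`min_aa_len` (default 90, below any plausible VHH) reject as `too_short`.
Identical merged sequences are collapsed before trimming/translation; the
per-read attrition report partitions the input pair count exactly at every
stage.

## CDR3 annotation

CDR3 boundaries follow an IMGT-like convention: the cysteine anchor is the
C of the last `[YFW][YFAVLI]C` motif whose C lies within the first 110
residues (fallback: last C before 110), the tryptophan anchor the W of the
first `WG.G` at or after cys+4 (fallback: first W after the cysteine).
CDR3 is the loop strictly between the anchors (3–40 residues;
`include_anchors` is available since downstream grouping only requires
internal consistency). Failures are statuses, not exceptions, so attrition
stays countable.

CDR3 identity is the normalized edit similarity `(L − d)/L` with
`L = max(|a|,|b|)` and `d` the unit-cost global edit distance — the
matches-over-columns score of the minimal-column optimal alignment. This
form is exactly symmetric; a traceback-dependent column count is not,
because optimal alignments are not unique.

## Enrichment ranking

Clonotype identity is the exact amino-acid sequence (synonymous nucleotide
variants collapse). Frequencies are relative to each library's merged-read
total. The amplification fold is
`(n_final/N_final) / (n_0,eff/N_0)`, where a clone unseen at round 0 gets
an effective count of 1 (`floor1`, default; `pseudo0.5` optional). The
floor keeps folds finite and conservative but deliberately breaks scale
invariance for round-0-absent clones (observed clones are exactly
scale-invariant); such clones are flagged `r0_floored` in the output.
Ranking is by descending fold with deterministic tie-breaks (higher final
frequency, then lexicographic sequence); clone ids are
`<library>_<rank>`. Summary percentages are rounded half-up to two
decimals; full precision is kept internally.

`counts_from_marginals` reconstructs a count multiset from published
marginals (merged total, singleton count, unique count, top count) by
spreading the residual reads evenly over the mid-abundance clones; it
exists to validate the summary arithmetic against published tables when
only marginals are known.

## Phylogeny and clustering

Pairwise distances are p-distances on global pairwise alignments
(1 − matches/columns, terminal gap runs excluded so overhangs are length
differences, not substitutions). No multiple alignment is used: top-K sets
are ≤ 200 sequences, i.e. ≤ 19,900 pairwise alignments. p-distances may
violate the triangle inequality; nothing downstream assumes it.

Neighbor joining is the Saitou–Nei algorithm with the Studier–Keppler
criterion `Q(i,j) = (m−2)d(i,j) − r_i − r_j`. Ties are broken by the
smallest (i, j) index pair in the current matrix order, so trees are
bit-reproducible. Limb lengths use the standard formulas; a negative limb
is clamped to 0 with the deficit moved to its sister (preserving the pair
sum), which keeps recovery of additive matrices exact. The unrooted result
is returned with the final trifurcation as root. On additive matrices from
random 4–16 leaf trees the implementation recovers topology
(Robinson–Foulds 0) and path lengths to < 1e-9; it is cross-checked
against an independent NJ implementation in the test suite.

Clusters are leaf sets separated by a single tree edge (either side of any
bipartition, plus the full leaf set) whose minimum pairwise homology
(1 − p-distance) meets the threshold — default 0.988 for cluster calling,
with 0.98 used for relaxed CDR3 grouping — and that have ≥ 2 members.
Overlapping candidates are resolved by preferring larger clusters, so the
result is a disjoint collection. A cluster from one library is
mono-specific, otherwise mixed.

## Cross-reactivity and the candidate report

Top-K clones from all libraries are grouped by CDR3: exact string identity
by default, or single-linkage at ≥ 0.98 identity in relaxed mode. Groups
spanning ≥ 2 libraries are flagged cross-reactive and labelled X, Y, Z, …
in order of multiplicity and peak fold. The candidate report applies an
evidence hierarchy: CDR3 sharing outranks tree-cluster purity, because an
identical binding loop independently enriched by two cell lines is direct
evidence of cross-reactivity, whereas cluster purity is only absence of
evidence. Cross-reactive CDR3 groups claim their members first; remaining
cluster members form one row per cluster (mono- or multi-specific by
library composition); everything else is listed as unclustered singletons,
so every top-K clone appears exactly once. Representatives are the
highest-fold member, ties to the earliest library name. All calls are
computational predictions of specificity, not validated binding.

## The panning simulator

**Repertoire.** Clones share fixed framework scaffolds carrying the
canonical anchors (FR3 ends `…YYC`, FR4 starts `WGQG`) with random 8-mer
CDR1/CDR2 and 5–18-mer CDR3 (alphabet without C/W so anchors stay
unambiguous). Each clone is a short-hinge (IgG2) or long-hinge (IgG3)
isotype with the matching hinge tail and reverse-primer site; the
nucleotide sequence is a random synonymous codon spelling flanked by the
primer regions, so trimming + frame-0 translation reproduce the amino-acid
truth exactly.

**Selection.** Round-0 composition is Dirichlet(α = 0.1) — a skewed
immune-library spectrum with a few dominant clones and a long singleton
tail — drawn once per experiment and shared by all arms. 2% of clones are
single-line binders (allocated round-robin over the lines) and 0.5%
cross-reactive (2–3 lines); binder weights are lognormal(μ = 3, σ = 0.5)
per line (median ≈ 20), all other weights 1. Subtraction by absorbent
cells is modelled implicitly: a clone's weight is its post-subtraction
advantage for the target line. Each round draws a multinomial of
`reads_per_round` (default 100,000) reads with probability ∝ previous
frequency × weight; default 2 rounds.

**Sequencing.** R1 is the 5′ 300 nt of the amplicon, R2 the reverse
complement of the 3′ 300 nt, so mates overlap in the middle. Per-base
qualities follow an Illumina-like cycle profile — a high plateau with a
steep fall-off in the last ~50 cycles (error ∝ 0.03 + 12.6·x¹², x the
relative cycle), rescaled so the mean per-base error equals
`per_base_error_rate` (default 0.005) — and substitutions are injected at
exactly the rate each emitted quality implies, so Phred scores are
calibrated. The cycle shape matters: each mate's error-prone tail falls in
the overlap where the partner's accurate head covers the same position, so
the merge consensus corrects most errors — the geometry long-amplicon
paired-end protocols are designed around. A position-independent error
model with the same mean would instead scatter unresolvable errors across
the read and fragment dominant clones into artifact clonotypes far beyond
what calibrated chemistry produces.

**What the simulator does not model:** indels (substitution-only, so frame
integrity is a controlled variable), chimeras, PCR amplification bias,
barcode demultiplexing (inputs are one FASTQ pair per library), phage
biology (propagation, helper phage, MOI), and cell-level effects (FACS
gating, viability). Passing end-to-end tests therefore demonstrates
correct recovery under calibrated substitution noise and multinomial
sampling, not robustness to chimeric or indel-rich libraries.

## Validation problem sizes

The test suite validates arithmetic against published summary-table values
exactly, the fold statistic against exact rational arithmetic (10⁵ random
tables), NJ against 200 random additive matrices, and the full pipeline on
a default-scale experiment: 1,000 clones, 4 cell lines, 2 rounds, 10⁵
reads/round, 0.5% error — about half a million read pairs end to end,
chosen as the smallest experiment that exercises dominant-clone artifacts,
weak binders near the fold-10 boundary, and multi-library CDR3 sharing at
once. Smaller error-free experiments verify the lossless round trip: at
error rate 0 the pipeline's dereplicated count tables equal the
simulator's ground truth exactly.

When scoring predictions against ground truth, an observed sequence is
attributed to its source clone by exact match or, failing that, the
nearest truth clone within edit distance 3: sequencing errors produce
near-identical images of a clone whose physical binding profile is
unchanged.

## Known limitations

* Exact amino-acid dereplication means sequencing-error variants of
  abundant clones appear as separate (floored-fold) clonotypes; the tree
  stage re-groups them into clusters, but they occupy top-K slots. This
  mirrors what the strategy does on real data; no denoising is applied.
* The 98%/98.8% homology thresholds are taken as given, not derived; both
  are configurable.
* Cluster candidates are restricted to tree bipartitions; a set of
  mutually homologous leaves that is not separated by a single edge will
  not be reported as one cluster.
* Fold values for clones unseen at round 0 depend on the pseudocount
  policy and should be compared only within a policy.
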