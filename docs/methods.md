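# Methods

This note documents the models, parameter choices and numerical conventions
behind `crossreg`, and what the synthetic benchmarks do and do not show
about real data.

## Coordinates and alphabet

All intervals are 0-based, half-open (BED-compatible); 1-based coordinates
appear only in human-readable reports. The internal alphabet is
`{A,C,G,T,N}`: input is uppercased and RNA `U` is mapped to `T`, so 3'UTR
analysis of AUUUA elements runs on the DNA-sense spelling `ATTTA`. A
promoter is taken to be the 1,000 bp strictly upstream of the TSS on the
gene's strand, reported 5'→3' on that strand with the TSS base excluded;
the package consumes already-extracted sequences and does no genome or
annotation access. Each FASTA record is treated as an independent promoter
variant, with ids `GENE` or `GENE.variant`.

## PWM scoring

A PFM column of counts `n(b,i)` with sum `N_i` becomes log2-odds weights

    w(b,i) = log2( ((n(b,i) + p·q(b)) / (N_i + p)) / q(b) )

with total pseudocount `p` spread proportionally to the background `q`.
Defaults: `p = 0.8`, uniform `q = 0.25` — the standard choice that avoids
−∞ weights while barely moving informative columns; both are configurable.
Window scores are rescaled between the matrix's minimum and maximum
attainable scores (the *relative score*), and the default reporting
threshold is 0.80 of that range, the conventional default of classical
scanning tools. Degenerate cases are pinned down explicitly: a zero score
range yields relative score 1.0; with `p = 0` a zero count makes the
minimum −∞, and the relative score is then defined as 1.0 for the maximal
raw score and 0.0 otherwise (so delta matrices at threshold 1.0 match
exactly the consensus). Windows containing `N` are skipped — a log-odds
model assigns no principled score to an ambiguous base. Hits on both
strands at the same interval are both reported; count tables deduplicate by
interval downstream.

For uniform-column matrices the 0.80 threshold has a sharp combinatorial
meaning: a window passes iff its number of mismatched columns `k` satisfies
`k ≤ 0.2·w`. This drives several design choices below.

## Bundled matrices

The curated matrices the intended application used (database matrices of
that era, plus a literature IRF3 matrix) are not redistributable here, so
the package bundles *synthetic, consensus-derived* matrices
(`data/pfms_synthetic.jaspar`, built by `motif.consensus_to_pfm`). Each
IUPAC consensus column becomes a count column over 20 nominal sites with a
one-count noise floor: a single-base column is 17/1/1/1, a two-base column
9/9/1/1, a three-base column 6/6/6/2, `N` is 5/5/5/5. The consensus
patterns are the published ones where available (IRF3 `GAAASSAAANY`, IRF7
`GAAWNYGAAANY`, canonical RELA `AGGAAATTCCG`) and field-standard motifs
otherwise (κB-site variants for NFKB1/2, REL, RELB; the AP-1 TRE
`TGASTCA`; the SP1 GC-box `GGGGCGGRRY`). Consequences worth knowing:

* Expected chance-hit rates at threshold 0.80 on uniform random 1-kb
  sequences, computed analytically from the construction, are ≈ 4.9
  hits/kb for AP-1 and ≈ 1.4 for SP1 (both strands) — the same order as
  published random-background counts for these factors, with the same
  qualitative ordering (AP-1 far less dataset-specific than SP1).
* Absolute per-gene counts from these matrices are *not* comparable to
  counts produced with specific database matrix versions; users with real
  matrices should load them via `load_pfm_file`.

## Conservation

Conservation is assessed pairwise against a designated reference species
(human in the intended application), since cross-species statements in
this kind of study are pairwise; no joint multi-species criterion is used.
Per-column identity (1 iff both bases equal and neither gapped) is smoothed
by a centered moving average with truncated edge windows. Defaults: window
21 columns, minimum smoothed identity 0.70, minimum region length 21
columns, minimum hit column-overlap 0.5 — common phylogenetic-footprinting
practice; all are knobs. Pairwise percent identity excludes gap–gap columns
from the denominator and counts single-gap columns as mismatches; it is
reported over the whole alignment (whole-promoter), which is the assumed
definition wherever a single "average conservation" number is quoted.

The bundled Needleman–Wunsch aligner (linear gap penalty, deterministic
tie-break diagonal > up > left; defaults match 1, mismatch −1, gap −2) is
plumbing so the pipeline runs without external alignment files; CLUSTAL or
aligned-FASTA alignments are consumed when provided. It is pairwise-only:
multi-species runs align each species to the reference independently.

## ARE classification

The three-class scheme follows the standard taxonomy: class II =
clustered/overlapping pentamers, class I = a single pentamer in an AU-rich
context, class III = AU-rich stretch without a pentamer. The source
literature delegates exact parameters to its references, so defaults were
fixed once at field-plausible values and exposed as `AREParams`:
`cluster_gap` 5 bp (adjacent/overlapping pentamers cluster), `ctx_window`
10 bp per flank with `ctx_at_min` 0.65, `classIII_min_len` 30 bp with
`classIII_at_min` 0.75. Class III sites are maximal unions of qualifying
pentamer-free windows, which makes the output deterministic and
order-independent; classes are mutually exclusive by construction. The
search is sense-strand only, since AREs are mRNA elements.

## Background model

`random_sequences` draws i.i.d. bases (uniform by default; a GC-matched
composition can be supplied since the original procedure's composition is
unstated), with `n_rand = 100` sequences of 1,000 bp as the default
procedure. The empirical p-value uses the add-one permutation-style
estimator `(1 + #{rand count ≥ mean_data}) / (n_rand + 1)`, which is never
zero; "dataset-specific" is reported (never enforced) as `mean_data >
mean_rand` with `p ≤ 0.05`. For exact consensus patterns on uniform
sequences the closed-form expectation `2·(L−w+1)·4^(−w)` serves as an
analytic cross-check. Dataset means average over supplied records; if
promoter variants should be collapsed per gene, collapse before calling.

## ChIP-seq cross-reference

Peaks are read from BED3/BED6/narrowPeak text (narrowPeak column 7 =
signal, column 10 = summit offset, −1 = absent). Support is binary
interval overlap with `min_bp = 1` by default, because "peak in the same
region" statements in the literature are qualitative; signal strength is
carried through but never thresholded. The default coordinate system is
promoter-local; `lift_hits_to_genome` shifts hits into genomic coordinates
when the promoter's genomic interval is known. Disjoint hit/peak sequence
ids trigger a coordinate-system-mismatch warning rather than silent zeros.

## Synthetic data: what it emulates and what it does not

The generators produce promoter-like i.i.d. background with planted PFM
instances (non-overlapping, random strand, sampled per column from the
counts), orthologous families mutated from a common ancestor, UTRs
assembled from fixed ARE feature blocks and inert spacers, and peak files
covering a controlled fraction of true sites.

* **Ortholog model.** Substitutions only (uniform over the three other
  bases), per-site probability equal to the species divergence outside
  conserved blocks and divergence/10 inside; planted instances are written
  identically into all species. Substitution-only evolution makes the
  identity alignment the true alignment, decoupling conservation-caller
  correctness from aligner quality. An optional single-base indel mode
  exists (the truth alignment is gapped accordingly) but the substitution
  model is the tested configuration. Under this model the per-site match
  probability between the reference (divergence 0) and a lineage at
  divergence `d` is exactly `1 − d`, and between two lineages at `d` it is
  `(1−d)² + d²/3` — no transition/transversion bias, no rate
  heterogeneity, no realistic phylogeny.
* **UTR construction.** Class II blocks are `ATTTATTTA`; class I blocks a
  pentamer inside pure-AT 10-nt flanks; class III blocks 36-nt AT runs with
  no `ATTTA` substring. Spacers are GC-dominated with isolated (never
  adjacent) A/T bases steered toward the requested overall AT fraction and
  GC-pinned ends, and are at least 30 nt long, so no classification window
  can bridge two features and no spacer can contain a pentamer or qualify
  as class III. Requested class counts are therefore reproduced exactly by
  construction — which validates the classifier's rules, not its parameter
  choices on real UTRs.
* **Planted-recovery benchmarks** use delta-like (maximum-information)
  24-bp matrices. The width is chosen so the 0.80 threshold admits at most
  4 mismatches (`k ≤ 0.2·w`), putting the chance-hit probability per
  window near 3·10⁻⁹; over the benchmark's 50 kb × 2 strands × 3-matrix
  panel the expected number of spurious family attributions is ~10⁻³, so
  perfect recall with zero decoy families is a property of the
  construction, not of a particular seed. Real motifs are shorter and
  noisier; recall on them degrades with matrix information content, which
  the benchmark does not measure.
* **Peak files** cover each true site independently with the requested
  probability using 150–300 bp peaks. The support fraction estimates the
  coverage only when sites are sparse relative to peak width (≈ 1 site per
  promoter); with dense sites, neighbouring peaks inflate support.

Every generator is bit-reproducible for a fixed seed and emits a JSON
truth file in BED-style coordinates.

## Pipeline and problem sizes

`run_pipeline` is a pure function of (config, input files, seeds): rerunning
with the same config produces byte-identical TSVs, and the run log records
every parameter and seed. The demo dataset and the acceptance script use
1-kb promoters in four species (three genes in the demo), 100 random
background sequences, a 2,100-bp and an 89-bp synthetic UTR, and 200
single-site promoters for the peak-support estimate — sizes at which the
whole suite and the acceptance script each complete in well under a minute
while keeping Monte-Carlo standard errors small relative to the asserted
tolerances.

## Known limitations

* No p-value calibration of PWM scores, no higher-order background models,
  no motif discovery.
* The conservation caller has no substitution-model-based scoring
  (phastCons-like); it is identity-threshold footprinting.
* Real count tables depend on the exact matrix versions and thresholds
  used; with the bundled synthetic matrices only qualitative structure
  (family rollups, overlap patterns, background ordering) is meaningful.
* ChIP-seq support is binary overlap; peak signal is not modeled.
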