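# Methods

This note records the models, numerical conventions and design choices
behind `lemurmhc`, and what the synthetic-data tests do and do not show
about real data.

## Study design being modelled

A 213-bp fragment of MHC class II *DRB* exon 2 is amplified per animal,
cloned, and 24–48 bacterial clones are Sanger-sequenced per animal over
(at least) two independent PCRs. The fragment's first codon encodes
beta-chain residue 8, so it spans residues 8–78 (71 codons). Eighteen of
those codons are antigen-binding sites (ABS) by homology with the human DR
molecule (residues 9, 11, 13, 28, 30, 32, 37, 38, 47, 56, 60, 61, 65, 68,
70, 71, 74, 78); six further ABS residues (81, 82, 85, 86, 88, 89) lie
outside the amplicon and are not analysable. Residue *r* maps to 1-based
codon index *r* − 7.

## Allele calling

1. **Identity screen.** Each distinct clone sequence is compared against a
   panel of previously published alleles; a clone is retained iff its best
   identity is **strictly greater** than the threshold (default 0.95).
   Identity is matches over aligned columns of a global Needleman–Wunsch
   alignment (match +1, mismatch 0, linear gap −2), a deterministic,
   dependency-free proxy for the BLAST identity a lab would use. Columns
   with an N in either sequence are excluded from numerator and
   denominator. Because BLAST identity definitions (local vs global,
   coverage handling) differ, borderline sequences near 95% may be
   admitted or rejected differently than by a BLAST-based screen.
2. **Collapse.** Retained clones are grouped by exact sequence — no
   clustering radius. Sequencing errors are expected to surface as
   singleton sequences and die at validation.
3. **Validation.** A candidate is accepted iff it has ≥ 2 distinct
   (animal, PCR) detections. Distinctness means the detections necessarily
   span two PCRs of one animal or two different animals; two observations
   within a single PCR never validate (the conservative reading of the
   replication rule).
4. **Nomenclature.** Validated alleles are named `<code>-DRB*NN` per
   species, numbered densely from 01 in a deterministic order: descending
   detection count, then lexicographically first observing animal, then
   sequence. The order is a package convention chosen for reproducibility;
   published nomenclature systems do not prescribe one.
5. **Genotypes.** An animal's genotype is the set of validated alleles
   among its retained clones: one allele → homozygous, two →
   heterozygous, more than two → reported in full with a duplication
   (copy-number-variation) flag. Animals with no validated allele are
   reported untyped and excluded from heterozygosity denominators.

Observed heterozygosity is (animals with exactly two distinct alleles) /
(typed animals); it is computed at full precision and rounded to two
decimals only for display. Allele frequencies count diploid copies
(homozygotes twice), so per-group frequencies sum to 1.

## Distances and trees

Site-pattern counting skips columns containing gaps or N; *complete
deletion* removes such columns globally before analysis (whole codons for
codon-based analyses, with the ABS mask renumbered onto the retained
codons). K2P distances use the transition/transversion proportions P and
Q; the gamma-corrected form (shape *a*, default 1, matching a strongly
rate-heterogeneous coding fragment) is used for tree building only.
Divergences with 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 raise an explicit
saturation error rather than returning NaN.

Neighbour joining follows the classic Q-criterion agglomeration with
rate-corrected limb lengths. Ties in Q are broken on the smallest (i, j)
index pair, so runs are deterministic. Negative limb lengths are clamped
to zero with the deficit moved to the sister limb (preserving the pair's
summed length). The final three clusters are closed with the three-point
formulas, giving an unrooted tree with a trifurcating root.

The bootstrap consensus resamples alignment columns with replacement
(default 2000 replicates; replicate *r* draws from an RNG substream keyed
by (seed, *r*), so increasing the replicate count never reshuffles earlier
replicates), builds an NJ tree per replicate, and keeps internal edges
present in ≥ 50% of replicates (majority rule; support reported as integer
percent; anything below the threshold collapses to a multifurcation).
Consensus branch lengths are means over the replicates containing each
edge. One convention matters for degenerate input: an internal edge of
length zero is treated as unresolved and contributes no bipartition, so an
alignment of identical sequences yields a star tree rather than an
arbitrary deterministic topology at 100% support.

## dN/dS and the selection test

Nei–Gojobori counting, unweighted-pathway variant:

* **Sites.** At each codon position, the synonymous fraction is the
  proportion of the single-base changes that preserve the amino acid,
  with changes to stop codons excluded from both sides of the fraction.
  Each codon therefore contributes exactly 3 sites (S + N = 3 per codon)
  — an invariant the tests enforce. Note that codon-level difference
  counts may exceed codon-level site counts (a synonymous change at a
  codon offering ⅓ of a synonymous site gives Sd = 1 > S); only the
  partition-level aggregates are meaningful.
* **Differences.** For codons differing at 2 or 3 positions, all
  orderings of the single-step pathways are averaged with equal weight;
  pathways passing through a stop codon are excluded and the weights
  renormalised over the survivors (for sense-codon endpoints at least one
  pathway always survives; the implementation is verified against an
  exhaustive enumeration oracle over all 61 × 61 sense-codon pairs).
* **Pooling.** S, N, Sd, Nd are averaged over all unordered sequence
  pairs; pS = Sd/S and pN = Nd/N are then Jukes–Cantor corrected. A
  partition with no synonymous (or nonsynonymous) sites reports the rate
  as missing rather than 0.

The positive-selection test is one-tailed (alternative dN > dS), with
Z = (dN − dS)/√(Var dN + Var dS) and p = 1 − Φ(Z). The variance estimator
is a **codon bootstrap**: codons within the partition are resampled with
replacement (default 1000 replicates, seeded substreams as above), dN and
dS recomputed per replicate, and their empirical variances taken.
Replicates whose resampled proportions saturate the JC correction are
dropped from the variance. Zero variance with dN = dS defines Z = 0,
p = 0.5. The Z denominator deliberately ignores the (typically negative)
covariance between the bootstrapped dN and dS, following the standard
formulation of this test; the neutral-simulation calibration in the
acceptance suite measures the resulting size of the test directly
(rejection rate ≈ 0.05–0.07 at nominal alpha = 0.05 for 71-codon
alignments of six sequences at ~6% divergence).

## Synthetic data generator

The generator is first-class, tested code, and its defaults are the
emulated study conditions: three species ("Eufr", "Euru", "Euma") with
17/5/4 alleles and 18/7/20 animals, one population each, 71-codon
alleles, 24 clones per PCR and two PCRs per animal.

* **Allele pools.** One random in-frame ancestor spawns `n_lineages` (5)
  lineage founders at `lineage_scale` (3×) the per-species substitution
  intensities; each species allele descends from a random founder plus
  species-private changes. Because founders are shared across species,
  trees over the pool can show trans-species clustering, as observed for
  MHC lineages older than species divergences. Substitutions are applied
  per codon: a synonymous change with probability `syn_rate` (0.02) and a
  nonsynonymous change with probability `nonsyn_rate_abs` (0.25) at ABS
  codons or `nonsyn_rate_nonabs` (0.05) elsewhere, always avoiding stop
  codons. The 5× ABS enrichment translates to per-site dN/dS of roughly 4
  at ABS and 0.8 at non-ABS (a codon offers ~2.2 nonsynonymous but only
  ~0.76 synonymous sites), which reproduces the qualitative selection
  pattern of balancing selection on antigen-binding sites: strongly
  positive Z at ABS, non-significant Z elsewhere.
* **Cohorts.** Population allele frequencies are Dirichlet(1) draws
  (giving the realistic mix of common and rare alleles); each animal
  draws two alleles with replacement — drawing the same allele twice
  yields a homozygote.
* **Clone libraries.** Each clone copies one of its animal's alleles with
  i.i.d. per-base errors (`error_rate` = 1e-4, a curated Sanger plasmid
  read); with probability `chimera_rate` (0.005, low because the 213-bp
  amplicon gives PCR recombination little opportunity) it is a
  single-crossover recombinant of the animal's two alleles (homozygotes
  fall back to plain copies); with probability `contaminant_rate` (0.02)
  it is a non-target sequence made by mutagenising 30% of a random
  allele's sites, guaranteeing it falls below the 95% identity screen.
  Every clone's provenance (parents, error positions, chimera crossover,
  contaminant flag) is recorded in the truth table.
* **Reference panel.** "Published" panel alleles are pool alleles with 1%
  per-base drift, so genuine clones sit near 99% panel identity and
  contaminants near 70%.

All stages draw from RNG substreams keyed by (seed, stage), so one seed
fixes the whole study and identical configs are byte-identical on disk.

What the generator does **not** model: realistic polymerase error spectra
(errors are uniform), faecal-DNA degradation and allelic dropout,
read-length variation, and chimera formation biased toward
high-similarity templates. Passing tests therefore demonstrate the
correctness of the analysis logic under the stated statistical model, not
robustness to every artefact of real noninvasive data.

## Known limitation: false alleles from recurring artifacts

The replication rule ("two PCRs or two animals") implicitly assumes
artifacts are not reproducible. Under i.i.d. sequencing errors that
assumption fails by a birthday argument: a 213-nt allele has only 639
distinct single-error derivatives, so when a common allele is represented
by hundreds of clones across a cohort (as in the least polymorphic
species, where one allele may occur in half the animals), two independent
clones will occasionally carry the same error and validate as a false
allele — likewise two chimeras of the same parent pair with crossovers in
the same interval between parental differences, arising in animals that
share a genotype. At the default error rate (1e-4) this produces a false
allele in roughly one synthetic cohort in six; the rate grows
quadratically with the error rate. Consequently end-to-end recovery of
the exact truth table succeeds in most but not ~95% of noisy replicates,
and the package reports the measured rate honestly in
`scripts/acceptance.py` rather than screening chimeras (which the
emulated protocol does not do). Real studies mitigate this with manual
chromatogram curation, which the error model cannot capture.

## Numerical conventions and edge cases

* FASTA parsing rejects malformed headers/characters with the line
  number; sequences are uppercased on input.
* Translation renders stop codons as `*` (internal stops additionally
  warn) and N-containing codons as `X`; frame violations and in-span gaps
  raise errors rather than truncating.
* All thresholds are compared strictly where the underlying rule says
  "higher than" (the 95% identity screen) and inclusively where it says
  "less than ... collapsed" (bootstrap support keeps ≥ 50%).
* Empty groups report heterozygosity as missing (None), never 0.
* The pipeline manifest echoes the full configuration, package version
  and per-stage record counts; re-running with the same inputs and seed
  reproduces every output byte-for-byte (tested).

## Problem sizes used in the test and acceptance runs

Simulation-heavy checks use deliberately moderate sizes chosen to give
stable Monte-Carlo estimates: 100 seeded pools for the ABS-enrichment
property, 50 pools for the Z-ordering property, 500 neutral replicates
(six sequences, 71 codons, 1000-replicate codon bootstrap) for the type-I
calibration, 20 replicates of the full 45-animal study for noisy
end-to-end recovery, and 2000-replicate bootstraps only where the tree is
actually reported. These are the package's own defaults for its
regression experiments; all scale linearly if larger runs are wanted.
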