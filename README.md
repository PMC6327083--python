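# lemurmhc

Noninvasive MHC class II *DRB* exon-2 genotyping and molecular evolution for
true lemurs (*Eulemur*), and for any study with the same design: PCR
amplicons cloned into bacteria, 24–48 clones Sanger-sequenced per animal,
and alleles accepted only when independently replicated.

The package is aimed at molecular ecologists and immunogeneticists who type
MHC genes from low-quality material (faeces, hair) and need the whole chain
— allele discovery and validation, genotype and heterozygosity summaries,
distance-based phylogenetics, and selection tests — as tested, scriptable
code rather than a point-and-click workflow. A fully seeded synthetic-data
generator emulates the study design (per-species allele pools with
trans-species lineage structure, diploid genotypes, clone libraries with
sequencing errors, PCR chimeras and contaminants), so every stage can be
validated against a known truth table.

## What it computes

**Allele calling.** Clones are screened against a reference panel of
published alleles, retained only when global-alignment identity exceeds 95%
(a Needleman–Wunsch proxy for a BLAST identity screen; match +1, mismatch
0, gap −2). Identical sequences are collapsed, and a candidate becomes an
allele only when detected in ≥ 2 independent contexts: two different PCRs
of one animal, or two different animals. Validated alleles are named
`<species>-DRB*NN`; an animal's genotype is the set of its validated
alleles (more than two flags possible gene duplication). Observed
heterozygosity is the fraction of typed animals carrying two distinct
alleles.

**Distances and trees.** Pairwise distances use the Kimura-2-parameter
model on transition (P) and transversion (Q) proportions,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

optionally with gamma rate variation of shape *a* (default *a* = 1):
`d = (a/2)(1-2P-Q)^(-1/a) + (a/4)(1-2Q)^(-1/a) - 3a/4`. Trees are built by
neighbour joining, with a majority-rule bootstrap consensus over resampled
alignment columns (default 2000 replicates; edges below 50% support
collapsed).

**Selection.** Synonymous and nonsynonymous substitution rates follow
Nei–Gojobori counting: per-codon site fractions from the proportion of
single-base changes that are synonymous, differences averaged with equal
weight over mutational pathway orderings (pathways through stop codons
excluded), proportions pooled over all sequence pairs and corrected for
multiple hits with Jukes–Cantor, d = -(3/4) ln(1 - 4p/3). Positive
selection (dN > dS) is tested one-tailed with

    Z = (dN - dS) / sqrt(Var(dN) + Var(dS)),

variances estimated by bootstrap over codons. Rates are computed overall
and separately for the 18 antigen-binding-site (ABS) codons (beta-chain
residues 9, 11, 13, 28, 30, 32, 37, 38, 47, 56, 60, 61, 65, 68, 70, 71,
74, 78; the amplicon starts at residue 8) and the 53 remaining codons.

## Worked example

The package ships the published genotype survey of 45 wild lemurs of three
species as a built-in dataset:

```python
from lemurmhc.datasets import survey_alleles, survey_animal_meta, survey_genotypes
from lemurmhc.diversity import allele_summary

genotypes, meta, alleles = survey_genotypes(), survey_animal_meta(), survey_alleles()
summary, freqs, sharing = allele_summary(
    alleles, genotypes, {a: m[0] for a, m in meta.items()}
)
print(summary)
```

```
       n_animals  n_alleles  observed_heterozygosity
group
Eufr          18         17                 0.777778
Euma          20          4                 0.550000
Euru           7          5                 0.571429
```

*E. rufifrons* (Eufr) carries 17 of the 26 alleles and is the most
heterozygous (0.78); the island population of *E. macaco* (Euma) carries
only 4 alleles. The sharing matrix is diagonal — no allele is observed in
two species (or, at population level, in two populations):

```
      Eufr  Euma  Euru
Eufr    17     0     0
Euma     0     4     0
Euru     0     0     5
```

Selection tests on a synthetic 26-allele pool generated with the default
ABS-enriched intensities (`generate_allele_pool(SimulationConfig(seed=6))`):

```python
from lemurmhc import SimulationConfig, generate_allele_pool
from lemurmhc.seqcore import CodonAlignment, SiteMap
from lemurmhc.molevol import complete_deletion, selection_scan

pool, _ = generate_allele_pool(SimulationConfig(seed=6))
aln = complete_deletion(
    CodonAlignment.from_sequences([r.sequence for r in pool], SiteMap())
)
print(selection_scan(aln, n_boot=1000, seed=1)[1].summary())
```

```
Codon-based Z-test of positive selection (ABS)
==========================================================
codons: 18    bootstrap replicates: 1000
dN = 0.7360 (var 0.002122)
dS = 0.1717 (var 0.003941)
Z  = 7.248   one-tailed P = 2.112e-13
positive selection at alpha=0.05: yes
```

dN exceeds dS more than fourfold at the antigen-binding codons (the
balancing-selection signature the generator emulates), while the non-ABS
partition of the same alignment gives Z = −0.14, P = 0.55 — no evidence of
positive selection outside the binding sites.

The same analyses run from the shell:

```sh
lemurmhc simulate --outdir study --seed 1
lemurmhc all --clones-dir study/clones --panel study/panel.fasta \
    --sample-sheet study/sample_sheet.tsv --outdir results --seed 1
```

which writes the genotype table, diversity/sharing TSVs, the bootstrap
consensus tree (Newick) and the selection table, plus a manifest
sufficient to reproduce every output bit-for-bit.

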