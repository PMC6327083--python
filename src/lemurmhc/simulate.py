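"""Synthetic allele pools, cohorts and noisy clone libraries.

The generator emulates the statistical structure a clone-based *DRB* exon-2
typing study assumes: per-species allele pools descending from ancient
lineages shared across species (so trees can show trans-species clustering),
diploid genotypes of at most two alleles drawn from Dirichlet-distributed
population frequencies, and clone libraries with i.i.d. per-base errors,
single-crossover PCR chimeras and heavily mutagenised non-target
contaminants. Defaults mirror the study scale: three species with 17/5/4
alleles and 18/7/20 animals, 71-codon in-frame alleles, 24 clones per PCR
and two PCRs per animal. All randomness flows from a single seed through
stage-keyed substreams, so identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from ._codontab import IS_STOP, decode_codons, single_base_neighbours
from .calling import AlleleRecord, CloneRecord, Genotype
from .seqcore import (
    DEFAULT_RESIDUE_OFFSET,
    Sequence,
    SiteMap,
    write_fasta,
)

_NON_STOP = np.flatnonzero(~IS_STOP)


class GenerationError(RuntimeError):
    """The requested pool could not be generated within bounded retries."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated study design."""

    species_codes: tuple[str, ...] = ("Eufr", "Euru", "Euma")
    populations: tuple[str, ...] = ("Kirindy", "Ranomafana", "NosyKomba")
    alleles_per_species: tuple[int, ...] = (17, 5, 4)
    n_animals: tuple[int, ...] = (18, 7, 20)
    n_codons: int = 71
    site_map: SiteMap = field(default_factory=SiteMap)
    residue_offset: int = DEFAULT_RESIDUE_OFFSET
    #: number of ancient allelic lineages shared across species
    n_lineages: int = 5
    #: lineage founders diverge at this multiple of the per-species rates
    lineage_scale: float = 3.0
    #: per-codon nonsynonymous substitution intensities (ABS 5x non-ABS).
    #: A codon offers ~2.2 nonsynonymous but only ~0.76 synonymous sites, so
    #: these give per-site dN/dS of roughly 4 at ABS and 0.8 at non-ABS --
    #: the balancing-selection signature the pool is meant to emulate.
    nonsyn_rate_abs: float = 0.25
    nonsyn_rate_nonabs: float = 0.05
    #: per-codon synonymous substitution intensity (uniform across codons)
    syn_rate: float = 0.02
    clones_per_pcr: int = 24
    pcrs_per_animal: int = 2
    #: per-base error probability of a curated Sanger clone read
    error_rate: float = 1e-4
    #: per-clone probability of a single-crossover PCR chimera (heterozygotes)
    chimera_rate: float = 0.005
    #: per-clone probability of a non-target contaminant sequence
    contaminant_rate: float = 0.02
    #: per-base divergence of the 'published' reference panel from the pool
    panel_mutation_rate: float = 0.01
    #: fraction of sites mutagenised to make a contaminant (<95% identity)
    contaminant_divergence: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.species_codes)
        if not (
            len(self.populations)
            == len(self.alleles_per_species)
            == len(self.n_animals)
            == n
        ):
            raise ValueError("per-species tuples must share one length")
        for name in (
            "nonsyn_rate_abs",
            "nonsyn_rate_nonabs",
            "syn_rate",
            "error_rate",
            "chimera_rate",
            "contaminant_rate",
            "panel_mutation_rate",
            "contaminant_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_codons", "n_lineages", "clones_per_pcr", "pcrs_per_animal"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(k < 0 for k in self.alleles_per_species):
            raise ValueError("allele counts must be nonnegative")
        if any(k < 1 for k in self.n_animals):
            raise ValueError("animal counts must be positive")

    def abs_positions(self) -> np.ndarray:
        """0-based codon positions of the ABS mask."""
        codons = self.site_map.abs_codons(self.residue_offset)
        return np.array(sorted(i - 1 for i in codons if i <= self.n_codons))


@dataclass(frozen=True)
class CloneProvenance:
    clone_id: str
    animal_id: str
    pcr_id: str
    parents: tuple[str, ...]
    error_positions: tuple[int, ...] = ()
    chimera: bool = False
    crossover: int | None = None
    contaminant: bool = False


@dataclass
class TruthTable:
    """Ground truth of a simulated study: alleles, genotypes, clone ancestry."""

    alleles: dict[str, dict[str, str]] = field(default_factory=dict)
    genotypes: dict[str, frozenset[str]] = field(default_factory=dict)
    animal_meta: dict[str, tuple[str, str]] = field(default_factory=dict)
    frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    clones: dict[str, CloneProvenance] = field(default_factory=dict)

    def allele_sequence(self, name: str) -> str:
        species = name.split(":", 1)[0]
        return self.alleles[species][name]

    def realized_alleles(self) -> set[str]:
        """Allele names actually carried by at least one simulated animal."""
        out: set[str] = set()
        for names in self.genotypes.values():
            out |= names
        return out

    def genotype_sequences(self, animal_id: str) -> frozenset[str]:
        return frozenset(
            self.allele_sequence(n) for n in self.genotypes[animal_id]
        )


def _mutate_codons(
    codons: np.ndarray,
    rng: np.random.Generator,
    syn_rate: float,
    nonsyn_rate_abs: float,
    nonsyn_rate_nonabs: float,
    abs_positions: np.ndarray,
) -> np.ndarray:
    """Apply per-codon synonymous/nonsynonymous changes; never creates stops."""
    out = codons.copy()
    is_abs = np.zeros(out.size, dtype=bool)
    is_abs[abs_positions] = True
    for k in range(out.size):
        if rng.random() < syn_rate:
            syn, _ = single_base_neighbours(int(out[k]))
            if syn:
                out[k] = syn[rng.integers(len(syn))]
        p_non = nonsyn_rate_abs if is_abs[k] else nonsyn_rate_nonabs
        if rng.random() < p_non:
            _, non = single_base_neighbours(int(out[k]))
            if non:
                out[k] = non[rng.integers(len(non))]
    return out


def generate_allele_pool(
    config: SimulationConfig,
) -> tuple[list[AlleleRecord], TruthTable]:
    """Simulate per-species allele pools with trans-species lineage structure.

    Ancient lineage founders are derived from one random in-frame ancestor;
    each species allele descends from a randomly assigned founder plus
    species-private substitutions, so alleles of different species can sit on
    shared lineage branches. All alleles are unique, stop-free, in frame.
    """
    rng = np.random.default_rng([config.seed, 0])
    abs_pos = config.abs_positions()
    ancestor = _NON_STOP[rng.integers(0, _NON_STOP.size, size=config.n_codons)]
    founders = [
        _mutate_codons(
            ancestor,
            rng,
            min(config.syn_rate * config.lineage_scale, 1.0),
            min(config.nonsyn_rate_abs * config.lineage_scale, 1.0),
            min(config.nonsyn_rate_nonabs * config.lineage_scale, 1.0),
            abs_pos,
        )
        for _ in range(config.n_lineages)
    ]

    truth = TruthTable()
    records: list[AlleleRecord] = []
    seen: set[str] = set()
    for species, population, n_alleles in zip(
        config.species_codes, config.populations, config.alleles_per_species
    ):
        truth.alleles[species] = {}
        for i in range(1, n_alleles + 1):
            name = f"{species}:true{i:02d}"
            for attempt in range(100):
                founder = founders[rng.integers(config.n_lineages)]
                codons = _mutate_codons(
                    founder,
                    rng,
                    config.syn_rate,
                    config.nonsyn_rate_abs,
                    config.nonsyn_rate_nonabs,
                    abs_pos,
                )
                nucleotides = decode_codons(codons)
                if nucleotides not in seen:
                    break
            else:
                raise GenerationError(
                    f"could not generate a unique allele for {species!r} "
                    f"after 100 attempts"
                )
            seen.add(nucleotides)
            truth.alleles[species][name] = nucleotides
            records.append(
                AlleleRecord(
                    name=name,
                    species=species,
                    populations=frozenset({population}),
                    sequence=Sequence(id=name, nucleotides=nucleotides),
                )
            )
    return records, truth


def generate_cohort(
    pool: list[AlleleRecord],
    config: SimulationConfig,
    truth: TruthTable,
    frequencies: dict[str, dict[str, float]] | None = None,
) -> TruthTable:
    """Draw diploid genotypes for every animal of every population.

    Each animal draws two alleles with replacement from its population's
    allele-frequency vector (Dirichlet(1)-distributed unless supplied);
    drawing the same allele twice yields a homozygous single-allele genotype.
    """
    if not pool:
        raise ValueError("allele pool is empty")
    rng = np.random.default_rng([config.seed, 1])
    by_species: dict[str, list[AlleleRecord]] = {}
    for rec in pool:
        by_species.setdefault(rec.species, []).append(rec)
    for species, population, n_animals in zip(
        config.species_codes, config.populations, config.n_animals
    ):
        alleles = by_species.get(species, [])
        if not alleles:
            raise ValueError(f"no alleles in pool for species {species!r}")
        names = [rec.name for rec in alleles]
        if frequencies is not None:
            freqs = np.array([frequencies[population][n] for n in names])
        else:
            freqs = rng.dirichlet(np.ones(len(names)))
        truth.frequencies[population] = dict(zip(names, freqs.tolist()))
        for i in range(1, n_animals + 1):
            animal = f"{species}-A{i:02d}"
            draw = rng.choice(len(names), size=2, replace=True, p=freqs)
            truth.genotypes[animal] = frozenset(names[k] for k in draw)
            truth.animal_meta[animal] = (species, population)
    return truth


def _apply_errors(
    nucleotides: str, rng: np.random.Generator, error_rate: float
) -> tuple[str, tuple[int, ...]]:
    arr = np.array(list(nucleotides))
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return "".join(arr), tuple(int(p) for p in hits)


def simulate_clones(
    truth: TruthTable, config: SimulationConfig
) -> list[CloneRecord]:
    """Emit noisy clone libraries per (animal, PCR) with recorded provenance.

    Each clone copies one of its animal's alleles with i.i.d. per-base
    errors; with probability ``chimera_rate`` it is a single-crossover
    recombinant of the animal's two alleles (homozygotes fall back to a plain
    copy); with probability ``contaminant_rate`` it is a non-target sequence
    made by mutagenising a random pool allele at ``contaminant_divergence``
    of its sites (guaranteeing <95% panel identity).
    """
    rng = np.random.default_rng([config.seed, 2])
    all_names = [
        name for per_species in truth.alleles.values() for name in per_species
    ]
    clones: list[CloneRecord] = []
    for animal in sorted(truth.genotypes):
        species, population = truth.animal_meta[animal]
        genotype = sorted(truth.genotypes[animal])
        for p in range(1, config.pcrs_per_animal + 1):
            pcr = f"PCR{p}"
            for k in range(1, config.clones_per_pcr + 1):
                clone_id = f"{animal}.{pcr}.c{k:03d}"
                u = rng.random()
                if u < config.contaminant_rate:
                    src = all_names[rng.integers(len(all_names))]
                    base = np.array(list(truth.allele_sequence(src)))
                    hits = np.flatnonzero(
                        rng.random(base.size) < config.contaminant_divergence
                    )
                    for pos in hits:
                        choices = [b for b in "ACGT" if b != base[pos]]
                        base[pos] = choices[rng.integers(3)]
                    nucleotides, err = "".join(base), ()
                    prov = CloneProvenance(
                        clone_id, animal, pcr, (src,), contaminant=True
                    )
                elif (
                    u < config.contaminant_rate + config.chimera_rate
                    and len(genotype) == 2
                ):
                    first, second = genotype
                    if rng.random() < 0.5:
                        first, second = second, first
                    sa = truth.allele_sequence(first)
                    sb = truth.allele_sequence(second)
                    x = int(rng.integers(1, len(sa)))
                    template = sa[:x] + sb[x:]
                    nucleotides, err = _apply_errors(
                        template, rng, config.error_rate
                    )
                    prov = CloneProvenance(
                        clone_id,
                        animal,
                        pcr,
                        (first, second),
                        error_positions=err,
                        chimera=True,
                        crossover=x,
                    )
                else:
                    parent = genotype[int(rng.integers(len(genotype)))]
                    nucleotides, err = _apply_errors(
                        truth.allele_sequence(parent), rng, config.error_rate
                    )
                    prov = CloneProvenance(
                        clone_id, animal, pcr, (parent,), error_positions=err
                    )
                truth.clones[clone_id] = prov
                clones.append(
                    CloneRecord(
                        sequence=Sequence(id=clone_id, nucleotides=nucleotides),
                        animal_id=animal,
                        pcr_id=pcr,
                        species=species,
                        population=population,
                    )
                )
    return clones


def generate_panel(
    pool: list[AlleleRecord], config: SimulationConfig
) -> list[Sequence]:
    """A 'previously published' reference panel: pool alleles with ~1% drift."""
    rng = np.random.default_rng([config.seed, 3])
    panel = []
    for i, rec in enumerate(pool, start=1):
        seq, _ = _apply_errors(
            rec.sequence.nucleotides, rng, config.panel_mutation_rate
        )
        panel.append(Sequence(id=f"panel{i:02d}", nucleotides=seq))
    return panel


@dataclass
class StudyData:
    config: SimulationConfig
    truth: TruthTable
    clones: list[CloneRecord]
    panel: list[Sequence]


def simulate_study(config: SimulationConfig) -> StudyData:
    """Full synthetic study: pool -> cohort -> clone libraries -> panel."""
    pool, truth = generate_allele_pool(config)
    generate_cohort(pool, config, truth)
    clones = simulate_clones(truth, config)
    panel = generate_panel(pool, config)
    return StudyData(config=config, truth=truth, clones=clones, panel=panel)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write clone FASTAs per (animal, PCR), panel, sample sheet, truth, config."""
    outdir = Path(outdir)
    clone_dir = outdir / "clones"
    clone_dir.mkdir(parents=True, exist_ok=True)
    by_group: dict[tuple[str, str], list[CloneRecord]] = {}
    for clone in study.clones:
        by_group.setdefault((clone.animal_id, clone.pcr_id), []).append(clone)
    sheet_rows = []
    for (animal, pcr), members in sorted(by_group.items()):
        write_fasta(
            [c.sequence for c in members], clone_dir / f"{animal}__{pcr}.fasta"
        )
        species, population = study.truth.animal_meta[animal]
        sheet_rows.append((animal, species, population, pcr))
    with open(outdir / "sample_sheet.tsv", "w") as fh:
        fh.write("animal_id\tspecies\tpopulation\tpcr_id\n")
        for row in sheet_rows:
            fh.write("\t".join(row) + "\n")
    write_fasta(study.panel, outdir / "panel.fasta")
    with open(outdir / "truth_genotypes.tsv", "w") as fh:
        fh.write("animal_id\tspecies\tpopulation\talleles\n")
        for animal in sorted(study.truth.genotypes):
            species, population = study.truth.animal_meta[animal]
            alleles = ",".join(sorted(study.truth.genotypes[animal]))
            fh.write(f"{animal}\t{species}\t{population}\t{alleles}\n")
    cfg = asdict(study.config)
    cfg["site_map"] = {
        "abs_residues": sorted(study.config.site_map.abs_residues),
        "excluded_residues": sorted(study.config.site_map.excluded_residues),
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def neutral_codon_alignment(
    n_seqs: int = 6,
    n_codons: int = 71,
    n_events: int = 12,
    seed: int = 0,
) -> list[Sequence]:
    """Alignment evolved WITHOUT selection: equal per-site intensity for
    synonymous and nonsynonymous changes (the null of the dN > dS test).

    Each sequence applies ``n_events`` uniform single-base substitutions to a
    shared random ancestor, resampling any event that would create a stop.
    """
    rng = np.random.default_rng(seed)
    ancestor = _NON_STOP[rng.integers(0, _NON_STOP.size, size=n_codons)]
    nucs = "ACGT"
    seqs = []
    for i in range(n_seqs):
        arr = list(decode_codons(ancestor))
        applied = 0
        while applied < n_events:
            pos = int(rng.integers(len(arr)))
            base = nucs[rng.integers(4)]
            if base == arr[pos]:
                continue
            old = arr[pos]
            arr[pos] = base
            codon_start = 3 * (pos // 3)
            codon = "".join(arr[codon_start : codon_start + 3])
            if IS_STOP[
                "ACGT".index(codon[0]) * 16
                + "ACGT".index(codon[1]) * 4
                + "ACGT".index(codon[2])
            ]:
                arr[pos] = old
                continue
            applied += 1
        seqs.append(Sequence(id=f"n{i}", nucleotides="".join(arr)))
    return seqs


def exact_recovery(
    truth: TruthTable,
    alleles: Iterable[AlleleRecord],
    genotypes: Iterable[Genotype],
) -> bool:
    """True iff calling recovered the realized allele set and every genotype.

    Comparison is by sequence (called names are renumbered), restricted to
    alleles actually carried by at least one animal.
    """
    called = {rec.name: rec.sequence.nucleotides for rec in alleles}
    true_seqs = {
        truth.allele_sequence(name) for name in truth.realized_alleles()
    }
    if set(called.values()) != true_seqs:
        return False
    by_animal = {g.animal_id: g for g in genotypes}
    if set(by_animal) != set(truth.genotypes):
        return False
    for animal, g in by_animal.items():
        called_seqs = frozenset(called[name] for name in g.alleles)
        if called_seqs != truth.genotype_sequences(animal):
            return False
    return True
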