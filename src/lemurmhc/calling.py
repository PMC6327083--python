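"""Allele discovery, validation, nomenclature and genotype calling from
cloned PCR amplicons.

The procedure mirrors standard practice for noninvasive MHC typing from
bacterial clones: clones are first screened against a reference panel of
published alleles (global-alignment identity strictly above a threshold,
default 95%), identical sequences are collapsed into candidates, and a
candidate becomes a named allele only when observed in at least two
independent contexts -- two different PCRs of one animal, or two different
animals. Two observations within a single PCR never validate. An animal's
genotype is the set of validated alleles among its retained clones; more
than two raises a gene-duplication flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .seqcore import Sequence, pairwise_identity

DEFAULT_SPECIES_CODES = frozenset({"Eufr", "Euru", "Euma"})


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone with its provenance."""

    sequence: Sequence
    animal_id: str
    pcr_id: str
    species: str
    population: str

    def __post_init__(self) -> None:
        for name in ("animal_id", "pcr_id", "species", "population"):
            if not getattr(self, name):
                raise ValueError(f"CloneRecord.{name} must be nonempty")


@dataclass
class CandidateAllele:
    """A distinct clone sequence with every (animal, pcr) that observed it."""

    sequence: Sequence
    detections: tuple[tuple[str, str], ...]
    species: tuple[str, ...] = ()
    populations: tuple[str, ...] = ()
    panel_identity: float | None = None

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def animals(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.detections)


@dataclass(frozen=True)
class AlleleRecord:
    """A validated, named allele."""

    name: str
    species: str
    populations: frozenset[str]
    sequence: Sequence | None


@dataclass(frozen=True)
class Genotype:
    """Per-animal validated allele set; >2 alleles flags possible duplication."""

    animal_id: str
    alleles: frozenset[str]
    duplication_flag: bool = False

    @property
    def typed(self) -> bool:
        return len(self.alleles) > 0

    @property
    def heterozygous(self) -> bool:
        return len(self.alleles) == 2


@dataclass
class FilterResult:
    retained: list[CloneRecord]
    identities: dict[str, float]  # best panel identity per distinct sequence
    rejected: list[tuple[CloneRecord, float]]


def filter_clones(
    clones: Iterable[CloneRecord],
    panel: list[Sequence],
    threshold: float = 0.95,
) -> FilterResult:
    """Retain clones whose best panel identity exceeds ``threshold`` strictly.

    The comparison deliberately uses a strict ``>``: a clone at exactly the
    threshold is removed. Identities are computed once per distinct sequence.
    """
    if not panel:
        raise ConfigurationError("reference panel must be nonempty")
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must lie in (0, 1]")
    clones = list(clones)
    best: dict[str, float] = {}
    for clone in clones:
        key = clone.sequence.nucleotides
        if key not in best:
            best[key] = max(
                pairwise_identity(clone.sequence, ref) for ref in panel
            )
    retained, rejected = [], []
    for clone in clones:
        identity = best[clone.sequence.nucleotides]
        if identity > threshold:
            retained.append(clone)
        else:
            rejected.append((clone, identity))
    return FilterResult(retained=retained, identities=best, rejected=rejected)


def collapse_candidates(retained: Iterable[CloneRecord]) -> list[CandidateAllele]:
    """Group retained clones by exact sequence into candidate alleles.

    No clustering radius is applied: only repeated identical sequences count,
    so sequencing errors are expected to surface as singletons and die at
    validation.
    """
    groups: dict[str, list[CloneRecord]] = {}
    for clone in retained:
        groups.setdefault(clone.sequence.nucleotides, []).append(clone)
    candidates = []
    for seq_key in sorted(groups):
        members = groups[seq_key]
        detections = tuple(
            sorted({(c.animal_id, c.pcr_id) for c in members})
        )
        candidates.append(
            CandidateAllele(
                sequence=Sequence(
                    id=f"candidate_{len(candidates) + 1:03d}", nucleotides=seq_key
                ),
                detections=detections,
                species=tuple(sorted({c.species for c in members})),
                populations=tuple(sorted({c.population for c in members})),
            )
        )
    return candidates


def validate_alleles(
    candidates: Iterable[CandidateAllele],
) -> tuple[list[CandidateAllele], list[CandidateAllele]]:
    """Split candidates into (validated, rejected) by the two-detection rule.

    A candidate validates iff it has >= 2 distinct (animal, pcr) detections;
    distinctness guarantees they span two PCRs of one animal or two animals.
    """
    validated, rejected = [], []
    for cand in candidates:
        (validated if cand.n_detections >= 2 else rejected).append(cand)
    return validated, rejected


def _naming_key(cand: CandidateAllele) -> tuple:
    # descending detection count, then first-observed animal, then sequence
    return (
        -cand.n_detections,
        min(a for a, _ in cand.detections),
        cand.sequence.nucleotides,
    )


def assign_names(
    validated: Iterable[CandidateAllele],
    species_code: str,
    known_codes: frozenset[str] = DEFAULT_SPECIES_CODES,
) -> list[AlleleRecord]:
    """Name one species' validated candidates ``<code>-DRB*NN`` (dense from 01).

    Ordering is deterministic: descending detection count, then the
    lexicographically first observing animal, then sequence.
    """
    if species_code not in known_codes:
        raise ConfigurationError(f"unknown species code {species_code!r}")
    records = []
    for i, cand in enumerate(sorted(validated, key=_naming_key), start=1):
        records.append(
            AlleleRecord(
                name=f"{species_code}-DRB*{i:02d}",
                species=species_code,
                populations=frozenset(cand.populations),
                sequence=Sequence(
                    id=f"{species_code}-DRB*{i:02d}",
                    nucleotides=cand.sequence.nucleotides,
                ),
            )
        )
    return records


def assign_names_by_species(
    validated: Iterable[CandidateAllele],
    known_codes: frozenset[str] = DEFAULT_SPECIES_CODES,
) -> list[AlleleRecord]:
    """Name validated candidates per species (species of the first detection)."""
    by_species: dict[str, list[CandidateAllele]] = {}
    for cand in validated:
        by_species.setdefault(cand.species[0], []).append(cand)
    records: list[AlleleRecord] = []
    for code in sorted(by_species):
        records.extend(assign_names(by_species[code], code, known_codes))
    return records


def call_genotypes(
    alleles: Iterable[AlleleRecord],
    retained_clones: Iterable[CloneRecord],
    animals: Iterable[str] | None = None,
) -> list[Genotype]:
    """Genotype every animal as the set of validated alleles among its clones.

    Animals whose retained clones contain no validated allele are reported as
    untyped genotypes (empty allele set), never dropped or raised; passing
    ``animals`` seeds the output with sampled animals that lost every clone.
    """
    by_sequence = {
        rec.sequence.nucleotides: rec.name
        for rec in alleles
        if rec.sequence is not None
    }
    seen: dict[str, set[str]] = (
        {a: set() for a in animals} if animals is not None else {}
    )
    for clone in retained_clones:
        seen.setdefault(clone.animal_id, set())
        name = by_sequence.get(clone.sequence.nucleotides)
        if name is not None:
            seen[clone.animal_id].add(name)
    return [
        Genotype(
            animal_id=animal,
            alleles=frozenset(names),
            duplication_flag=len(names) > 2,
        )
        for animal, names in sorted(seen.items())
    ]
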