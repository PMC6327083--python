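"""Built-in genotype survey of wild true lemurs (*Eulemur*).

A published noninvasive survey typed 45 wild individuals of three congeneric
true lemur species at MHC class II *DRB* exon 2: *E. rufifrons* (Eufr, 18
animals across Kirindy Forest, Isalo NP and Ranomafana NP), *E. rubriventer*
(Euru, 7 animals, Ranomafana NP) and *E. macaco* (Euma, 20 animals, Nosy
Komba), finding 26 alleles in total (17/5/4 per species) and no animal with
more than two alleles. The per-animal genotype table is embedded here so the
diversity stage can be exercised and checked against the published counts
without any sequence data (the nucleotide sequences themselves are deposited
in a public repository and are not required).
"""

from __future__ import annotations

from .calling import AlleleRecord, Genotype

# animal_id -> (species code, population, allele numbers)
_SURVEY: dict[str, tuple[str, str, tuple[int, ...]]] = {
    # E. rufifrons, Kirindy Forest
    "K1RF": ("Eufr", "Kirindy", (1, 4)),
    "K2RF": ("Eufr", "Kirindy", (2, 9)),
    "K3RF": ("Eufr", "Kirindy", (10, 12)),
    "K4RF": ("Eufr", "Kirindy", (4, 10)),
    "K5RF": ("Eufr", "Kirindy", (1, 7)),
    "K6RF": ("Eufr", "Kirindy", (6,)),
    "K7RF": ("Eufr", "Kirindy", (2, 9)),
    "K8RF": ("Eufr", "Kirindy", (7, 11)),
    "K9RF": ("Eufr", "Kirindy", (4,)),
    "K10RF": ("Eufr", "Kirindy", (3, 8)),
    "K11RF": ("Eufr", "Kirindy", (10, 12)),
    "K25RF": ("Eufr", "Kirindy", (4, 5)),
    "K27RF": ("Eufr", "Kirindy", (7,)),
    # E. rufifrons, Isalo NP
    "I2RF": ("Eufr", "Isalo", (14, 15)),
    "I4RF": ("Eufr", "Isalo", (13, 15)),
    "I7RF": ("Eufr", "Isalo", (13, 15)),
    # E. rufifrons, Ranomafana NP
    "R105RF": ("Eufr", "Ranomafana", (17,)),
    "R90RF": ("Eufr", "Ranomafana", (16, 17)),
    # E. rubriventer, Ranomafana NP
    "R43RB": ("Euru", "Ranomafana", (1,)),
    "R33RB": ("Euru", "Ranomafana", (3, 5)),
    "R34RB": ("Euru", "Ranomafana", (5,)),
    "R55RB": ("Euru", "Ranomafana", (5,)),
    "R29RB": ("Euru", "Ranomafana", (1, 3)),
    "R30RB": ("Euru", "Ranomafana", (2, 4)),
    "R27RB": ("Euru", "Ranomafana", (1, 2)),
    # E. macaco, Nosy Komba
    "NK21": ("Euma", "NosyKomba", (2,)),
    "NK16": ("Euma", "NosyKomba", (2, 3)),
    "NK7": ("Euma", "NosyKomba", (1, 2)),
    "NK17": ("Euma", "NosyKomba", (2,)),
    "NK3": ("Euma", "NosyKomba", (2, 3)),
    "NK1EMA": ("Euma", "NosyKomba", (2,)),
    "NB1EMA": ("Euma", "NosyKomba", (3,)),
    "NK22": ("Euma", "NosyKomba", (3,)),
    "NK13": ("Euma", "NosyKomba", (1,)),
    "NK4": ("Euma", "NosyKomba", (2, 3)),
    "NK12": ("Euma", "NosyKomba", (2, 3)),
    "NK1": ("Euma", "NosyKomba", (2,)),
    "NK2": ("Euma", "NosyKomba", (1, 3)),
    "NK14": ("Euma", "NosyKomba", (1,)),
    "NK9": ("Euma", "NosyKomba", (1, 2)),
    "NK10": ("Euma", "NosyKomba", (2, 3)),
    "NK19": ("Euma", "NosyKomba", (1, 4)),
    "NK23": ("Euma", "NosyKomba", (2, 3)),
    "NK5": ("Euma", "NosyKomba", (2, 3)),
    "NK15": ("Euma", "NosyKomba", (2,)),
}

SPECIES_NAMES = {
    "Eufr": "Eulemur rufifrons",
    "Euru": "Eulemur rubriventer",
    "Euma": "Eulemur macaco",
}


def _allele_name(code: str, number: int) -> str:
    return f"{code}-DRB*{number:02d}"


def survey_genotypes() -> list[Genotype]:
    """The 45 published genotypes (1-2 alleles each, no duplication flags)."""
    return [
        Genotype(
            animal_id=animal,
            alleles=frozenset(_allele_name(code, n) for n in numbers),
        )
        for animal, (code, _pop, numbers) in _SURVEY.items()
    ]


def survey_animal_meta() -> dict[str, tuple[str, str]]:
    """animal_id -> (species code, population)."""
    return {a: (code, pop) for a, (code, pop, _n) in _SURVEY.items()}


def survey_alleles() -> list[AlleleRecord]:
    """The 26 named survey alleles (sequences deposited externally, not held)."""
    seen: dict[str, tuple[str, set[str]]] = {}
    for animal, (code, pop, numbers) in _SURVEY.items():
        for n in numbers:
            name = _allele_name(code, n)
            seen.setdefault(name, (code, set()))[1].add(pop)
    return [
        AlleleRecord(
            name=name, species=code, populations=frozenset(pops), sequence=None
        )
        for name, (code, pops) in sorted(seen.items())
    ]
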