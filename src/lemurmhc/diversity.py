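"""Population-level diversity summaries: allele counts, observed
heterozygosity, allele frequencies and allele sharing between groups.

Observed heterozygosity is the fraction of typed individuals carrying two
distinct alleles; untyped animals are excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as TypingSequence

import pandas as pd

from .calling import AlleleRecord, Genotype


class IntegrityError(ValueError):
    """A genotype references an allele absent from the allele list."""


@dataclass(frozen=True)
class DiversitySummary:
    group: str
    n_animals: int
    n_alleles: int
    observed_heterozygosity: float | None


def observed_heterozygosity(genotypes: Iterable[Genotype]) -> float | None:
    """Fraction of typed animals with exactly two distinct alleles.

    Returns None (reported as missing) for a group with no typed animals.
    """
    typed = [g for g in genotypes if g.typed]
    if not typed:
        return None
    return sum(1 for g in typed if g.heterozygous) / len(typed)


def _allele_copy_counts(genotypes: list[Genotype]) -> dict[str, int]:
    """Diploid copy counts: a single-allele (homozygous) animal counts twice."""
    counts: dict[str, int] = {}
    for g in genotypes:
        if not g.typed:
            continue
        if len(g.alleles) == 1:
            (allele,) = g.alleles
            counts[allele] = counts.get(allele, 0) + 2
        else:
            for allele in g.alleles:
                counts[allele] = counts.get(allele, 0) + 1
    return counts


def allele_frequencies(genotypes: Iterable[Genotype]) -> pd.Series:
    """Observed allele frequencies (copy counts over 2 x typed animals)."""
    genotypes = [g for g in genotypes if g.typed]
    counts = _allele_copy_counts(genotypes)
    total = 2 * len(genotypes)
    freqs = pd.Series(
        {a: c / total for a, c in sorted(counts.items())}, dtype=float
    )
    freqs.index.name = "allele"
    return freqs


def allele_summary(
    alleles: TypingSequence[AlleleRecord],
    genotypes: TypingSequence[Genotype],
    groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-group diversity summary, allele-frequency matrix and sharing matrix.

    ``groups`` maps animal_id to its group label (species or population).
    Returns (summary, frequency table with alleles as rows and groups as
    columns, and a symmetric group-by-group matrix counting alleles observed
    in both members of each pair).
    """
    known = {rec.name for rec in alleles}
    for g in genotypes:
        unknown = g.alleles - known
        if unknown:
            raise IntegrityError(
                f"animal {g.animal_id}: unknown alleles {sorted(unknown)}"
            )
    missing = [g.animal_id for g in genotypes if g.animal_id not in groups]
    if missing:
        raise IntegrityError(f"animals without group assignment: {missing}")

    labels = sorted(set(groups[g.animal_id] for g in genotypes))
    by_group: dict[str, list[Genotype]] = {lab: [] for lab in labels}
    for g in genotypes:
        by_group[groups[g.animal_id]].append(g)

    rows = []
    observed: dict[str, set[str]] = {}
    freq_columns: dict[str, pd.Series] = {}
    for lab in labels:
        members = by_group[lab]
        typed = [g for g in members if g.typed]
        observed[lab] = set().union(*(g.alleles for g in typed)) if typed else set()
        rows.append(
            DiversitySummary(
                group=lab,
                n_animals=len(typed),
                n_alleles=len(observed[lab]),
                observed_heterozygosity=observed_heterozygosity(members),
            )
        )
        freq_columns[lab] = allele_frequencies(members)

    summary = pd.DataFrame(
        [
            {
                "group": r.group,
                "n_animals": r.n_animals,
                "n_alleles": r.n_alleles,
                "observed_heterozygosity": r.observed_heterozygosity,
            }
            for r in rows
        ]
    ).set_index("group")
    freq = pd.DataFrame(freq_columns).fillna(0.0).sort_index()
    freq.index.name = "allele"
    sharing = pd.DataFrame(
        [
            [len(observed[a] & observed[b]) for b in labels]
            for a in labels
        ],
        index=labels,
        columns=labels,
        dtype=int,
    )
    return summary, freq, sharing
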