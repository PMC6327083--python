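"""Nucleotide distances: site-pattern counting, Kimura-2-parameter (optionally
gamma-corrected) and the Jukes-Cantor proportion correction, plus complete
deletion of gapped/ambiguous positions."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..seqcore import CodonAlignment, Sequence

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Observed divergence too high for the requested distance correction."""


@dataclass(frozen=True)
class SitePatternCounts:
    """Pairwise site-pattern summary over L compared positions.

    P and Q are transition (A<->G, C<->T) and transversion difference
    proportions; p = P + Q is the total difference proportion.
    """

    P: float
    Q: float
    L: int

    @property
    def p(self) -> float:
        return self.P + self.Q


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append(
                label.ljust(12) + " ".join(f"{x:.6f}" for x in row)
            )
        return "\n".join(lines) + "\n"


def complete_deletion_sites(sequences: list[Sequence]) -> list[Sequence]:
    """Remove every alignment column holding '-' or 'N' in any sequence."""
    if not sequences:
        raise ValueError("empty alignment")
    arr = np.array([list(s.nucleotides) for s in sequences])
    keep = ~np.any((arr == "-") | (arr == "N"), axis=0)
    if not keep.any():
        raise ValueError("complete deletion removed every column")
    return [
        Sequence(s.id, "".join(row)) for s, row in zip(sequences, arr[:, keep])
    ]


def complete_deletion(alignment: CodonAlignment) -> CodonAlignment:
    """Codon-wise complete deletion: drop whole codons containing '-' or 'N'
    in any sequence, remapping the ABS codon mask onto the retained codons."""
    arr = np.array([list(s.nucleotides) for s in alignment.sequences])
    bad_col = np.any((arr == "-") | (arr == "N"), axis=0)
    bad_codon = bad_col.reshape(-1, 3).any(axis=1)
    keep = ~bad_codon
    if not keep.any():
        raise ValueError("complete deletion removed every codon")
    keep_cols = np.repeat(keep, 3)
    new_seqs = tuple(
        Sequence(s.id, "".join(row))
        for s, row in zip(alignment.sequences, arr[:, keep_cols])
    )
    old_kept = [i + 1 for i in range(len(keep)) if keep[i]]
    renumber = {old: new + 1 for new, old in enumerate(old_kept)}
    new_mask = frozenset(
        renumber[i] for i in alignment.abs_mask if i in renumber
    )
    return CodonAlignment(
        sequences=new_seqs,
        residue_offset=alignment.residue_offset,
        abs_mask=new_mask,
    )


def count_site_patterns(a: Sequence, b: Sequence) -> SitePatternCounts:
    """Transition/transversion difference proportions between two aligned
    sequences; positions with '-' or 'N' in either sequence are skipped."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    transitions = transversions = compared = 0
    for x, y in zip(a.nucleotides, b.nucleotides):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x == y:
            continue
        if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise ValueError("no comparable sites")
    return SitePatternCounts(
        P=transitions / compared, Q=transversions / compared, L=compared
    )


def k2p_distance(counts: SitePatternCounts, gamma_a: float | None = None) -> float:
    """Kimura-2-parameter distance, optionally gamma-rate-corrected.

    Without gamma: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q). With gamma shape a:
    d = (a/2)(1-2P-Q)^(-1/a) + (a/4)(1-2Q)^(-1/a) - 3a/4, converging to the
    uncorrected form as a -> infinity.
    """
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance undefined: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f} "
            "(sequences too divergent)"
        )
    if gamma_a is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    if gamma_a <= 0:
        raise ValueError("gamma shape must be positive")
    a = gamma_a
    return (a / 2.0) * w1 ** (-1.0 / a) + (a / 4.0) * w2 ** (-1.0 / a) - 0.75 * a


def jc_proportion_correction(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise SaturationError(
            f"Jukes-Cantor correction undefined for p={p:.4f} >= 0.75"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p_matrix(
    sequences: list[Sequence], gamma_a: float | None = None
) -> DistanceMatrix:
    """Pairwise K2P (optionally gamma) distance matrix over aligned sequences."""
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = count_site_patterns(sequences[i], sequences[j])
            d[i, j] = d[j, i] = k2p_distance(counts, gamma_a)
    return DistanceMatrix(tuple(s.id for s in sequences), d)
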