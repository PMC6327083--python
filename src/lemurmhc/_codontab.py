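"""Shared codon machinery: codon indexing, translation table, mutational neighbours.

Codons are indexed 0..63 as 16*b1 + 4*b2 + b3 with A=0, C=1, G=2, T=3.
The standard nuclear genetic code (Biopython table 1) is used throughout.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCS)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

CODONS = ["".join(p) for p in itertools.product(NUCS, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: amino acid per codon index, '*' for stops
AA = np.array(
    ["*" if c in STOP_CODONS else _STANDARD.forward_table[c] for c in CODONS]
)

IS_STOP = np.array([c in STOP_CODONS for c in CODONS])


def codon_to_index(codon: str) -> int:
    """Index of an unambiguous codon; raises KeyError for N/gap codons."""
    return CODON_INDEX[codon]


def index_to_codon(idx: int) -> str:
    return CODONS[idx]


def translate_codon(codon: str) -> str:
    """One-letter amino acid; '*' for stop, 'X' if the codon contains N."""
    if "N" in codon:
        return "X"
    return AA[CODON_INDEX[codon]]


@lru_cache(maxsize=None)
def single_base_neighbours(idx: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Non-stop single-base mutational neighbours of a codon.

    Returns (synonymous_neighbours, nonsynonymous_neighbours), each a tuple of
    codon indices. Changes producing stop codons are excluded.
    """
    codon = CODONS[idx]
    syn, nonsyn = [], []
    for pos in range(3):
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            j = CODON_INDEX[alt]
            if IS_STOP[j]:
                continue
            (syn if AA[j] == AA[idx] else nonsyn).append(j)
    return tuple(syn), tuple(nonsyn)


def encode_sequence(nucleotides: str) -> np.ndarray:
    """Encode an in-frame gap/N-free nucleotide string as codon indices."""
    n = len(nucleotides)
    if n % 3:
        raise ValueError(f"length {n} is not a multiple of 3")
    try:
        return np.array(
            [CODON_INDEX[nucleotides[i : i + 3]] for i in range(0, n, 3)],
            dtype=np.int64,
        )
    except KeyError as exc:  # ambiguous or gap codon
        raise ValueError(f"cannot encode ambiguous codon {exc.args[0]!r}") from exc


def decode_codons(indices) -> str:
    return "".join(CODONS[int(i)] for i in indices)
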