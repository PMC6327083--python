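"""Sequence containers, FASTA I/O, translation, pairwise identity and the
codon/residue coordinate system shared by all analysis stages.

The study system is a 213-bp amplicon of MHC class II *DRB* exon 2 whose first
codon encodes beta-chain residue 8; the amplicon therefore spans residues 8-78
(71 codons). Antigen-binding sites (ABS) are addressed in beta-chain residue
numbers and mapped onto 1-based codon indices of the alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TypingSequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codontab import translate_codon

ALPHABET = frozenset("ACGTN-")

#: beta-chain residues forming the antigen-binding site within the amplicon
DEFAULT_ABS_RESIDUES = frozenset(
    {9, 11, 13, 28, 30, 32, 37, 38, 47, 56, 60, 61, 65, 68, 70, 71, 74, 78}
)
#: ABS residues that lie outside the amplified fragment
DEFAULT_EXCLUDED_RESIDUES = frozenset({81, 82, 85, 86, 88, 89})

#: beta-chain residue number encoded by codon 1 of the amplicon
DEFAULT_RESIDUE_OFFSET = 8


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class FrameError(ValueError):
    """Sequence span cannot be interpreted as whole codons."""


class InternalStopWarning(UserWarning):
    """Translation encountered a stop codon before the final codon."""


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N, -}."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        object.__setattr__(self, "nucleotides", self.nucleotides.upper())
        bad = set(self.nucleotides) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    def ungapped(self) -> str:
        return self.nucleotides.replace("-", "")


def _prescan_fasta(path: Path) -> None:
    """Reject malformed FASTA with an error naming the line number."""
    seen_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                seen_header = True
            else:
                if not seen_header:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                bad = set(line.upper()) - ALPHABET
                if bad:
                    raise FastaParseError(
                        f"line {lineno}: illegal sequence characters {sorted(bad)}"
                    )


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Records are returned in file order with nucleotides uppercased. Malformed
    headers or illegal characters raise :class:`FastaParseError` naming the
    line number.
    """
    path = Path(path)
    _prescan_fasta(path)
    return [
        Sequence(id=rec.id, nucleotides=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(sequences: Iterable[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.nucleotides), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def translate(seq: Sequence, offset: int = 0) -> str:
    """Translate ``seq`` from nucleotide ``offset`` with the standard code.

    Codons containing N translate to 'X'. Internal stop codons are reported
    via :class:`InternalStopWarning` (and rendered '*'), never dropped.
    Gaps within the translated span, or a span length not divisible by 3,
    raise :class:`FrameError`.
    """
    span = seq.nucleotides[offset:]
    if len(span) % 3:
        raise FrameError(
            f"sequence {seq.id!r}: span of {len(span)} nt from offset {offset} "
            "is not a multiple of 3"
        )
    if "-" in span:
        raise FrameError(f"sequence {seq.id!r}: gap character inside coding span")
    residues = [translate_codon(span[i : i + 3]) for i in range(0, len(span), 3)]
    if "*" in residues[:-1]:
        warnings.warn(
            f"sequence {seq.id!r}: internal stop codon at codon "
            f"{residues.index('*') + 1}",
            InternalStopWarning,
            stacklevel=2,
        )
    return "".join(residues)


_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=-2.0,
    extend_gap_score=-2.0,
)


def pairwise_identity(a: Sequence, b: Sequence) -> float:
    """Global-alignment identity between two sequences.

    Identity is matches over aligned columns of a Needleman-Wunsch alignment
    (match +1, mismatch 0, linear gap -2) -- a deterministic proxy for a BLAST
    identity. Columns in which either sequence has an N are excluded from both
    numerator and denominator; gap columns count against identity. Inputs are
    compared after removing alignment gaps of their own.
    """
    sa, sb = a.ungapped(), b.ungapped()
    if not sa or not sb:
        raise ValueError("pairwise_identity requires nonempty sequences")
    alignment = _ALIGNER.align(sa, sb)[0]
    row_a, row_b = alignment[0], alignment[1]
    matches = 0
    columns = 0
    for x, y in zip(row_a, row_b):
        if x == "N" or y == "N":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    if columns == 0:
        raise ValueError("no comparable columns (all positions ambiguous)")
    return matches / columns


@dataclass(frozen=True)
class SiteMap:
    """Beta-chain residue bookkeeping for the DRB exon-2 amplicon.

    ``abs_residues`` are antigen-binding residues inside the amplicon;
    ``excluded_residues`` are ABS residues lying outside it (not analysable).
    Residue r maps to 1-based codon index ``r - residue_offset + 1``.
    """

    abs_residues: frozenset[int] = DEFAULT_ABS_RESIDUES
    excluded_residues: frozenset[int] = DEFAULT_EXCLUDED_RESIDUES

    def codon_index(self, residue: int, residue_offset: int = DEFAULT_RESIDUE_OFFSET) -> int:
        return residue - residue_offset + 1

    def abs_codons(self, residue_offset: int = DEFAULT_RESIDUE_OFFSET) -> frozenset[int]:
        return frozenset(
            self.codon_index(r, residue_offset) for r in self.abs_residues
        )


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length in-frame nucleotide sequences with an ABS codon mask.

    ``abs_mask`` holds 1-based codon indices within the alignment;
    ``residue_offset`` is the beta-chain residue number of codon 1 (8 for
    this amplicon, so the default mask marks 18 of 71 codons).
    """

    sequences: tuple[Sequence, ...]
    residue_offset: int = DEFAULT_RESIDUE_OFFSET
    abs_mask: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment needs at least one sequence")
        object.__setattr__(self, "sequences", tuple(self.sequences))
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")
        n_codons = length // 3
        out = [i for i in self.abs_mask if not 1 <= i <= n_codons]
        if out:
            raise ValueError(f"abs_mask indices out of range: {sorted(out)}")

    @classmethod
    def from_sequences(
        cls,
        sequences: TypingSequence[Sequence],
        site_map: SiteMap | None = None,
        residue_offset: int = DEFAULT_RESIDUE_OFFSET,
    ) -> "CodonAlignment":
        site_map = site_map or SiteMap()
        return cls(
            sequences=tuple(sequences),
            residue_offset=residue_offset,
            abs_mask=site_map.abs_codons(residue_offset),
        )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)

    def non_abs_mask(self) -> frozenset[int]:
        return frozenset(range(1, self.n_codons + 1)) - self.abs_mask

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def translated(self) -> list[str]:
        return [translate(s) for s in self.sequences]


def variable_amino_acid_positions(alignment: CodonAlignment) -> set[int]:
    """1-based codon indices whose translated residues differ across sequences."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InternalStopWarning)
        proteins = alignment.translated()
    return {
        i + 1
        for i in range(alignment.n_codons)
        if len({p[i] for p in proteins}) > 1
    }
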