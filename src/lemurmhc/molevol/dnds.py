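"""Nei-Gojobori synonymous/nonsynonymous counting and codon-based Z-tests
for positive selection.

Synonymous site fractions are computed per codon position as the fraction of
single-base changes that preserve the amino acid, with changes to stop codons
excluded, so each codon always contributes exactly three sites (S + N = 3 per
codon). Differences between codon pairs are averaged with equal weight over
all orderings of the 2- or 3-step mutational pathways, excluding pathways
that pass through stop codons (weights renormalised over surviving pathways).
Proportions are corrected for multiple hits with the Jukes-Cantor formula.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .._codontab import AA, CODONS, IS_STOP, encode_sequence
from ..seqcore import CodonAlignment, Sequence
from .distances import SaturationError, jc_proportion_correction


class AnalysisError(ValueError):
    """Input violates the assumptions of the codon-based analysis."""


@lru_cache(maxsize=1)
def _site_table() -> np.ndarray:
    """Synonymous sites per codon (NaN for stop codons)."""
    syn_sites = np.full(64, np.nan)
    for i, codon in enumerate(CODONS):
        if IS_STOP[i]:
            continue
        total = 0.0
        for pos in range(3):
            syn = non = 0
            for nuc in "ACGT":
                if nuc == codon[pos]:
                    continue
                alt = codon[:pos] + nuc + codon[pos + 1 :]
                j = CODONS.index(alt)
                if IS_STOP[j]:
                    continue
                if AA[j] == AA[i]:
                    syn += 1
                else:
                    non += 1
            if syn + non:
                total += syn / (syn + non)
        syn_sites[i] = total
    return syn_sites


def _pathway_counts(i: int, j: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between codons i and j,
    averaged over stop-free mutational pathways."""
    a, b = CODONS[i], CODONS[j]
    diffs = [pos for pos in range(3) if a[pos] != b[pos]]
    if not diffs:
        return 0.0, 0.0
    outcomes: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        current = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            k = CODONS.index(nxt)
            if IS_STOP[k] and nxt != b:
                blocked = True
                break
            if AA[CODONS.index(current)] == AA[k]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            outcomes.append((sd, nd))
    if not outcomes:  # unreachable for non-stop endpoints in the standard code
        raise AnalysisError(f"no stop-free pathway between {a} and {b}")
    sd = sum(o[0] for o in outcomes) / len(outcomes)
    nd = sum(o[1] for o in outcomes) / len(outcomes)
    return sd, nd


@lru_cache(maxsize=1)
def _difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """64x64 synonymous/nonsynonymous difference tables (NaN involving stops)."""
    sd_tab = np.full((64, 64), np.nan)
    nd_tab = np.full((64, 64), np.nan)
    for i in range(64):
        if IS_STOP[i]:
            continue
        for j in range(64):
            if IS_STOP[j]:
                continue
            sd, nd = _pathway_counts(i, j)
            sd_tab[i, j] = sd
            nd_tab[i, j] = nd
    return sd_tab, nd_tab


@dataclass(frozen=True)
class NGCounts:
    """Nei-Gojobori site and difference counts for one pair and partition."""

    S: float
    N: float
    Sd: float
    Nd: float

    def __post_init__(self) -> None:
        # Note Sd <= S (and Nd <= N) holds for realistic whole-sequence
        # partitions but NOT codon-by-codon: a synonymous change at a codon
        # offering only 1/3 of a synonymous site gives Sd=1 > S. Only
        # nonnegativity is enforced here.
        if min(self.S, self.N, self.Sd, self.Nd) < -1e-9:
            raise ValueError("counts must be nonnegative")


def _encode_checked(seq: Sequence | str, label: str | None = None) -> np.ndarray:
    nucleotides = seq.nucleotides if isinstance(seq, Sequence) else seq
    name = label or (seq.id if isinstance(seq, Sequence) else "<sequence>")
    try:
        codons = encode_sequence(nucleotides)
    except ValueError as exc:
        raise AnalysisError(f"sequence {name!r}: {exc}") from exc
    stops = np.nonzero(IS_STOP[codons])[0]
    if stops.size:
        raise AnalysisError(
            f"sequence {name!r}: internal stop codon at codon {stops[0] + 1}"
        )
    return codons


def _mask_positions(n_codons: int, mask) -> np.ndarray:
    """0-based codon positions selected by a 1-based mask (None = all)."""
    if mask is None:
        return np.arange(n_codons)
    positions = np.array(sorted({int(i) - 1 for i in mask}), dtype=np.int64)
    if positions.size and (positions[0] < 0 or positions[-1] >= n_codons):
        raise ValueError("mask codon indices out of range")
    return positions


def nei_gojobori_pair(
    a: Sequence | str, b: Sequence | str, mask=None
) -> NGCounts:
    """Nei-Gojobori counts between two in-frame sequences.

    ``mask`` restricts the sums to a subset of 1-based codon indices
    (e.g. the ABS codons); None uses every codon.
    """
    ca, cb = _encode_checked(a), _encode_checked(b)
    if ca.size != cb.size:
        raise AnalysisError("sequences differ in codon length")
    pos = _mask_positions(ca.size, mask)
    syn_sites = _site_table()
    sd_tab, nd_tab = _difference_tables()
    s = float(((syn_sites[ca[pos]] + syn_sites[cb[pos]]) / 2.0).sum())
    n = 3.0 * pos.size - s
    sd = float(sd_tab[ca[pos], cb[pos]].sum())
    nd = float(nd_tab[ca[pos], cb[pos]].sum())
    return NGCounts(S=s, N=n, Sd=sd, Nd=nd)


def _pooled_per_codon(
    alignment: CodonAlignment, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon S, N, Sd, Nd averaged over all unordered sequence pairs."""
    matrix = np.vstack(
        [_encode_checked(s) for s in alignment.sequences]
    )[:, positions]
    syn_sites = _site_table()
    sd_tab, nd_tab = _difference_tables()
    n_seq = matrix.shape[0]
    pairs = [(i, j) for i in range(n_seq) for j in range(i + 1, n_seq)]
    if not pairs:
        raise AnalysisError("at least two sequences required")
    s = np.zeros(positions.size)
    sd = np.zeros(positions.size)
    nd = np.zeros(positions.size)
    for i, j in pairs:
        s += (syn_sites[matrix[i]] + syn_sites[matrix[j]]) / 2.0
        sd += sd_tab[matrix[i], matrix[j]]
        nd += nd_tab[matrix[i], matrix[j]]
    s /= len(pairs)
    sd /= len(pairs)
    nd /= len(pairs)
    n = 3.0 - s
    return s, n, sd, nd


def mean_dnds(
    alignment: CodonAlignment, mask=None
) -> tuple[float | None, float | None]:
    """Mean (dN, dS) over all unordered sequence pairs, Jukes-Cantor corrected.

    Site and difference counts are pooled by averaging over pairs before the
    proportions are formed. A partition with zero synonymous (or
    nonsynonymous) sites yields None for the undefined rate.
    """
    positions = _mask_positions(alignment.n_codons, mask)
    if positions.size == 0:
        raise ValueError("empty codon partition")
    s, n, sd, nd = _pooled_per_codon(alignment, positions)
    S, N, Sd, Nd = s.sum(), n.sum(), sd.sum(), nd.sum()
    dn = jc_proportion_correction(Nd / N) if N > 0 else None
    ds = jc_proportion_correction(Sd / S) if S > 0 else None
    return dn, ds


@dataclass(frozen=True)
class SelectionEstimate:
    """One-tailed codon-based Z-test of positive selection (dN > dS)."""

    partition: str
    dN: float
    dS: float
    var_dN: float
    var_dS: float
    Z: float
    p_one_tailed: float
    n_codons: int
    n_boot: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_one_tailed < self.alpha

    def summary(self) -> str:
        lines = [
            f"Codon-based Z-test of positive selection ({self.partition})",
            "=" * 58,
            f"codons: {self.n_codons}    bootstrap replicates: {self.n_boot}",
            f"dN = {self.dN:.4f} (var {self.var_dN:.6f})",
            f"dS = {self.dS:.4f} (var {self.var_dS:.6f})",
            f"Z  = {self.Z:.3f}   one-tailed P = {self.p_one_tailed:.4g}",
            f"positive selection at alpha={self.alpha:g}: "
            + ("yes" if self.significant else "no"),
        ]
        return "\n".join(lines)


def _jc_vec(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    ok = p < 0.75
    out[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return out


def selection_z_test(
    alignment: CodonAlignment,
    mask=None,
    n_boot: int = 1000,
    seed: int = 0,
    partition: str = "overall",
    alpha: float = 0.05,
) -> SelectionEstimate:
    """Test dN > dS on a codon partition with codon-bootstrap variances.

    Codons within the partition are resampled with replacement ``n_boot``
    times (replicate r drawing from an RNG substream keyed by (seed, r));
    dN and dS are recomputed per replicate and their empirical variances
    enter Z = (dN - dS) / sqrt(var_dN + var_dS). The one-tailed p-value is
    1 - Phi(Z) for the positive-selection alternative.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    positions = _mask_positions(alignment.n_codons, mask)
    if positions.size == 0:
        raise ValueError("empty codon partition")
    s, n, sd, nd = _pooled_per_codon(alignment, positions)
    S, N, Sd, Nd = s.sum(), n.sum(), sd.sum(), nd.sum()
    if S <= 0 or N <= 0:
        raise AnalysisError(
            f"partition {partition!r} has no synonymous or no nonsynonymous sites"
        )
    try:
        dn = jc_proportion_correction(Nd / N)
        ds = jc_proportion_correction(Sd / S)
    except SaturationError as exc:
        raise AnalysisError(f"partition {partition!r}: {exc}") from exc

    L = positions.size
    idx = np.empty((n_boot, L), dtype=np.int64)
    for r in range(n_boot):
        idx[r] = np.random.default_rng([seed, r]).integers(0, L, size=L)
    S_b = s[idx].sum(axis=1)
    N_b = n[idx].sum(axis=1)
    Sd_b = sd[idx].sum(axis=1)
    Nd_b = nd[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dn_b = _jc_vec(np.where(N_b > 0, Nd_b / np.maximum(N_b, 1e-300), np.nan))
        ds_b = _jc_vec(np.where(S_b > 0, Sd_b / np.maximum(S_b, 1e-300), np.nan))
    valid = np.isfinite(dn_b) & np.isfinite(ds_b)
    if valid.sum() < 2:
        raise AnalysisError("too few valid bootstrap replicates for a variance")
    var_dn = float(np.var(dn_b[valid], ddof=1))
    var_ds = float(np.var(ds_b[valid], ddof=1))

    denom = math.sqrt(var_dn + var_ds)
    if denom == 0.0:
        z = 0.0 if dn == ds else math.copysign(math.inf, dn - ds)
    else:
        z = (dn - ds) / denom
    p = float(norm.sf(z))
    return SelectionEstimate(
        partition=partition,
        dN=dn,
        dS=ds,
        var_dN=var_dn,
        var_dS=var_ds,
        Z=z,
        p_one_tailed=p,
        n_codons=int(L),
        n_boot=int(valid.sum()),
        alpha=alpha,
    )


def selection_scan(
    alignment: CodonAlignment,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[SelectionEstimate]:
    """Z-tests for the overall, ABS and non-ABS codon partitions."""
    scans = [
        ("overall", None),
        ("ABS", alignment.abs_mask),
        ("non-ABS", alignment.non_abs_mask()),
    ]
    return [
        selection_z_test(
            alignment, mask, n_boot=n_boot, seed=seed, partition=name, alpha=alpha
        )
        for name, mask in scans
    ]
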