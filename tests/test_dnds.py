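import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from lemurmhc import SimulationConfig, generate_allele_pool
from lemurmhc.seqcore import CodonAlignment, Sequence, SiteMap
from lemurmhc.molevol import (
    AnalysisError,
    complete_deletion,
    mean_dnds,
    nei_gojobori_pair,
    selection_scan,
    selection_z_test,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOPS
]


def oracle_sites(codon):
    """Synonymous sites of one codon by direct enumeration (Biopython code)."""
    aa = str(Seq(codon).translate())
    total = 0.0
    for pos in range(3):
        syn = non = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOPS:
                continue
            if str(Seq(alt).translate()) == aa:
                syn += 1
            else:
                non += 1
        if syn + non:
            total += syn / (syn + non)
    return total


def oracle_differences(a, b):
    """(Sd, Nd) between two codons: equal-weight average over orderings of
    the mutational pathway, skipping pathways through stop codons."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    outcomes = []
    for order in itertools.permutations(diffs):
        current, sd, nd, ok = a, 0, 0, True
        for pos in order:
            step = current[:pos] + b[pos] + current[pos + 1 :]
            if step in STOPS:
                ok = False
                break
            if str(Seq(current).translate()) == str(Seq(step).translate()):
                sd += 1
            else:
                nd += 1
            current = step
        if ok:
            outcomes.append((sd, nd))
    assert outcomes, f"no stop-free path {a}->{b}"
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


class TestNeiGojoboriPair:
    def test_identical_sequences(self):
        c = nei_gojobori_pair("ATGTTTGGG", "ATGTTTGGG")
        assert c.Sd == 0 and c.Nd == 0
        assert c.S + c.N == pytest.approx(9.0)

    def test_phe_to_leu_single_nonsynonymous(self):
        c = nei_gojobori_pair("TTT", "TTA")
        assert c.Nd == 1.0 and c.Sd == 0.0

    def test_val_third_position_synonymous(self):
        c = nei_gojobori_pair("GTT", "GTA")
        assert c.Sd == 1.0 and c.Nd == 0.0

    def test_all_sense_codon_pairs_match_enumeration_oracle(self):
        # exhaustive: all 61x61 ordered sense-codon pairs
        sites = {c: oracle_sites(c) for c in SENSE_CODONS}
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                counts = nei_gojobori_pair(a, b)
                sd, nd = oracle_differences(a, b)
                assert counts.Sd == pytest.approx(sd), (a, b)
                assert counts.Nd == pytest.approx(nd), (a, b)
                assert counts.S == pytest.approx((sites[a] + sites[b]) / 2), (a, b)
                assert counts.S + counts.N == pytest.approx(3.0)

    def test_two_difference_codon_follows_pathway_average(self):
        # TTT (Phe) vs GTA (Val): both orderings counted with equal weight
        sd, nd = oracle_differences("TTT", "GTA")
        c = nei_gojobori_pair("TTT", "GTA")
        assert (c.Sd, c.Nd) == (pytest.approx(sd), pytest.approx(nd))

    def test_internal_stop_is_analysis_error_naming_codon(self):
        with pytest.raises(AnalysisError, match="codon 2"):
            nei_gojobori_pair("ATGTAAGGG", "ATGTTTGGG")

    def test_partition_counts_are_conserved(self):
        rng = np.random.default_rng(21)
        a = "".join(rng.choice(SENSE_CODONS, 30))
        b = "".join(rng.choice(SENSE_CODONS, 30))
        mask_abs = set(range(1, 11))
        mask_rest = set(range(11, 31))
        full = nei_gojobori_pair(a, b)
        part_a = nei_gojobori_pair(a, b, mask_abs)
        part_b = nei_gojobori_pair(a, b, mask_rest)
        for attr in ("S", "N", "Sd", "Nd"):
            assert getattr(full, attr) == pytest.approx(
                getattr(part_a, attr) + getattr(part_b, attr)
            )


class TestMeanDnds:
    def test_identical_alignment_zero_rates(self):
        aln = CodonAlignment(
            sequences=tuple(Sequence(f"s{i}", "ATGTTTGGGCAT") for i in range(3))
        )
        dn, ds = mean_dnds(aln)
        assert dn == 0.0 and ds == 0.0

    def test_synonymous_only_alignment(self):
        # two synonymous third-position changes over ten codons
        base = "GTTCCTGGGACTTCAGCTATTACCGAAGAT"
        mutated = "GTACCAGGGACTTCAGCTATTACCGAAGAT"
        aln = CodonAlignment(
            sequences=(Sequence("a", base), Sequence("b", mutated))
        )
        dn, ds = mean_dnds(aln)
        assert dn == 0.0 and ds > 0.0

    def test_five_sequence_alignment_matches_pairwise_recomputation(self):
        rng = np.random.default_rng(31)
        seqs = []
        base = rng.choice(SENSE_CODONS, 12)
        for i in range(5):
            codons = base.copy()
            for k in rng.integers(0, 12, 3):
                codons[k] = rng.choice(SENSE_CODONS)
            seqs.append(Sequence(f"s{i}", "".join(codons)))
        aln = CodonAlignment(sequences=tuple(seqs))
        dn, ds = mean_dnds(aln)

        # independent recomputation: oracle per pair, pooled by averaging
        S = N = Sd = Nd = 0.0
        pairs = list(itertools.combinations(range(5), 2))
        for i, j in pairs:
            a, b = seqs[i].nucleotides, seqs[j].nucleotides
            for k in range(12):
                ca, cb = a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3]
                sa, sb = oracle_sites(ca), oracle_sites(cb)
                sd, nd = oracle_differences(ca, cb)
                S += (sa + sb) / 2
                N += 3 - (sa + sb) / 2
                Sd += sd
                Nd += nd
        S, N, Sd, Nd = (x / len(pairs) for x in (S, N, Sd, Nd))
        expect_ds = -0.75 * np.log1p(-4 * (Sd / S) / 3)
        expect_dn = -0.75 * np.log1p(-4 * (Nd / N) / 3)
        assert ds == pytest.approx(expect_ds)
        assert dn == pytest.approx(expect_dn)


class TestSelectionZTest:
    def test_no_variation_gives_z_zero_p_half(self):
        aln = CodonAlignment(
            sequences=tuple(Sequence(f"s{i}", "ATGTTTGGGCAT") for i in range(3))
        )
        est = selection_z_test(aln, n_boot=50, seed=1)
        assert est.Z == 0.0
        assert est.p_one_tailed == pytest.approx(0.5)

    def test_synonymous_only_alignment_negative_z(self):
        rng = np.random.default_rng(17)
        base = list(rng.choice(SENSE_CODONS, 40))
        seqs = [Sequence("s0", "".join(base))]
        for i in range(1, 5):
            codons = base.copy()
            changed = 0
            for k in rng.permutation(40):
                codon = codons[k]
                syns = [
                    c
                    for c in SENSE_CODONS
                    if sum(x != y for x, y in zip(c, codon)) == 1
                    and str(Seq(c).translate()) == str(Seq(codon).translate())
                ]
                if syns:
                    codons[k] = syns[int(rng.integers(len(syns)))]
                    changed += 1
                if changed >= 8:
                    break
            seqs.append(Sequence(f"s{i}", "".join(codons)))
        est = selection_z_test(CodonAlignment(sequences=tuple(seqs)), n_boot=300, seed=5)
        assert est.Z < 0
        assert est.p_one_tailed > 0.5

    def test_z_matches_its_own_definition(self):
        pool, _ = generate_allele_pool(SimulationConfig(seed=3))
        aln = complete_deletion(
            CodonAlignment.from_sequences([r.sequence for r in pool], SiteMap())
        )
        est = selection_z_test(aln, aln.abs_mask, n_boot=300, seed=2, partition="ABS")
        assert est.Z == pytest.approx(
            (est.dN - est.dS) / np.sqrt(est.var_dN + est.var_dS)
        )
        assert 0 <= est.p_one_tailed <= 1

    def test_abs_enriched_pools_rank_abs_above_nonabs(self):
        # parameter recovery: with ABS nonsynonymous intensity 5x the
        # non-ABS intensity, Z_ABS should exceed Z_nonABS nearly always
        wins = 0
        for seed in range(50):
            config = SimulationConfig(
                seed=seed, alleles_per_species=(8,), n_animals=(4,),
                species_codes=("Eufr",), populations=("P1",),
            )
            pool, _ = generate_allele_pool(config)
            aln = complete_deletion(
                CodonAlignment.from_sequences([r.sequence for r in pool], SiteMap())
            )
            z_abs = selection_z_test(
                aln, aln.abs_mask, n_boot=200, seed=seed, partition="ABS"
            ).Z
            z_non = selection_z_test(
                aln, aln.non_abs_mask(), n_boot=200, seed=seed, partition="non-ABS"
            ).Z
            wins += z_abs > z_non
        assert wins >= 48  # >= 95% of 50 replicates

    def test_scan_returns_three_partitions(self):
        pool, _ = generate_allele_pool(SimulationConfig(seed=12))
        aln = complete_deletion(
            CodonAlignment.from_sequences([r.sequence for r in pool], SiteMap())
        )
        ests = selection_scan(aln, n_boot=100, seed=0)
        assert [e.partition for e in ests] == ["overall", "ABS", "non-ABS"]
        assert "Z-test" in ests[1].summary()
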