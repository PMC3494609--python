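import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from paralogscope import evolution as ev
from paralogscope.io import CodingSequence
from paralogscope.simulate import SeqSimConfig, simulate_codon_pair

from conftest import random_codon_alignment

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 10.0, 1.0


def score_alignment(a1, a2):
    """Affine-gap score of a fixed alignment: gap run of length k costs
    GAP_OPEN + k * GAP_EXTEND."""
    score = 0.0
    in_gap1 = in_gap2 = False
    for x, y in zip(a1, a2):
        if x == "-":
            score -= GAP_EXTEND + (0 if in_gap1 else GAP_OPEN)
            in_gap1, in_gap2 = True, False
        elif y == "-":
            score -= GAP_EXTEND + (0 if in_gap2 else GAP_OPEN)
            in_gap1, in_gap2 = False, True
        else:
            score += BLOSUM62[x, y]
            in_gap1 = in_gap2 = False
    return score


def enumerate_alignments(s1, s2):
    """All global alignments (no gap-vs-gap column) of two short strings."""
    if not s1 and not s2:
        yield "", ""
        return
    if s1:
        for a1, a2 in enumerate_alignments(s1[1:], s2):
            yield s1[0] + a1, "-" + a2
    if s2:
        for a1, a2 in enumerate_alignments(s1, s2[1:]):
            yield "-" + a1, s2[0] + a2
    if s1 and s2:
        for a1, a2 in enumerate_alignments(s1[1:], s2[1:]):
            yield s1[0] + a1, s2[0] + a2


class TestTranslate:
    def test_codon_table(self):
        assert ev.translate_codons(CodingSequence("g", "ATGGCC")) == "MA"

    def test_terminal_stop_stripped(self):
        assert ev.translate_codons(CodingSequence("g", "ATGTAA")) == "M"

    def test_internal_stop_names_codon(self):
        with pytest.raises(ev.TranslationError, match="codon 2"):
            ev.translate_codons(CodingSequence("g", "ATGTAAGCC"))


class TestAlignProteinPair:
    def test_identity(self):
        aln = ev.align_protein_pair("MAV", "MAV")
        assert (aln.aligned1, aln.aligned2) == ("MAV", "MAV")

    def test_empty_input(self):
        with pytest.raises(ev.AlignmentError):
            ev.align_protein_pair("M", "")

    @pytest.mark.parametrize("s1,s2", [("MAV", "MV"), ("MKTA", "MTA"), ("WW", "WAW")])
    def test_optimal_against_enumeration(self, s1, s2):
        aln = ev.align_protein_pair(s1, s2)
        best = max(score_alignment(a1, a2) for a1, a2 in enumerate_alignments(s1, s2))
        assert score_alignment(aln.aligned1, aln.aligned2) == best
        assert aln.score == best

    def test_gap_vs_gap_rejected(self):
        with pytest.raises(ev.AlignmentError):
            ev.ProteinAlignment("M-A", "M-V", 0.0)


class TestBuildCodonAlignment:
    def test_no_gaps(self):
        aln = ev.ProteinAlignment("MA", "MA", 0.0)
        ca = ev.build_codon_alignment(
            aln, CodingSequence("a", "ATGGCC"), CodingSequence("b", "ATGGCG")
        )
        assert ca.codon_columns == (("ATG", "ATG"), ("GCC", "GCG"))

    def test_gap_column_dropped(self):
        aln = ev.ProteinAlignment("MA-", "MAV", 0.0)
        ca = ev.build_codon_alignment(
            aln, CodingSequence("a", "ATGGCC"), CodingSequence("b", "ATGGCGGTG")
        )
        assert len(ca) == 2

    def test_mismatch_error(self):
        aln = ev.ProteinAlignment("MA", "MA", 0.0)
        with pytest.raises(ev.AlignmentError, match="mismatch"):
            ev.build_codon_alignment(
                aln, CodingSequence("a", "ATGTCC"), CodingSequence("b", "ATGGCG")
            )


class TestDivergence:
    def test_identical(self):
        aln = ev.ProteinAlignment("M" * 100, "M" * 100, 0.0)
        assert ev.amino_acid_divergence(aln) == 0.0

    def test_one_in_hundred(self):
        aln = ev.ProteinAlignment("M" * 100, "A" + "M" * 99, 0.0)
        assert ev.amino_acid_divergence(aln) == 1.0

    def test_hand_count(self):
        aln = ev.ProteinAlignment("MAVL", "MIVL", 0.0)
        assert ev.amino_acid_divergence(aln) == 25.0

    def test_no_shared_columns(self):
        aln = ev.ProteinAlignment("M-", "-V", 0.0)
        with pytest.raises(ev.AlignmentError):
            ev.amino_acid_divergence(aln)


UNIFORM = ev.Tn93Params(0.25, 0.25, 0.25, 0.25, 1.0, 1.0)


class TestTn93Distance:
    def test_zero_differences(self):
        assert ev.tn93_distance(ev.DiffSummary(0, 0, 0, 300), UNIFORM) == 0.0

    def test_jc_limit(self):
        p = 0.1
        d = ev.DiffSummary(p / 6, p / 6, 2 * p / 3, 3000)
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert ev.tn93_distance(d, UNIFORM) == pytest.approx(expected, abs=1e-9)

    def test_saturation(self):
        # Q large enough that 1 - Q/(2 pi_R pi_Y) <= 0
        assert ev.tn93_distance(ev.DiffSummary(0, 0, 0.6, 300), UNIFORM) is None

    def test_gamma_infinite_shape_matches_log(self):
        d = ev.DiffSummary(0.05, 0.04, 0.06, 3000)
        log_d = ev.tn93_distance(d, UNIFORM)
        gamma_d = ev.tn93_distance(d, UNIFORM.with_gamma(1e9))
        assert gamma_d == pytest.approx(log_d, abs=1e-6)

    def test_gamma_correction_exceeds_log(self):
        d = ev.DiffSummary(0.05, 0.04, 0.06, 3000)
        log_d = ev.tn93_distance(d, UNIFORM)
        prev = log_d
        for shape in (100.0, 10.0, 1.0, 0.5):
            g = ev.tn93_distance(d, UNIFORM.with_gamma(shape))
            assert g >= prev - 1e-12
            prev = g


class TestEstimateTn93Params:
    def test_no_differences_fallback(self):
        ca = ev.CodonAlignment((("ACG", "ACG"), ("TCA", "TCA"), ("GAT", "GAT"),
                                ("CTG", "CTG")))
        params = ev.estimate_tn93_params(ca)
        assert params.kappa_R == params.kappa_Y == 1.0
        assert params.pi_A == pytest.approx(0.25)

    def test_purine_transitions_only(self):
        # single A<->G difference, no transversions
        ca = ev.CodonAlignment((("AAA", "AAG"), ("CCT", "CCT"), ("GGC", "GGC"),
                                ("TTT", "TTT")))
        params = ev.estimate_tn93_params(ca)
        assert params.kappa_R > params.kappa_Y

    def test_kappa_recovery_simulation(self):
        cfg = SeqSimConfig(n_codons=10_000, branch_length_s=0.3, omega_true=1.0,
                           kappa_R=4.0, kappa_Y=4.0, seed=7)
        s1, s2, _ = simulate_codon_pair(cfg)
        ca = ev.CodonAlignment(tuple(zip(s1.codons(), s2.codons())))
        params = ev.estimate_tn93_params(ca)
        assert params.kappa_R == pytest.approx(4.0, rel=0.15)
        assert params.kappa_Y == pytest.approx(4.0, rel=0.15)


class TestNg86:
    def test_identical_sequences(self):
        ca = ev.CodonAlignment((("ATG", "ATG"), ("GCC", "GCC")))
        est = ev.ng86_kaks(ca)
        assert est.Sd == est.Nd == 0
        assert est.ka == 0 and est.ks == 0
        assert est.omega is None

    def test_hand_computed_glycine_pair(self):
        ca = ev.CodonAlignment((("GGT", "GGC"), ("GGA", "GGA")))
        est = ev.ng86_kaks(ca)
        assert est.S == pytest.approx(2.0)
        assert est.N == pytest.approx(4.0)
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)
        assert est.ka == pytest.approx(0.0)
        assert est.ks == pytest.approx(-0.75 * math.log(1 - 4 * 0.5 / 3), abs=1e-4)

    def test_symmetry(self, rng):
        ca = random_codon_alignment(rng, 30)
        flipped = ev.CodonAlignment(tuple((b, a) for a, b in ca.codon_columns))
        e1, e2 = ev.ng86_kaks(ca), ev.ng86_kaks(flipped)
        assert e1.S == pytest.approx(e2.S)
        assert e1.Sd == pytest.approx(e2.Sd)
        assert (e1.ks is None) == (e2.ks is None)
        if e1.ks is not None:
            assert e1.ks == pytest.approx(e2.ks)


def oracle_pathway_counts(c1, c2):
    """Independent exhaustive-pathway oracle: mean (syn, nonsyn) step counts
    over all stop-free permutations of the differing positions."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in ev.STOP_CODONS:
                ok = False
                break
            steps.append(ev.GENETIC_CODE[cur] == ev.GENETIC_CODE[nxt])
            cur = nxt
        if ok:
            totals.append((sum(steps), len(steps) - sum(steps)))
    if not totals:
        return None
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


class TestPathwayOracle:
    def test_counts_match_exhaustive_oracle(self, rng):
        sense = sorted(ev.GENETIC_CODE)
        for _ in range(400):
            c1, c2 = rng.choice(sense, size=2)
            expected = oracle_pathway_counts(c1, c2)
            counts = ev.count_pathway_differences(c1, c2)
            if expected is None:
                continue
            syn = sum(counts["syn"].values())
            nonsyn = sum(counts["nonsyn"].values())
            assert syn == pytest.approx(expected[0], abs=1e-12), (c1, c2)
            assert nonsyn == pytest.approx(expected[1], abs=1e-12), (c1, c2)


class TestMyn:
    def test_identical_sequences(self):
        ca = ev.CodonAlignment((("ATG", "ATG"), ("GCC", "GCC")))
        est = ev.myn_kaks(ca)
        assert est.ka == 0 and est.ks == 0

    def test_unbiased_limit_matches_ng86(self):
        cfg = SeqSimConfig(n_codons=200, branch_length_s=0.3, omega_true=0.5,
                           kappa_R=1.0, kappa_Y=1.0, seed=11)
        s1, s2, _ = simulate_codon_pair(cfg)
        ca = ev.CodonAlignment(tuple(zip(s1.codons(), s2.codons())))
        myn = ev.myn_kaks(ca, params=UNIFORM)
        ng = ev.ng86_kaks(ca)
        assert abs(myn.ka - ng.ka) <= 0.01
        assert abs(myn.ks - ng.ks) <= 0.02

    def test_symmetry(self, rng):
        ca = random_codon_alignment(rng, 40)
        flipped = ev.CodonAlignment(tuple((b, a) for a, b in ca.codon_columns))
        e1, e2 = ev.myn_kaks(ca), ev.myn_kaks(flipped)
        assert (e1.ks is None) == (e2.ks is None)
        if e1.ks is not None:
            assert e1.ks == pytest.approx(e2.ks)
        if e1.ka is not None:
            assert e1.ka == pytest.approx(e2.ka)


@pytest.fixture(scope="module")
def simulated_ca():
    cfg = SeqSimConfig(n_codons=300, branch_length_s=0.5, omega_true=0.3, seed=3)
    s1, s2, _ = simulate_codon_pair(cfg)
    return ev.CodonAlignment(tuple(zip(s1.codons(), s2.codons())))


class TestGammaMyn:
    def test_identical_sequences_any_shape(self):
        ca = ev.CodonAlignment((("ATG", "ATG"), ("GCC", "GCC")))
        for shape in (0.2, 1.0, 50.0):
            est = ev.gamma_myn_kaks(ca, gamma_shape=shape)
            assert est.ka == 0 and est.ks == 0

    def test_large_shape_limit_equals_myn(self, simulated_ca):
        myn = ev.myn_kaks(simulated_ca)
        gmyn = ev.gamma_myn_kaks(simulated_ca, gamma_shape=1e6)
        assert abs(gmyn.ka - myn.ka) <= 1e-4
        assert abs(gmyn.ks - myn.ks) <= 1e-4
        assert gmyn.method == "gMYN"

    def test_distance_monotone_in_shape(self, simulated_ca):
        shapes = [1e6, 100.0, 10.0, 2.0, 1.0, 0.5]
        ks_values = [
            ev.gamma_myn_kaks(simulated_ca, gamma_shape=s).ks for s in shapes
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ks_values, ks_values[1:]))

    def test_invalid_shape(self):
        ca = ev.CodonAlignment((("ATG", "ATG"), ("GCC", "GCC")))
        with pytest.raises(ValueError):
            ev.gamma_myn_kaks(ca, gamma_shape=0.0)


class TestSiteConservation:
    @pytest.mark.parametrize("estimator", [ev.ng86_kaks, ev.myn_kaks])
    def test_s_plus_n(self, estimator, rng):
        for n in (2, 10, 33):
            ca = random_codon_alignment(rng, n)
            est = estimator(ca)
            assert est.S + est.N == pytest.approx(3 * n, abs=1e-6)


class TestPairPipeline:
    def test_identical_genes(self):
        g = CodingSequence("g", "ATGGCCGTTCTG")
        est, div = ev.pair_kaks_pipeline(g, g)
        assert est.ka == 0 and est.ks == 0
        assert div == 0.0

    def test_internal_stop_propagates(self):
        g1 = CodingSequence("g1", "ATGTAAGCC")
        g2 = CodingSequence("g2", "ATGGCCGCC")
        with pytest.raises(ev.TranslationError):
            ev.pair_kaks_pipeline(g1, g2)

    def test_simulated_recovery_single_pair(self):
        cfg = SeqSimConfig(n_codons=500, branch_length_s=0.4, omega_true=0.3, seed=21)
        s1, s2, truth = simulate_codon_pair(cfg)
        est, div = ev.pair_kaks_pipeline(s1, s2, method="MYN")
        assert est.omega == pytest.approx(0.3, rel=0.5)
        assert est.ks == pytest.approx(truth.ks_realized, rel=0.35)

    def test_unknown_method(self):
        g = CodingSequence("g", "ATGGCCGTT")
        with pytest.raises(ValueError, match="method"):
            ev.pair_kaks_pipeline(g, g, method="codeml")
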