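"""Code-length mathematics: entropy, multinomial NML, Dirichlet mixtures,
the generic exponential-family expansion, and the exact Shtarkov oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdlseq import (
    BoundaryMLEError,
    DirichletPrior,
    SymbolSequence,
    WordCounts,
    WordSequence,
    bayes_expansion,
    bic_codelength,
    count_words,
    empirical_entropy,
    fisher_det_multinomial,
    gaussian_mean_family,
    iid_string,
    jeffreys_log_integral_multinomial,
    lz78_codelength,
    mixture_codelength_dirichlet,
    multinomial_complexity_bits,
    multinomial_family,
    nml_codelength_exact,
    nml_codelength_multinomial,
    nml_parametric_expansion,
    parse_fixed_length,
    predictive_codelength_sequential,
    shtarkov_normalizer_exact,
)
from mdlseq.simulate import SourceSpec

count_vectors = st.lists(st.integers(1, 50), min_size=2, max_size=8)


def wc_of(*counts) -> WordCounts:
    return WordCounts.from_vector(counts)


class TestEmpiricalEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 1, 1, 1], 2.0),
            ([4], 0.0),
            ([3, 1], 0.8112781244591328),  # -(3/4)log2(3/4) - (1/4)log2(1/4)
        ],
    )
    def test_direct_values(self, counts, expected):
        assert empirical_entropy(wc_of(*counts)) == pytest.approx(expected, abs=1e-12)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            empirical_entropy(WordCounts({}))

    @given(count_vectors)
    def test_bounded_by_log_dictionary_size(self, counts):
        h = empirical_entropy(wc_of(*counts))
        assert -1e-12 <= h <= math.log2(len(counts)) + 1e-12


class TestMultinomialNML:
    @pytest.mark.parametrize(
        "n, m, rest",
        [
            (2907, 4, 16.58),
            (1453, 16, 59.81),
            (969, 58, 157.11),
            (726, 218, 345.07),
            (969, 21, 69.92),
        ],
    )
    def test_complexity_terms_at_gene_scale(self, n, m, rest):
        assert multinomial_complexity_bits(n, m) == pytest.approx(rest, abs=0.005)

    def test_breakdown_sums(self):
        bd = nml_codelength_multinomial(wc_of(3, 1))
        assert bd.total_bits == pytest.approx(bd.entropy_bits + bd.complexity_bits)
        assert bd.entropy_bits == pytest.approx(4 * 0.8112781244591328)

    def test_degenerate_single_word_dictionary_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="single-word"):
            assert multinomial_complexity_bits(100, 1) == 0.0

    def test_no_overflow_for_huge_dictionaries(self):
        val = multinomial_complexity_bits(10**6, 10**4)
        assert math.isfinite(val) and val > 0

    @given(st.integers(2, 30))
    def test_complexity_increases_with_n_and_d(self, m):
        # strictly increasing in n at fixed d >= 1, increasing in d at fixed n
        ns = [10, 100, 1000]
        vals = [multinomial_complexity_bits(n, m) for n in ns]
        assert vals[0] < vals[1] < vals[2]
        assert multinomial_complexity_bits(100, m) < multinomial_complexity_bits(100, m + 1)


class TestBIC:
    def test_gene_scale_value(self):
        # 0.5 * 218 * log2(726) ~ 1036 bits
        # n = 726 words over 219 distinct: d = 218
        assert bic_codelength(wc_of(*([3] * 150 + [4] * 69))).complexity_bits == \
            pytest.approx(0.5 * 218 * math.log2(726), abs=1e-9)
        assert 0.5 * 218 * math.log2(726) == pytest.approx(1036, abs=1)

    def test_binary_closed_form(self):
        assert bic_codelength(wc_of(1500, 1500)).complexity_bits == \
            pytest.approx(0.5 * math.log2(3000))

    def test_dimension_zero_is_free(self):
        assert bic_codelength(wc_of(7)).complexity_bits == 0.0


class TestFisherAndJeffreys:
    @pytest.mark.parametrize(
        "p, det",
        [((0.5, 0.5), 4.0), ((0.25,) * 4, 256.0), ((0.5, 0.25, 0.25), 32.0)],
    )
    def test_fisher_determinant(self, p, det):
        assert fisher_det_multinomial(p) == pytest.approx(det)

    def test_rejects_boundary_probabilities(self):
        with pytest.raises(ValueError):
            fisher_det_multinomial((1.0, 0.0))

    @pytest.mark.parametrize("d, expected", [(1, math.log2(math.pi)),
                                             (3, 2 * math.log2(math.pi))])
    def test_jeffreys_integral_closed_form(self, d, expected):
        assert jeffreys_log_integral_multinomial(d) == pytest.approx(expected)

    @given(st.integers(2, 2000), st.integers(2, 200))
    def test_generic_expansion_with_jeffreys_matches_multinomial_form(self, n, m):
        spec = multinomial_family(m)
        wc = wc_of(*([1] * (m - 1) + [n - m + 1])) if n >= m else None
        if wc is None:
            return
        asym = nml_parametric_expansion(spec, wc)
        assert asym.complexity_bits == pytest.approx(
            multinomial_complexity_bits(n, m), abs=1e-9
        )


class TestGenericExpansionSecondInstance:
    def test_gaussian_mean_on_interval(self):
        # |I| = 1/sigma^2 on [-a, a]: integral term log2(2a/sigma)
        spec = gaussian_mean_family(half_width=1.0, sigma=1.0)
        bd = nml_parametric_expansion(spec, wc_of(50, 50))
        assert bd.complexity_bits == pytest.approx(
            0.5 * math.log2(100 / (2 * math.pi)) + 1.0
        )

    def test_quadrupling_n_adds_one_bit_at_dimension_one(self):
        spec = multinomial_family(2)
        a = nml_parametric_expansion(spec, wc_of(50, 50)).complexity_bits
        b = nml_parametric_expansion(spec, wc_of(200, 200)).complexity_bits
        assert b - a == pytest.approx(1.0, abs=1e-12)

    def test_infinite_integral_is_refused(self):
        with pytest.raises(ValueError, match="finite"):
            gaussian_mean_family(half_width=math.inf)


class TestDirichletMixture:
    def test_single_symbol_jeffreys(self):
        ws = WordSequence(("0",), 1)
        wc = count_words(ws)
        bd = mixture_codelength_dirichlet(wc, DirichletPrior.jeffreys(2),
                                          support=["0", "1"])
        assert bd.total_bits == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "seq, expected_bits",
        [("01", 3.0), ("00", math.log2(8 / 3))],
    )
    def test_two_symbol_sequences_jeffreys(self, seq, expected_bits):
        wc = count_words(WordSequence(tuple(seq), 2))
        bd = mixture_codelength_dirichlet(wc, DirichletPrior.jeffreys(2),
                                          support=["0", "1"])
        assert bd.total_bits == pytest.approx(expected_bits, abs=1e-12)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            DirichletPrior((0.5, -1.0))

    def test_word_outside_support_rejected(self):
        ws = WordSequence(("0", "2"), 2)
        with pytest.raises(ValueError, match="support"):
            predictive_codelength_sequential(ws, DirichletPrior.jeffreys(2),
                                             support=["0", "1"])

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=40),
        st.lists(st.floats(0.1, 5.0), min_size=4, max_size=4),
        st.randoms(use_true_random=False),
    )
    def test_sequential_predictive_equals_closed_form(self, word_ids, alphas, rnd):
        """One-pass posterior-predictive coding totals the mixture marginal."""
        words = tuple(str(i) for i in word_ids)
        ws = WordSequence(words, len(words))
        prior = DirichletPrior(tuple(alphas))
        support = ["0", "1", "2", "3"]
        seq_bits = predictive_codelength_sequential(ws, prior, support)
        closed = mixture_codelength_dirichlet(count_words(ws), prior, support)
        assert seq_bits == pytest.approx(closed.total_bits, abs=1e-9)
        # exchangeability: any permutation of the words gives the same total
        shuffled = list(words)
        rnd.shuffle(shuffled)
        assert predictive_codelength_sequential(
            WordSequence(tuple(shuffled), len(words)), prior, support
        ) == pytest.approx(seq_bits, abs=1e-9)

    def test_single_word_costs_minus_log_prior_mean(self):
        prior = DirichletPrior((2.0, 3.0, 5.0))
        ws = WordSequence(("b",), 1)
        bits = predictive_codelength_sequential(ws, prior, support=["a", "b", "c"])
        assert bits == pytest.approx(-math.log2(3.0 / 10.0))


class TestBayesExpansion:
    def test_jeffreys_prior_recovers_nml_expansion(self):
        wc = wc_of(600, 400)
        spec = multinomial_family(2)
        bayes = bayes_expansion(spec, wc)  # default prior = Jeffreys
        asym = nml_parametric_expansion(spec, wc)
        assert bayes.total_bits == pytest.approx(asym.total_bits, abs=1e-9)

    def test_uniform_prior_closed_form_assembly(self):
        wc = wc_of(600, 400)
        spec = multinomial_family(2)
        bd = bayes_expansion(spec, wc, log2_prior_at_mle=0.0)
        expected = 0.5 * math.log2(1000 / (2 * math.pi)) + \
            0.5 * math.log2(fisher_det_multinomial((0.6, 0.4)))
        assert bd.complexity_bits == pytest.approx(expected, abs=1e-12)

    def test_boundary_mle_refused(self):
        wc = wc_of(5, 5)
        with pytest.raises(BoundaryMLEError):
            bayes_expansion(multinomial_family(2), wc, support_size=3)

    def test_converges_to_exact_mixture_as_n_grows(self):
        """At fixed composition the expansion error shrinks with n."""
        prior = DirichletPrior.jeffreys(3)
        gaps = []
        for scale in (1, 4, 16, 64):
            wc = wc_of(6 * scale, 3 * scale, 1 * scale)
            exact = mixture_codelength_dirichlet(wc, prior).total_bits
            approx = bayes_expansion(multinomial_family(3), wc).total_bits
            gaps.append(abs(exact - approx))
        assert gaps[3] < gaps[2] < gaps[1] < gaps[0]
        assert gaps[3] < 0.02


class TestShtarkovOracle:
    @pytest.mark.parametrize(
        "n, m, expected",
        [(1, 2, 1.0), (2, 2, math.log2(2.5)), (3, 2, math.log2(26 / 9))],
    )
    def test_small_cases_match_brute_force_by_hand(self, n, m, expected):
        assert shtarkov_normalizer_exact(n, m) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n, m", [(2, 2), (4, 2), (6, 2), (3, 3), (5, 3)])
    def test_composition_dp_equals_full_sequence_enumeration(self, n, m):
        total = 0.0
        for x in itertools.product(range(m), repeat=n):
            counts = np.bincount(x, minlength=m).astype(float)
            p_hat = counts / n
            total += float(np.prod(p_hat**counts))
        assert shtarkov_normalizer_exact(n, m) == pytest.approx(
            math.log2(total), abs=1e-10
        )

    @pytest.mark.parametrize("n, m", [(4, 2), (6, 2), (5, 3), (6, 3)])
    def test_exact_nml_satisfies_kraft_with_equality(self, n, m):
        """2^(-L_exact) over all m^n sequences is a probability distribution."""
        log_c = shtarkov_normalizer_exact(n, m)
        mass = 0.0
        for x in itertools.product(range(m), repeat=n):
            counts = np.bincount(x, minlength=m)
            observed = counts[counts > 0]
            wc = WordCounts.from_vector(observed)
            l_exact = wc.n * empirical_entropy(wc) + log_c
            mass += 2.0 ** (-l_exact)
        assert mass == pytest.approx(1.0, abs=1e-9)

    def test_size_guard_refuses_huge_enumerations(self):
        with pytest.raises(ValueError, match="guard"):
            shtarkov_normalizer_exact(10**4, 10)

    @pytest.mark.parametrize("m", [2, 3])
    def test_asymptotic_complexity_approaches_exact_normalizer(self, m):
        gaps = [
            abs(multinomial_complexity_bits(n, m) - shtarkov_normalizer_exact(n, m))
            for n in (50, 200, 500)
        ]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.1

    def test_exact_codelength_helper_uses_observed_dictionary(self):
        wc = wc_of(3, 1)
        expected = 4 * empirical_entropy(wc) + shtarkov_normalizer_exact(4, 2)
        assert nml_codelength_exact(wc) == pytest.approx(expected)


class TestLZ78CodeLength:
    @pytest.mark.parametrize(
        "c, alpha, expected",
        [
            (635, 4, 635 * math.log2(635) + 635 * 2),  # ~5912 + 1270 bits
            (1, 2, 1.0),
            (0, 2, 0.0),
        ],
    )
    def test_phrase_count_formula(self, c, alpha, expected):
        assert lz78_codelength(c, alpha) == pytest.approx(expected)

    def test_gene_scale_address_bits_round_to_printed_values(self):
        assert 635 * math.log2(635) == pytest.approx(5912, abs=1)


class TestUnderestimateProperty:
    def test_plugin_entropy_underestimates_source_entropy_on_average(self):
        """n.H(theta_hat) falls below n.H(theta_0) on average: the plug-in
        bound is an underestimate for i.i.d. sources."""
        p0 = (0.5, 0.5)
        n = 400
        deficits = []
        for seed in range(30):
            seq = iid_string(SourceSpec(("0", "1"), p0, n, seed=seed))
            wc = count_words(parse_fixed_length(seq, 1))
            deficits.append(n * 1.0 - wc.n * empirical_entropy(wc))
        assert np.mean(deficits) > 0
        assert min(deficits) >= 0  # H(p_hat) <= log2 2 = H(p0) at p0 uniform
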