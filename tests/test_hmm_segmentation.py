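"""Emission model, forward-backward, EM training and MR decoding."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from scipy.stats import betabinom

import methylseg as ms
from methylseg.hmm_segmentation import (
    STATE_HIGH,
    STATE_LOW,
    BetaBinomialParams,
    DomainError,
    HMMModel,
    ObservationChain,
    baum_welch,
    bb_log_pmf,
    chains_from_methylome,
    decode_regions,
    forward_backward,
    train_models,
)
from methylseg.io_formats import CONTEXTS, ValidationError
from methylseg.methylome import SampleMethylome


# ---------------------------------------------------------------------------
# beta-binomial emission


class TestBetaBinomialPmf:
    def test_empty_support(self):
        assert bb_log_pmf(0, 0, BetaBinomialParams(2.0, 3.0)) == pytest.approx(0.0)

    def test_uniform_case(self):
        # alpha = beta = 1 makes every k equally likely
        p = BetaBinomialParams(1.0, 1.0)
        for k in range(5):
            assert bb_log_pmf(k, 4, p) == pytest.approx(math.log(1 / 5))

    def test_exact_fraction_oracle(self):
        # C(10,3) * B(3+2, 7+5) / B(2,5) computed with exact integer
        # arithmetic: B(a,b) = (a-1)!(b-1)!/(a+b-1)! for integer shapes
        def fact(x):
            return math.factorial(x)

        def beta_fn(a, b):
            return Fraction(fact(a - 1) * fact(b - 1), fact(a + b - 1))

        expected = Fraction(math.comb(10, 3)) * beta_fn(5, 12) / beta_fn(2, 5)
        got = math.exp(bb_log_pmf(3, 10, BetaBinomialParams(2.0, 5.0)))
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_matches_scipy_reference(self):
        p = BetaBinomialParams(2.5, 0.7)
        ks = np.arange(0, 13)
        ours = bb_log_pmf(ks, 12, p)
        ref = betabinom.logpmf(ks, 12, p.alpha, p.beta)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bb_log_pmf(5, 3, BetaBinomialParams(1.0, 1.0))
        with pytest.raises(DomainError):
            BetaBinomialParams(-1.0, 2.0)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0, 50.0])
    @pytest.mark.parametrize("beta", [0.1, 1.0, 8.0])
    def test_normalisation(self, alpha, beta):
        p = BetaBinomialParams(alpha, beta)
        for n in (1, 7, 50):
            total = np.exp(bb_log_pmf(np.arange(n + 1), n, p)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# forward-backward vs brute-force path enumeration


def brute_force_fb(obs, model):
    """Enumerate all state paths: reference for likelihood and posteriors."""
    a, b = model.emission_arrays()
    T = len(obs)
    total = 0.0
    post = np.zeros((T, 2))
    for path in product((0, 1), repeat=T):
        prob = model.initial[path[0]]
        for t in range(1, T):
            prob *= model.transition[path[t - 1], path[t]]
        for t, (k, n, ctx) in enumerate(obs):
            ci = CONTEXTS.index(ctx)
            prob *= math.exp(
                bb_log_pmf(k, n, BetaBinomialParams(a[path[t], ci], b[path[t], ci]))
            )
        total += prob
        for t in range(T):
            post[t, path[t]] += prob
    return math.log(total), post / total


def _grid_models():
    models = []
    for p_stay_low, p_stay_high in [(0.9, 0.8), (0.6, 0.6), (0.99, 0.5)]:
        for mlow, mhigh in [(0.05, 0.9), (0.3, 0.6)]:
            emission = {}
            for ctx in CONTEXTS:
                emission[(STATE_LOW, ctx)] = BetaBinomialParams.from_mean_dispersion(mlow, 0.2)
                emission[(STATE_HIGH, ctx)] = BetaBinomialParams.from_mean_dispersion(mhigh, 0.1)
            models.append(
                HMMModel(
                    np.array([0.7, 0.3]),
                    np.array([[p_stay_low, 1 - p_stay_low], [1 - p_stay_high, p_stay_high]]),
                    emission,
                )
            )
    return models


class TestForwardBackward:
    def test_length_one_posterior_is_scaled_initial_emission(self):
        model = _grid_models()[0]
        obs = [(3, 5, "CG")]
        ll, gamma = forward_backward(obs, model)
        a, b = model.emission_arrays()
        weights = np.array(
            [
                model.initial[s]
                * math.exp(bb_log_pmf(3, 5, BetaBinomialParams(a[s, 0], b[s, 0])))
                for s in (0, 1)
            ]
        )
        np.testing.assert_allclose(gamma[0], weights / weights.sum(), atol=1e-12)
        assert ll == pytest.approx(math.log(weights.sum()))

    def test_symmetric_model_gives_uniform_posterior(self):
        emission = {
            (s, ctx): BetaBinomialParams(2.0, 2.0) for s in (0, 1) for ctx in CONTEXTS
        }
        model = HMMModel(np.array([0.5, 0.5]), np.full((2, 2), 0.5), emission)
        _, gamma = forward_backward([(1, 4, "CG"), (2, 6, "CHH"), (0, 3, "CHG")], model)
        np.testing.assert_allclose(gamma, 0.5, atol=1e-12)

    def test_length_three_equals_path_enumeration(self):
        model = _grid_models()[0]
        obs = [(0, 5, "CG"), (4, 4, "CHG"), (5, 6, "CHH")]
        ll, gamma = forward_backward(obs, model)
        ll_ref, post_ref = brute_force_fb(obs, model)
        assert ll == pytest.approx(ll_ref, abs=1e-10)
        np.testing.assert_allclose(gamma, post_ref, atol=1e-10)

    def test_posteriors_sum_to_one_on_long_sequence(self, known_model_chain):
        chain, _ = known_model_chain
        model = HMMModel.default_init()
        ll, gamma = forward_backward(chain, model)
        assert np.isfinite(ll)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_enumeration_agreement_over_model_and_sequence_grid(self):
        # property: FB == brute force for every sequence up to length 5
        # across a model grid (deterministic observation grid)
        rng = np.random.default_rng(0)
        n_cases = 0
        for model in _grid_models():
            for T in (1, 2, 3, 5):
                for _ in range(6):
                    ks = rng.integers(0, 6, T)
                    ns = ks + rng.integers(0, 5, T)
                    ctxs = rng.choice(CONTEXTS, T)
                    obs = [(int(k), int(n), c) for k, n, c in zip(ks, ns, ctxs)]
                    ll, gamma = forward_backward(obs, model)
                    ll_ref, post_ref = brute_force_fb(obs, model)
                    assert abs(ll - ll_ref) < 1e-9
                    assert np.abs(gamma - post_ref).max() < 1e-9
                    n_cases += 1
        assert n_cases >= 100


# ---------------------------------------------------------------------------
# Baum-Welch


class TestBaumWelch:
    def test_loglik_trace_non_decreasing(self, known_model_chain):
        chain, _ = known_model_chain
        result = baum_welch([chain], max_iter=15)
        trace = result.loglik_trace
        assert all(b - a >= -1e-6 * abs(a) for a, b in zip(trace, trace[1:]))

    def test_single_iteration_does_not_decrease_loglik(self, known_model_chain):
        chain, _ = known_model_chain
        result = baum_welch([chain], max_iter=2, tol=0.0)
        assert len(result.loglik_trace) == 2
        assert result.loglik_trace[1] >= result.loglik_trace[0] - 1e-6

    def test_max_iter_zero_returns_init_unchanged(self, known_model_chain):
        chain, _ = known_model_chain
        init = HMMModel.default_init()
        result = baum_welch([chain], init=init, max_iter=0)
        assert result.loglik_trace == []
        np.testing.assert_array_equal(result.model.transition, init.transition)

    def test_parameter_recovery_from_known_model(self, known_model_chain):
        chain, truth = known_model_chain
        result = baum_welch([chain])
        model = result.model
        for ctx in CONTEXTS:
            assert model.emission[(STATE_HIGH, ctx)].mean == pytest.approx(
                truth["mean_high"], abs=0.05
            )
            assert model.emission[(STATE_LOW, ctx)].mean == pytest.approx(
                truth["mean_low"], abs=0.05
            )
        assert model.transition[0, 0] == pytest.approx(truth["transition"][0, 0], abs=0.02)
        assert model.transition[1, 1] == pytest.approx(truth["transition"][1, 1], abs=0.02)

    def test_degenerate_all_zero_data_is_flagged(self):
        chain = ObservationChain(
            "c", np.arange(300), np.zeros(300, int), np.full(300, 10), np.zeros(300, int)
        )
        result = baum_welch([chain], max_iter=10)
        assert result.no_high_state_support
        # LOW state dominates the chain
        assert result.model.transition[STATE_LOW, STATE_LOW] > 0.9

    def test_sparse_context_keeps_initialisation(self):
        rng = np.random.default_rng(3)
        n = 500
        ctx = np.zeros(n, int)  # CG only; CHG and CHH have no sites
        cov = rng.poisson(10, n) + 1
        k = rng.binomial(cov, 0.05)
        chain = ObservationChain("c", np.arange(n) * 10, k, cov, ctx)
        init = HMMModel.default_init()
        result = baum_welch([chain], init=init, max_iter=5)
        assert any("CHG" in w for w in result.warnings)
        assert result.model.emission[(STATE_HIGH, "CHG")] == init.emission[(STATE_HIGH, "CHG")]


# ---------------------------------------------------------------------------
# decoding


def _planted_methylome(seed=0, block_rate=0.9, background=0.02, n_block=200, n_flank=5000):
    rng = np.random.default_rng(seed)
    n = n_flank * 2 + n_block
    pos = np.sort(rng.choice(n * 20, n, replace=False))
    block = slice(n_flank, n_flank + n_block)
    levels = np.full(n, background)
    levels[block] = block_rate
    cov = rng.poisson(10, n) + 1
    k = rng.binomial(cov, levels)
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": "Chr1", "pos": pos, "strand": "+",
            "context": rng.choice(CONTEXTS, n), "n_meth": k, "n_total": cov,
        }
    )
    truth = (int(pos[block][0]), int(pos[block][-1]) + 1)
    return SampleMethylome("s", df), truth


class TestDecodeRegions:
    def test_all_zero_methylome_yields_no_mrs(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "chrom": "Chr1", "pos": np.arange(500) * 10, "strand": "+",
                "context": "CG", "n_meth": 0, "n_total": 10,
            }
        )
        mrs = decode_regions(SampleMethylome("s", df), HMMModel.default_init())
        assert mrs == []

    def test_planted_block_recovered_within_two_sites(self):
        meth, (t_start, t_end) = _planted_methylome(seed=11)
        result = baum_welch(chains_from_methylome(meth, desert_distance=10**9))
        mrs = decode_regions(meth, result.model, desert_distance=10**9)
        assert len(mrs) == 1
        mr = mrs[0]
        pos = meth.sites["pos"].to_numpy()
        i_start = np.searchsorted(pos, mr.start)
        i_end = np.searchsorted(pos, mr.end - 1)
        t_i_start = np.searchsorted(pos, t_start)
        t_i_end = np.searchsorted(pos, t_end - 1)
        assert abs(i_start - t_i_start) <= 2
        assert abs(i_end - t_i_end) <= 2

    def test_block_below_min_sites_is_discarded(self):
        meth, _ = _planted_methylome(seed=4, n_block=4)
        result = baum_welch(chains_from_methylome(meth, desert_distance=10**9))
        mrs = decode_regions(meth, result.model, min_sites=5, desert_distance=10**9)
        assert mrs == []

    def test_label_symmetry(self, trained_sample):
        meth, result = trained_sample
        swapped = result.model.relabelled().relabelled()
        mrs_a = decode_regions(meth, result.model)
        mrs_b = decode_regions(meth, swapped)
        assert [(m.start, m.end) for m in mrs_a] == [(m.start, m.end) for m in mrs_b]

    def test_relabelled_model_fails_ordering_validation(self, trained_sample):
        meth, result = trained_sample
        with pytest.raises(ValidationError):
            decode_regions(meth, result.model.relabelled())

    def test_mrs_disjoint_sorted_and_order_invariant(self, trained_sample):
        meth, result = trained_sample
        mrs = decode_regions(meth, result.model)
        for a, b in zip(mrs, mrs[1:]):
            assert (a.chrom, a.start) <= (b.chrom, b.start)
            if a.chrom == b.chrom:
                assert a.end <= b.start
        # reversing chromosome-block order in the frame does not change MRs
        import pandas as pd

        rev = pd.concat(
            [df for _, df in reversed(list(meth.per_chrom()))], ignore_index=True
        )
        mrs_rev = decode_regions(SampleMethylome(meth.sample_id, rev), result.model)
        assert [(m.chrom, m.start, m.end) for m in mrs] == [
            (m.chrom, m.start, m.end) for m in mrs_rev
        ]

    def test_desert_distance_breaks_chains(self):
        import pandas as pd

        # two well-covered blocks separated by a 5 kb gap
        pos = np.concatenate([np.arange(0, 500, 10), np.arange(5500, 6000, 10)])
        df = pd.DataFrame(
            {
                "chrom": "Chr1", "pos": pos, "strand": "+", "context": "CG",
                "n_meth": 9, "n_total": 10,
            }
        )
        chains = chains_from_methylome(SampleMethylome("s", df), desert_distance=2000)
        assert len(chains) == 2


class TestTrainModes:
    def test_reference_mode_shares_one_model(self, two_group_sim):
        cohort = {
            sid: two_group_sim.methylomes[sid] for sid in ("sample01", "sample02", "sample03")
        }
        trained = train_models(cohort, mode="reference_sample", reference="sample01")
        models = list(trained.values())
        assert all(m is models[0] for m in models)

    def test_unknown_reference_rejected(self, two_group_sim):
        with pytest.raises(ValueError, match="nope"):
            train_models(two_group_sim.methylomes, mode="reference_sample", reference="nope")

    def test_per_sample_models_agree_on_shared_generator(self, two_group_sim):
        # two samples drawn from the same generative distribution recover
        # nearly identical emission means
        cohort = {
            sid: two_group_sim.methylomes[sid] for sid in ("sample01", "sample02")
        }
        trained = train_models(cohort, mode="per_sample")
        m1, m2 = (trained[s].model for s in ("sample01", "sample02"))
        for key in m1.emission:
            assert m1.emission[key].mean == pytest.approx(m2.emission[key].mean, abs=0.05)


def test_model_text_round_trip(tmp_path, trained_sample):
    _, result = trained_sample
    path = tmp_path / "model.txt"
    result.model.to_text(path)
    back = HMMModel.from_text(path)
    np.testing.assert_allclose(back.initial, result.model.initial, rtol=1e-10)
    np.testing.assert_allclose(back.transition, result.model.transition, rtol=1e-10)
    for key, p in result.model.emission.items():
        assert back.emission[key].alpha == pytest.approx(p.alpha, rel=1e-10)
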