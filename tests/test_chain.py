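import numpy as np
import pytest

from memc import (
    EnergyFunction,
    FeatureMonomial,
    build_model,
    build_transfer,
    detailed_balance_residual,
    gibbs_bound_diagnostic,
    ks_entropy,
    load_model,
    match_state_order,
    model_expectation,
    save_model,
    standard_feature_sets,
    stochasticize,
)

from conftest import (
    F_LAG_12,
    F_LAG_21,
    F_RATE0,
    F_SYNC,
    make_lagged_pair_model,
    random_iid_model,
    random_memory_model,
)
from _suites import variational_gaps

# the two-neuron lagged-pair chain has Perron eigenvalue e^beta + 3
LAGGED_RHO = lambda b: np.exp(b) + 3


class TestTransferBuild:
    @pytest.mark.parametrize("beta1", [-2.0, -1.0, 0.0, 1.0, 2.0])
    def test_lagged_pair_perron_eigenvalue_closed_form(self, beta1):
        t = build_transfer(EnergyFunction((F_LAG_21,), (beta1,), 2))
        assert t.rho == pytest.approx(LAGGED_RHO(beta1), abs=1e-12)
        assert t.pressure == pytest.approx(np.log(LAGGED_RHO(beta1)))

    def test_range_one_right_eigenvector_constant(self):
        feats = standard_feature_sets("ising", 3)
        beta = (-1.0, -1.7, -2.8, 0.46, 0.86, 1.03)
        t = build_transfer(EnergyFunction(tuple(feats), beta, 3))
        assert np.allclose(t.V, t.V[0])

    def test_zero_energy_pressure_is_n_log2(self):
        t = build_transfer(EnergyFunction((F_SYNC,), (0.0,), 2))
        assert t.rho == pytest.approx(4.0)
        assert t.pressure == pytest.approx(np.log(4.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_memory_and_blocks_representations_share_rho(self, seed):
        rng = np.random.default_rng(seed)
        beta = rng.uniform(-2, 2, 3)
        e = EnergyFunction((F_LAG_12, F_LAG_21, F_SYNC), tuple(beta), 2)
        tm = build_transfer(e, "memory")
        tb = build_transfer(e, "blocks")
        assert tm.rho == pytest.approx(tb.rho, rel=1e-10)

    def test_representations_share_block_marginals(self):
        e = EnergyFunction((F_LAG_12, F_LAG_21, F_SYNC), (-3.0, 3.0, 0.5), 2)
        mm = build_model(e, "memory")
        mb = build_model(e, "blocks")
        # stationary probability of each 2-block: pi_u P_uv vs pi of the
        # block state in the literal representation
        marg_memory = np.zeros(mb.state_space.n_states)
        N = 2
        for u in range(mm.state_space.n_states):
            for q in range(mm.state_space.n_patterns):
                v = mm.state_space.successor(u, q)
                marg_memory[u | (q << N)] += mm.pi[u] * mm.P[u, v]
        assert np.allclose(marg_memory, mb.pi, atol=1e-10)

    def test_oversized_state_space_refused(self):
        feats = (FeatureMonomial(((0, 0), (3, 11))),)
        with pytest.raises(ValueError, match="refused"):
            build_transfer(EnergyFunction(feats, (1.0,), 12))


class TestStochasticize:
    def test_zero_energy_gives_uniform_chain(self):
        m = build_model(EnergyFunction((F_SYNC,), (0.0,), 2))
        assert np.allclose(m.P, 0.25)
        assert np.allclose(m.pi, 0.25)

    def test_rows_sum_to_one_and_pi_stationary(self, memory_model):
        assert np.abs(memory_model.P.sum(axis=1) - 1).max() < 1e-12
        assert np.abs(memory_model.pi @ memory_model.P - memory_model.pi).max() < 1e-12
        assert (memory_model.pi > 0).all()

    def test_strong_coupling_chain_matches_printed_transition_matrix(self, memory_model):
        # 4x4 matrix reported for beta = (-3, 3, 0.5), states listed
        # 00,01,10,11 with the opposite neuron-bit order
        reference = np.array(
            [
                [0.13026, 0.02580, 0.65762, 0.18632],
                [0.65763, 0.13026, 0.16529, 0.04682],
                [0.02580, 0.10266, 0.13026, 0.74128],
                [0.15015, 0.59735, 0.03774, 0.21476],
            ]
        )
        convention, perm = match_state_order(memory_model.P, reference, 2, atol=1.5e-5)
        assert convention in ("neuron0-lsb", "neuron0-msb")
        assert np.abs(memory_model.P[np.ix_(perm, perm)] - reference).max() < 1.5e-5

    def test_range_one_chain_is_iid(self):
        m = random_iid_model(np.random.default_rng(11), 2)
        # every row of P equals pi: the chain forgets its state
        assert np.allclose(m.P, np.tile(m.pi, (len(m.pi), 1)), atol=1e-12)

    def test_pi_equals_stationary_vector_of_p(self, memory_model):
        w, vl = np.linalg.eig(memory_model.P.T)
        i = int(np.argmax(w.real))
        v = np.abs(vl[:, i].real)
        assert np.abs(v / v.sum() - memory_model.pi).max() < 1e-10


class TestExpectations:
    @pytest.mark.parametrize(
        "beta1,expected", [(0.0, 0.25), (1.0, np.e / (np.e + 3))]
    )
    def test_lagged_pair_constraint_map(self, beta1, expected):
        m = make_lagged_pair_model(beta1)
        assert model_expectation(m, F_LAG_21) == pytest.approx(expected, abs=1e-12)

    def test_strong_coupling_synchronous_expectation(self, memory_model):
        assert model_expectation(memory_model, F_SYNC) == pytest.approx(
            0.292611, abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_expectation_equals_pressure_derivative(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = random_memory_model(rng) if seed % 2 else random_iid_model(rng, 2)
        energy = model.energy
        h = 1e-5
        for k, f in enumerate(energy.features):
            beta = energy.beta
            bp, bm = beta.copy(), beta.copy()
            bp[k] += h
            bm[k] -= h
            deriv = (
                build_model(energy.with_coefficients(bp)).pressure
                - build_model(energy.with_coefficients(bm)).pressure
            ) / (2 * h)
            assert model_expectation(model, f) == pytest.approx(deriv, abs=1e-6)

    def test_feature_beyond_model_range_rejected(self, memory_model):
        f3 = FeatureMonomial(((0, 0), (2, 1)))
        with pytest.raises(ValueError, match="exceeds model range"):
            model_expectation(memory_model, f3)

    def test_feature_with_unknown_neuron_rejected(self, memory_model):
        with pytest.raises(ValueError, match="neuron"):
            model_expectation(memory_model, FeatureMonomial(((0, 2),)))


class TestEntropy:
    def test_zero_energy_entropy_is_two_bits(self):
        m = build_model(EnergyFunction((F_SYNC,), (0.0,), 2))
        assert ks_entropy(m) == pytest.approx(2 * np.log(2))

    def test_iid_chain_reduces_to_shannon_entropy(self):
        m = random_iid_model(np.random.default_rng(21), 2)
        shannon = -np.sum(m.pi * np.log(m.pi))
        assert ks_entropy(m) == pytest.approx(shannon, abs=1e-12)

    def test_variational_identity_at_the_memc(self, lagged_pair_model):
        m = lagged_pair_model
        lhs = ks_entropy(m) + 1.0 * model_expectation(m, F_LAG_21)
        assert lhs == pytest.approx(m.pressure, abs=1e-10)

    def test_perturbed_chains_never_beat_the_pressure(self, memory_model):
        gaps = variational_gaps(memory_model, n_perturbations=100, seed=7)
        assert (gaps >= -1e-10).all()
        assert gaps.min() > 1e-6  # strict perturbations stay strictly below


class TestGibbsBound:
    def test_iid_chain_spread_is_zero(self):
        m = random_iid_model(np.random.default_rng(31), 2)
        rep = gibbs_bound_diagnostic(m, 6)
        assert rep.spread < 1e-10
        assert rep.passed

    def test_memory_chain_bound_flat_in_length(self, lagged_pair_model):
        rep = gibbs_bound_diagnostic(lagged_pair_model, 10)
        assert rep.passed
        assert abs(rep.trend) < 1e-10
        # per-length band width settles rather than growing
        widths = np.subtract(rep.g_max, rep.g_min)
        assert widths[-1] <= widths[0] + 1e-10

    def test_zero_energy_spread_is_zero(self):
        m = build_model(EnergyFunction((F_SYNC,), (0.0,), 2))
        rep = gibbs_bound_diagnostic(m, 6)
        assert rep.spread < 1e-10


class TestDetailedBalance:
    def test_iid_chain_reversible(self):
        m = random_iid_model(np.random.default_rng(41), 2)
        assert detailed_balance_residual(m) < 1e-14

    def test_symmetric_lagged_chain_reversible(self):
        assert detailed_balance_residual(make_lagged_pair_model(0.0)) < 1e-14

    def test_strong_coupling_chain_irreversible(self, memory_model):
        assert detailed_balance_residual(memory_model) > 1e-3


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, memory_model):
        path = tmp_path / "model.json"
        save_model(memory_model, path)
        back = load_model(path)
        assert np.allclose(back.P, memory_model.P, atol=1e-12)
        assert np.allclose(back.pi, memory_model.pi, atol=1e-12)
        assert back.energy == memory_model.energy
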