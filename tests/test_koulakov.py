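"""Koulakov model: energies, acceptance rule, incremental bookkeeping."""

import numpy as np
import pytest

from ephmap.models import koulakov
from ephmap.substrate import build_substrate, genotype


@pytest.fixture(scope="module")
def tiny():
    return build_substrate(genotype("wild_type"), 20, 20, seed=2)


class TestEnergyTerms:
    def test_empty_state_zero_energy(self, tiny):
        st = koulakov.empty_state(20, 20)
        assert koulakov.energy_terms(st, tiny) == (0.0, 0.0, 0.0)

    def test_single_synapse_self_pair(self, tiny):
        st = koulakov.empty_state(20, 20)
        st.mu[0], st.nu[0], st.n_syn = 3, 5, 1
        st.count_rgc[3] = 1
        st.count_sc[5] = 1
        p = koulakov.KoulakovParams()
        e_chem, e_act, e_comp = koulakov.energy_terms(st, tiny)
        # the self-pair contributes C = U = 1, weighted by -gamma/2
        assert e_act == pytest.approx(-p.gamma / 2.0)
        expected_chem = p.alpha * tiny.R_A[3] * tiny.L_A[5] - p.beta * tiny.R_B[3] * tiny.L_B[5]
        assert e_chem == pytest.approx(expected_chem)

    def test_competition_term_direct_substitution(self, tiny):
        # one RGC with 4 synapses: -500 * 2 + 16 = -984, plus the SC side
        st = koulakov.empty_state(20, 20)
        st.mu[:4] = 0
        st.nu[:4] = np.array([1, 2, 3, 4])
        st.n_syn = 4
        st.count_rgc[0] = 4
        st.count_sc[1:5] = 1
        _, _, e_comp = koulakov.energy_terms(st, tiny)
        # RGC part: -500 * sqrt(4) + 4^2 = -984; SC part: 4 neurons with n=1
        assert e_comp == pytest.approx(-984.0 + 4.0)


class TestAcceptance:
    def test_half_at_zero(self):
        assert koulakov.acceptance_probability(0.0) == 0.5

    def test_limits(self):
        assert koulakov.acceptance_probability(1e6) == pytest.approx(0.0, abs=1e-12)
        assert koulakov.acceptance_probability(-1e6) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_point(self):
        assert koulakov.acceptance_probability(0.25) == pytest.approx(1.0 / (1.0 + np.e))

    def test_monotone_decreasing(self):
        dE = np.linspace(-3, 3, 101)
        p = koulakov.acceptance_probability(dE)
        assert np.all(np.diff(p) < 0)

    def test_detailed_balance_identity(self):
        dE = np.linspace(-5, 5, 41)
        p = koulakov.acceptance_probability(dE)
        q = koulakov.acceptance_probability(-dE)
        assert np.allclose(p / q, np.exp(-4.0 * dE))


class TestIncrementalBookkeeping:
    def test_incremental_matches_brute_force(self, tiny):
        """1000 iterations on a 20x20 instance: the running energy from
        incremental updates equals full recomputation to 1e-8."""
        st = koulakov.empty_state(20, 20)
        pre = koulakov.precompute(tiny)
        st = koulakov.koulakov_iteration(st, pre, seed=13, n_iter=1000, substrate=tiny)
        brute = sum(koulakov.energy_terms(st, tiny))
        assert st.n_syn > 0
        assert abs(st.energy - brute) < 1e-8

    def test_correlation_cache_consistent(self, tiny):
        st = koulakov.empty_state(20, 20)
        pre = koulakov.precompute(tiny)
        st = koulakov.koulakov_iteration(st, pre, seed=3, n_iter=300, substrate=tiny)
        _, C, _ = pre
        mu, nu = st.synapses
        G_ref = np.zeros((20, 20))
        for m, n in zip(mu, nu):
            G_ref[:, n] += C[:, m]
        assert np.allclose(st.G, G_ref, atol=1e-9)

    def test_remove_on_empty_is_noop(self, tiny):
        st = koulakov.empty_state(20, 20)
        pre = koulakov.precompute(tiny)
        # with chem >> 0 additions are rejected; removals must not crash
        st = koulakov.koulakov_iteration(st, pre, seed=1, n_iter=5, substrate=tiny)
        assert st.n_syn >= 0

    def test_first_addition_strongly_favoured(self, tiny):
        # empty system: the competition drive -500(sqrt(1)-0)+2 dominates
        n = 0.0
        d_comp = -500.0 * (np.sqrt(n + 1) - np.sqrt(n)) + (2 * n + 1) + (2 * n + 1)
        assert koulakov.acceptance_probability(d_comp + 100.0) > 0.999


class TestRun:
    def test_counts_consistent_and_logged(self, tiny):
        state = koulakov.run_koulakov(tiny, n_epochs=200, seed=5, log_every=10)
        assert state.W.min() >= 0
        assert state.W.sum() > 0
        assert state.log["n_synapses"][-1] == state.W.sum()
        assert 0.0 <= state.log["rejected_fraction"][-1] <= 1.0

    def test_synapse_count_stabilizes(self, tiny):
        state = koulakov.run_koulakov(tiny, n_epochs=400, seed=5, log_every=10)
        counts = state.log["n_synapses"]
        tail = counts[-len(counts) // 10 :]
        drift = abs(tail[-1] - tail[0]) / max(tail.mean(), 1.0)
        assert drift < 0.1

    def test_chemical_energy_decreases_without_activity(self, tiny):
        """gamma = 0, beta = 0: synapses settle on low alpha*R_A*L_A pairs."""
        params = koulakov.KoulakovParams(beta=0.0, gamma=0.0)
        state = koulakov.run_koulakov(tiny, n_epochs=400, seed=6, params=params)
        energies = state.log["energy"]
        assert energies[-1] < energies[len(energies) // 4]

    def test_determinism(self, tiny):
        a = koulakov.run_koulakov(tiny, n_epochs=100, seed=8)
        b = koulakov.run_koulakov(tiny, n_epochs=100, seed=8)
        assert np.array_equal(a.W, b.W)


class TestScaledParams:
    def test_reference_scale_keeps_calibrated_balance(self):
        p = koulakov.scaled_params(koulakov.REFERENCE_N)
        assert p.gamma == pytest.approx(koulakov.GAMMA * koulakov.ACTIVITY_BALANCE)
        assert p.alpha == koulakov.ALPHA

    def test_gamma_scales_with_network_size(self):
        half = koulakov.scaled_params(1000)
        full = koulakov.scaled_params(2000)
        assert half.gamma == pytest.approx(full.gamma / 2.0)
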