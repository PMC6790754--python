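"""Moment definitions, Price identity, reproductive values, classifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protodogma import (PhaseStats, classify_phase, mean_activities,
                        minority_frequency, price_decompose,
                        reproductive_value, trait_projection,
                        variance_decomposition)
from protodogma.observables import variance_decomposition_arrays
from protodogma.io import FixtureSpec, generate_fixture
from protodogma.world import Snapshot


def make_snapshot(traits_by_cell, substrate=None, rtype_by_cell=None):
    """Snapshot with all 8 profile entries equal to each replicator's trait."""
    cells = np.arange(len(traits_by_cell), dtype=np.int64)
    traits = np.concatenate([np.asarray(t, dtype=float) for t in traits_by_cell])
    cell_uid = np.concatenate([
        np.full(len(t), c, dtype=np.int64) for c, t in zip(cells, traits_by_cell)
    ])
    if rtype_by_cell is None:
        rtype = (np.arange(traits.size) % 2).astype(np.int8)
    else:
        rtype = np.concatenate([np.asarray(r) for r in rtype_by_cell]).astype(np.int8)
    if substrate is None:
        substrate = np.zeros(len(cells), dtype=np.int64)
    return Snapshot(
        step=0,
        rep_id=np.arange(traits.size, dtype=np.int64),
        cell_uid=cell_uid,
        rtype=rtype,
        profile=np.repeat(traits[:, None], 8, axis=1),
        cells=cells,
        substrate=np.asarray(substrate, dtype=np.int64),
    )


class TestMeanActivities:
    def test_uniform_profiles(self):
        snap = make_snapshot([[1.0, 1.0], [1.0]])
        assert np.allclose(mean_activities(snap), 1.0)

    def test_simple_average(self):
        snap = make_snapshot([[0.2], [0.8]])
        assert np.allclose(mean_activities(snap), 0.5)

    def test_invariant_under_cell_relabelling(self):
        snap_a = make_snapshot([[0.1, 0.9], [0.4]])
        snap_b = make_snapshot([[0.4], [0.1, 0.9]])
        assert np.allclose(mean_activities(snap_a), mean_activities(snap_b))

    def test_empty_snapshot_rejected(self):
        snap = make_snapshot([[]])
        with pytest.raises(ValueError):
            mean_activities(snap)


class TestMinorityFrequency:
    def test_per_cell_values_and_size_filter(self):
        # cell 0: 30 P / 70 Q -> 0.3; cell 1: 50/50 -> 0.5;
        # cell 2 below V/2 particles -> excluded
        snap = make_snapshot(
            [np.ones(100), np.ones(100), np.ones(10)],
            rtype_by_cell=[[0] * 30 + [1] * 70, [0] * 50 + [1] * 50, [0] * 10],
        )
        out = np.sort(minority_frequency(snap, V=100))
        assert np.allclose(out, [0.3, 0.5])

    def test_substrate_counts_toward_cell_size(self):
        snap = make_snapshot([np.ones(30)], substrate=[40])
        # 30 replicators + 40 substrate = 70 particles >= V/2 for V=100
        assert minority_frequency(snap, V=100).size == 1

    def test_upper_bound_is_half(self):
        snap = make_snapshot([np.ones(60)])
        assert np.all(minority_frequency(snap, V=100) <= 0.5)


class TestVarianceDecomposition:
    def test_pure_between_cell_variance(self):
        vd = variance_decomposition_arrays(np.array([1.0, 1.0, 0.0, 0.0]),
                                           np.array([0, 0, 1, 1]))
        assert vd.sigma2_cel == pytest.approx(0.25)
        assert vd.sigma2_mol == pytest.approx(0.0)
        assert vd.r == pytest.approx(1.0)

    def test_pure_within_cell_variance(self):
        vd = variance_decomposition_arrays(np.array([0.0, 1.0]), np.array([0, 0]))
        assert vd.sigma2_cel == pytest.approx(0.0)
        assert vd.sigma2_mol == pytest.approx(0.25)
        assert vd.r == pytest.approx(0.0)

    def test_degenerate_identical_traits(self):
        vd = variance_decomposition_arrays(np.full(6, 0.3), np.array([0, 0, 0, 1, 1, 1]))
        assert vd.sigma2_cel == 0.0 and vd.sigma2_mol == 0.0
        assert math.isnan(vd.r)
        assert vd.note is not None

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_law_of_total_variance(self, seed):
        rng = np.random.default_rng(seed)
        n_cells = rng.integers(2, 8)
        cells = rng.integers(0, n_cells, size=rng.integers(4, 60))
        traits = rng.normal(0.5, 0.2, size=cells.size)
        vd = variance_decomposition_arrays(traits, cells)
        assert vd.sigma2_cel + vd.sigma2_mol == pytest.approx(np.var(traits), abs=1e-12)

    def test_snapshot_projection_uses_raw_values(self):
        snap = make_snapshot([[0.5, -0.3]])
        kappa = trait_projection(snap, 0)
        assert np.allclose(kappa, [0.5, -0.3])  # no clipping at zero

    def test_fixture_targets_recovered(self):
        spec = FixtureSpec(n_cells=20, cell_size=50, sigma2_cel=0.09,
                           sigma2_mol=0.04, mean_trait=0.5, seed=5)
        snap = generate_fixture(spec)
        for c in (0, 1):
            vd = variance_decomposition(snap, c)
            assert vd.sigma2_cel == pytest.approx(0.09, rel=1e-9)
            assert vd.sigma2_mol == pytest.approx(0.04, rel=1e-9)


class TestPriceDecomposition:
    def test_no_selection_when_fitness_uniform(self):
        pt = price_decompose(np.array([0.1, 0.9, 0.4]), np.full(3, 2.0),
                             np.array([0, 0, 1]))
        assert pt.lhs == pytest.approx(0.0, abs=1e-15)
        assert pt.between == pytest.approx(0.0, abs=1e-15)
        assert pt.within == pytest.approx(0.0, abs=1e-15)

    def test_frozen_two_cell_example(self):
        # offspring-pool enumeration: <lambda>=1.25, post-selection mean
        # = (2*1 + 1*0 + 1*1 + 1*0)/5 = 0.6, so lhs = 1.25*(0.6-0.5) = 0.125;
        # cell means of kappa are equal (0.5, 0.5) -> between = 0;
        # within-cell covariances are 0.25 and 0 -> within = 0.125
        pt = price_decompose(np.array([1.0, 0.0, 1.0, 0.0]),
                             np.array([2.0, 1.0, 1.0, 1.0]),
                             np.array([0, 0, 1, 1]))
        assert pt.lhs == pytest.approx(0.125)
        assert pt.between == pytest.approx(0.0)
        assert pt.within == pytest.approx(0.125)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        k = rng.uniform(0, 1, 30)
        lam = rng.uniform(0, 2, 30)
        cells = rng.integers(0, 5, 30)
        a = price_decompose(k, lam, cells)
        b = price_decompose(k + 5.0, lam, cells)
        assert a.lhs == pytest.approx(b.lhs, abs=1e-9)
        assert a.between == pytest.approx(b.between, abs=1e-9)
        assert a.within == pytest.approx(b.within, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_identity_exact_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 80)
        k = rng.uniform(-1, 1, n)
        lam = rng.uniform(0, 3, n)
        cells = rng.integers(0, max(1, n // 4), n)
        pt = price_decompose(k, lam, cells)
        assert pt.lhs == pytest.approx(pt.between + pt.within, abs=1e-12)

    def test_zero_total_fitness_rejected(self):
        with pytest.raises(ValueError):
            price_decompose(np.array([0.5, 0.5]), np.zeros(2), np.array([0, 0]))


class TestReproductiveValue:
    def test_row_sum_eigenstructure(self):
        lam, u = reproductive_value(0.3, 0.7)
        assert lam == pytest.approx(1.0)
        assert np.allclose(u, [0.3, 0.7])

    def test_never_copied_role_has_zero_value(self):
        lam, u = reproductive_value(0.0, 0.6)
        assert np.allclose(u, [0.0, 1.0])

    def test_symmetric_case(self):
        lam, u = reproductive_value(0.5, 0.5)
        assert lam == pytest.approx(1.0)
        assert np.allclose(u, [0.5, 0.5])

    def test_agrees_with_generic_eigensolver(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            wp, wq = rng.uniform(0, 2, 2)
            if wp + wq == 0:
                continue
            lam, u = reproductive_value(wp, wq)
            mat = np.array([[wp, wq], [wp, wq]])
            evals, evecs = np.linalg.eig(mat.T)  # left eigenvectors
            i = int(np.argmax(evals.real))
            assert lam == pytest.approx(evals[i].real, abs=1e-12)
            v = np.abs(evecs[:, i].real)
            assert np.allclose(u, v / v.sum(), atol=1e-12)

    def test_double_zero_rejected(self):
        with pytest.raises(ValueError):
            reproductive_value(0.0, 0.0)


class TestEmpiricalFitness:
    def test_omega_bar_sums_to_one_on_simulation_logs(self):
        from protodogma import Params, run
        from protodogma.observables import empirical_omega_bar

        res = run(Params(V=20, n_tot=400, init_cells=10, m=0.05, t_max=100,
                         record_every=50, seed=23))
        w = empirical_omega_bar(res.logs.births, (20, 100))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w > 0)

    def test_rates_counted_per_template(self):
        from protodogma.observables import empirical_fitness

        # template 7 produces two P and one Q over a 10-step window
        births = np.array([
            [11, 100, 0, 7, 3, 0],
            [14, 101, 0, 7, 3, 0],
            [18, 102, 1, 7, 4, 0],
            [15, 103, 1, 8, 3, 0],
        ], dtype=np.int64)
        fr = empirical_fitness(births, (10, 20))
        i = int(np.nonzero(fr.rep_id == 7)[0][0])
        assert fr.omega_p[i] == pytest.approx(0.2)
        assert fr.omega_q[i] == pytest.approx(0.1)
        assert fr.lam[i] == pytest.approx(0.3)


class TestClassifier:
    @staticmethod
    def stats(mean_k, minority, window=5000):
        return PhaseStats(mean_k=np.asarray(mean_k, dtype=float),
                          median_minority=minority, window_length=window)

    def test_undifferentiated_high_state_is_none(self):
        assert classify_phase(self.stats(np.ones(8), 0.5)) == "none"

    def test_threefold_symmetry_breaking(self):
        mk = [0.02] * 4 + [0.8] * 4
        mk[5] = 0.01  # reverse transcription k[Q][P][Q] collapsed
        assert classify_phase(self.stats(mk, 0.18)) == "threefold"

    def test_catalytic_informatic_without_numerical(self):
        mk = [0.02] * 4 + [0.8] * 4
        mk[5] = 0.01
        assert classify_phase(self.stats(mk, 0.48)) == "catalytic_informatic_only"

    def test_catalytic_only_is_incomplete(self):
        mk = [0.02] * 4 + [0.8] * 4  # reverse transcription still high
        assert classify_phase(self.stats(mk, 0.48)) == "incomplete"

    def test_short_window_refused(self):
        with pytest.raises(ValueError, match="window"):
            classify_phase(self.stats(np.ones(8), 0.5, window=10))

    def test_symmetric_under_type_exchange(self):
        mk = [0.9] * 4 + [0.01] * 4
        mk[2] = 0.005  # reverse transcription k[P][Q][P] collapsed
        assert classify_phase(self.stats(mk, 0.2)) == "threefold"
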