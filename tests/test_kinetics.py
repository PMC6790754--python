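"""Within-cell chemistry: complex formation, synthesis, mutation, decay."""

import numpy as np
import pytest
from scipy import stats

from protodogma import P, Q, channel_rates, mutate_profile, profile_index
from protodogma.kinetics import (form_complexes_cell, reaction_substep,
                                 seed_kernel)
from conftest import make_single_cell_world


def _react(world, m=None, d=None, log_mut=False, seed=None):
    """Run the reaction kernel on a world, defaulting to its params."""
    p = world.params
    if seed is not None:
        seed_kernel(seed)
    return reaction_substep(
        world.cell_ix, world.rtype, world.profile, world.substrate,
        p.m if m is None else m, p.delta_mut, p.k_max,
        p.d if d is None else d, log_mut,
    )


class TestChannelRates:
    def test_uniform_profiles_give_four_unit_channels(self):
        prof = np.ones(8)
        cr = channel_rates(prof, P, prof, Q, k_max=1.0)
        assert np.allclose(cr.rates, 1.0)
        assert cr.total == 4.0

    def test_single_active_channel(self):
        # X of type P catalysing product P from a type-Q template
        px = np.zeros(8)
        px[profile_index(P, P, Q)] = 0.5
        py = np.zeros(8)
        cr = channel_rates(px, P, py, Q, k_max=1.0)
        assert cr.total == 0.5
        assert np.count_nonzero(cr.rates) == 1
        assert cr.rates[0] == 0.5  # X-as-catalyst, product P

    def test_negative_entries_contribute_zero(self):
        px = np.full(8, -0.4)
        py = np.full(8, -0.4)
        cr = channel_rates(px, P, py, Q, k_max=1.0)
        assert cr.total == 0.0

    def test_role_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(0)
        px, py = rng.uniform(-0.2, 1.0, (2, 8))
        a = channel_rates(px, P, py, Q, k_max=1.0)
        b = channel_rates(py, Q, px, P, k_max=1.0)
        # swapping arguments relabels X<->Y: channels 0,1 <-> 2,3
        assert np.allclose(a.rates, b.rates[[2, 3, 0, 1]])


class TestFormComplexes:
    def test_all_k_max_pairs_every_free_replicator(self):
        for n in (2, 5, 8, 31):
            rtype = (np.arange(n) % 2).astype(np.int8)
            prof = np.ones((n, 8))
            cat, tmpl, pt = form_complexes_cell(rtype, prof, 1.0, seed=n)
            assert len(cat) == n // 2

    def test_inactive_profiles_form_nothing(self):
        rtype = np.zeros(6, dtype=np.int8)
        prof = np.full((6, 8), -0.5)
        cat, tmpl, pt = form_complexes_cell(rtype, prof, 1.0, seed=1)
        assert len(cat) == 0

    def test_single_replicator_cannot_pair(self):
        cat, tmpl, pt = form_complexes_cell(np.zeros(1, np.int8), np.ones((1, 8)),
                                            1.0, seed=1)
        assert len(cat) == 0

    def test_complexes_are_disjoint(self):
        rtype = (np.arange(40) % 2).astype(np.int8)
        prof = np.ones((40, 8))
        cat, tmpl, pt = form_complexes_cell(rtype, prof, 1.0, seed=3)
        members = np.concatenate([cat, tmpl])
        assert len(members) == len(np.unique(members))

    def test_catalyst_type_determines_product_channel(self):
        # only the P-type replicators can catalyse, and only transcription
        # of Q-templates into Q products: k[P][Q][Q]
        n = 100
        rtype = (np.arange(n) % 2).astype(np.int8)
        prof = np.zeros((n, 8))
        prof[:, profile_index(P, Q, Q)] = 1.0
        cat, tmpl, pt = form_complexes_cell(rtype, prof, 1.0, seed=5)
        assert len(cat) > 0
        assert np.all(rtype[cat] == P)
        assert np.all(rtype[tmpl] == Q)
        assert np.all(pt == Q)


class TestSynthesis:
    def test_no_substrate_no_births(self):
        w = make_single_cell_world(10, k_value=1.0, substrate=0)
        out = _react(w, d=0.0, seed=11)
        assert out[1].shape[0] == 0  # no children

    def test_one_complex_consumes_one_substrate(self):
        w = make_single_cell_world(2, k_value=1.0, substrate=3)
        out = _react(w, d=0.0, seed=12)
        assert out[1].shape[0] == 1
        assert w.substrate[0] == 2

    def test_substrate_limits_births_and_producers_are_uniform(self):
        # 5 complexes, substrate 2 -> exactly 2 births; over many seeds the
        # producing templates are uniform over replicators (chi-square)
        counts = np.zeros(10)
        for s in range(400):
            w = make_single_cell_world(10, k_value=1.0, substrate=2)
            out = _react(w, d=0.0, seed=1000 + s)
            tmpl = out[4]
            assert len(tmpl) == 2
            for t in tmpl:
                counts[t] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=9) > 1e-3

    def test_inheritance_is_exact_without_mutation(self):
        w = make_single_cell_world(20, substrate=10)
        rng = np.random.default_rng(8)
        w.profile = rng.uniform(-0.3, 1.0, (20, 8))
        out = _react(w, m=0.0, d=0.0, seed=21)
        c_prof, c_tmpl = out[1], out[4]
        assert c_prof.shape[0] > 0
        for child, tmpl in zip(c_prof, c_tmpl):
            assert np.array_equal(child, w.profile[tmpl])

    def test_product_type_copied_from_channel_not_template(self):
        # all catalysts transcribe P-templates into Q: children are Q but
        # inherit the P-template's profile
        n = 40
        w = make_single_cell_world(n, substrate=20)
        w.profile[:] = 0.0
        w.profile[:, profile_index(P, Q, P)] = 1.0
        w.profile[:, profile_index(Q, Q, P)] = 1.0
        out = _react(w, m=0.0, d=0.0, seed=31)
        c_rtype, c_tmpl = out[2], out[4]
        assert len(c_rtype) > 0
        assert np.all(c_rtype == Q)
        assert np.all(w.rtype[c_tmpl] == P)


class TestDecay:
    def test_d_zero_changes_nothing(self):
        w = make_single_cell_world(50, k_value=-1.0, substrate=5)
        out = _react(w, d=0.0, seed=41)
        assert not out[0].any()
        assert w.substrate[0] == 5

    def test_d_one_removes_everything(self):
        w = make_single_cell_world(50, k_value=-1.0, substrate=5)
        out = _react(w, d=1.0, seed=42)
        assert out[0].all()
        assert w.substrate[0] == 55

    def test_survivors_follow_binomial_law(self):
        survivors = []
        for s in range(200):
            w = make_single_cell_world(1000, k_value=-1.0)
            out = _react(w, d=0.02, seed=5000 + s)
            survivors.append(1000 - int(out[0].sum()))
        mean = np.mean(survivors)
        se = np.sqrt(1000 * 0.02 * 0.98 / 200)
        assert abs(mean - 980.0) < 5 * se


class TestMutation:
    def test_m_zero_is_identity(self, rng):
        prof = rng.uniform(-0.5, 1.0, 8)
        out = mutate_profile(prof, 0.0, 0.05, 1.0, rng)
        assert np.array_equal(out, prof)

    def test_reflection_arithmetic_at_upper_bound(self):
        class ForcedRng:
            def random(self, shape):
                return np.zeros(shape)  # always below m -> always mutate

            def uniform(self, lo, hi, size):
                return np.full(size, 0.03)

        out = mutate_profile(np.full(8, 0.99), 1.0, 0.05, 1.0, ForcedRng())
        assert np.allclose(out, 0.98)  # 2*1 - 1.02

    def test_no_lower_bound(self):
        class ForcedRng:
            def random(self, shape):
                return np.zeros(shape)

            def uniform(self, lo, hi, size):
                return np.full(size, -0.04)

        out = mutate_profile(np.full(8, 0.01), 1.0, 0.05, 1.0, ForcedRng())
        assert np.allclose(out, -0.03)

    def test_increment_distribution_uniform_generator_path(self, rng):
        prof = np.full((12500, 8), 0.5)
        out = mutate_profile(prof, 1.0, 0.05, 1.0, rng)
        inc = (out - prof).ravel()
        res = stats.kstest(inc, stats.uniform(loc=-0.05, scale=0.1).cdf)
        assert res.pvalue > 1e-3

    def test_increment_distribution_uniform_kernel_path(self):
        # collect logged increments from the compiled path, away from the
        # reflecting boundary (template entries at 0.5)
        incs = []
        s = 0
        while sum(len(i) for i in incs) < 100_000:
            w = make_single_cell_world(2000, k_value=0.5, substrate=1000)
            w.params.m = 1.0
            out = _react(w, m=1.0, d=0.0, log_mut=True, seed=7000 + s)
            incs.append(out[8])
            s += 1
        inc = np.concatenate(incs)
        res = stats.kstest(inc, stats.uniform(loc=-0.05, scale=0.1).cdf)
        assert res.pvalue > 1e-3
        assert abs(np.abs(inc).max() - 0.05) < 1e-3


class TestConservationAndTradeoff:
    def test_reaction_conserves_particles(self):
        for s in range(20):
            w = make_single_cell_world(100, k_value=0.8, substrate=30)
            n0 = 100 + 30
            out = _react(w, m=0.2, d=0.05, seed=800 + s)
            dead, c_dead = out[0], out[6]
            n_reps = 100 - int(dead.sum()) + len(c_dead) - int(c_dead.sum())
            assert n_reps + int(w.substrate[0]) == n0

    def test_monotone_birth_rate_in_common_k(self):
        # with all profiles identical the per-capita birth rate is
        # nondecreasing in the shared k value (rising, then substrate-limited)
        ks = [0.005, 0.01, 0.02, 0.05, 0.2, 1.0]
        means = []
        for k in ks:
            births = []
            for s in range(60):
                w = make_single_cell_world(100, k_value=k, substrate=50)
                out = _react(w, m=0.0, d=0.0, seed=int(k * 10000) + s)
                births.append(out[1].shape[0])
            means.append(np.mean(births))
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 1.0
        assert means[-1] > means[0]
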