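"""CssCRBM energy, conditionals, pooling, sampling and CD training,
checked against brute-force enumeration oracles on tiny instances."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import expit

from eegnet import rbm
from eegnet.synthetic import (
    enumerate_spike_posterior,
    exact_loglik_gradient,
    gen_filter_images,
    gen_tiny_rbm,
)


def simple_params(**kw):
    base = dict(w=np.ones((1, 1, 1, 1)), b=np.zeros(1), c=np.zeros(1),
                a=np.ones(1))
    base.update(kw)
    return rbm.CssCRBMParams(**base)


class TestEnergy:
    def test_zero_couplings_leave_only_quadratic_visible_term(self, rng):
        v = rng.normal(size=(1, 3, 3))
        p = simple_params(w=np.zeros((1, 1, 2, 2)))
        st = rbm.LayerState(v=v, h=np.zeros((1, 2, 2)), s=np.zeros((1, 2, 2)))
        assert rbm.energy(st, p) == pytest.approx((v**2).sum() / 2)

    def test_hand_evaluated_single_unit_energy(self):
        st = rbm.LayerState(v=np.full((1, 1, 1), 2.0), h=np.ones((1, 1, 1)),
                            s=np.ones((1, 1, 1)))
        assert rbm.energy(st, simple_params()) == pytest.approx(0.5)

    def test_feature_map_permutation_invariance(self, rng):
        p, samples = gen_tiny_rbm(seed=9, n_kernels=3)
        v = samples[0]
        h = (rng.random((3, 2, 2)) < 0.5).astype(float)
        s = rng.normal(size=(3, 2, 2))
        e = rbm.energy(rbm.LayerState(v=v, h=h, s=s), p)
        perm = [2, 0, 1]
        p2 = replace(p, w=p.w[perm], b=p.b[perm], a=p.a[perm])
        e2 = rbm.energy(rbm.LayerState(v=v, h=h[perm], s=s[perm]), p2)
        assert e == pytest.approx(e2)

    def test_shape_mismatch_raises(self, rng):
        p, samples = gen_tiny_rbm(seed=1)
        st = rbm.LayerState(v=samples[0], h=np.zeros((1, 3, 3)),
                            s=np.zeros((1, 3, 3)))
        with pytest.raises(ValueError, match="shape"):
            rbm.energy(st, p)


class TestSpikeConditional:
    def test_zero_weights_give_one_half_everywhere(self):
        p = simple_params(w=np.zeros((1, 1, 2, 2)))
        q = rbm.spike_given_v(np.ones((1, 3, 3)), p)
        assert np.allclose(q, 0.5)

    def test_unit_response_of_two_gives_logistic_of_two(self):
        # response z = 2 with a = 1, b = 0: argument z^2/2 = 2
        p = simple_params()
        q = rbm.spike_given_v(np.full((1, 1, 1), 2.0), p)
        assert q[0, 0, 0] == pytest.approx(expit(2.0), abs=1e-10)
        assert q[0, 0, 0] == pytest.approx(0.88080, abs=1e-5)

    def test_monotone_in_spike_bias(self, tiny_rbm):
        p, samples = tiny_rbm
        q1 = rbm.spike_given_v(samples[0], p)
        q2 = rbm.spike_given_v(samples[0], replace(p, b=p.b + 0.5))
        assert np.all(q2 > q1)

    def test_nonpositive_slab_penalty_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simple_params(a=np.zeros(1))


class TestPooledConditional:
    def test_uniform_over_block_and_off_state_at_zero_activation(self):
        # z = 0, b = 0: each of the 4 positions and the off state get 1/5
        p = simple_params(w=np.zeros((1, 1, 2, 2)), pool=2)
        q, off = rbm.pooled_spike_given_v(np.zeros((1, 3, 3)), p)
        assert np.allclose(q, 0.2)
        assert np.allclose(off, 0.2)

    def test_block_probabilities_sum_to_one(self, tiny_rbm_pooled):
        p, samples = tiny_rbm_pooled
        q, off = rbm.pooled_spike_given_v(samples, p)
        total = q.sum(axis=(2, 3)) + off[..., 0, 0]
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_dominant_activation_saturates_its_position(self):
        p = simple_params(w=np.full((1, 1, 2, 2), 5.0), pool=2, b=np.zeros(1))
        v = np.zeros((1, 3, 3))
        v[0, 0, 0] = 2.0  # one huge response in the block
        q, off = rbm.pooled_spike_given_v(v, p)
        assert q.max() > 0.999
        assert off.max() < 1e-3

    def test_matches_enumerated_block_posterior(self, tiny_rbm_pooled):
        p, samples = tiny_rbm_pooled
        q, _ = rbm.pooled_spike_given_v(samples[0], p)
        _, _, marg = enumerate_spike_posterior(samples[0], p)
        assert np.abs(q - marg).max() < 1e-8


class TestSlabConditional:
    def test_inactive_spike_gives_prior_slab(self, tiny_rbm):
        p, samples = tiny_rbm
        mean, var = rbm.slab_given_vh(samples[0], np.zeros((1, 2, 2)), p)
        assert np.allclose(mean, 0.0)
        assert np.allclose(var, 1.0 / p.a[0])

    def test_active_spike_gives_scaled_response_mean(self):
        p = simple_params()
        mean, var = rbm.slab_given_vh(np.full((1, 1, 1), 2.0),
                                      np.ones((1, 1, 1)), p)
        assert mean[0, 0, 0] == pytest.approx(2.0)
        assert var[0, 0, 0] == pytest.approx(1.0)

    def test_variance_independent_of_v_and_h(self, tiny_rbm, rng):
        p, samples = tiny_rbm
        h = (rng.random((1, 2, 2)) < 0.5).astype(float)
        _, var1 = rbm.slab_given_vh(samples[0], h, p)
        _, var2 = rbm.slab_given_vh(samples[1], np.ones((1, 2, 2)), p)
        assert np.allclose(var1, var2)

    def test_pooled_slab_takes_block_maximum_of_unit_means(self):
        p = simple_params(pool=2, w=np.ones((1, 1, 2, 2)))
        v = np.zeros((1, 3, 3))
        v[0, 0, 0], v[0, 0, 1] = 1.0, 3.0  # unit means {1, 3, ...}
        h = np.ones((1, 2, 2))
        mean, var = rbm.pooled_slab_given_v(v, h, p)
        unit_means, _ = rbm.slab_given_vh(v, h, p)
        assert mean[0, 0, 0] == pytest.approx(unit_means.max())
        assert var[0, 0, 0] == pytest.approx(1.0)

    def test_pool_of_one_reduces_to_unit_slab(self, tiny_rbm, rng):
        p, samples = tiny_rbm
        h = (rng.random((1, 2, 2)) < 0.5).astype(float)
        m1, v1 = rbm.slab_given_vh(samples[0], h, p)
        m2, v2 = rbm.pooled_slab_given_v(samples[0], h, p)
        assert np.allclose(m1, m2) and np.allclose(v1, v2)


class TestVisibleConditional:
    def test_no_spikes_give_bias_mean(self):
        p = simple_params(w=np.ones((1, 1, 2, 2)), c=np.array([0.7]),
                          sigma=1.5)
        mean, var = rbm.visible_given_sh(np.zeros((1, 2, 2)),
                                         np.zeros((1, 2, 2)), p)
        assert np.allclose(mean, 0.7)
        assert np.allclose(var, 1.5**2)

    def test_single_active_unit_projects_through_kernel(self):
        p = simple_params()
        mean, _ = rbm.visible_given_sh(np.full((1, 1, 1), 3.0),
                                       np.ones((1, 1, 1)), p)
        assert mean[0, 0, 0] == pytest.approx(3.0)

    def test_linearity_in_slab(self, tiny_rbm, rng):
        p, _ = tiny_rbm
        h = np.ones((1, 2, 2))
        s = rng.normal(size=(1, 2, 2))
        m1, _ = rbm.visible_given_sh(s, h, p)
        m2, _ = rbm.visible_given_sh(2 * s, h, p)
        c = p.c[:, None, None]
        assert np.allclose(m2 - c, 2 * (m1 - c), atol=1e-12)


class TestConditionalConsistency:
    """Closed forms match the Boltzmann conditional obtained by enumerating
    h and analytically integrating the slab out of exp(-E)."""

    @pytest.mark.parametrize("seed,pool,n_kernels", [
        (3, 1, 1), (4, 2, 1), (5, 1, 2), (6, 2, 2),
    ])
    def test_closed_form_equals_enumeration(self, seed, pool, n_kernels):
        p, samples = gen_tiny_rbm(seed=seed, pool=pool, n_kernels=n_kernels)
        for v in samples[:3]:
            if pool == 1:
                q = rbm.spike_given_v(v, p)
            else:
                q, _ = rbm.pooled_spike_given_v(v, p)
            _, probs, marg = enumerate_spike_posterior(v, p)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.abs(q - marg).max() < 1e-8


class TestSampling:
    def test_block_constraint_never_violated(self, tiny_rbm_pooled):
        p, samples = tiny_rbm_pooled
        rng = np.random.default_rng(0)
        batch = np.repeat(samples[:1], 10000, axis=0)
        st = rbm.sample_pooled_state(batch, p, rng)
        per_block = st.h.sum(axis=(2, 3))  # single 2x2 block per map
        assert per_block.max() <= 1

    def test_empirical_frequencies_match_closed_form(self, tiny_rbm_pooled):
        p, samples = tiny_rbm_pooled
        q, _ = rbm.pooled_spike_given_v(samples[0], p)
        rng = np.random.default_rng(1)
        n = 100_000
        batch = np.repeat(samples[:1], n, axis=0)
        st = rbm.sample_pooled_state(batch, p, rng)
        freq = st.h.mean(axis=0)
        se = np.sqrt(q * (1 - q) / n)
        assert np.all(np.abs(freq - q) <= 3 * se + 1e-12)

    def test_fixed_seed_reproduces_samples(self, tiny_rbm_pooled):
        p, samples = tiny_rbm_pooled
        s1 = rbm.sample_pooled_state(samples[0], p, np.random.default_rng(42))
        s2 = rbm.sample_pooled_state(samples[0], p, np.random.default_rng(42))
        assert np.array_equal(s1.h, s2.h) and np.array_equal(s1.s, s2.s)
        assert np.array_equal(s1.pooled, s2.pooled)

    def test_pooled_output_is_elementwise_product(self, tiny_rbm_pooled):
        p, samples = tiny_rbm_pooled
        st = rbm.sample_pooled_state(samples[0], p, np.random.default_rng(7))
        assert np.array_equal(st.pooled, st.p_h * st.p_s)

    def test_long_gibbs_chain_reproduces_model_marginals(self):
        """Detailed-balance smoke test: the Gibbs chain's h marginals match
        the enumerated model marginals within Monte-Carlo error."""
        from eegnet.synthetic import _free_energy_quadratic, enumerate_h_configs

        p, _ = gen_tiny_rbm(seed=11, pool=1)
        configs = enumerate_h_configs((1, 2, 2), 1)
        logw = np.array([_free_energy_quadratic(h, p, 3) for h in configs])
        w = np.exp(logw - logw.max())
        w /= w.sum()
        exact = sum(wi * h for wi, h in zip(w, configs))
        rng = np.random.default_rng(5)
        n_chains, n_sweeps = 2000, 100  # 200,000 total sweeps
        v = rng.normal(size=(n_chains, 1, 3, 3))
        for _ in range(n_sweeps):
            v = rbm.gibbs_step(v, p, rng)
        h = rbm.sample_pooled_state(v, p, rng).h
        freq = h.mean(axis=0)
        se = np.sqrt(exact * (1 - exact) / n_chains)
        assert np.all(np.abs(freq - exact) <= 3 * se + 0.01)


class TestContractivePenalty:
    def test_zero_weights_zero_penalty_and_gradient(self, tiny_rbm):
        p, samples = tiny_rbm
        p0 = replace(p, w=np.zeros_like(p.w))
        g = rbm.contractive_grad(samples[0], p0)
        assert g["value"] == 0.0
        assert np.all(g["w"] == 0.0)

    def test_penalty_matches_finite_difference_jacobian(self, tiny_rbm):
        p, samples = tiny_rbm
        v = samples[0]
        eps = 1e-5
        J = np.zeros((4, 9))
        vf = v.ravel()
        for i in range(9):
            vp, vm = vf.copy(), vf.copy()
            vp[i] += eps
            vm[i] -= eps
            J[:, i] = (
                rbm.spike_given_v(vp.reshape(v.shape), p)
                - rbm.spike_given_v(vm.reshape(v.shape), p)
            ).ravel() / (2 * eps)
        oracle = (J**2).sum()
        value = rbm.contractive_penalty(v, p, with_grad=False)
        assert value == pytest.approx(oracle, rel=1e-4)

    def test_gradient_matches_finite_difference(self, tiny_rbm):
        p, samples = tiny_rbm
        v = samples[0]
        _, gw = rbm.contractive_penalty(v, p)
        eps = 1e-6
        num = np.zeros_like(p.w)
        it = np.nditer(p.w, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            for sgn in (+1, -1):
                wp = p.w.copy()
                wp[i] += sgn * eps
                num[i] += sgn * rbm.contractive_penalty(
                    v, replace(p, w=wp), with_grad=False)
            num[i] /= 2 * eps
        assert np.abs(num - gw).max() / np.abs(num).max() < 1e-5

    def test_invariant_under_feature_map_permutation(self):
        p, samples = gen_tiny_rbm(seed=8, n_kernels=3)
        v = samples[0]
        val = rbm.contractive_penalty(v, p, with_grad=False)
        perm = [1, 2, 0]
        p2 = replace(p, w=p.w[perm], b=p.b[perm], a=p.a[perm])
        assert rbm.contractive_penalty(v, p2, with_grad=False) == \
            pytest.approx(val)


class TestContrastiveDivergence:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_rbm):
        p, samples = tiny_rbm
        cfg = rbm.TrainConfig(eta=0.0)
        p2 = rbm.cd_update(samples, p, cfg, np.random.default_rng(0))
        for name in ("w", "b", "c", "a"):
            assert np.array_equal(getattr(p, name), getattr(p2, name))

    def test_fixed_seed_reproduces_update(self, tiny_rbm):
        p, samples = tiny_rbm
        cfg = rbm.TrainConfig(eta=0.01, lam=0.1, cd_steps=3)
        p1 = rbm.cd_update(samples, p, cfg, np.random.default_rng(9))
        p2 = rbm.cd_update(samples, p, cfg, np.random.default_rng(9))
        assert np.array_equal(p1.w, p2.w) and np.array_equal(p1.a, p2.a)

    def test_divergent_parameters_raise(self, tiny_rbm):
        p, samples = tiny_rbm
        cfg = rbm.TrainConfig(eta=1e12, lam=0.0, cd_steps=1, clip_norm=None)
        bad = replace(p, w=p.w * 100)
        with pytest.raises(FloatingPointError):
            for _ in range(50):
                bad = rbm.cd_update(samples * 100, bad, cfg,
                                    np.random.default_rng(0))

    def test_cd_gradient_sign_agrees_with_exact_gradient(self):
        """CD-k, Rao-Blackwellised and averaged over chains, matches the
        exact enumerated log-likelihood gradient in sign on >= 90% of
        parameters across 20 seeded tiny instances."""
        ok = tot = 0
        for seed in range(20):
            p, samples = gen_tiny_rbm(seed=seed, pool=1, n_samples=6)
            exact = exact_loglik_gradient(samples, p)
            rng = np.random.default_rng(seed + 1000)
            acc = None
            for _ in range(60):
                g = rbm.cd_gradient(samples, p, 20, rng)
                if acc is None:
                    acc = {k: v.copy() for k, v in g.items()}
                else:
                    for k in acc:
                        acc[k] += g[k]
            for name in ("w", "b", "c", "a"):
                cd_nll = acc[name]
                exact_nll = -exact[name]
                ok += int(np.sum(np.sign(cd_nll) == np.sign(exact_nll)))
                tot += exact_nll.size
        assert ok / tot >= 0.90


class TestFilterRecovery:
    def test_recovers_known_orthogonal_generating_filters(self):
        f1 = np.array([[1.0, 1, 1], [0, 0, 0], [-1, -1, -1]])
        f1 /= np.linalg.norm(f1)
        f2 = f1.T.copy()
        cosines = []
        for seed in range(5):
            X = gen_filter_images([f1, f2], n_images=300, image_size=10,
                                  density=0.08, noise=0.1, seed=seed)
            model = rbm.CssCRBM(
                n_kernels=2, kernel_size=3, pool=2, eta=0.01, lam=0.05,
                cd_steps=1, batch_size=25, n_epochs=12, random_state=seed,
            ).fit(X)
            w = model.params_.w
            worst_best = min(
                max(abs(np.vdot(w[k, 0] / np.linalg.norm(w[k, 0]), f))
                    for k in range(2))
                for f in (f1, f2)
            )
            cosines.append(worst_best)
        assert np.median(cosines) > 0.8
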