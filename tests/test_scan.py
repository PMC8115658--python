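import numpy as np
import pytest
from scipy import linalg, stats

from nbgwas import (CausalSet, SimConfig, assoc_scan, effective_scale,
                    generate_genotypes, make_kinship, place_on_grid,
                    prepare_inputs, pve_partition, records_to_frame, reml_fit,
                    simulate_phenotype)
from nbgwas.scan import PVEResult


def _draw(rng, K, s2):
    lam, U = linalg.eigh(K)
    n = K.shape[0]
    return U @ (np.sqrt(np.maximum(lam, 0) * s2) * rng.standard_normal(n))


def _kinship_pair(rng, n):
    """Two kinship-like PSD matrices with low mutual correlation."""
    K1 = make_kinship(np.where(rng.random((n, 400)) < 0.5, 1, -1)).values
    K2 = make_kinship(np.where(rng.random((n, 400)) < 0.5, 1, -1)).values
    return K1, K2


class TestPVEPartition:
    def test_equal_components_recovered_as_thirds(self):
        rng = np.random.default_rng(0)
        n = 150
        K1, K2 = _kinship_pair(rng, n)
        W = np.ones((n, 1))
        ps, pn = [], []
        for _ in range(20):
            y = _draw(rng, K1, 1.0) + _draw(rng, K2, 1.0) \
                + rng.standard_normal(n)
            res = pve_partition(y, W, K1, {1: K2})
            ps.append(res.partial_pve_self[1])
            pn.append(res.partial_pve_nei[1])
        assert np.mean(ps) == pytest.approx(1 / 3, abs=0.1)
        assert np.mean(pn) == pytest.approx(1 / 3, abs=0.1)

    def test_partial_sums_below_one(self):
        rng = np.random.default_rng(1)
        n = 100
        K1, K2 = _kinship_pair(rng, n)
        y = _draw(rng, K1, 2.0) + rng.standard_normal(n)
        res = pve_partition(y, np.ones((n, 1)), K1, {1: K2})
        assert res.partial_pve_self[1] + res.partial_pve_nei[1] <= 1 + 1e-8

    def test_pure_noise_gives_null_pves_and_pvalues(self):
        G = generate_genotypes(n=150, q=500, n_subpop=3, fst=0.15, seed=21)
        smap = place_on_grid(150, 10, 30, checkered=True, seed=22)
        inp = prepare_inputs(G, smap, 1)
        rng = np.random.default_rng(2)
        W = np.ones((150, 1))
        ok, reps = 0, 10
        selfs, neis, nets = [], [], []
        for _ in range(reps):
            y = rng.standard_normal(150)
            res = pve_partition(y, W, inp.K1, {1: inp.K2_by_scale[1]})
            selfs.append(res.single_pve_self)
            neis.append(res.partial_pve_nei[1])
            nets.append(res.net_pve_nei[1])
            ok += (res.lrt_single_self[1] > 0.05
                   and res.lrt_partial_nei[1][1] > 0.05)
        assert ok >= 0.9 * reps
        assert np.median(selfs) < 0.05
        assert np.median(neis) < 0.05
        assert abs(np.median(nets)) < 0.05

    def test_zero_neighbor_simulation_has_null_net_pve(self):
        """Phenotypes generated without any neighbor contribution: the net
        neighbor PVE stays near zero while the single neighbor PVE
        overstates it — the reason 'single PVE_nei' is not reported."""
        nets, singles = [], []
        for seed in range(6):
            G = generate_genotypes(n=200, q=300, seed=seed)
            smap = place_on_grid(200, 10, 40, checkered=True, seed=seed + 50)
            rng = np.random.default_rng(seed + 100)
            idx = rng.choice(300, 20, replace=False)
            b1 = np.zeros(300)
            b1[idx] = rng.choice([-1.0, 1.0], 20)
            causal = CausalSet(indices=idx,
                               classes=np.array(["self-only"] * 20),
                               beta1=b1, beta2=np.zeros(300),
                               beta12=np.zeros(300))
            cfg = SimConfig(alpha=1.0, pve_beta=0.3, pve_total=0.8,
                            ratio=(1, 0, 0), n_causal=20, s_max=3,
                            seed=seed + 200)
            sim = simulate_phenotype(G, smap, causal, cfg)
            inp = prepare_inputs(G, smap, 1)
            res = pve_partition(sim.y, np.ones((200, 1)), inp.K1,
                                inp.K2_by_scale)
            nets.append(res.net_pve_nei[1])
            singles.append(res.single_pve_nei[1])
        assert abs(np.median(nets)) < 0.05
        assert np.median(singles) > np.median(nets)


class TestEffectiveScale:
    def _result(self, partial_nei):
        scales = sorted(partial_nei)
        delta, prev = {}, 0.0
        for s in scales:
            delta[s] = partial_nei[s] - prev
            prev = partial_nei[s]
        return PVEResult(scales=scales, single_pve_self=0.0,
                         single_pve_nei={}, partial_pve_self={},
                         partial_pve_nei=partial_nei, net_pve_nei={},
                         delta_pve_nei=delta, lrt_single_self=(0, 1),
                         lrt_single_nei={}, lrt_partial_self={},
                         lrt_partial_nei={})

    def test_flat_profile_ties_break_to_smallest(self):
        res = self._result({1: 0.2, 2: 0.4, 3: 0.6})
        assert effective_scale(res) == 1

    def test_saturating_profile_picks_first_scale(self):
        res = self._result({1: 0.3, 2: 0.32, 3: 0.33})
        assert effective_scale(res) == 1

    def test_accelerating_profile_picks_last_scale(self):
        res = self._result({1: 0.1, 2: 0.25, 3: 0.45})
        assert effective_scale(res) == 3

    def _scale_profile(self, alpha, seed):
        from nbgwas import assign_causal
        ss = [int(s.generate_state(1)[0] % 2 ** 31)
              for s in np.random.SeedSequence(seed + 300).spawn(4)]
        G = generate_genotypes(n=200, q=300, seed=ss[0])
        smap = place_on_grid(200, 10, 40, checkered=True, seed=ss[1])
        causal = assign_causal(300, 50, seed=ss[2])
        cfg = SimConfig(alpha=alpha, pve_beta=0.3, pve_total=0.8,
                        ratio=(1, 8, 1), n_causal=50, s_max=3, seed=ss[3])
        sim = simulate_phenotype(G, smap, causal, cfg)
        inp = prepare_inputs(G, smap, 3)
        return pve_partition(sim.y, np.ones((200, 1)), inp.K1,
                             inp.K2_by_scale)

    def test_recovery_from_simulated_phenotypes(self):
        """Strong distance decay concentrates the neighbor PVE at the first
        shell (s_hat = 1); near-zero decay keeps the partial neighbor PVE
        growing as the reference scale broadens."""
        reps = 7
        strong = [self._scale_profile(3.0, seed) for seed in range(reps)]
        weak = [self._scale_profile(0.01, seed) for seed in range(reps)]
        hits_strong = sum(r.s_hat == 1 for r in strong)
        assert hits_strong > reps / 2
        # weak decay: profile keeps increasing toward the widest scale
        increasing = sum(r.partial_pve_nei[3] >= r.partial_pve_nei[1] - 1e-6
                         for r in weak)
        assert increasing > reps / 2
        assert np.mean([r.s_hat for r in weak]) > np.mean(
            [r.s_hat for r in strong])


class TestAssocScan:
    def test_self_pvalues_match_single_kinship_reference(self):
        """With sigma2^2 = 0 the model is standard mixed-model GWAS: the
        scan's self p-values must match an independent dense single-kinship
        LRT implementation."""
        rng = np.random.default_rng(5)
        n, q = 80, 30
        G = generate_genotypes(n=n, q=q, seed=6)
        smap = place_on_grid(n, 8, 20, checkered=True, seed=7)
        K1 = make_kinship(G.values).values
        y = _draw(rng, K1, 1.0) + rng.standard_normal(n)
        W = np.ones((n, 1))
        inp = prepare_inputs(G, smap, 1)
        recs = assoc_scan(y, W, G, inp.X2_by_scale[1], inp.K1,
                          inp.K2_by_scale[1])

        # reference: dense GLS LRT with the same plug-in variance ratio
        vc = reml_fit(y, W, [K1])
        V0 = (vc.sigma1_sq / vc.sigma_e_sq) * K1 + np.eye(n)
        V0inv = np.linalg.inv(V0)
        _, ldV0 = np.linalg.slogdet(V0)

        def ll(X):
            b = np.linalg.solve(X.T @ V0inv @ X, X.T @ V0inv @ y)
            r = y - X @ b
            return -0.5 * (n * np.log(2 * np.pi * (r @ V0inv @ r) / n)
                           + ldV0 + n)

        ll0 = ll(W)
        for k, rec in enumerate(recs):
            stat = max(2 * (ll(np.column_stack([W, G.values[:, k]])) - ll0), 0)
            p_ref = stats.chi2.sf(stat, 1)
            assert rec.p_self == pytest.approx(p_ref, abs=1e-6)

    def test_forward_selection_matches_dense_oracle(self):
        """Self, neighbor, and asymmetric LRTs agree with brute-force dense
        GLS under the same plug-in covariances."""
        rng = np.random.default_rng(8)
        n, q = 40, 12
        G = generate_genotypes(n=n, q=q, seed=9)
        smap = place_on_grid(n, 5, 16, checkered=True, seed=10)
        inp = prepare_inputs(G, smap, 1)
        y = _draw(rng, inp.K1.values, 0.8) + rng.standard_normal(n)
        W = np.ones((n, 1))
        X2, X12 = inp.X2_by_scale[1], inp.X12_by_scale[1]
        recs = assoc_scan(y, W, G, X2, inp.K1, inp.K2_by_scale[1],
                          test_asym=True, X12=X12)

        vc1 = reml_fit(y, W, [inp.K1])
        vc2 = reml_fit(y, W, [inp.K1, inp.K2_by_scale[1]])

        def dense_ll(X, Ks, vc):
            V0 = np.eye(n)
            for s2, K in zip(vc.sigmas, Ks):
                V0 = V0 + (s2 / vc.sigma_e_sq) * K.values
            Vi = np.linalg.inv(V0)
            b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ b
            return -0.5 * (n * np.log(2 * np.pi * (r @ Vi @ r) / n)
                           + np.linalg.slogdet(V0)[1] + n)

        K1only = [inp.K1]
        Kboth = [inp.K1, inp.K2_by_scale[1]]
        for k, rec in enumerate(recs):
            x = G.values[:, k].astype(float)
            ll_n = dense_ll(W, K1only, vc1)
            ll_s = dense_ll(np.column_stack([W, x]), K1only, vc1)
            p_self = stats.chi2.sf(max(2 * (ll_s - ll_n), 0), 1)
            ll_s2 = dense_ll(np.column_stack([W, x]), Kboth, vc2)
            ll_n2 = dense_ll(np.column_stack([W, x, X2[:, k]]), Kboth, vc2)
            p_nei = stats.chi2.sf(max(2 * (ll_n2 - ll_s2), 0), 1)
            ll_a = dense_ll(np.column_stack([W, x, X2[:, k], X12[:, k]]),
                            Kboth, vc2)
            p_asym = stats.chi2.sf(max(2 * (ll_a - ll_n2), 0), 1)
            assert rec.p_self == pytest.approx(p_self, abs=1e-8)
            assert rec.p_nei == pytest.approx(p_nei, abs=1e-8)
            assert rec.p_asym == pytest.approx(p_asym, abs=1e-8)

    def test_planted_neighbor_signal_is_top_hit(self):
        """A single large neighbor-only causal marker should attain the
        genome-wide minimum neighbor p-value in most replicates."""
        hits = 0
        reps = 10
        for seed in range(reps):
            G = generate_genotypes(n=200, q=300, seed=seed + 400)
            smap = place_on_grid(200, 10, 40, checkered=True, seed=seed + 500)
            b2 = np.zeros(300)
            b2[137] = 1.0
            causal = CausalSet(indices=np.array([137]),
                               classes=np.array(["nei-only"]),
                               beta1=np.zeros(300), beta2=b2,
                               beta12=np.zeros(300))
            cfg = SimConfig(alpha=3.0, pve_beta=0.6, pve_total=0.7,
                            ratio=(1, 8, 1), n_causal=1, s_max=3,
                            seed=seed + 600)
            sim = simulate_phenotype(G, smap, causal, cfg)
            inp = prepare_inputs(G, smap, 1)
            recs = assoc_scan(sim.y, np.ones((200, 1)), G,
                              inp.X2_by_scale[1], inp.K1,
                              inp.K2_by_scale[1])
            df = records_to_frame(recs)
            hits += df.p_nei.idxmin() == 137
        assert hits >= 8

    def test_self_only_signals_do_not_leak_into_neighbor_test(self):
        """Conservatism by construction: markers whose only signal is
        self-genotypic should not earn small neighbor p-values."""
        med_p = []
        for seed in range(5):
            G = generate_genotypes(n=200, q=300, seed=seed + 700)
            smap = place_on_grid(200, 10, 40, checkered=True, seed=seed + 800)
            rng = np.random.default_rng(seed + 900)
            idx = rng.choice(300, 10, replace=False)
            b1 = np.zeros(300)
            b1[idx] = rng.choice([-1.0, 1.0], 10)
            causal = CausalSet(indices=idx,
                               classes=np.array(["self-only"] * 10),
                               beta1=b1, beta2=np.zeros(300),
                               beta12=np.zeros(300))
            cfg = SimConfig(alpha=1.0, pve_beta=0.6, pve_total=0.8,
                            ratio=(1, 0, 0), n_causal=10, s_max=3,
                            seed=seed + 1000)
            sim = simulate_phenotype(G, smap, causal, cfg)
            inp = prepare_inputs(G, smap, 1)
            recs = assoc_scan(sim.y, np.ones((200, 1)), G,
                              inp.X2_by_scale[1], inp.K1,
                              inp.K2_by_scale[1])
            df = records_to_frame(recs)
            med_p.append(df.p_nei.values[idx])
        assert np.median(np.concatenate(med_p)) > 0.1

    def test_monomorphic_marker_flagged(self, small_genotypes, checkered_map):
        import warnings
        G = small_genotypes
        vals = G.values.copy()
        vals[:, 0] = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from conftest import make_genotype_table
            G2 = make_genotype_table(vals)
        inp = prepare_inputs(G2, checkered_map, 1)
        rng = np.random.default_rng(11)
        y = rng.standard_normal(G2.n)
        recs = assoc_scan(y, np.ones((G2.n, 1)), G2, inp.X2_by_scale[1],
                          inp.K1, inp.K2_by_scale[1])
        assert recs[0].p_self == 1.0 and recs[0].flagged
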