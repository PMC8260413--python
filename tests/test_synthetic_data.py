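import numpy as np
import pandas as pd
import pytest

from sweepscan.ld_decay import LdFilterSpec, decay_curve, pair_r2
from sweepscan.synthetic_data import (
    BaldingNicholsSpec,
    Bottleneck,
    SimulationError,
    Sweep,
    WrightFisherSpec,
    inject_sweep_differentiation,
    read_truth,
    simulate_balding_nichols,
    simulate_wright_fisher,
    write_truth,
)
from sweepscan.window_stats import WindowGrid, scan, window_fst, window_pi


class TestBaldingNicholsBasics:
    def test_no_drift_limit(self):
        spec = BaldingNicholsSpec(F=(1e-6, 1e-6, 1e-6), n_diploids=(30, 30, 30),
                                  n_sites=2000, site_spacing_bp=100, seed=4)
        gm, truth = simulate_balding_nichols(spec)
        # population frequencies all hug the ancestral value
        spread = truth.pop_freqs[["p_Target", "p_Control", "p_Background"]].std(axis=1)
        assert spread.max() < 0.01
        fst = window_fst(gm, WindowGrid(), "Target", "Control", min_snps=1).fst
        assert abs(np.nanmean(fst)) < 0.01

    def test_determinism_byte_identical(self):
        spec = BaldingNicholsSpec(n_sites=500, seed=123)
        a, _ = simulate_balding_nichols(spec)
        b, _ = simulate_balding_nichols(spec)
        assert a.genotypes.tobytes() == b.genotypes.tobytes()
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_rejects_bad_F(self):
        with pytest.raises(SimulationError):
            BaldingNicholsSpec(F=(0.0, 0.1, 0.1))
        with pytest.raises(SimulationError):
            BaldingNicholsSpec(F=(1.0, 0.1, 0.1))

    def test_rejects_tiny_samples(self):
        with pytest.raises(SimulationError):
            BaldingNicholsSpec(n_diploids=(1, 10, 10))

    def test_positions_strictly_increasing(self):
        spec = BaldingNicholsSpec(n_sites=100, seed=0)
        gm, _ = simulate_balding_nichols(spec)
        assert (np.diff(gm.pos) > 0).all()

    def test_unphased_output(self):
        gm, _ = simulate_balding_nichols(BaldingNicholsSpec(n_sites=10, seed=0))
        assert not gm.is_phased


class TestBaldingNicholsStatistics:
    def test_frequency_variance_matches_F(self):
        F = 0.08
        spec = BaldingNicholsSpec(F=(F, F, F), n_sites=20_000, seed=31)
        _, truth = simulate_balding_nichols(spec)
        p = truth.pop_freqs[["p_Target", "p_Control", "p_Background"]].to_numpy()
        var_across = p.var(axis=1, ddof=1)
        p_bar = p.mean(axis=1)
        expected = F * p_bar * (1 - p_bar)
        assert var_across.mean() == pytest.approx(expected.mean(), rel=0.05)

    def test_label_permutation_symmetry(self):
        # permuting the drift parameters relocates the long branch; the
        # permuted run's Control-branch length matches the original run's
        # Target-branch length statistically
        base = BaldingNicholsSpec(F=(0.2, 0.05, 0.05), n_sites=6000,
                                  site_spacing_bp=200, seed=41)
        perm = BaldingNicholsSpec(F=(0.05, 0.2, 0.05), n_sites=6000,
                                  site_spacing_bp=200, seed=42)
        grid = WindowGrid()
        t1 = scan(simulate_balding_nichols(base)[0], grid, min_snps=1)
        t2 = scan(simulate_balding_nichols(perm)[0], grid, min_snps=1)
        target_branch_1 = np.nanmean(t1.lsbl)
        control_branch_2 = np.nanmean((t2.fst_TC + t2.fst_CB - t2.fst_TB) / 2.0)
        assert target_branch_1 == pytest.approx(control_branch_2, abs=0.015)


class TestWrightFisherBasics:
    def test_determinism(self):
        spec = WrightFisherSpec(N_e=30, L=50_000, mu=5e-7, rho=1e-6,
                                split_gens=20, n_sites=100, samples_per_pop=10,
                                burnin_factor=2, seed=9)
        a, _ = simulate_wright_fisher(spec)
        b, _ = simulate_wright_fisher(spec)
        assert a.haplotypes.tobytes() == b.haplotypes.tobytes()

    def test_phased_output_consistent_with_dosage(self):
        spec = WrightFisherSpec(N_e=30, L=50_000, mu=5e-7, rho=1e-6,
                                split_gens=20, n_sites=100, samples_per_pop=10,
                                burnin_factor=2, seed=9)
        gm, _ = simulate_wright_fisher(spec)
        assert gm.is_phased
        np.testing.assert_array_equal(
            gm.haplotypes[:, 0::2] + gm.haplotypes[:, 1::2], gm.genotypes
        )

    def test_rejects_sweep_outside_sequence(self):
        with pytest.raises(SimulationError):
            WrightFisherSpec(sweep=Sweep("Target", 10**9, 0.1))

    def test_rejects_oversized_bottleneck(self):
        with pytest.raises(SimulationError):
            WrightFisherSpec(N_e=50, bottleneck=Bottleneck("Target", 50, 10))

    def test_site_capacity_guard(self):
        with pytest.raises(SimulationError, match="segregating"):
            WrightFisherSpec(N_e=500, L=10**6, mu=1e-4, n_sites=100)

    def test_sweep_loss_fail_mode(self):
        # an impossible completion requirement must raise in fail mode
        spec = WrightFisherSpec(
            N_e=30, L=50_000, mu=5e-7, rho=1e-6, split_gens=5, n_sites=100,
            samples_per_pop=10, burnin_factor=1,
            sweep=Sweep("Target", 25_000, 0.01), sweep_min_freq=0.999,
            sweep_loss="fail", seed=5,
        )
        with pytest.raises(SimulationError):
            simulate_wright_fisher(spec)


class TestWrightFisherEquilibrium:
    def test_heterozygosity_near_theta_over_one_plus_theta(self):
        # theta = 4 N_e u = 0.05 per site; expected H ~ theta / (1 + theta)
        # (the symmetric two-allele stationary value theta/(1+2*theta) lies
        # within the same 15% band at this theta)
        N_e, S, L = 50, 300, 300_000
        u_site_target = 0.05 / (4 * N_e)
        mu = u_site_target / (L / S)
        hs = []
        for seed in range(5):
            spec = WrightFisherSpec(N_e=N_e, L=L, mu=mu, rho=0.0,
                                    split_gens=0, n_sites=S,
                                    samples_per_pop=50, burnin_factor=10,
                                    seed=seed)
            gm, _ = simulate_wright_fisher(spec)
            p = gm.alt_freq(gm.samples_for("Target"))
            n_hap = 2 * 50
            hs.append(np.mean(2 * p * (1 - p)) * n_hap / (n_hap - 1))
        theta = 0.05
        assert np.mean(hs) == pytest.approx(theta / (1 + theta), rel=0.15)

    def test_no_recombination_no_distance_decay(self):
        # rho = 0: r2 shows no systematic trend with distance
        corrs = []
        for seed in range(3):
            spec = WrightFisherSpec(N_e=50, L=200_000, mu=1e-6, rho=0.0,
                                    split_gens=0, n_sites=200,
                                    samples_per_pop=30, burnin_factor=6,
                                    seed=100 + seed)
            gm, _ = simulate_wright_fisher(spec)
            idx = gm.samples_for("Target")
            hap_cols = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
            p = gm.alt_freq(idx)
            keep = np.flatnonzero((p > 0.1) & (p < 0.9))
            rng = np.random.default_rng(seed)
            dists, r2s = [], []
            for _ in range(600):
                i, j = rng.choice(keep, size=2, replace=False)
                v = pair_r2(gm.haplotypes[i, hap_cols], gm.haplotypes[j, hap_cols],
                            phased=True)
                if v is not None:
                    dists.append(abs(int(gm.pos[j]) - int(gm.pos[i])))
                    r2s.append(v)
            corrs.append(np.corrcoef(dists, r2s)[0, 1])
        assert abs(np.mean(corrs)) < 0.1


class TestBottleneckDirectionality:
    def test_pi_and_ld_over_seeds(self):
        # scaled-down version of the acceptance check: 4 seeds, both
        # directions required in at least 3
        pi_wins = ld_wins = 0
        for seed in range(4):
            spec = WrightFisherSpec(
                N_e=100, L=500_000, mu=6e-7, rho=2.5e-7, split_gens=300,
                n_sites=1000, samples_per_pop=25, burnin_factor=5,
                bottleneck=Bottleneck("Target", 8, 200), seed=50 + seed,
            )
            gm, _ = simulate_wright_fisher(spec)
            grid = WindowGrid()
            pi_t = window_pi(gm, grid, "Target").pi.mean()
            pi_c = window_pi(gm, grid, "Control").pi.mean()
            ct = decay_curve(gm, "Target", LdFilterSpec(), bin_width=20_000, smooth=True)
            cc = decay_curve(gm, "Control", LdFilterSpec(), bin_width=20_000, smooth=True)
            pi_wins += pi_t < pi_c
            ld_wins += (ct.half_decay_distance or np.inf) > (cc.half_decay_distance or np.inf)
        assert pi_wins >= 3
        assert ld_wins >= 3


class TestSweepDetection:
    def test_completed_sweep_attains_max_lsbl(self):
        # completed sweeps (selection strong enough to fix within the
        # simulated horizon) put the maximum LSBL in a sweep-spanning window
        hits = 0
        for seed in range(10):
            spec = WrightFisherSpec(
                N_e=100, L=250_000, mu=1e-6, rho=2e-6, split_gens=50,
                n_sites=500, samples_per_pop=25, burnin_factor=5,
                sweep=Sweep("Target", 125_000, 0.5), sweep_min_freq=0.9,
                seed=seed * 100,
            )
            gm, truth = simulate_wright_fisher(spec)
            assert truth.sweep_window_ids
            table = scan(gm, WindowGrid(), min_snps=5)
            best = table.loc[table.lsbl.idxmax()]
            wid = f"{best.chrom}:{best.start}-{best.end}"
            hits += wid in truth.sweep_window_ids
        assert hits >= 9


class TestInjectSweep:
    def test_rejects_bad_delta(self):
        gm, _ = simulate_balding_nichols(BaldingNicholsSpec(n_sites=10, seed=0))
        with pytest.raises(SimulationError):
            inject_sweep_differentiation(gm, "chr1", 1, 1000, delta=1.5)


class TestTruthRoundTrip:
    def test_write_read_equal(self, tmp_path):
        spec = BaldingNicholsSpec(n_sites=50, seed=77)
        _, truth = simulate_balding_nichols(spec)
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        back = read_truth(path)
        assert back.spec == truth.spec
        assert back.sweep_window_ids == truth.sweep_window_ids
        pd.testing.assert_frame_equal(
            back.pop_freqs, truth.pop_freqs, check_dtype=False
        )

    def test_empty_sweep_field_preserved(self, tmp_path):
        _, truth = simulate_balding_nichols(BaldingNicholsSpec(n_sites=5, seed=0))
        path = tmp_path / "t.tsv"
        write_truth(truth, path)
        assert read_truth(path).sweep_window_ids == []

    def test_F_recovered_from_file(self, tmp_path):
        spec = BaldingNicholsSpec(F=(0.17, 0.03, 0.06), n_sites=5, seed=0)
        _, truth = simulate_balding_nichols(spec)
        path = tmp_path / "t.tsv"
        write_truth(truth, path)
        assert tuple(read_truth(path).spec["F"]) == (0.17, 0.03, 0.06)

    def test_wf_sweep_windows_in_truth(self, tmp_path):
        spec = WrightFisherSpec(N_e=30, L=100_000, mu=5e-7, rho=1e-6,
                                split_gens=20, n_sites=100, samples_per_pop=10,
                                burnin_factor=2, sweep=Sweep("Target", 60_000, 0.5),
                                seed=2)
        _, truth = simulate_wright_fisher(spec)
        assert truth.sweep_window_ids  # non-empty iff sweep requested
        path = tmp_path / "t.tsv"
        write_truth(truth, path)
        assert read_truth(path).sweep_window_ids == truth.sweep_window_ids
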