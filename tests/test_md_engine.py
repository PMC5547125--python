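"""Langevin engine: force field oracles, thermostat, protocol contracts."""

import numpy as np
import pytest

from transloc.chain_model import ChainGeometryParams
from transloc.iftp_solver import cis_front_profile
from transloc.md_engine import (MDConfig, TranslocationRun, build_pore,
                                equilibrium_bond_length,
                                equilibrium_end_to_end, forces,
                                measure_trans_friction, run_ensemble,
                                run_translocation, sample_wlc_configuration,
                                write_xyz)

FAST = dict(equilibration_steps=20_000, max_steps=500_000)


class TestForces:
    def test_wca_vanishes_at_cutoff(self):
        cfg = MDConfig(n_beads=2, bend_kappa=0.0, fene_k=1e-12)
        pos = np.array([[0.0, 0.0, 0.0], [2 ** (1 / 6), 0.0, 0.0]])
        f = forces(pos, cfg)
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_collinear_bending_force_zero(self):
        cfg = MDConfig(n_beads=3)
        b0 = equilibrium_bond_length(cfg)
        pos = np.array([[0.0, 0, 0], [b0, 0, 0], [2 * b0, 0, 0]])
        f = forces(pos, cfg)
        # at the FENE+WCA minimum with zero bending, all forces vanish
        assert np.allclose(f, 0.0, atol=1e-6)

    def test_fene_tension_analytic(self):
        """|F| = k r / (1 - r^2/R0^2) = 48.7805 at r = 0.96 (analytic
        differentiation of the FENE potential; WCA disabled here)."""
        cfg = MDConfig(n_beads=2, bend_kappa=0.0, epsilon=1e-12)
        pos = np.array([[0.0, 0, 0], [0.96, 0, 0]])
        f = forces(pos, cfg)
        assert abs(f[0, 0]) == pytest.approx(48.7805, abs=0.01)

    def test_fene_overextension_raises(self):
        cfg = MDConfig(n_beads=2)
        pos = np.array([[0.0, 0, 0], [1.6, 0, 0]])
        with pytest.raises(RuntimeError, match="FENE bond 0"):
            forces(pos, cfg)

    def test_wall_repels_both_sides_outside_lumen(self):
        # far-apart probe beads: disable bonded terms via a huge FENE range
        cfg = MDConfig(n_beads=2, bend_kappa=0.0, fene_k=1e-12, fene_r0=100.0)
        pos = np.array([[0.8, 3.0, 0.0], [-0.8, -3.0, 0.0]])
        f = forces(pos, cfg, wall=True)
        assert f[0, 0] > 0  # pushed to +x on the trans side
        assert f[1, 0] < 0  # pushed to -x on the cis side

    def test_wall_exempt_inside_lumen(self):
        cfg = MDConfig(n_beads=2, bend_kappa=0.0, fene_k=1e-12, fene_r0=100.0)
        pos = np.array([[0.3, 0.0, 0.0], [-5.0, 0.3, 0.0]])
        f = forces(pos, cfg, wall=True)
        assert np.allclose(f[:, 0], 0.0, atol=1e-9)  # in lumen / out of range

    def test_drive_only_inside_pore(self):
        cfg = MDConfig(n_beads=2, bend_kappa=0.0, fene_k=1e-12, fene_r0=100.0)
        pos = np.array([[0.2, 0.0, 0.0], [-5.0, 0.0, 0.0]])
        f = forces(pos, cfg, drive=20.0)
        assert f[0, 0] == pytest.approx(20.0)
        assert f[1, 0] == pytest.approx(0.0, abs=1e-9)

    def test_pore_beads_are_static_scatterers(self):
        cfg = MDConfig()
        pore = build_pore(cfg)
        assert pore.shape == (16, 3)
        assert np.allclose(pore[:, 0], 0.0)
        assert np.allclose(np.hypot(pore[:, 1], pore[:, 2]), 1.5)


class TestSampler:
    def test_bond_length_is_potential_minimum(self):
        b0 = equilibrium_bond_length(MDConfig())
        assert b0 == pytest.approx(0.961, abs=0.02)

    def test_wlc_statistics_match_bending_boltzmann(self, rng):
        """Sampled <cos theta> equals the Langevin function
        coth(kappa) - 1/kappa of the bending weight."""
        cfg = MDConfig()
        kappa = cfg.bend_kappa / cfg.kBT
        cosines = []
        for _ in range(40):
            pos = sample_wlc_configuration(cfg, 40, rng)
            b = np.diff(pos, axis=0)
            b /= np.linalg.norm(b, axis=1, keepdims=True)
            cosines.append(np.sum(b[:-1] * b[1:], axis=1))
        mean_cos = np.mean(np.concatenate(cosines))
        expected = 1.0 / np.tanh(kappa) - 1.0 / kappa
        assert mean_cos == pytest.approx(expected, abs=0.01)

    def test_no_hard_overlaps(self, rng):
        cfg = MDConfig(bend_kappa=0.0)
        pos = sample_wlc_configuration(cfg, 48, rng)
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.85


class TestThermostat:
    def test_equipartition(self):
        """Mean kinetic energy per bead = (3/2) kBT = 1.8 within 2%."""
        cfg = MDConfig(n_beads=16)
        res = equilibrium_end_to_end(cfg, 16, n_samples=4, seed=7,
                                     burn_steps=5_000, sample_steps=60_000,
                                     sample_every=200)
        assert res["kinetic_per_bead"] == pytest.approx(1.8, rel=0.02)

    def test_determinism(self):
        cfg = MDConfig(n_beads=12)
        a = equilibrium_end_to_end(cfg, 12, n_samples=2, seed=5,
                                   burn_steps=2_000, sample_steps=10_000)
        b = equilibrium_end_to_end(cfg, 12, n_samples=2, seed=5,
                                   burn_steps=2_000, sample_steps=10_000)
        assert a["r2_mean"] == b["r2_mean"]


class TestEquilibriumStatistics:
    def test_stiff_chain_matches_interpolation_formula(self):
        """MD <R_ee^2>^{1/2} for kappa_b = 30, kBT = 1.2 vs the
        interpolation formula at lp = 25 (distances in mean-bond-length
        units, N - 1 segments)."""
        from transloc.chain_model import end_to_end_distance
        cfg = MDConfig(n_beads=16)
        res = equilibrium_end_to_end(cfg, 16, n_samples=6, seed=11,
                                     burn_steps=10_000, sample_steps=40_000)
        chain = ChainGeometryParams(persistence_length=25.0)
        expected = end_to_end_distance(chain, res["n_segments"])
        measured = res["r_rms"] / res["bond_length"]
        assert measured == pytest.approx(expected, rel=0.05)

    def test_two_bead_bond_length(self):
        cfg = MDConfig(n_beads=2, bend_kappa=0.0)
        res = equilibrium_end_to_end(cfg, 2, n_samples=3, seed=3,
                                     burn_steps=2_000, sample_steps=20_000)
        assert res["r_rms"] == pytest.approx(res["bond_length"], rel=0.02)

    def test_flexible_chain_swells_like_saw(self):
        """kappa_b = 0: <R_ee^2> grows faster than the ideal-chain linear
        law across N = 8..32 (excluded-volume swelling)."""
        cfg = MDConfig(bend_kappa=0.0)
        sizes = np.array([8, 16, 32])
        r2 = [equilibrium_end_to_end(cfg, int(n), n_samples=4, seed=21,
                                     burn_steps=20_000,
                                     sample_steps=40_000)["r2_mean"]
              for n in sizes]
        slope = np.polyfit(np.log(sizes - 1), np.log(r2), 1)[0]
        assert 1.05 < slope < 1.45  # 2 nu = 1.176 for a SAW in 3D


class TestTranslocation:
    @pytest.fixture(scope="class")
    def reference_run(self):
        cfg = MDConfig(**FAST)
        return run_translocation(cfg, seed=11)

    def test_reference_run_succeeds(self, reference_run):
        assert reference_run.success
        assert reference_run.tau > 0

    def test_waiting_times_sum_to_tau(self, reference_run):
        assert reference_run.waiting_times.sum() == pytest.approx(
            reference_run.tau, rel=1e-9)
        assert np.all(reference_run.waiting_times >= 0)

    def test_determinism(self, reference_run):
        again = run_translocation(MDConfig(**FAST), seed=11)
        assert again.tau == reference_run.tau
        assert np.array_equal(again.waiting_times,
                              reference_run.waiting_times)

    def test_zero_drive_fails_loudly(self):
        cfg = MDConfig(drive_force=1e-9, n_beads=16,
                       equilibration_steps=5_000, max_steps=40_000,
                       max_restarts=2)
        with pytest.raises((RuntimeError, TimeoutError)):
            run_translocation(cfg, seed=1)

    def test_drive_monotonicity(self):
        """Mean tau decreases with driving force (sign test)."""
        taus = {}
        for f in (10.0, 20.0):
            cfg = MDConfig(n_beads=32, drive_force=f,
                           equilibration_steps=15_000, max_steps=500_000)
            runs = run_ensemble(cfg, 4, seed=42)
            taus[f] = np.mean([r.tau for r in runs])
        assert taus[20.0] < taus[10.0]


class TestFrictionExtraction:
    def test_round_trip_from_synthetic_runs(self, three_regime_model):
        """Waiting times generated from the theory itself invert back to
        the known friction model exactly."""
        from transloc.trans_friction import evaluate
        cfg = MDConfig()
        chain = ChainGeometryParams(persistence_length=25.0)
        s_mid = np.arange(1, 65) - 0.5
        front = cis_front_profile(chain, 63.0, np.minimum(s_mid, 63.0))
        eta_p = 4.0
        gamma = front + eta_p + evaluate(three_regime_model, s_mid)
        w_lj = gamma / cfg.dimensionless_force * cfg.time_unit
        runs = [TranslocationRun(tau=float(w_lj.sum()), waiting_times=w_lj,
                                 restarted=0, seed=k, success=True)
                for k in range(12)]
        trace, used_etap = measure_trans_friction(
            runs, cfg, pore_friction=eta_p, smooth_window=0)
        assert used_etap == eta_p
        assert np.allclose(trace.eta_values,
                           evaluate(three_regime_model, s_mid), atol=1e-9)

    def test_too_few_runs_rejected(self):
        cfg = MDConfig()
        with pytest.raises(ValueError):
            measure_trans_friction([], cfg)

    def test_small_ensemble_flagged_low_confidence(self, three_regime_model):
        from transloc.trans_friction import evaluate
        cfg = MDConfig()
        chain = ChainGeometryParams(persistence_length=25.0)
        s_mid = np.arange(1, 65) - 0.5
        front = cis_front_profile(chain, 63.0, np.minimum(s_mid, 63.0))
        gamma = front + 4.0 + evaluate(three_regime_model, s_mid)
        w_lj = gamma / cfg.dimensionless_force * cfg.time_unit
        runs = [TranslocationRun(tau=float(w_lj.sum()), waiting_times=w_lj,
                                 restarted=0, seed=k, success=True)
                for k in range(3)]
        trace, _ = measure_trans_friction(runs, cfg, pore_friction=4.0,
                                          smooth_window=0)
        assert trace.low_confidence


class TestIO:
    def test_xyz_round_trip(self, tmp_path, rng):
        cfg = MDConfig()
        pos = sample_wlc_configuration(cfg, 8, rng)
        path = tmp_path / "frame.xyz"
        write_xyz(path, pos, time=1.5, translocated=3)
        lines = path.read_text().splitlines()
        assert lines[0] == "8"
        assert "t=1.500000" in lines[1] and "s=3" in lines[1]
        back = np.array([[float(v) for v in ln.split()[1:]]
                         for ln in lines[2:]])
        assert np.allclose(back, pos, atol=1e-6)
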