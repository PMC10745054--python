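"""Generative membrane model: diffusion curve, sampling ledger, panels."""

import json

import numpy as np
import pytest

from franzperm import (
    FormulationEffect,
    FranzCellSpec,
    MembraneModel,
    SimulationConfig,
    cross_membrane_regression,
    cumulative_amount,
    diffusion_profile,
    generate_study_fixture,
    simulate_franz_sampling,
    simulate_tmwl_screen,
)
from franzperm import reference
from franzperm.barrier_screen import pair_by_formulation
from franzperm.study_data import ValidationError
from franzperm.synthetic_membrane import (
    ResolutionError,
    formulation_effects_from_panel,
    membrane_for,
)

MEM = MembraneModel(diffusivity_cm2_h=1e-4, thickness_cm=0.05, partition_k=1.0, label="slab")


def finite_difference_q(membrane, c0, t_end, n_nodes=200):
    """Explicit finite-difference solution of Fick's second law in the slab.

    Donor face held at K·C0, receptor face at 0 (sink), zero initial
    loading; the cumulative exit flux is integrated in time.
    """
    d, h, k = membrane.diffusivity_cm2_h, membrane.thickness_cm, membrane.partition_k
    dx = h / n_nodes
    dt = 0.4 * dx**2 / d
    steps = int(np.ceil(t_end / dt))
    dt = t_end / steps
    c = np.zeros(n_nodes + 1)
    c[0] = k * c0
    q = 0.0
    lam = d * dt / dx**2
    for _ in range(steps):
        # second-order one-sided receptor-face flux, with c[-1] = 0
        flux_out = d * (4 * c[-2] - c[-3]) / (2 * dx)
        c[1:-1] += lam * (c[2:] - 2 * c[1:-1] + c[:-2])
        flux_next = d * (4 * c[-2] - c[-3]) / (2 * dx)
        q += 0.5 * (flux_out + flux_next) * dt  # trapezoid in time
    return q


class TestDiffusionProfile:
    def test_zero_at_time_zero(self):
        q = diffusion_profile(MEM, 1e4, [0.0, 1.0, 4.0])
        assert q[0] == 0.0

    def test_nonnegative_nondecreasing(self):
        t = np.linspace(0, 10, 60)
        q = diffusion_profile(MEM, 1e4, t)
        assert np.all(q >= 0)
        assert np.all(np.diff(q) >= -1e-12)

    def test_large_t_asymptote_slope_and_intercept(self):
        tlag = MEM.lag_time_h  # ≈ 4.17 h for this slab
        t = np.array([40 * tlag, 50 * tlag])
        q = diffusion_profile(MEM, 1e4, t, n_terms=80)
        slope = (q[1] - q[0]) / (t[1] - t[0])
        assert slope == pytest.approx(MEM.steady_flux(1e4), rel=1e-9)
        intercept_t = t[0] - q[0] / slope
        assert intercept_t == pytest.approx(tlag, rel=1e-6)

    def test_matches_finite_difference_oracle(self):
        c0, t_end = 1e4, 4.0
        q_series = diffusion_profile(MEM, c0, [t_end], n_terms=60)[0]
        q_fd = finite_difference_q(MEM, c0, t_end)
        assert q_series == pytest.approx(q_fd, rel=5e-3)

    def test_truncation_convergence(self):
        t = np.array([0.5, 1, 2, 4.0])
        q40 = diffusion_profile(MEM, 1e4, t, n_terms=40)
        q80 = diffusion_profile(MEM, 1e4, t, n_terms=80)
        np.testing.assert_allclose(q80, q40, rtol=1e-9)

    def test_insufficient_terms_raises_resolution_error(self):
        slow = MembraneModel(diffusivity_cm2_h=1e-6, thickness_cm=0.1, partition_k=1.0)
        with pytest.raises(ResolutionError, match="n_terms"):
            diffusion_profile(slow, 1e4, [0.01], n_terms=20)


class TestFranzSampling:
    def test_zero_flux_membrane_all_zero(self, cell):
        res = simulate_franz_sampling(np.zeros(5), cell, SimulationConfig(noise_cv=0.0))
        assert np.all(res.series.concentrations_ug_ml == 0)

    def test_noise_free_cumulative_amount_recovers_truth(self, cell):
        """Sampling correction inverts the withdraw-and-replace dilution."""
        q_true = diffusion_profile(membrane_for("mucosa", "caffeine"), 1e4,
                                   cell.sampling_times_h)
        res = simulate_franz_sampling(q_true, cell, SimulationConfig(noise_cv=0.0))
        prof = cumulative_amount(res.series, cell)
        pos = q_true > 0
        np.testing.assert_allclose(prof.qn_ug_cm2[pos], q_true[pos], rtol=1e-10)

    def test_vs_zero_concentration_is_q_a_over_vc(self):
        cell = FranzCellSpec(sample_volume_ml=0.0)
        q_true = np.array([0.0, 10.0, 20.0, 40.0, 80.0])
        res = simulate_franz_sampling(q_true, cell, SimulationConfig(noise_cv=0.0))
        np.testing.assert_allclose(
            res.series.concentrations_ug_ml, q_true * 1.86 / 3.0, rtol=1e-12
        )

    def test_mass_conservation_ledger(self, cell, rng):
        """Transferred mass = receptor mass + Σ withdrawn, exactly."""
        for _ in range(10):
            mem = MembraneModel(
                diffusivity_cm2_h=float(rng.uniform(5e-4, 5e-3)),
                thickness_cm=float(rng.uniform(0.005, 0.06)),
                partition_k=float(rng.uniform(0.05, 2.0)),
            )
            q_true = diffusion_profile(mem, 1e4, cell.sampling_times_h)
            res = simulate_franz_sampling(q_true, cell, SimulationConfig(noise_cv=0.05),
                                          rng=rng)
            for n in range(len(cell.sampling_times_h)):
                transferred = q_true[n] * cell.orifice_area_cm2
                ledger = res.receptor_mass_ug[n] + res.withdrawn_mass_ug[:n].sum()
                assert ledger == pytest.approx(transferred, rel=1e-12, abs=1e-12)

    def test_profile_must_cover_schedule(self, cell):
        with pytest.raises(ValidationError):
            simulate_franz_sampling(np.zeros(3), cell, SimulationConfig())


class TestTmwlScreen:
    BASELINES = dict(reference.TMWL_BASELINES)

    def test_noise_free_controls_equal_baselines(self):
        effects = [FormulationEffect("f1", 0.5)]
        recs = simulate_tmwl_screen(self.BASELINES, effects, SimulationConfig(noise_cv=0.0))
        controls = {r.membrane: r.tmwl for r in recs if r.is_control}
        assert controls == {"nuclepore": 80.8, "mucosa": 72.4}

    def test_noise_free_shared_multipliers_give_r2_one(self):
        effects = [FormulationEffect(f"f{i}", m)
                   for i, m in enumerate([0.03, 0.2, 0.5, 0.8, 0.95])]
        recs = simulate_tmwl_screen(self.BASELINES, effects, SimulationConfig(noise_cv=0.0))
        _, x, y = pair_by_formulation(recs, "nuclepore", "mucosa")
        res = cross_membrane_regression(np.column_stack([x, y]))
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_panel_derived_effects_mimic_observed_classes(self):
        effects = formulation_effects_from_panel()
        assert len(effects) == 16
        by_class = {}
        for e in effects:
            by_class.setdefault(e.formulation_class, []).append(e.permeability_multiplier)
        # hydrophobic formulations block water transport the most
        assert min(by_class["hydrophobic"]) < 0.1
        assert np.mean(by_class["hydrophobic"]) < np.mean(by_class["liposomal"])
        assert np.mean(by_class["liposomal"]) < np.mean(by_class["hydrophilic"])

    def test_noisy_recovery_r2_over_20_seeds(self):
        """Shared effects at noise CV 5% keep the surrogate correlation high."""
        effects = formulation_effects_from_panel()
        r2s = []
        for seed in range(20):
            recs = simulate_tmwl_screen(self.BASELINES, effects,
                                        SimulationConfig(noise_cv=0.05, seed=seed))
            _, x, y = pair_by_formulation(recs, "nuclepore", "mucosa")
            r2s.append(cross_membrane_regression(np.column_stack([x, y])).r2)
        assert np.median(r2s) >= 0.95

    def test_single_membrane_rejected(self):
        with pytest.raises(ValidationError):
            simulate_tmwl_screen({"only": 80.0}, [], SimulationConfig())


class TestStudyFixture:
    def test_deterministic_byte_identical(self, tmp_path):
        cfg = SimulationConfig(noise_cv=0.05, seed=1)
        a = generate_study_fixture(tmp_path / "a", cfg,
                                   membranes=("nuclepore",), analyte_names=("caffeine",),
                                   n_cells=2)
        b = generate_study_fixture(tmp_path / "b", cfg,
                                   membranes=("nuclepore",), analyte_names=("caffeine",),
                                   n_cells=2)
        for name in ("timecourse.csv", "tmwl.csv", "config.yaml", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        target = tmp_path / "out"
        target.mkdir()
        (target / "keep.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_study_fixture(target, SimulationConfig(seed=1),
                                   membranes=("nuclepore",), analyte_names=("caffeine",),
                                   n_cells=1)
        generate_study_fixture(target, SimulationConfig(seed=1), force=True,
                               membranes=("nuclepore",), analyte_names=("caffeine",),
                               n_cells=1)

    def test_fixture_spans_observed_lipophilicity_range(self, tmp_path):
        out = generate_study_fixture(tmp_path / "f", SimulationConfig(seed=3),
                                     membranes=("nuclepore",), n_cells=1)
        import yaml

        cfg = yaml.safe_load((out / "config.yaml").read_text())
        kows = [a["log_kow"] for a in cfg["analytes"]]
        assert min(kows) == pytest.approx(-0.1)
        assert max(kows) == pytest.approx(6.5)

    def test_truth_json_matches_membrane_presets(self, tmp_path):
        out = generate_study_fixture(tmp_path / "f", SimulationConfig(seed=2),
                                     membranes=("skin", "nuclepore"),
                                     analyte_names=("caffeine",), n_cells=1)
        truth = json.loads((out / "truth.json").read_text())
        kp = {c["membrane"]: c["kp_cm_h"] for c in truth["cells"].values()}
        assert kp["skin"] == pytest.approx(5.1e-3, rel=1e-9)
        assert kp["nuclepore"] == pytest.approx(54.7e-3, rel=1e-9)
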