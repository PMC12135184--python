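import numpy as np
import pytest

from nucleofold.constants import BP_PER_BEAD
from nucleofold.mesoscale import (
    EnergyParams,
    FiberTemplate,
    SamplerSettings,
    State,
    T_LINKER,
    build_system,
    discretize_linker,
    initial_configuration,
    replicate_seeds,
    run_mc,
    set_conditions,
    total_energy,
)


class TestDiscretization:
    def test_zero(self):
        assert discretize_linker(0) == 0

    def test_44bp_is_5_beads(self):
        assert discretize_linker(44) == 5
        assert 5 * BP_PER_BEAD == pytest.approx(44.12, abs=0.01)

    def test_negative_clamped(self):
        assert discretize_linker(-12) == 0

    def test_representable_set(self):
        # the representable lengths are multiples of 8.8235 bp
        for beads, bp in [(0, 0.0), (2, 17.65), (3, 26.47), (4, 35.29),
                          (5, 44.12), (6, 52.94), (7, 61.76), (8, 70.59),
                          (9, 79.41), (13, 114.71)]:
            assert beads * BP_PER_BEAD == pytest.approx(bp, abs=0.01)
            assert discretize_linker(bp) == beads


class TestConditions:
    def test_150mm(self):
        p = set_conditions(EnergyParams(), 150.0)
        assert p.debye_nm == pytest.approx(0.785, abs=0.005)
        assert p.persistence_nm == 50.0
        assert p.debye_dd_nm is None

    def test_5mm(self):
        p = set_conditions(EnergyParams(), 5.0)
        assert p.debye_nm == pytest.approx(4.30, abs=0.01)

    def test_mg_mode(self):
        p = set_conditions(EnergyParams(), 150.0, mg=True)
        assert p.persistence_nm == 30.0
        assert p.debye_dd_nm == pytest.approx(0.4)

    def test_mg_literal_kappa(self):
        p = set_conditions(EnergyParams(), 150.0, mg=True, literal_kappa=True)
        assert p.debye_dd_nm == pytest.approx(2.5)

    def test_nonpositive_salt_rejected(self):
        with pytest.raises(ValueError):
            set_conditions(EnergyParams(), 0.0)


class TestEnergy:
    def test_relaxed_chain_zero_bonded(self):
        # stem-capable junction: the native build lays the linker straight
        # along the anchor directions, so stretch and bend vanish exactly
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        tpl = FiberTemplate(2, (4,), (1.0, 1.0))
        system = build_system(tpl, params)
        state = initial_configuration(system, "native")
        comp = total_energy(system, state)
        assert comp["stretch"] == pytest.approx(0.0, abs=1e-9)
        assert comp["bend"] == pytest.approx(0.0, abs=1e-9)
        assert comp["elec"] == 0.0 and comp["lh"] == 0.0

    def test_screened_coulomb_closed_form(self):
        # two linker beads far from everything else: E = lB q1 q2 e^(-r/l)/r
        params = set_conditions(EnergyParams(ev_eps=0.0, tails=False), 150.0)
        tpl = FiberTemplate(2, (3,), (0.0, 0.0))
        system = build_system(tpl, params)
        system.q[:] = 0.0
        # non-adjacent beads of the same linker (bonded pairs are excluded)
        i, _, j = np.where(system.typ == T_LINKER)[0]
        system.q[i] = 1.0
        system.q[j] = 1.0
        state = initial_configuration(system, "native")
        state.bead_pos[i] = (0.0, 500.0, 0.0)
        state.bead_pos[j] = (3.0, 500.0, 0.0)
        elec = total_energy(system, state)["elec"]
        lam = params.debye_nm
        expected = params.bjerrum_nm * np.exp(-3.0 / lam) / 3.0
        assert elec == pytest.approx(expected, rel=1e-9)

    def test_overlapping_cores_capped_finite(self):
        params = EnergyParams(charges_on=False)
        tpl = FiberTemplate(2, (0,), (1.0, 1.0))
        system = build_system(tpl, params)
        state = initial_configuration(system, "native")
        state.core_pos[1] = state.core_pos[0]
        state.core_rot[1] = state.core_rot[0].copy()
        from nucleofold.mesoscale import sync_rigid_beads

        sync_rigid_beads(system, state)
        comp = total_energy(system, state)
        assert np.isfinite(comp["total"])

    def test_zero_linker_template_finite_energy(self):
        params = set_conditions(EnergyParams(), 150.0)
        tpl = FiberTemplate(4, (0, 0, 0), (1.0,) * 4)
        system = build_system(tpl, params)
        state = initial_configuration(system, "native")
        assert np.isfinite(total_energy(system, state)["total"])

    def test_salt_monotonicity(self):
        # raising NaCl never increases the electrostatic repulsion magnitude
        tpl = FiberTemplate(3, (3, 3), (1.0,) * 3)
        energies = []
        for salt in (5.0, 50.0, 150.0):
            params = set_conditions(EnergyParams(), salt)
            system = build_system(tpl, params)
            state = initial_configuration(system, "native")
            comp = total_energy(system, state)
            energies.append(abs(comp["elec"]))
        assert energies[0] >= energies[1] >= energies[2]


class TestSampler:
    def test_determinism_bit_identical(self):
        tpl = FiberTemplate(4, (3, 0, 4), (1.0,) * 4)
        params = set_conditions(EnergyParams(), 150.0)
        settings = SamplerSettings(n_frames=5, burn_in_sweeps=30, sweeps_per_frame=2)
        a = run_mc(tpl, params, settings, seed=17)
        b = run_mc(tpl, params, settings, seed=17)
        assert np.array_equal(a.bead_positions, b.bead_positions)
        assert np.array_equal(a.core_positions, b.core_positions)

    def test_incremental_energy_matches_full_recompute(self):
        tpl = FiberTemplate(5, (4, 0, 3, 5), (1.0,) * 5)
        params = set_conditions(EnergyParams(), 150.0)
        settings = SamplerSettings(n_frames=10, burn_in_sweeps=150, sweeps_per_frame=2)
        ens = run_mc(tpl, params, settings, seed=3)
        assert ens.energy_drift_check < 1e-8 * max(1.0, ens.n_frames)

    def test_harmonic_spring_variance(self):
        # one bead tethered by two zero-rest-length springs of stiffness k to
        # frozen anchors: E = k|r-a|^2 + k|r-b|^2 -> var per axis kT/(2k)
        k = 50.0
        params = EnergyParams(
            charges_on=False, ev_eps=0.0, persistence_nm=0.0,
            bead_spacing_nm=0.0, stretch_k=k, tails=False,
        )
        tpl = FiberTemplate(2, (1,), (0.0, 0.0))
        settings = SamplerSettings(
            n_frames=4000, burn_in_sweeps=500, sweeps_per_frame=5,
            freeze_cores=True, pivot_prob=0.0, crank_prob=0.0,
        )
        ens = run_mc(tpl, params, settings, seed=42)
        bead = int(np.where(ens.system.typ == T_LINKER)[0][0])
        traj = ens.bead_positions[:, bead, :]
        expected = 1.0 / (2 * k)
        # 3 SE of the variance estimate, inflated for autocorrelation
        n_eff = len(traj) / 10
        se = expected * np.sqrt(2.0 / n_eff)
        for axis in range(3):
            assert traj[:, axis].var() == pytest.approx(expected, abs=3 * se)

    def test_persistence_length_recovery(self):
        params = EnergyParams(
            charges_on=False, ev_eps=0.0, persistence_nm=50.0, tails=False
        )
        tpl = FiberTemplate(2, (40,), (0.0, 0.0))
        settings = SamplerSettings(
            n_frames=300, burn_in_sweeps=300, sweeps_per_frame=5,
            pivot_prob=0.1, crank_prob=0.0,
        )
        ens = run_mc(tpl, params, settings, seed=4)
        idx = np.where(ens.system.typ == T_LINKER)[0]
        pos = ens.bead_positions[:, idx, :]
        bonds = np.diff(pos, axis=1)
        units = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
        mean_cos = float(np.mean(np.sum(units[:, :-1] * units[:, 1:], axis=2)))
        lp = -3.0 / np.log(mean_cos)
        # discrete-WLC expectation for g = Lp/l0: <cos> = coth(g) - 1/g
        g = 50.0 / 3.0
        lp_expected = -3.0 / np.log(1.0 / np.tanh(g) - 1.0 / g)
        assert lp == pytest.approx(lp_expected, rel=0.10)
        assert lp == pytest.approx(50.0, rel=0.10)

    def test_replicate_seed_splitting(self):
        seeds = replicate_seeds(123, 20)
        assert len(set(seeds)) == 20
        assert seeds == replicate_seeds(123, 20)

    def test_pdb_roundtrip_of_real_ensemble(self, tmp_path):
        from nucleofold.io_model import read_ensemble_pdb, write_ensemble_pdb

        tpl = FiberTemplate(3, (3, 2), (1.0,) * 3)
        params = set_conditions(EnergyParams(), 150.0)
        ens = run_mc(
            tpl, params,
            SamplerSettings(n_frames=3, burn_in_sweeps=10, sweeps_per_frame=1),
            seed=1,
        )
        out = tmp_path / "ens.pdb"
        write_ensemble_pdb(ens, out)
        coords, kinds = read_ensemble_pdb(out)
        assert coords.shape == ens.bead_positions.shape
        np.testing.assert_allclose(coords, ens.bead_positions, atol=1e-3)
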