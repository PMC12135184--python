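import numpy as np
import pytest

from nucleofold.mesoscale import (
    Ensemble,
    EnergyParams,
    FiberTemplate,
    SamplerSettings,
    build_system,
    initial_configuration,
    run_mc,
    set_conditions,
)
from nucleofold.sim_observables import (
    TAIL_CATEGORIES,
    fan_distribution,
    interaction_pattern,
    packing_ratio,
    stem_index,
    stem_report,
    tail_interaction_fractions,
)


def _static_ensemble(template, params, n_frames=3, jitter=0.0, seed=0):
    """Ensemble whose frames repeat the initial configuration."""
    system = build_system(template, params)
    state = initial_configuration(system, "native")
    rng = np.random.default_rng(seed)
    core_pos = np.stack([state.core_pos] * n_frames)
    core_rot = np.stack([state.core_rot] * n_frames)
    bead_pos = np.stack([state.bead_pos] * n_frames)
    if jitter:
        bead_pos = bead_pos + rng.normal(0, jitter, bead_pos.shape)
    return Ensemble(
        system=system, core_positions=core_pos, core_rotations=core_rot,
        bead_positions=bead_pos, seed=seed,
    )


class _CoresOnly:
    def __init__(self, core_positions):
        self.core_positions = np.asarray(core_positions, float)


class TestPackingRatio:
    def test_closed_form_12_cores_33nm(self):
        pts = np.zeros((1, 12, 3))
        pts[0, :, 0] = np.linspace(0, 33, 12)
        out = packing_ratio(_CoresOnly(pts))
        assert out["mean"] == pytest.approx(4.0)

    def test_two_core_frame_rejected(self):
        with pytest.raises(ValueError):
            packing_ratio(_CoresOnly(np.zeros((1, 2, 3))))

    def test_degenerate_frame_skipped(self):
        pts = np.zeros((2, 5, 3))
        pts[1, :, 0] = np.linspace(0, 11, 5)
        out = packing_ratio(_CoresOnly(pts))
        assert out["n_skipped"] == 1
        assert out["mean"] == pytest.approx(5.0)

    def test_rigid_ensemble_zero_sd(self):
        pts = np.zeros((4, 6, 3))
        pts[:, :, 0] = np.linspace(0, 30, 6)
        out = packing_ratio(_CoresOnly(pts))
        assert out["sd"] == pytest.approx(0.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(3, 8, 3)) * 15
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=1).as_matrix()
        rotated = pts @ R.T + np.array([5.0, -3.0, 2.0])
        a = packing_ratio(_CoresOnly(pts))
        b = packing_ratio(_CoresOnly(rotated))
        assert a["mean"] == pytest.approx(b["mean"], rel=1e-9)


class TestInteractionPattern:
    def test_zigzag_mode_k2(self):
        pts = np.zeros((1, 12, 3))
        for i in range(12):
            pts[0, i] = ((i // 2) * 6.0 + (i % 2) * 3.0, (i % 2) * 20.0, 0.0)
        out = interaction_pattern(_CoresOnly(pts))
        assert np.argmax(out["frequency"]) == 1  # k = 2

    def test_extended_chain_empty(self):
        pts = np.zeros((1, 10, 3))
        pts[0, :, 0] = np.arange(10) * 15.0
        out = interaction_pattern(_CoresOnly(pts))
        assert out["frequency"].sum() == 0.0

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 40, size=(10, 15, 3))
        out = interaction_pattern(_CoresOnly(pts), contact_nm=11.0)
        # exhaustive O(n^2) recount
        n = 15
        counts = np.zeros(n)
        for f in range(10):
            for i in range(n):
                for j in range(i + 1, n):
                    if np.linalg.norm(pts[f, i] - pts[f, j]) < 11.0:
                        counts[abs(i - j)] += 1
        np.testing.assert_allclose(out["frequency"], counts[1:] / (10 * n))


class TestStems:
    def test_parallel_linkers_index_one(self):
        # native start of a stem-capable fiber has the two linkers parallel
        # at ~2.2 nm separation: every pair below the 2.5 nm threshold
        tpl = FiberTemplate(3, (4, 4), (1.0,) * 3, (42.0, 42.0))
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        ens = _static_ensemble(tpl, params)
        rec = stem_index(ens, core=1)
        assert rec.eligible
        assert rec.index == pytest.approx(1.0)

    def test_short_linker_ineligible(self):
        tpl = FiberTemplate(3, (2, 4), (1.0,) * 3)
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        ens = _static_ensemble(tpl, params)
        rec = stem_index(ens, core=1)
        assert not rec.eligible and rec.index is None

    def test_splayed_linkers_low_index(self):
        tpl = FiberTemplate(3, (4, 4), (1.0,) * 3, (42.0, 42.0))
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        system = build_system(tpl, params)
        state = initial_configuration(system, "native")
        # splay the exit linker of core 1 to 90 degrees from the entry
        s0 = int(system.linker_start[1])
        a_out = state.core_pos[1] + state.core_rot[1] @ np.array([-3.5, -0.9, -0.6])
        perp = state.core_rot[1] @ np.array([0.0, 0.0, 1.0])
        for s in range(4):
            state.bead_pos[s0 + s] = a_out + 3.0 * (s + 1) * perp
        ens = Ensemble(
            system=system,
            core_positions=state.core_pos[None],
            core_rotations=state.core_rot[None],
            bead_positions=state.bead_pos[None],
            seed=0,
        )
        rec = stem_index(ens, core=1)
        assert rec.index <= 0.25  # at most the first pair can touch

    def test_report_covers_all_cores(self):
        tpl = FiberTemplate(4, (4, 2, 4), (1.0,) * 4)
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        ens = _static_ensemble(tpl, params)
        recs = stem_report(ens)
        assert [r.core for r in recs] == [0, 1, 2, 3]
        # cores flanking the 2-bead linker are ineligible
        assert not recs[1].eligible and not recs[2].eligible


class TestFan:
    def test_rigid_point_mass(self):
        tpl = FiberTemplate(3, (4, 4), (1.0,) * 3)
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        ens = _static_ensemble(tpl, params, n_frames=5)
        out = fan_distribution(ens, core=1)
        # every bead occupies a single histogram cell across frames
        assert (out["hist"] > 0).sum() <= 8
        assert out["hist"].sum() == 5 * 8  # 5 frames x 8 linker beads

    def test_frame_shuffle_invariance(self):
        tpl = FiberTemplate(3, (4, 4), (1.0,) * 3)
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        ens = _static_ensemble(tpl, params, n_frames=6, jitter=0.5, seed=3)
        out1 = fan_distribution(ens, core=1)
        perm = np.random.default_rng(0).permutation(6)
        ens2 = Ensemble(
            system=ens.system,
            core_positions=ens.core_positions[perm],
            core_rotations=ens.core_rotations[perm],
            bead_positions=ens.bead_positions[perm],
            seed=0,
        )
        out2 = fan_distribution(ens2, core=1)
        np.testing.assert_allclose(out1["hist"], out2["hist"])
        np.testing.assert_allclose(out1["mean_entry"], out2["mean_entry"])

    def test_rigid_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        tpl = FiberTemplate(3, (4, 4), (1.0,) * 3)
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        ens = _static_ensemble(tpl, params, n_frames=4, jitter=0.3, seed=5)
        out1 = fan_distribution(ens, core=1)
        R = Rotation.random(random_state=2).as_matrix()
        t = np.array([10.0, -5.0, 3.0])
        ens2 = Ensemble(
            system=ens.system,
            core_positions=ens.core_positions @ R.T + t,
            core_rotations=np.einsum("ij,fcjk->fcik", R, ens.core_rotations),
            bead_positions=ens.bead_positions @ R.T + t,
            seed=0,
        )
        out2 = fan_distribution(ens2, core=1)
        np.testing.assert_allclose(out1["hist"], out2["hist"], atol=1e-9)


class TestTails:
    def test_categories_partition(self):
        tpl = FiberTemplate(3, (4, 4), (1.0,) * 3)
        params = set_conditions(EnergyParams(), 150.0)
        ens = run_mc(
            tpl, params,
            SamplerSettings(n_frames=5, burn_in_sweeps=50, sweeps_per_frame=2),
            seed=6,
        )
        out = tail_interaction_fractions(ens, cutoff_nm=2.0)
        assert set(out) == set(TAIL_CATEGORIES)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_far_apart_all_free(self):
        tpl = FiberTemplate(3, (9, 9), (1.0,) * 3)
        params = EnergyParams(charges_on=False, ev_eps=0.0)
        ens = _static_ensemble(tpl, params)
        out = tail_interaction_fractions(ens, cutoff_nm=0.01)
        assert out["free"] == pytest.approx(1.0)

    def test_tails_disabled_raises(self):
        tpl = FiberTemplate(3, (4, 4), (1.0,) * 3)
        params = EnergyParams(charges_on=False, ev_eps=0.0, tails=False)
        ens = _static_ensemble(tpl, params)
        with pytest.raises(ValueError):
            tail_interaction_fractions(ens)
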