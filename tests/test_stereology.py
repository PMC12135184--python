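import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleofold.io_model import PoseTable, Scene
from nucleofold.stereology import (
    apply_exclusions,
    compute_geometry,
    nearest_neighbors,
    stacked_fraction,
    summarize,
)
from .conftest import brute_force_nearest


def scene_from_arrays(arrays, normals=None, boundary=None, resolved=None):
    """Build a Scene from {array_id: (n,3) centroids}."""
    rows = []
    for array_id, pts in arrays.items():
        pts = np.asarray(pts, float)
        for i, p in enumerate(pts):
            nrm = (
                normals[array_id][i]
                if normals
                else np.array([0.0, 0.0, 1.0])
            )
            nrm = np.asarray(nrm, float)
            nrm = nrm / np.linalg.norm(nrm)
            rows.append(
                dict(
                    sample_id="s",
                    tomogram_id="t",
                    array_id=array_id,
                    nuc_index=i + 1,
                    x_nm=p[0],
                    y_nm=p[1],
                    z_nm=p[2],
                    nx=nrm[0],
                    ny=nrm[1],
                    nz=nrm[2],
                    near_boundary=bool(boundary[array_id][i]) if boundary else False,
                    linker_to_next_resolved=(
                        bool(resolved[array_id][i]) if resolved else True
                    ),
                )
            )
    return Scene(poses=PoseTable(pd.DataFrame(rows)))


def test_pythagorean_distance():
    scene = scene_from_arrays({"a": [(0, 0, 0), (3, 4, 0)]})
    rec = compute_geometry(scene)
    assert rec.iloc[0]["D"] == pytest.approx(5.0)


def test_collinear_and_right_angle_alpha():
    collinear = scene_from_arrays({"a": [(0, 0, 0), (1, 0, 0), (2, 0, 0)]})
    rec = compute_geometry(collinear)
    assert rec.iloc[1]["alpha"] == pytest.approx(180.0)
    right = scene_from_arrays({"a": [(1, 0, 0), (0, 0, 0), (0, 1, 0)]})
    rec = compute_geometry(right)
    assert rec.iloc[1]["alpha"] == pytest.approx(90.0)


def test_beta_folding_convention():
    normals = {"a": [(0, 0, 1), (0, 0, -1)]}
    scene = scene_from_arrays({"a": [(0, 0, 0), (10, 0, 0)]}, normals=normals)
    rec = compute_geometry(scene)
    assert rec.iloc[0]["beta"] == pytest.approx(0.0)


def test_n_less_or_equal_d(large_scene):
    rec = compute_geometry(large_scene.scene)
    both = rec.dropna(subset=["D", "N"])
    assert (both["N"] <= both["D"] + 1e-9).all()


def test_angle_ranges(large_scene):
    rec = compute_geometry(large_scene.scene)
    assert rec["alpha"].dropna().between(0, 180).all()
    assert rec["beta"].dropna().between(0, 90).all()
    assert rec["para"].dropna().between(0, 90).all()


def test_normal_sign_invariance(small_scene):
    rec1 = compute_geometry(small_scene.scene)
    df = small_scene.scene.poses.df.copy()
    rng = np.random.default_rng(3)
    flip = rng.random(len(df)) < 0.5
    for col in ("nx", "ny", "nz"):
        df.loc[flip, col] = -df.loc[flip, col]
    rec2 = compute_geometry(Scene(poses=PoseTable(df)))
    np.testing.assert_allclose(
        rec1["beta"].to_numpy(), rec2["beta"].to_numpy(), atol=1e-9, equal_nan=True
    )
    np.testing.assert_allclose(
        rec1["para"].to_numpy(), rec2["para"].to_numpy(), atol=1e-9, equal_nan=True
    )


def test_nearest_neighbor_matches_brute_force(large_scene):
    scene = large_scene.scene
    dist, idx = nearest_neighbors(scene)
    bd, bi = brute_force_nearest(scene.poses.centroids())
    np.testing.assert_allclose(dist, bd)
    np.testing.assert_array_equal(idx, bi)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_nearest_neighbor_property_random_scenes(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 60))
    pts = rng.uniform(0, 60, size=(n, 3))
    scene = scene_from_arrays({"a": pts})
    dist, idx = nearest_neighbors(scene)
    bd, bi = brute_force_nearest(pts)
    np.testing.assert_allclose(dist, bd)
    np.testing.assert_array_equal(idx, bi)


class TestExclusions:
    def test_boundary_removed(self):
        boundary = {"a": [True, False, False]}
        scene = scene_from_arrays(
            {"a": [(0, 0, 0), (15, 0, 0), (30, 0, 0)]}, boundary=boundary
        )
        rec = compute_geometry(scene)
        out, audit = apply_exclusions(rec, scene)
        assert len(out) == 2
        assert audit.n_boundary_removed == 1

    def test_unresolved_drops_d_alpha_beta_keeps_n_para(self):
        resolved = {"a": [False, True, True]}
        scene = scene_from_arrays(
            {"a": [(0, 0, 0), (15, 0, 0), (30, 0, 0)]}, resolved=resolved
        )
        rec = compute_geometry(scene)
        out, _ = apply_exclusions(rec, scene)
        first = out.iloc[0]
        assert np.isnan(first["D"]) and np.isnan(first["beta"])
        assert np.isfinite(first["N"]) and np.isfinite(first["para"])
        # alpha of the downstream flank is dropped too
        assert np.isnan(out.iloc[1]["alpha"])

    def test_no_flags_identity(self):
        rng = np.random.default_rng(8)
        scene = scene_from_arrays(
            {f"a{k}": rng.uniform(0, 80, size=(6, 3)) for k in range(4)}
        )
        rec = compute_geometry(scene)
        out, audit = apply_exclusions(rec, scene)
        assert audit.n_boundary_removed == 0
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), rec.reset_index(drop=True)
        )

    def test_pn1_missing_rate_near_printed_value(self, large_scene):
        rec = compute_geometry(large_scene.scene)
        out, audit = apply_exclusions(rec, large_scene.scene)
        n_d_before = rec["D"].notna().sum()
        frac = audit.n_d_dropped_unresolved / n_d_before
        assert frac == pytest.approx(0.054, abs=0.03)


class TestStacking:
    def test_tight_pair_counted(self):
        normals = {"a": [(0, 0, 1), (np.sin(np.deg2rad(10)), 0, np.cos(np.deg2rad(10)))]}
        scene = scene_from_arrays({"a": [(0, 0, 0), (6.5, 0, 0)]}, normals=normals)
        rec = compute_geometry(scene)
        frac, pairs, _ = stacked_fraction(rec)
        assert frac == 1.0

    def test_wide_angle_not_counted(self):
        normals = {"a": [(0, 0, 1), (np.sin(np.deg2rad(40)), 0, np.cos(np.deg2rad(40)))]}
        scene = scene_from_arrays({"a": [(0, 0, 0), (6.5, 0, 0)]}, normals=normals)
        rec = compute_geometry(scene)
        frac, _, _ = stacked_fraction(rec)
        assert frac == 0.0

    def test_empty_records_fraction_absent(self):
        rec = pd.DataFrame(columns=["N", "para"])
        frac, _, _ = stacked_fraction(rec)
        assert frac is None


class TestSummarize:
    def test_identical_groups(self, small_scene):
        rec = compute_geometry(small_scene.scene)
        rec["sample_id"] = "A"
        rec2 = rec.copy()
        rec2["sample_id"] = "B"
        out = summarize(pd.concat([rec, rec2]))
        pair = out["tests"]["A vs B"]
        for d in pair.values():
            assert d["pct_change"] == pytest.approx(0.0, abs=1e-9)
            assert d["welch_p"] > 0.99

    def test_pn1_vs_pn56_mean_d_shift(self):
        from nucleofold.synth import sample_scene

        recs = []
        for name, seed in (("PN1", 11), ("PN56", 11)):
            build = sample_scene(name, 50, (10, 12), seed=seed)
            rec = compute_geometry(build.scene)
            rec, _ = apply_exclusions(rec, build.scene)
            rec["sample_id"] = name
            recs.append(rec)
        out = summarize(pd.concat(recs))
        d1 = out["groups"]["PN1"]["D"]["mean"]
        d56 = out["groups"]["PN56"]["D"]["mean"]
        se = np.hypot(
            out["groups"]["PN1"]["D"]["sd"] / np.sqrt(out["groups"]["PN1"]["D"]["n"]),
            out["groups"]["PN56"]["D"]["sd"] / np.sqrt(out["groups"]["PN56"]["D"]["n"]),
        )
        assert (d56 - d1) == pytest.approx(2.3, abs=3 * se + 0.3)
        # printed dispersion: SD = 5.9 nm
        assert out["groups"]["PN1"]["D"]["sd"] == pytest.approx(5.9, abs=0.6)

    def test_small_group_suppressed(self):
        rec = pd.DataFrame(
            dict(
                sample_id=["A"],
                D=[1.0], N=[1.0], alpha=[1.0], beta=[1.0], para=[1.0],
            )
        )
        out = summarize(rec)
        assert out["groups"]["A"]["D"].get("note") == "too few values"
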