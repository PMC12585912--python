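"""Alignment tensors, Q-factors, superposition RMSD and helix geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hmgdyn import synthetic
from hmgdyn.rdc import (
    backbone_rmsd,
    back_calc_rdc,
    ensemble_q,
    extract_nh_vectors,
    inter_helix_angle,
    q_factor,
    svd_fit_tensor,
)


def rotate_model(model, seed=0):
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    return replace(model, coords=model.coords @ rot.T + shift)


class TestNHVectors:
    def test_helical_nh_directions_form_canonical_cone(self, toy_structure,
                                                       toy_ranges, toy_nh_vectors):
        # within an ideal helix every NH vector makes the same canonical
        # angle with the (anti-parallel) helix axis; the cone half-angle
        # is ~12-18 deg and its spread stays below 1 deg
        from hmgdyn.rdc import helix_axis

        axis, _ = helix_axis(toy_structure, toy_ranges[0])
        seg = [r for r in toy_ranges[0] if r in toy_nh_vectors]
        vecs = np.array([toy_nh_vectors[r] for r in seg])
        angles = np.degrees(np.arccos(np.clip(vecs @ (-axis), -1, 1)))
        assert 8.0 < np.mean(angles) < 18.0
        assert np.max(np.abs(angles - np.mean(angles))) < 5.0

    def test_built_h_bond_length(self, toy_structure):
        from hmgdyn.rdc import _build_amide_h

        res = int(toy_structure.residues[1])
        h = _build_amide_h(toy_structure, res)
        n = toy_structure.atom(res, "N")
        assert np.linalg.norm(h - n) == pytest.approx(1.02, abs=1e-9)

    def test_no_h_and_no_building_yields_empty_set(self, toy_structure):
        assert extract_nh_vectors(toy_structure, build_h=False) == {}


class TestTensorFit:
    def test_noiseless_exact_recovery(self, toy_nh_vectors):
        tensor = synthetic.default_alignment_tensor()
        obs = back_calc_rdc(tensor, toy_nh_vectors)
        fit = svd_fit_tensor(toy_nh_vectors, obs)
        scale = np.abs(tensor.saupe).max()
        assert np.abs(fit.tensor.saupe - tensor.saupe).max() / scale < 1e-10
        assert fit.q < 1e-10

    def test_underdetermined_rejected(self, toy_nh_vectors):
        some = dict(list(toy_nh_vectors.items())[:4])
        obs = {r: 1.0 for r in some}
        with pytest.raises(ValueError, match="at least 5"):
            svd_fit_tensor(some, obs)

    def test_collinear_geometry_rejected(self):
        v = np.array([0.3, -0.5, 0.81])
        v /= np.linalg.norm(v)
        vecs = {i: v.copy() for i in range(1, 8)}
        with pytest.raises(ValueError, match="degenerate"):
            svd_fit_tensor(vecs, {i: 5.0 for i in vecs})

    def test_da_recovery_under_noise(self, toy_nh_vectors):
        tensor = synthetic.default_alignment_tensor()
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(50):
            obs = {r: v + rng.normal(0, 1.0)
                   for r, v in back_calc_rdc(tensor, toy_nh_vectors).items()}
            fit = svd_fit_tensor(toy_nh_vectors, obs)
            if abs(fit.tensor.da - tensor.da) / abs(tensor.da) < 0.05:
                hits += 1
        assert hits >= 45


class TestQFactor:
    def test_perfect_agreement(self):
        assert q_factor([5.0, -3.0], [5.0, -3.0]) == 0.0

    def test_zero_prediction(self):
        assert q_factor([5.0, -3.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert q_factor([10.0, -10.0], [9.0, -9.0]) == pytest.approx(0.1)

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            q_factor([0.0, 0.0], [1.0, 1.0])

    def test_rotation_invariance(self, toy_structure, toy_nh_vectors):
        tensor = synthetic.default_alignment_tensor()
        obs = synthetic.gen_rdc_data(toy_structure, tensor, noise_hz=1.0, seed=3)
        q0 = svd_fit_tensor(toy_nh_vectors, obs).q
        rotated = rotate_model(toy_structure, seed=4)
        q1 = svd_fit_tensor(extract_nh_vectors(rotated), obs).q
        assert q1 == pytest.approx(q0, rel=1e-8)


class TestEnsembleQ:
    def _observed(self, model):
        return synthetic.gen_rdc_data(model, noise_hz=1.0, seed=5)

    def test_identical_models_zero_sd(self, toy_structure):
        obs = self._observed(toy_structure)
        mean, sd, qs = ensemble_q([toy_structure] * 5, obs)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert len(qs) == 5

    def test_sd_grows_with_coordinate_noise(self, toy_structure):
        from dataclasses import replace

        obs = self._observed(toy_structure)
        rng = np.random.default_rng(6)

        def noisy(scale, n=8):
            return [replace(toy_structure,
                            coords=toy_structure.coords + rng.normal(0, scale,
                                                                     toy_structure.coords.shape))
                    for _ in range(n)]

        _, sd_small, _ = ensemble_q(noisy(0.02), obs)
        _, sd_large, _ = ensemble_q(noisy(0.2), obs)
        assert sd_large > sd_small

    def test_single_model_sd_undefined(self, toy_structure):
        obs = self._observed(toy_structure)
        mean, sd, _ = ensemble_q([toy_structure], obs)
        assert np.isnan(sd)
        assert mean > 0


class TestRmsd:
    def test_identical_structures(self, toy_structure):
        assert backbone_rmsd(toy_structure, toy_structure) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, toy_structure):
        moved = rotate_model(toy_structure, seed=1)
        assert backbone_rmsd(toy_structure, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, toy_structure):
        from dataclasses import replace

        rng = np.random.default_rng(2)
        other = replace(toy_structure,
                        coords=toy_structure.coords + rng.normal(0, 0.5,
                                                                 toy_structure.coords.shape))
        ab = backbone_rmsd(toy_structure, other)
        ba = backbone_rmsd(other, toy_structure)
        assert ab == pytest.approx(ba, rel=1e-9)

    def test_gaussian_noise_rmsd_magnitude(self, toy_structure):
        # sd 1.0 A per coordinate -> per-atom displacement rms sqrt(3);
        # superposition absorbs a little, so bracket by simulation
        from dataclasses import replace

        rng = np.random.default_rng(3)
        vals = []
        for _ in range(10):
            other = replace(toy_structure,
                            coords=toy_structure.coords + rng.normal(0, 1.0,
                                                                     toy_structure.coords.shape))
            vals.append(backbone_rmsd(toy_structure, other))
        assert np.sqrt(3) * 0.85 < np.mean(vals) < np.sqrt(3) * 1.05

    def test_too_few_atoms_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            backbone_rmsd(toy_structure, toy_structure, residues=[], atom_names=["N"])


class TestHelixGeometry:
    def test_constructed_angles_recovered(self, toy_structure, toy_ranges):
        assert inter_helix_angle(toy_structure, toy_ranges[0], toy_ranges[1]) == \
            pytest.approx(120.0, abs=2.0)
        assert inter_helix_angle(toy_structure, toy_ranges[0], toy_ranges[2]) == \
            pytest.approx(107.0, abs=2.0)

    def test_parallel_duplicate_near_zero(self, toy_structure, toy_ranges):
        angle = inter_helix_angle(toy_structure, toy_ranges[0], toy_ranges[0])
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_near_180(self):
        model = synthetic.gen_toy_structure(lengths=(12, 12), angles=(179.0,))
        ranges = synthetic.toy_segment_ranges((12, 12))
        angle = inter_helix_angle(model, ranges[0], ranges[1])
        assert angle == pytest.approx(179.0, abs=2.0)

    def test_single_helix_axis_defined(self, toy_structure, toy_ranges):
        from hmgdyn.rdc import helix_axis

        axis, resid = helix_axis(toy_structure, toy_ranges[0])
        assert np.linalg.norm(axis) == pytest.approx(1.0)
        # CA atoms of an alpha helix sit ~2.3 A from the axis
        assert 1.5 < resid < 3.0

    def test_too_short_range_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            inter_helix_angle(toy_structure, range(1, 5), range(15, 25))
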