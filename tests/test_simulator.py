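"""Phantom construction, session/study simulation and the TRE theory oracle."""

import numpy as np
import pandas as pd
import pytest

from splintnav.geometry import BL_IMAGE, DRF, LandmarkSet, PATIENT, apply, invert
from splintnav.simulator import (
    BONE_ANCHORED,
    DesignError,
    EM,
    FIDUCIAL_LABELS,
    NoiseModel,
    OPTICAL,
    REGISTRATION_FREE,
    SURFACE_BASED,
    StudyDesign,
    TARGET_LABELS,
    make_phantom,
    predict_tre_point_based,
    records_to_tre,
    simulate_lmm_dataset,
    simulate_session,
    simulate_study,
)

from conftest import random_rigid

ARMS = [
    (OPTICAL, BONE_ANCHORED),
    (OPTICAL, REGISTRATION_FREE),
    (EM, BONE_ANCHORED),
    (EM, SURFACE_BASED),
    (EM, REGISTRATION_FREE),
]


class TestPhantom:
    def test_deterministic_for_seed(self):
        a, b = make_phantom(11), make_phantom(11)
        np.testing.assert_array_equal(a.targets.coordinates, b.targets.coordinates)
        np.testing.assert_array_equal(a.fiducials.coordinates, b.fiducials.coordinates)
        np.testing.assert_array_equal(a.true_ct_pose.matrix, b.true_ct_pose.matrix)

    def test_counts_and_labels(self, phantom):
        assert len(phantom.fiducials) == 5
        assert len(phantom.targets) == 14
        assert set(phantom.targets.labels) == set(TARGET_LABELS)
        assert list(phantom.fiducials.labels) == FIDUCIAL_LABELS

    def test_fiducials_near_coplanar(self, phantom):
        centered = phantom.fiducials.coordinates - phantom.fiducials.coordinates.mean(0)
        sing = np.linalg.svd(centered, compute_uv=False)
        # smallest principal-axis SD <= 5 mm (limited craniocaudal variation)
        assert sing[2] / np.sqrt(5) <= 5.0
        # patch extent roughly 40 x 25 mm in its plane
        spans = np.ptp(phantom.fiducials.coordinates, axis=0)
        assert 30.0 < spans.max() < 55.0
        assert 8.0 < np.sort(spans)[1] < 35.0

    def test_target_distance_span_and_symmetry(self, phantom):
        cen = phantom.splint_centroid_patient
        d = {lab: np.linalg.norm(x - cen)
             for lab, x in zip(phantom.targets.labels, phantom.targets.coordinates)}
        assert min(d.values()) < 60.0
        assert max(d.values()) > 140.0
        coords = dict(zip(phantom.targets.labels, phantom.targets.coordinates))
        for left in [lab for lab in TARGET_LABELS if lab.endswith("_L")]:
            right = left[:-2] + "_R"
            np.testing.assert_allclose(
                coords[left] * np.array([-1, 1, 1]), coords[right], atol=1e-12
            )

    def test_overrides_and_unknown_key(self, phantom):
        moved = make_phantom(3, overrides={"fiducials": phantom.fiducials})
        np.testing.assert_array_equal(
            moved.fiducials.coordinates, phantom.fiducials.coordinates
        )
        with pytest.raises(TypeError, match="unknown"):
            make_phantom(3, overrides={"nope": 1})


class TestSession:
    @pytest.mark.parametrize("technique,method", ARMS)
    def test_zero_noise_identity(self, phantom, technique, method):
        records = simulate_session(phantom, technique, method, NoiseModel.zero(), 5)
        df = records_to_tre(records, phantom)
        assert df["tre_mm"].max() < 1e-9

    def test_seeded_reproducibility(self, phantom):
        a = simulate_session(phantom, EM, BONE_ANCHORED, NoiseModel(seed=1), 9)
        b = simulate_session(phantom, EM, BONE_ANCHORED, NoiseModel(seed=1), 9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.coords, rb.coords)

    def test_invalid_pairing_rejected(self, phantom):
        with pytest.raises(DesignError, match="not available"):
            simulate_session(phantom, OPTICAL, SURFACE_BASED, NoiseModel.zero(), 1)

    def test_regfree_tre_invariant_to_preregistration(self, phantom, rng):
        """Replacing the recorded prereg with any other rigid transform leaves
        the recalculated TRE unchanged."""
        noise = NoiseModel(seed=2)
        records = simulate_session(phantom, EM, REGISTRATION_FREE, noise, 7)
        base = records_to_tre(records, phantom)["tre_mm"].to_numpy()
        new_t_reg = random_rigid(rng, DRF, BL_IMAGE)
        for rec in records:
            p_drf = invert(rec.t_reg).transform_points(rec.coords)
            rec.coords = new_t_reg.transform_points(p_drf)[0]
            rec.t_reg = new_t_reg
        swapped = records_to_tre(records, phantom)["tre_mm"].to_numpy()
        np.testing.assert_allclose(swapped, base, atol=1e-9)


class TestStudy:
    def test_reference_bookkeeping(self):
        df = simulate_study(StudyDesign.reference(), 7, NoiseModel.zero())
        assert len(df) == 3496
        assert (df["method"] == REGISTRATION_FREE).sum() == 1396

    def test_no_missing_gives_full_factorial(self):
        df = simulate_study(StudyDesign(), 7, NoiseModel.zero())
        assert len(df) == 3500

    def test_arbitrary_design_counts(self):
        design = StudyDesign(
            n_observers=1, n_repetitions=2, n_cadavers=2, missing_records=[0, 30, 279]
        )
        df = simulate_study(design, 5, NoiseModel.zero())
        assert len(df) == 5 * 1 * 2 * 2 * 14 - 3

    def test_missing_indices_validated(self):
        with pytest.raises(DesignError, match="out of range"):
            StudyDesign(missing_records=[10_000])
        with pytest.raises(DesignError, match="unique"):
            StudyDesign(missing_records=[1, 1])

    def test_metadata_complete(self):
        design = StudyDesign(n_observers=1, n_repetitions=1, n_cadavers=1)
        df = simulate_study(design, 5, NoiseModel.zero())
        assert set(df.columns) >= {
            "cadaver", "technique", "method", "observer", "repetition",
            "target", "x", "y", "z", "frame", "tre_mm",
        }
        assert sorted(df["method"].unique()) == sorted(
            {m for _, m in StudyDesign().arms}
        )


class TestTreTheory:
    def test_zero_fle_gives_zero(self, phantom):
        t = phantom.targets.coordinates[0]
        assert predict_tre_point_based(phantom.fiducials, t, 0.0) == 0.0

    def test_minimum_at_fiducial_centroid(self, phantom):
        cen = phantom.fiducials.coordinates.mean(axis=0)
        fle = 0.5
        assert predict_tre_point_based(phantom.fiducials, cen, fle) == pytest.approx(
            fle / np.sqrt(5)
        )
        off = predict_tre_point_based(phantom.fiducials, cen + (40, 0, 30), fle)
        assert off > fle / np.sqrt(5)

    def test_collinear_rejected(self):
        from splintnav.registration import ConfigurationError

        line = LandmarkSet(
            ["a", "b", "c"], np.outer([0.0, 1.0, 2.0], (1.0, 0.0, 0.0)), PATIENT
        )
        with pytest.raises(ConfigurationError):
            predict_tre_point_based(line, (0, 0, 100), 0.3)

    def test_monte_carlo_matches_formula(self, phantom):
        """Session-level Monte Carlo RMS TRE tracks the first-order prediction."""
        sigma = 0.3
        noise = NoiseModel({OPTICAL: sigma, EM: sigma}, 0.0, 0.0, 0.0)
        fle_rms = sigma * np.sqrt(3)
        tre_sq = {lab: 0.0 for lab in TARGET_LABELS}
        n_rep = 400
        for rep in range(n_rep):
            records = simulate_session(
                phantom, EM, BONE_ANCHORED, noise, seed=rep, repetition=rep
            )
            df = records_to_tre(records, phantom)
            for lab, v in zip(df["target"], df["tre_mm"]):
                tre_sq[lab] += v**2
        label = "cranium"  # largest lever arm from the fiducial patch
        mc = np.sqrt(tre_sq[label] / n_rep)
        pred = predict_tre_point_based(
            phantom.fiducials,
            phantom.targets.subset([label]).coordinates[0],
            fle_rms,
        )
        assert mc == pytest.approx(pred, rel=0.08)


class TestLmmDataset:
    def test_counts_follow_design(self):
        design = StudyDesign.reference()
        lines = {arm: (1.0, 0.004) for arm in design.arms}
        dists = {lab: float(d) for lab, d in zip(TARGET_LABELS, np.linspace(-10, 110, 14))}
        df = simulate_lmm_dataset(design, lines, dists, seed=0)
        assert len(df) == 3496

    def test_deterministic(self):
        design = StudyDesign(n_observers=1, n_repetitions=1, n_cadavers=2)
        lines = {arm: (1.0, 0.004) for arm in design.arms}
        dists = {lab: float(d) for lab, d in zip(TARGET_LABELS, np.linspace(-10, 110, 14))}
        a = simulate_lmm_dataset(design, lines, dists, seed=3)
        b = simulate_lmm_dataset(design, lines, dists, seed=3)
        pd.testing.assert_frame_equal(a, b)
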