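"""Sorting chain: statistics, outlier rejection, angles, classes, merging."""

import numpy as np
import pytest

from helixcdi.models import Grid2D
from helixcdi.simulate import DetectorGeometry, DiffractionImage, ShotConfig, ShotSimulator
from helixcdi.sorting import (
    brute_force_equatorial_angle,
    class_average,
    classify_block,
    contrast_score,
    estimate_equatorial_angle,
    reject_outliers,
    rotate_about_beam_center,
    select_align_merge,
    shot_statistics,
)


@pytest.fixture(scope="module")
def labelled_shots(detector, grid):
    """40 filament shots, 40 background-only shots and 20 jet-edge
    artefact shots with generator labels."""
    fil = ShotSimulator(
        ShotConfig(random_seed=31, protofilament_mixture={13: 0.5, 14: 0.5},
                   n_axial_rotations=4),
        detector, grid,
    )
    bg = ShotSimulator(
        ShotConfig(n_filaments_mean=0.0, background_level=0.5, random_seed=32),
        detector,
    )
    edge = ShotSimulator(
        ShotConfig(n_filaments_mean=0.0, background_level=0.5,
                   edge_streak_fraction=1.0, random_seed=33),
        detector,
    )
    shots = (
        [fil.shot(i) for i in range(40)]
        + [bg.shot(i) for i in range(40)]
        + [edge.shot(i) for i in range(20)]
    )
    labels = ["filament"] * 40 + ["background"] * 40 + ["edge"] * 20
    return shots, labels


class TestShotStatistics:
    def test_all_zero_image_has_zero_total(self, small_detector):
        img = DiffractionImage(
            np.zeros(small_detector.shape), small_detector,
            small_detector.valid_mask(),
        )
        assert shot_statistics(img, use_central_panels=False).total_intensity == 0

    def test_fully_masked_image_raises(self, small_detector):
        img = DiffractionImage(
            np.ones(small_detector.shape), small_detector,
            np.zeros(small_detector.shape, dtype=bool),
        )
        with pytest.raises(ValueError):
            shot_statistics(img, use_central_panels=False)

    def test_invariant_under_quarter_turn(self, detector, grid):
        sim = ShotSimulator(
            ShotConfig(random_seed=41, protofilament_mixture={13: 1.0},
                       n_axial_rotations=2),
            detector, grid,
        )
        shot = sim.shot(0)
        rot = DiffractionImage(
            np.rot90(shot.intensity).copy(), shot.geometry,
            np.rot90(shot.mask).copy(), shot.metadata,
        )
        s0 = shot_statistics(shot, use_central_panels=False)
        s1 = shot_statistics(rot, use_central_panels=False)
        assert s0.total_intensity == pytest.approx(s1.total_intensity)
        assert s0.anisotropy_score == pytest.approx(s1.anisotropy_score, rel=1e-9)
        assert s0.edge_streak_score == pytest.approx(s1.edge_streak_score, rel=1e-9)

    def test_edge_streak_score_separates_artefacts(self, labelled_shots):
        """Jet-edge shots score above the 99th percentile of clean shots."""
        shots, labels = labelled_shots
        scores = [shot_statistics(s).edge_streak_score for s in shots]
        clean = [s for s, l in zip(scores, labels) if l != "edge"]
        cut = np.percentile(clean, 99)
        edge = [s for s, l in zip(scores, labels) if l == "edge"]
        assert np.mean(np.array(edge) > cut) >= 0.9


class TestRejectOutliers:
    def test_keeps_exactly_the_requested_fraction(self, labelled_shots):
        shots, _ = labelled_shots
        stats = [shot_statistics(s) for s in shots]
        assert len(reject_outliers(stats, 0.40)) == 40

    def test_keep_all_is_identity(self, labelled_shots):
        shots, _ = labelled_shots
        stats = [shot_statistics(s) for s in shots[:10]]
        np.testing.assert_array_equal(reject_outliers(stats, 1.0), np.arange(10))

    def test_kept_shots_are_mostly_true_filament_shots(self, labelled_shots):
        shots, labels = labelled_shots
        stats = [shot_statistics(s) for s in shots]
        kept = reject_outliers(stats, 0.40)
        frac = np.mean([labels[i] == "filament" for i in kept])
        assert frac >= 0.90

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            reject_outliers([], 0.4)


class TestEquatorialAngle:
    def test_single_filament_recovers_jet_angle(self, single_filament_sim):
        for i in range(5):
            shot = single_filament_sim.shot(i)
            if shot.metadata["n_filaments"] == 1:
                break
        est = estimate_equatorial_angle(shot)
        assert abs(est.angle - 30.0) <= 1.0
        assert not est.low_confidence

    def test_agrees_with_fine_brute_force_scan(self, single_filament_sim):
        shots = [single_filament_sim.shot(i) for i in range(6)]
        shots = [s for s in shots if s.metadata["n_filaments"] >= 1][:3]
        for shot in shots:
            est = estimate_equatorial_angle(shot)
            oracle = brute_force_equatorial_angle(shot, step=0.1)
            diff = abs((est.angle - oracle + 90) % 180 - 90)
            assert diff <= 0.5

    def test_equivariant_under_quarter_turn(self, single_filament_sim):
        for i in range(8):
            shot = single_filament_sim.shot(i)
            if shot.metadata["n_filaments"] >= 1:
                break
        rot = DiffractionImage(
            np.rot90(shot.intensity, k=-1).copy(), shot.geometry,
            np.rot90(shot.mask, k=-1).copy(), shot.metadata,
        )
        a0 = estimate_equatorial_angle(shot).angle
        a1 = estimate_equatorial_angle(rot).angle
        assert abs((a1 - a0 - 90) % 180) <= 1.0 or abs((a1 - a0 - 90) % 180 - 180) <= 1.0

    def test_isotropic_background_is_low_confidence(self, small_detector):
        rng = np.random.default_rng(0)
        img = DiffractionImage(
            rng.poisson(2.0, small_detector.shape).astype(float),
            small_detector, small_detector.valid_mask(),
        )
        assert estimate_equatorial_angle(img).low_confidence

    def test_estimated_angles_follow_jet_distribution(self, detector, grid):
        """Generator self-consistency: per-shot estimated equatorial angles
        match the configured jet-angle distribution within Monte-Carlo and
        per-shot estimation error."""
        cfg = ShotConfig(jet_angle_mean=20.0, jet_angle_sigma=8.0,
                         random_seed=51, protofilament_mixture={13: 1.0},
                         n_axial_rotations=4)
        sim = ShotSimulator(cfg, detector, grid)
        est = []
        for i in range(150):
            shot = sim.shot(i)
            if shot.metadata["kind"] == "filament":
                est.append(estimate_equatorial_angle(shot).angle)
        est = np.array(est)
        centred = (est - 20.0 + 90) % 180 - 90
        assert abs(np.mean(centred)) < 1.5
        # per-shot mode noise (~3 deg) adds in quadrature to the 8 deg jet
        assert 6.0 < np.std(centred) < 11.0


class TestClassification:
    def test_two_well_separated_modes_are_recovered(self):
        rng = np.random.default_rng(7)
        angles = np.concatenate([
            rng.normal(30.0, 2.0, 500) % 180,
            rng.normal(120.0, 2.0, 500) % 180,
        ])
        truth = np.repeat([0, 1], 500)
        order = rng.permutation(1000)
        labels = classify_block(angles[order], block_size=1000, k=2, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth[order], labels) >= 0.9

    def test_identical_angles_fall_in_one_class(self):
        labels = classify_block(np.full(50, 42.0), block_size=50, k=5, seed=0)
        assert len(np.unique(labels)) == 1

    def test_block_bookkeeping(self):
        """ceil(n / block) blocks x k classes, mirroring the 186-from-38588
        accounting."""
        rng = np.random.default_rng(3)
        n = 2300
        angles = rng.uniform(0, 180, n)
        labels = classify_block(angles, block_size=1000, k=5, seed=0)
        assert len(np.unique(labels)) == int(np.ceil(n / 1000)) * 5

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        angles = rng.uniform(0, 180, 400)
        l1 = classify_block(angles, 200, 5, seed=4)
        l2 = classify_block(angles, 200, 5, seed=4)
        np.testing.assert_array_equal(l1, l2)


class TestClassAverage:
    def test_single_member_is_itself(self, single_filament_sim):
        shot = single_filament_sim.shot(0)
        avg = class_average([shot], [30.0])
        np.testing.assert_array_equal(
            avg.image.intensity, np.where(shot.mask, shot.intensity, 0.0)
        )
        assert avg.n_members == 1

    def test_n_copies_sum_to_n_times_image(self, single_filament_sim):
        shot = single_filament_sim.shot(0)
        avg = class_average([shot] * 5, [30.0] * 5)
        np.testing.assert_allclose(
            avg.image.intensity, 5 * np.where(shot.mask, shot.intensity, 0.0)
        )

    def test_averaging_raises_layer_line_snr_as_sqrt_n(self, detector, grid):
        """Summing n independent shots of one class raises the 4 nm
        layer-line peak SNR by ~sqrt(n) (Poisson scaling)."""
        from helixcdi.simulate import radius_of_q

        cfg = ShotConfig(random_seed=61, jet_angle_sigma=0.0,
                         alignment_sigma=2.0,
                         protofilament_mixture={13: 1.0}, n_axial_rotations=4)
        sim = ShotSimulator(cfg, detector, grid)
        n = 64
        shots = [sim.shot(i) for i in range(n)]

        def layer_snr(intensity, mask):
            r = radius_of_q(detector, 0.25)
            row = int(round(detector.beam_center[0] - r))
            band = intensity[row - 1 : row + 2]
            bmask = mask[row - 1 : row + 2]
            peak = band[bmask].max()
            far = intensity[row - 20 : row - 10]
            fmask = mask[row - 20 : row - 10]
            noise = far[fmask].std() + 1e-12
            return peak / noise

        single = np.median([layer_snr(s.intensity, s.mask) for s in shots[:8]])
        avg = class_average(shots, [0.0] * n)
        summed = layer_snr(avg.image.intensity, avg.image.mask)
        ratio = summed / single
        assert np.sqrt(n) / 3 < ratio < 3 * np.sqrt(n)


def test_merged_layer_line_snr_grows_with_shot_count(pipeline_run):
    """Layer-line SNR of the merged pattern is non-decreasing in the number
    of input shots (100 / 500 / 2000 of the same fixed-seed stack).  The
    noise scale is estimated by split-half comparison: two merges built
    from disjoint halves of the shots differ only by stochastic noise."""
    from helixcdi.io import read_shot_stack
    from helixcdi.simulate import radius_of_q

    stack = pipeline_run["workdir"] / "shots.h5"

    def layer_snr(n):
        # one classification for all n shots, then member-wise split halves
        # built with identical angles and class assignments: the two merges
        # differ only by per-shot stochastic noise
        indices = np.arange(n)
        stats = [
            shot_statistics(img) for img in read_shot_stack(stack, indices)
        ]
        kept = indices[reject_outliers(stats, 0.4)]
        angles = np.array([
            estimate_equatorial_angle(img).angle
            for img in read_shot_stack(stack, kept)
        ])
        labels = classify_block(angles, block_size=1000, k=5, seed=0)
        halves = [[], []]
        for lab in np.unique(labels):
            sel = labels == lab
            members = list(read_shot_stack(stack, kept[sel]))
            if len(members) < 2:
                continue
            class_angle = class_average(members, angles[sel]).equatorial_angle
            for h, chunk in enumerate((members[::2], members[1::2])):
                avg = class_average(chunk, [class_angle] * len(chunk))
                avg.contrast = 1.0  # keep all classes in both merges
                halves[h].append(avg)
        m1 = select_align_merge(halves[0], 1.0)
        m2 = select_align_merge(halves[1], 1.0)
        g = m1.geometry
        r = radius_of_q(g, 0.25)
        row = int(round(g.beam_center[0] - r))
        common = m1.mask & m2.mask
        band = np.zeros_like(common)
        band[row - 1 : row + 2] = True
        bsel = band & common
        signal = 0.5 * (m1.intensity + m2.intensity)[bsel].max()
        noise = 0.5 * np.sqrt(
            np.mean((m1.intensity - m2.intensity)[bsel] ** 2)
        )
        return signal / (noise + 1e-12)

    snrs = [layer_snr(n) for n in (100, 500, 2000)]
    assert snrs[0] < snrs[1] < snrs[2]


class TestContrastAndMerge:
    def test_flat_layer_line_scores_about_two(self, small_detector):
        img = DiffractionImage(
            np.ones(small_detector.shape), small_detector,
            np.ones(small_detector.shape, dtype=bool),
        )
        avg = class_average([img], [0.0])
        assert contrast_score(avg) == pytest.approx(2.0, abs=0.1)

    def test_score_invariant_to_intensity_scaling(self, single_filament_sim):
        shot = single_filament_sim.shot(0)
        a1 = class_average([shot], [shot.metadata["jet_angle"]])
        scaled = DiffractionImage(shot.intensity * 7.5, shot.geometry,
                                  shot.mask, shot.metadata)
        a2 = class_average([scaled], [shot.metadata["jet_angle"]])
        assert contrast_score(a1) == pytest.approx(contrast_score(a2), rel=1e-9)

    def test_filament_classes_outscore_background(self, labelled_shots):
        shots, labels = labelled_shots
        fil = [s for s, l in zip(shots, labels) if l == "filament"][:20]
        bg = [s for s, l in zip(shots, labels) if l == "background"][:20]
        fil_avg = class_average(fil, [s.metadata["jet_angle"] for s in fil])
        bg_avg = class_average(bg, [0.0] * len(bg))
        assert contrast_score(fil_avg) > contrast_score(bg_avg)

    def test_single_class_merge_is_that_class(self, single_filament_sim):
        shot = single_filament_sim.shot(0)
        avg = class_average([shot], [0.0])  # angle 0: no rotation applied
        avg.contrast = 10.0
        merged = select_align_merge([avg], 1.0)
        good = merged.mask & shot.mask
        np.testing.assert_allclose(
            merged.intensity[good], shot.intensity[good], rtol=1e-6
        )

    def test_rotation_merge_matches_reverse_rotation_oracle(
        self, single_filament_sim
    ):
        """Merging one class at angle 40 equals rotating its image by -40
        (interpolation error < 1% RMS)."""
        shot = single_filament_sim.shot(1)
        angle = 40.0
        avg = class_average([shot], [angle])
        avg.contrast = 1.0
        merged = select_align_merge([avg], 1.0)
        oracle = rotate_about_beam_center(
            np.where(shot.mask, shot.intensity, 0.0), -angle, shot.geometry
        )
        sel = merged.mask
        rms = np.sqrt(np.mean((merged.intensity[sel] - oracle[sel]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(oracle[sel] ** 2)) + 1e-9

    def test_two_perpendicular_classes_share_a_horizontal_equator(
        self, detector, grid
    ):
        """Classes at 0 and 90 deg merge onto a common horizontal equator
        and their panel gaps fill in."""
        cfg = ShotConfig(random_seed=71, jet_angle_sigma=0.0,
                         alignment_sigma=1.0,
                         protofilament_mixture={13: 1.0}, n_axial_rotations=4)
        sim0 = ShotSimulator(cfg, detector, grid)
        cfg90 = ShotConfig(random_seed=72, jet_angle_mean=90.0,
                           jet_angle_sigma=0.0, alignment_sigma=1.0,
                           protofilament_mixture={13: 1.0},
                           n_axial_rotations=4)
        sim90 = ShotSimulator(cfg90, detector, grid)
        a0 = class_average([sim0.shot(i) for i in range(10)], [0.0] * 10)
        a90 = class_average([sim90.shot(i) for i in range(10)], [90.0] * 10)
        merged = select_align_merge([a0, a90], 1.0)
        r0, c0 = detector.beam_center
        eq_band = merged.intensity[int(r0) - 1 : int(r0) + 2, :]
        off_band = merged.intensity[int(r0) - 30 : int(r0) - 27, :]
        assert eq_band.mean() > 5 * off_band.mean()
        # gap filling: fewer masked pixels than a single class average
        assert merged.mask.sum() > a0.image.mask.sum()
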