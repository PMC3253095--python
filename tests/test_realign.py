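import numpy as np
import pytest

from tests.conftest import series_from_volumes
from trialprep import geometry, qc_select, realign
from trialprep.core_io import AffineParams, TransformSet, Trial, TrialTable
from trialprep.synthetic import SimConfig, make_phantom, simulate_session

VOX = np.array([2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def still_session():
    """Session with no motion/artefacts but realistic noise."""
    cfg = SimConfig.small(seed=21).replace(
        shift_amplitude_mm=0.0, gap_shift_mm=0.0, ghost_fraction=0.0,
        affine_max_translation_mm=0.0, affine_max_rotation_rad=0.0,
        affine_max_scale_dev=0.0, affine_max_shear=0.0)
    series, trials, _, truth = simulate_session(cfg)
    concat, index = qc_select.concatenate(series, trials)
    return concat, trials, index


class TestEstimateShift1d:
    def test_self_registration_is_zero(self, phantom):
        s = realign.estimate_shift_1d(phantom[0], phantom[0], 1, VOX)
        assert abs(s) < 0.02 * VOX[1]

    @pytest.mark.parametrize("shift_vox,tol_vox", [(0.75, 0.1), (3.0, 0.05),
                                                   (-1.3, 0.1)])
    def test_known_shift_recovered(self, phantom, shift_vox, tol_vox):
        moving = geometry.shift_volume(phantom[0], shift_vox, 1, order=3)
        est = realign.estimate_shift_1d(moving, phantom[0], 1, VOX)
        assert est / VOX[1] == pytest.approx(shift_vox, abs=tol_vox)

    def test_flat_image_rejected(self):
        flat = np.zeros((16, 16, 8))
        with pytest.raises(ValueError, match="flat"):
            realign.estimate_shift_1d(flat, flat, 1, VOX)


class TestWithinTrialRealign:
    def test_static_session_gives_near_zero_shifts(self, still_session):
        concat, trials, index = still_session
        shifts = realign.within_trial_realign(concat, trials, index)
        assert np.abs(shifts / VOX[1]).max() < 0.05

    def test_first_volume_of_each_trial_exactly_zero(self, corrupted_session):
        _, (series, trials, _, _) = corrupted_session
        concat, index = qc_select.concatenate(series, trials)
        shifts = realign.within_trial_realign(concat, trials, index)
        for positions in realign.trial_positions(trials, index).values():
            assert shifts[positions[0]] == 0.0

    def test_sinusoidal_shift_recovered(self):
        cfg = SimConfig.small(seed=23).replace(
            shift_amplitude_mm=0.5, gap_shift_mm=0.0, ghost_fraction=0.0,
            affine_max_translation_mm=0.0, affine_max_rotation_rad=0.0,
            affine_max_scale_dev=0.0, affine_max_shear=0.0)
        series, trials, _, truth = simulate_session(cfg)
        concat, index = qc_select.concatenate(series, trials)
        shifts = realign.within_trial_realign(concat, trials, index)
        kept = [series.run_slice(r).start + i for r, i in index.kept]
        injected = truth.injected_shift1d[kept]
        r = np.corrcoef(shifts, injected)[0, 1]
        assert r > 0.95

    def test_single_volume_trial_shift_is_zero(self, phantom):
        series = series_from_volumes([phantom[0]], voxel_size=VOX)
        trials = TrialTable([Trial(0, 0, 0, 0)])
        shifts = realign.within_trial_realign(series, trials)
        assert shifts.tolist() == [0.0]


class TestTrialMean:
    def test_identical_volumes_zero_shift(self, phantom):
        series = series_from_volumes([phantom[0]] * 3, voxel_size=VOX)
        mean = realign.trial_mean(series, [0, 1, 2], np.zeros(3))
        np.testing.assert_allclose(mean, phantom[0], atol=1e-12)

    def test_opposite_shifts_cancel(self, phantom):
        img = phantom[0]
        plus = geometry.shift_volume(img, 1.0, 1, order=3)
        minus = geometry.shift_volume(img, -1.0, 1, order=3)
        series = series_from_volumes([plus, minus], voxel_size=VOX)
        mean = realign.trial_mean(series, [0, 1],
                                  np.array([1.0 * VOX[1], -1.0 * VOX[1]]))
        interior = tuple(slice(3, -3) for _ in range(2)) + (slice(1, -1),)
        err = np.abs(mean - img)[interior].max()
        assert err < 0.02 * img.max()

    def test_order_invariant(self, phantom):
        rng = np.random.default_rng(0)
        vols = [phantom[0] + rng.standard_normal(phantom[0].shape)
                for _ in range(3)]
        series = series_from_volumes(vols, voxel_size=VOX)
        m1 = realign.trial_mean(series, [0, 1, 2], np.zeros(3))
        m2 = realign.trial_mean(series, [2, 0, 1], np.zeros(3))
        np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_empty_trial_errors(self, phantom):
        series = series_from_volumes([phantom[0]], voxel_size=VOX)
        with pytest.raises(ValueError, match="empty"):
            realign.trial_mean(series, [], np.zeros(1))


class TestEstimateAffine:
    def test_self_registration_is_identity(self, phantom):
        fit = realign.estimate_affine(phantom[0], phantom[0], VOX)
        p = fit.params
        assert np.abs(p.translation / VOX).max() < 0.05
        assert np.abs(p.scale - 1).max() < 0.005
        assert np.abs(p.rotation).max() < 0.005
        assert np.abs(p.shear).max() < 0.005

    def test_known_affine_recovered(self, phantom):
        inj = AffineParams(np.array([1.0, -0.8, 0.4]),
                           np.array([0.0, 0.0, 0.02]),
                           np.array([1.0, 1.01, 1.0]), np.zeros(3))
        moving = geometry.resample(phantom[0], inj.matrix(), VOX, order=3)
        fit = realign.estimate_affine(moving, phantom[0], VOX)
        resid = AffineParams.from_matrix(fit.params.matrix() @ inj.matrix())
        # in-plane parameters: tight; thin z stack is checked loosely
        assert np.abs(resid.translation[:2] / VOX[:2]).max() < 0.1
        assert np.abs(resid.rotation).max() < 0.005
        assert np.abs(resid.scale[:2] - 1).max() < 0.005
        assert np.abs(resid.translation[2] / VOX[2]) < 0.2

    def test_pure_translation_agrees_with_1dof(self, phantom):
        moving = geometry.shift_volume(phantom[0], 0.9, 1, order=3)
        fit = realign.estimate_affine(moving, phantom[0], VOX)
        s1d = realign.estimate_shift_1d(moving, phantom[0], 1, VOX)
        # the aligning map samples the moving image back at +shift
        assert fit.params.translation[1] == pytest.approx(s1d, abs=0.1 * VOX[1])


class TestComposeAndReslice:
    def test_identity_transforms_return_input(self, still_session):
        concat, trials, index = still_session
        tf = TransformSet(np.zeros(concat.n_volumes),
                          {t.trial_id: AffineParams.identity() for t in trials})
        out = realign.compose_and_reslice(concat, tf, trials, index)
        err = np.abs(out.data - concat.data).max()
        assert err < 1e-6 * concat.data.max()

    def test_missing_affine_errors(self, still_session):
        concat, trials, index = still_session
        tf = TransformSet(np.zeros(concat.n_volumes), {})
        with pytest.raises(ValueError, match="affine"):
            realign.compose_and_reslice(concat, tf, trials, index)

    def test_cost_not_increased_by_realignment(self):
        """Each realigned trial mean is at least as close to the reference
        mean as the unaligned one (in the registration's own cost)."""
        cfg = SimConfig.small(seed=29).replace(gap_shift_mm=0.0,
                                               ghost_fraction=0.0)
        series, trials, _, _ = simulate_session(cfg)
        concat, index = qc_select.concatenate(series, trials)
        tf = realign.two_step_realign(concat, trials, index)
        realigned = realign.compose_and_reslice(concat, tf, trials, index)
        positions = realign.trial_positions(trials, index)
        ordered = sorted(positions)
        ref_before = realign.trial_mean(concat, positions[ordered[0]], tf.shift1d)
        interior = tuple(slice(4, -4) for _ in range(2)) + (slice(1, -1),)
        worse = 0
        for tid in ordered[1:]:
            before = concat.data[..., positions[tid]].mean(axis=-1)
            after = realigned.data[..., positions[tid]].mean(axis=-1)
            c_before = np.mean((before - ref_before)[interior] ** 2)
            c_after = np.mean((after - ref_before)[interior] ** 2)
            if c_after > c_before:
                worse += 1
        assert worse == 0

    def test_single_reslice_beats_two_pass(self):
        """Composing shift+affine into one interpolation leaves a smaller
        residual against the clean series than two sequential reslices."""
        cfg = SimConfig.small(seed=31).replace(
            noise_sd=0.0, ghost_fraction=0.0, gap_shift_mm=0.0)
        series, trials, _, truth = simulate_session(cfg)
        concat, index = qc_select.concatenate(series, trials)
        tf = realign.two_step_realign(concat, trials, index)
        one = realign.compose_and_reslice(concat, tf, trials, index)
        # two-pass: shift-reslice then affine-reslice
        axis = concat.phase_axis
        shifted = np.empty_like(concat.data)
        for p in range(concat.n_volumes):
            post = np.zeros(3)
            post[axis] = tf.shift1d[p] / concat.voxel_size[axis]
            shifted[..., p] = geometry.resample(
                concat.data[..., p], np.eye(4), concat.voxel_size,
                post_translation_vox=post)
        two = np.empty_like(concat.data)
        for tid, pos in realign.trial_positions(trials, index).items():
            M = tf.affines[tid].matrix()
            for p in pos:
                two[..., p] = geometry.resample(shifted[..., p], M,
                                                concat.voxel_size)
        kept = [series.run_slice(r).start + i for r, i in index.kept]
        clean = truth.clean_series.subset(np.asarray(kept))
        brain = truth.brain_mask
        err_one = np.abs(one.data - clean.data)[brain].mean()
        err_two = np.abs(two - clean.data)[brain].mean()
        assert err_one < err_two


class TestRigidBaseline:
    def test_rigid_recovers_translation_and_rotation(self, phantom):
        inj = AffineParams(np.array([1.2, -0.6, 0.0]),
                           np.array([0.0, 0.0, 0.015]),
                           np.ones(3), np.zeros(3))
        moving = geometry.resample(phantom[0], inj.matrix(), VOX, order=3)
        fit = realign.estimate_rigid(moving, phantom[0], VOX)
        resid = AffineParams.from_matrix(fit.params.matrix() @ inj.matrix())
        assert np.abs(resid.translation[:2] / VOX[:2]).max() < 0.1
        assert np.abs(resid.rotation).max() < 0.005

    def test_reslice_rigid_identity(self, phantom):
        series = series_from_volumes([phantom[0]] * 2, voxel_size=VOX)
        out = realign.reslice_rigid(series, [AffineParams.identity()] * 2)
        np.testing.assert_array_equal(out.data, series.data)
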