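import numpy as np
import pytest

from svca.kinetic_classes import (
    CLASS_ORDER,
    ClassBuildConfig,
    ClassTAC,
    KineticClassSet,
    aggregate_classes,
    build_blood_mask,
    build_class_sets,
    build_class_sets_loo,
    extract_class_tac,
    prepare_tissue_mask,
    validate_blood_shape,
)
from svca.normalization import normalize_frames
from svca.petio import DynamicImage, FrameSchedule, MaskImage
from svca.synthdata import PhantomSpec, generate_cohort, generate_phantom


def _sched(n=5):
    return FrameSchedule(np.arange(n) * 10.0, np.arange(1, n + 1) * 10.0)


class TestPrepareTissueMask:
    def test_uniform_cube_erode_once(self):
        # 5^3 cube of prob 1.0 inside a 7^3 grid; one 6-connected erosion
        # leaves the 3^3 interior = 27 voxels (hand-enumerated oracle)
        vol = np.zeros((7, 7, 7))
        vol[1:6, 1:6, 1:6] = 1.0
        out = prepare_tissue_mask(MaskImage(vol, np.eye(4), kind="probability"), 0.9, 1)
        assert out.voxels.sum() == 27
        assert out.voxels[2:5, 2:5, 2:5].all()

    def test_all_below_threshold_errors(self):
        vol = np.full((4, 4, 4), 0.5)
        with pytest.raises(ValueError, match="empty"):
            prepare_tissue_mask(MaskImage(vol, np.eye(4), kind="probability"), 0.9, 0)

    def test_erode_zero_is_threshold_only(self, rng):
        vol = rng.random((6, 6, 6))
        out = prepare_tissue_mask(MaskImage(vol, np.eye(4), kind="probability"), 0.5, 0)
        np.testing.assert_array_equal(out.voxels, (vol > 0.5).astype(float))

    def test_strict_threshold(self):
        vol = np.full((3, 3, 3), 0.9)
        vol[0, 0, 0] = 0.95
        out = prepare_tissue_mask(MaskImage(vol, np.eye(4), kind="probability"), 0.9, 0)
        assert out.voxels.sum() == 1  # 0.9 itself is excluded


class TestBuildBloodMask:
    def test_phantom_vessel_recovered(self):
        pet, truth, masks = generate_phantom(PhantomSpec(noise_level=0.0, seed=3))
        blood = build_blood_mask(pet, 180.0, 50, masks["brain"])
        assert blood.voxels.sum() == 50
        assert truth.region("blood")[blood.as_bool].all()

    def test_n_top_equals_mask_size(self, small_dynamic):
        img, mask = small_dynamic
        out = build_blood_mask(img, 60.0, int(mask.voxels.sum()), mask)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_tie_break_by_linear_index(self):
        sched = _sched(3)
        vox = np.zeros((2, 2, 2, 3))
        vox[..., 0] = 1.0  # every voxel ties
        img = DynamicImage(vox, sched, np.eye(4))
        search = MaskImage(np.ones((2, 2, 2)), np.eye(4))
        out = build_blood_mask(img, 60.0, 3, search)
        np.testing.assert_array_equal(np.flatnonzero(out.voxels.ravel()), [0, 1, 2])

    def test_window_before_first_midpoint_errors(self, small_dynamic):
        img, mask = small_dynamic
        with pytest.raises(ValueError, match="early window"):
            build_blood_mask(img, 1.0, 5, mask)


class TestExtractClassTac:
    def _norm(self, rng):
        sched = _sched(4)
        img = DynamicImage(rng.random((6, 6, 6, 4)) + 0.5, sched, np.eye(4))
        brain = MaskImage(np.ones((6, 6, 6)), np.eye(4))
        return normalize_frames(img, brain)

    def test_single_voxel_identity(self, rng):
        norm = self._norm(rng)
        m = np.zeros((6, 6, 6))
        m[2, 3, 4] = 1.0
        tac = extract_class_tac(norm, MaskImage(m, np.eye(4)), "wm")
        np.testing.assert_array_equal(tac.values, norm.voxels[2, 3, 4, :])

    def test_symmetric_pair_cancels(self):
        sched = _sched(3)
        t = np.array([1.0, 2.0, 3.0])
        vox = np.zeros((2, 1, 1, 3))
        vox[0, 0, 0] = t
        vox[1, 0, 0] = -t
        norm_like = normalize_frames(
            DynamicImage(vox, sched, np.eye(4)),
            MaskImage(np.ones((2, 1, 1)), np.eye(4)),
        )
        tac = extract_class_tac(norm_like, MaskImage(np.ones((2, 1, 1)), np.eye(4)), "lbgm")
        np.testing.assert_allclose(tac.values, 0.0, atol=1e-12)

    def test_matches_brute_force_mean(self, rng):
        norm = self._norm(rng)
        sel = np.zeros((6, 6, 6), dtype=bool)
        idx = rng.choice(216, size=10, replace=False)
        sel.ravel()[idx] = True
        tac = extract_class_tac(norm, MaskImage(sel.astype(float), np.eye(4)), "lbgm")
        brute = np.stack([norm.voxels[i, j, k] for i, j, k in np.argwhere(sel)]).mean(axis=0)
        np.testing.assert_allclose(tac.values, brute, atol=1e-12)

    def test_empty_mask_errors(self, rng):
        norm = self._norm(rng)
        with pytest.raises(ValueError, match="empty"):
            extract_class_tac(norm, MaskImage(np.zeros((6, 6, 6)), np.eye(4)), "wm")


class TestValidateBloodShape:
    def test_gamma_variate_passes(self, schedule):
        t = schedule.mid
        tac = (t / 45.0) * np.exp(1 - t / 45.0)  # peaks at frame 1 of 20
        res = validate_blood_shape(tac, schedule)
        assert res["passed"]
        assert res["peak_index"] <= 2

    def test_monotone_increasing_fails(self, schedule):
        res = validate_blood_shape(np.linspace(0, 1, schedule.n_frames), schedule)
        assert not res["passed"]

    def test_flat_fails(self, schedule):
        res = validate_blood_shape(np.ones(schedule.n_frames), schedule)
        assert not res["passed"]


class TestAggregateClasses:
    def _tacs(self, sid, offset=0.0, n=5):
        rng = np.random.default_rng(hash(sid) % 2**32)
        return [
            ClassTAC(c, rng.random(n) + offset, sid) for c in CLASS_ORDER
        ]

    def test_single_subject_identity(self):
        sched = _sched(5)
        tacs = self._tacs("s1")
        cs = aggregate_classes(tacs, "mean", schedule=sched)
        for j, c in enumerate(CLASS_ORDER):
            np.testing.assert_array_equal(cs.K[:, j], tacs[j].values)

    def test_mean_of_shifted_pair(self):
        sched = _sched(5)
        base = self._tacs("s1")
        shifted = [ClassTAC(t.class_name, t.values + 2.0, "s2") for t in base]
        cs = aggregate_classes(base + shifted, "mean", schedule=sched)
        for j, t in enumerate(base):
            np.testing.assert_allclose(cs.K[:, j], t.values + 1.0, atol=1e-12)

    def test_median_matches_sort_oracle(self):
        sched = _sched(5)
        tacs = []
        curves = {}
        for i in range(11):
            subj = self._tacs(f"s{i}", offset=100.0 if i == 0 else 0.0)
            tacs.extend(subj)
            for t in subj:
                curves.setdefault(t.class_name, []).append(t.values)
        cs = aggregate_classes(tacs, "median", schedule=sched)
        for j, c in enumerate(CLASS_ORDER):
            stack = np.stack(curves[c])
            # independent sort-based median oracle
            srt = np.sort(stack, axis=0)
            oracle = srt[5]  # middle of 11
            np.testing.assert_allclose(cs.K[:, j], oracle, atol=1e-12)

    def test_mean_linearity(self):
        sched = _sched(5)
        a = self._tacs("s1") + self._tacs("s2")
        b = [ClassTAC(t.class_name, t.values * 0.5 + 1, t.subject_id) for t in a]
        ab = [ClassTAC(t.class_name, t.values + u.values, t.subject_id)
              for t, u in zip(a, b)]
        Ka = aggregate_classes(a, "mean", schedule=sched).K
        Kb = aggregate_classes(b, "mean", schedule=sched).K
        Kab = aggregate_classes(ab, "mean", schedule=sched).K
        np.testing.assert_allclose(Kab, Ka + Kb, atol=1e-12)

    def test_missing_class_errors(self):
        sched = _sched(5)
        tacs = [t for t in self._tacs("s1") if t.class_name != "blood"]
        with pytest.raises(ValueError, match="missing class"):
            aggregate_classes(tacs, "mean", schedule=sched)

    def test_schedule_mismatch_errors(self):
        with pytest.raises(ValueError, match="schedule mismatch"):
            aggregate_classes(self._tacs("s1", n=4), "mean", schedule=_sched(5))


class TestSerialization:
    def test_roundtrip_bit_exact(self, tmp_path, rng):
        sched = _sched(6)
        cs = KineticClassSet(
            K=rng.standard_normal((6, 4)),
            class_names=list(CLASS_ORDER),
            schedule=sched,
            genotype="HAB",
            aggregation="median",
            norm_mask_hash="abc123",
            training_subjects=["s1", "s2"],
        )
        cs.save(tmp_path / "c.json")
        back = KineticClassSet.load(tmp_path / "c.json")
        np.testing.assert_array_equal(back.K, cs.K)
        assert back.schedule == cs.schedule
        assert back.genotype == "HAB"
        assert back.aggregation == "median"
        assert back.norm_mask_hash == "abc123"
        assert back.training_subjects == ["s1", "s2"]
        assert back.lbgm_index == cs.lbgm_index


class TestCohortPipeline:
    def test_build_on_phantom_cohort(self):
        spec = PhantomSpec(noise_level=0.0, seed=5)
        cohort, truths = generate_cohort(12, spec, inter_subject_jitter=0.0)
        sets = build_class_sets(cohort, ClassBuildConfig())
        cs = sets["ALL"]
        assert cs.K.shape == (20, 4)
        assert cs.class_names == list(CLASS_ORDER)
        assert len(cs.training_subjects) == 12

    def test_class_curves_correlate_with_own_template(self):
        spec = PhantomSpec(noise_level=0.05, seed=5)
        cohort, truths = generate_cohort(12, spec, inter_subject_jitter=0.03)
        cs = build_class_sets(cohort, ClassBuildConfig())["ALL"]
        # independent normalized-space reference curves: z-normalize a fresh
        # noiseless phantom and average over the TRUE label regions (no mask
        # preparation pipeline involved)
        pet, truth, masks = generate_phantom(PhantomSpec(noise_level=0.0, seed=5))
        norm = normalize_frames(pet, masks["brain"])
        ref_curves = {
            cls: norm.voxels[truth.region(cls)].mean(axis=0) for cls in CLASS_ORDER
        }
        for j, cls in enumerate(CLASS_ORDER):
            corrs = {
                other: np.corrcoef(cs.K[:, j], ref_curves[other])[0, 1]
                for other in CLASS_ORDER
            }
            assert max(corrs, key=corrs.get) == cls, (cls, corrs)

    def test_genotype_strata_disjoint(self):
        spec = PhantomSpec(noise_level=0.0, seed=6, shape=(16, 16, 16))
        genos = ["HAB"] * 7 + ["MAB"] * 7
        cohort, _ = generate_cohort(14, spec, inter_subject_jitter=0.0, genotypes=genos)
        with pytest.warns(UserWarning, match="only 7 subjects"):
            sets = build_class_sets(cohort, ClassBuildConfig(), strata=("HAB", "MAB"))
        hab, mab = sets["HAB"], sets["MAB"]
        assert set(hab.training_subjects).isdisjoint(mab.training_subjects)
        assert len(hab.training_subjects) == 7

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_class_sets([], ClassBuildConfig())

    def test_loo_excludes_held_out(self):
        spec = PhantomSpec(noise_level=0.0, seed=7, shape=(16, 16, 16))
        cohort, _ = generate_cohort(12, spec, inter_subject_jitter=0.0)
        cs = build_class_sets_loo(cohort, ClassBuildConfig(), held_out="s07")
        assert len(cs.training_subjects) == 11
        assert "s07" not in cs.training_subjects

    def test_loo_unknown_id_errors(self):
        spec = PhantomSpec(noise_level=0.0, seed=7, shape=(16, 16, 16))
        cohort, _ = generate_cohort(3, spec, inter_subject_jitter=0.0)
        with pytest.raises(ValueError, match="not in cohort"):
            build_class_sets_loo(cohort, ClassBuildConfig(), held_out="nope")

    def test_loo_equals_manual_subset(self):
        spec = PhantomSpec(noise_level=0.02, seed=8, shape=(16, 16, 16))
        cohort, _ = generate_cohort(6, spec, inter_subject_jitter=0.02)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = build_class_sets_loo(cohort, ClassBuildConfig(), held_out="s03")
            manual = build_class_sets(
                [s for s in cohort if s.subject_id != "s03"], ClassBuildConfig()
            )["ALL"]
        np.testing.assert_array_equal(loo.K, manual.K)
        assert loo.training_subjects == manual.training_subjects
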