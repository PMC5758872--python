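"""Projection, ROI segmentation, ratio measurement and group statistics."""

import numpy as np
import pytest

from dlekit.reporter_quant import (
    EmbryoStack,
    EmptyROIError,
    best_focus_window,
    compare_groups,
    measure,
    project,
    segment_roi,
)
from dlekit.seqio import ValidationError
from dlekit.synthetic_data import (
    ImageConfig,
    SimConfig,
    gen_embryo_cohort,
    gen_measurement_cohort,
)


def make_stack(planes):
    return np.stack([np.asarray(p, dtype=float) for p in planes])


class TestProjection:
    def test_single_slice_identity(self):
        plane = np.arange(16.0).reshape(4, 4)
        out = project(make_stack([plane]), window=1)
        assert np.array_equal(out, plane)

    def test_dominant_slice_sets_projection(self):
        dim = np.ones((4, 4))
        bright = np.full((4, 4), 50.0)
        stack = make_stack([dim, dim, bright, dim, dim, dim])
        a, b = best_focus_window(stack, window=2)
        assert a <= 2 < b
        assert np.array_equal(project(stack, window=2), bright)

    def test_planted_focus_block_recovered(self):
        cfg = SimConfig(
            seed=23,
            image=ImageConfig(
                noise_cv=0.0, n_per_cell=1, stages=("1K",),
                ratio_per_group={"g": 0.5}, n_controls=1,
            ),
        )
        stacks, truth = gen_embryo_cohort(cfg)
        embryo = next(s for s in stacks if not s.is_control)
        row = truth[truth["embryo_id"] == embryo.embryo_id].iloc[0]
        assert best_focus_window(embryo.rfp, 4) == (
            row["focus_start"], row["focus_end"]
        )

    def test_empty_stack_rejected(self):
        with pytest.raises(ValidationError):
            best_focus_window(np.zeros((0, 4, 4)), 1)

    def test_window_larger_than_stack_rejected(self):
        with pytest.raises(ValidationError):
            project(np.zeros((2, 4, 4)), window=4)


class TestSegmentation:
    def test_uniform_plane_is_empty_roi(self):
        with pytest.raises(EmptyROIError):
            segment_roi(np.zeros((16, 16)))

    def test_bright_disc_recovered_within_tolerance(self):
        yy, xx = np.ogrid[:64, :64]
        disc = (yy - 30) ** 2 + (xx - 34) ** 2 <= 12**2
        plane = 100.0 + 3000.0 * disc
        mask = segment_roi(plane)
        assert abs(mask.sum() - disc.sum()) / disc.sum() < 0.02

    def test_largest_component_wins(self):
        plane = np.zeros((32, 32))
        plane[2:6, 2:6] = 100.0      # 16 px
        plane[10:20, 10:20] = 100.0  # 100 px
        mask = segment_roi(plane, threshold=50.0)
        assert mask.sum() == 100
        assert mask[15, 15] and not mask[3, 3]


class TestMeasure:
    def _cohort(self, noise_cv=0.0, ratio=0.5, n=2):
        cfg = SimConfig(
            seed=23,
            image=ImageConfig(
                noise_cv=noise_cv, n_per_cell=n, stages=("1K",),
                ratio_per_group={"g": ratio}, n_controls=2,
            ),
        )
        return gen_embryo_cohort(cfg)

    def test_background_subtracted_ratio_arithmetic(self):
        from dlekit.reporter_quant import EmbryoMeasurement

        m = EmbryoMeasurement(
            embryo_id="e", group="g", stage="s", roi_area=10,
            mean_gfp=150.0, mean_rfp=300.0, bg_gfp=50.0, bg_rfp=100.0,
        )
        assert m.ratio == pytest.approx(0.5)
        assert not m.flagged

    def test_zero_denominator_flagged(self):
        from dlekit.reporter_quant import EmbryoMeasurement

        m = EmbryoMeasurement(
            embryo_id="e", group="g", stage="s", roi_area=10,
            mean_gfp=100.0, mean_rfp=100.0, bg_gfp=100.0, bg_rfp=100.0,
        )
        assert m.flagged and np.isnan(m.ratio)

    def test_noiseless_cohort_recovers_planted_ratio_and_area(self):
        stacks, truth = self._cohort(noise_cv=0.0, ratio=0.5)
        controls = [s for s in stacks if s.is_control]
        for s in stacks:
            if s.is_control:
                continue
            m = measure(s, controls)
            row = truth[truth["embryo_id"] == s.embryo_id].iloc[0]
            assert m.ratio == pytest.approx(row["true_ratio"], rel=0.02)
            assert m.roi_area == pytest.approx(row["roi_area"], rel=0.02)

    def test_zero_ratio_construct_measures_zero(self):
        stacks, _ = self._cohort(noise_cv=0.0, ratio=0.0)
        controls = [s for s in stacks if s.is_control]
        embryo = next(s for s in stacks if not s.is_control)
        m = measure(embryo, controls)
        assert m.ratio == pytest.approx(0.0, abs=1e-9)

    def test_ratio_invariant_under_common_gain(self):
        stacks, _ = self._cohort(noise_cv=0.0)
        controls = [s for s in stacks if s.is_control]
        embryo = next(s for s in stacks if not s.is_control)
        m1 = measure(embryo, controls)
        scaled = EmbryoStack(
            embryo_id=embryo.embryo_id, group=embryo.group, stage=embryo.stage,
            gfp=embryo.gfp * 3.7, rfp=embryo.rfp * 3.7,
        )
        scaled_controls = [
            EmbryoStack(
                embryo_id=c.embryo_id, group=c.group, stage=c.stage,
                gfp=c.gfp * 3.7, rfp=c.rfp * 3.7, is_control=True,
            )
            for c in controls
        ]
        m2 = measure(scaled, scaled_controls)
        assert m1.ratio == pytest.approx(m2.ratio, abs=1e-9)

    def test_requires_controls(self):
        stacks, _ = self._cohort()
        embryo = next(s for s in stacks if not s.is_control)
        with pytest.raises(ValidationError):
            measure(embryo, [])

    def test_pipeline_deterministic(self):
        stacks, _ = self._cohort(noise_cv=0.2)
        controls = [s for s in stacks if s.is_control]
        embryo = next(s for s in stacks if not s.is_control)
        m1 = measure(embryo, controls)
        m2 = measure(embryo, controls)
        assert (m1.ratio, m1.roi_area) == (m2.ratio, m2.roi_area)


class TestCompareGroups:
    def test_detects_planted_group_difference(self):
        ms = gen_measurement_cohort(
            seed=29, group_means={"control": 1.0, "Mybx1": 1.5}, n_per_cell=34
        )
        out = compare_groups(ms)
        assert out["anova"].loc["group", "PR(>F)"] < 0.05
        assert out["contrasts"]["significant"].all()

    def test_null_difference_usually_not_significant(self):
        ms = gen_measurement_cohort(
            seed=29, group_means={"a": 1.0, "b": 1.0}, n_per_cell=34
        )
        out = compare_groups(ms)
        assert out["anova"].loc["group", "PR(>F)"] > 0.001  # sanity, not strict

    def test_single_embryo_cell_rejected(self):
        ms = gen_measurement_cohort(
            seed=1, group_means={"a": 1.0, "b": 1.0}, n_per_cell=2
        )
        dropped = [m for m in ms if m.embryo_id != ms[0].embryo_id]
        with pytest.raises(ValidationError, match="cell"):
            compare_groups(dropped)

    def test_one_group_rejected(self):
        ms = gen_measurement_cohort(seed=1, group_means={"a": 1.0}, n_per_cell=3)
        with pytest.raises(ValidationError):
            compare_groups(ms)

    def test_bonferroni_adjustment_multiplies_raw_p(self):
        ms = gen_measurement_cohort(
            seed=29, group_means={"a": 1.0, "b": 1.2}, n_per_cell=10
        )
        out = compare_groups(ms)
        c = out["contrasts"]
        n_tests = len(c)
        for _, row in c.iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, row["p_raw"] * n_tests)
            )
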