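"""Tests for segmentation, intensity measurement and aggregation."""

import numpy as np
import pytest

from conftest import match_records_to_truth
from mpskit.errors import InputError
from mpskit.fixtures import StackSpec, gen_fov_stacks, gen_zstack
from mpskit.imaging import (
    FocusSelection,
    MicrotissueRecord,
    ScaffoldSummary,
    ZStack,
    compare_conditions,
    measure_intensity,
    segment_microtissues,
    select_focus,
    summarize,
)


class TestSegmentMicrotissues:
    def test_blank_image_zero_records(self):
        labels, records = segment_microtissues(np.zeros((64, 64)))
        assert records == []
        assert labels.max() == 0

    def test_noise_free_count_matches_truth(self, fov_stack, stack_spec):
        stack, truth = fov_stack
        focus = select_focus(stack)
        _, records = segment_microtissues(stack.channel("nuclei")[focus.plane_idx])
        assert len(records) == len(truth.microtissues)

    def test_counts_stay_in_configured_range(self):
        spec = StackSpec(seed=21)
        for stack, truth in gen_fov_stacks(spec, 6, count_range=(8, 12)):
            focus = select_focus(stack)
            _, records = segment_microtissues(stack.channel("nuclei")[focus.plane_idx])
            assert 8 <= len(records) <= 12
            assert len(records) == len(truth.microtissues)

    def test_labels_row_major(self, fov_stack):
        stack, _ = fov_stack
        focus = select_focus(stack)
        _, records = segment_microtissues(stack.channel("nuclei")[focus.plane_idx])
        rows = [r.centroid[0] for r in records]
        assert rows == sorted(rows)


class TestMeasureIntensity:
    def test_truth_recovery_within_one_percent(self, fov_stack):
        stack, truth = fov_stack
        focus = select_focus(stack)
        labels, records = segment_microtissues(stack.channel("nuclei")[focus.plane_idx])
        records = measure_intensity(labels, stack, focus, records)
        for rec, tr in match_records_to_truth(records, truth.microtissues):
            for ch in ("asma", "collagen1"):
                assert rec.total_intensity[ch] == pytest.approx(tr.intensity[ch], rel=0.01)

    def test_uniform_image_measures_zero(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[:32, :] = 1
        stack = ZStack(
            pixels={"asma": np.full((1, 64, 64), 40.0)},
            z_step_um=5.0,
            channel_names=("asma",),
        )
        rec = MicrotissueRecord(fov_id="f", label=1, area_px=32 * 64, centroid=(16.0, 32.0))
        (out,) = measure_intensity(
            labels, stack, FocusSelection(0, np.zeros(1)), [rec], channels=("asma",)
        )
        assert out.total_intensity["asma"] == pytest.approx(0.0, abs=1e-6)

    def test_three_to_one_ratio(self):
        # segmentation runs on nuclei (equal objects); measurement on asma (3:1)
        from mpskit.fixtures.render import add_tapered_disk

        nuclei = np.full((128, 128), 10.0, dtype=np.float32)
        asma = np.full((128, 128), 10.0, dtype=np.float32)
        for centre, asma_amp in (((40.0, 40.0), 3000.0), ((90.0, 90.0), 1000.0)):
            add_tapered_disk(nuclei, centre, 10.0, 2000.0)
            add_tapered_disk(asma, centre, 10.0, asma_amp)
        stack = ZStack(
            pixels={"asma": asma[None], "nuclei": nuclei[None]},
            z_step_um=5.0,
            channel_names=("nuclei", "asma"),
        )
        focus = FocusSelection(0, np.zeros(1))
        labels, records = segment_microtissues(nuclei)
        assert len(records) == 2
        records = measure_intensity(labels, stack, focus, records, channels=("asma",))
        vals = sorted(r.total_intensity["asma"] for r in records)
        assert vals[1] / vals[0] == pytest.approx(3.0, rel=0.05)

    def test_missing_channel_rejected(self, fov_stack):
        stack, _ = fov_stack
        focus = select_focus(stack)
        labels, records = segment_microtissues(stack.channel("nuclei")[focus.plane_idx])
        with pytest.raises(InputError, match="nope"):
            measure_intensity(labels, stack, focus, records, channels=("nope",))

    def test_stack_mode_runs(self, fov_stack):
        stack, _ = fov_stack
        focus = select_focus(stack)
        labels, records = segment_microtissues(stack.channel("nuclei")[focus.plane_idx])
        records = measure_intensity(labels, stack, focus, records, mode="stack")
        assert all(r.total_intensity["asma"] >= 0 for r in records)


def _rec(fov, label, asma):
    return MicrotissueRecord(
        fov_id=fov, label=label, area_px=200, centroid=(0.0, 0.0),
        total_intensity={"asma": asma},
    )


class TestSummarize:
    def test_single_record_passthrough(self):
        fovs, scaffolds = summarize(
            [_rec("f1", 1, 5.0)], {"f1": "s1"}, {"s1": "control"}
        )
        assert fovs[0].mean_intensity["asma"] == 5.0
        assert scaffolds[0].mean_intensity["asma"] == 5.0
        assert scaffolds[0].n_microtissues == 1

    def test_unweighted_mean_of_fov_means(self):
        # FOV means 2 and 4 with unequal counts -> scaffold mean 3
        records = [_rec("f1", 1, 2.0), _rec("f2", 1, 3.0), _rec("f2", 2, 5.0)]
        _, scaffolds = summarize(records, {"f1": "s1", "f2": "s1"}, {"s1": "control"})
        assert scaffolds[0].mean_intensity["asma"] == pytest.approx(3.0)
        assert scaffolds[0].n_microtissues == 3

    def test_empty_fov_excluded(self):
        _, scaffolds = summarize(
            [_rec("f1", 1, 2.0)], {"f1": "s1", "f_empty": "s1"}, {"s1": "control"}
        )
        assert scaffolds[0].n_fovs == 1

    def test_unmapped_record_rejected(self):
        with pytest.raises(InputError, match="f9"):
            summarize([_rec("f9", 1, 1.0)], {"f1": "s1"}, {"s1": "c"})


def _summary(sid, cond, asma):
    return ScaffoldSummary(
        scaffold_id=sid, condition=cond, mean_intensity={"asma": asma},
        n_fovs=2, n_microtissues=20,
    )


class TestCompareConditions:
    def test_identical_conditions_fold_one(self):
        summaries = [_summary("s1", "control", 4.0), _summary("s2", "treated", 4.0)]
        (cmp_row,) = compare_conditions(summaries, "control")
        assert cmp_row.fold_change == pytest.approx(1.0)

    def test_half_gives_fifty_percent_change(self):
        summaries = [_summary("s1", "control", 4.0), _summary("s2", "treated", 2.0)]
        (cmp_row,) = compare_conditions(summaries, "control")
        assert cmp_row.percent_change == pytest.approx(50.0)

    def test_zero_reference_flagged_not_numeric(self):
        summaries = [_summary("s1", "control", 0.0), _summary("s2", "treated", 2.0)]
        (cmp_row,) = compare_conditions(summaries, "control")
        assert cmp_row.undefined_fold
        assert cmp_row.fold_change is None

    def test_missing_reference_rejected(self):
        with pytest.raises(InputError, match="reference"):
            compare_conditions([_summary("s1", "treated", 1.0)], "control")


class TestFoldRecoveryEndToEnd:
    @pytest.mark.parametrize("fold", [1.0, 2.0, 6.0, 8.0])
    def test_fold_recovered_within_ten_percent(self, fold):
        def condition_mean(folds, seed):
            spec = StackSpec(seed=seed, condition_fold=folds, noise_cv=0.02)
            vals = []
            for stack, _ in gen_fov_stacks(spec, 4):
                focus = select_focus(stack)
                labels, records = segment_microtissues(
                    stack.channel("nuclei")[focus.plane_idx]
                )
                records = measure_intensity(labels, stack, focus, records)
                vals.append(np.mean([r.total_intensity["collagen1"] for r in records]))
            return float(np.mean(vals))

        ref = condition_mean({}, seed=100)
        cond = condition_mean({"collagen1": fold}, seed=200)
        assert cond / ref == pytest.approx(fold, rel=0.1)

    def test_translation_leaves_intensities_unchanged(self):
        # shifting the FOV scene equals shifting object coordinates; intensities invariant
        spec = StackSpec(seed=31)
        stack, truth = gen_zstack(spec)
        focus = select_focus(stack)
        shifted = ZStack(
            pixels={c: np.roll(stack.pixels[c], (7, -5), axis=(1, 2))
                    for c in stack.channel_names},
            z_step_um=stack.z_step_um,
            channel_names=stack.channel_names,
        )
        for s, expect_shift in ((stack, (0.0, 0.0)), (shifted, (7.0, -5.0))):
            labels, records = segment_microtissues(s.channel("nuclei")[focus.plane_idx])
            records = measure_intensity(labels, s, focus, records)
            if expect_shift == (0.0, 0.0):
                base = {
                    (round(r.centroid[0]), round(r.centroid[1])): r.total_intensity["asma"]
                    for r in records
                }
            else:
                for r in records:
                    key = (
                        round(r.centroid[0] - expect_shift[0]),
                        round(r.centroid[1] - expect_shift[1]),
                    )
                    assert base[key] == pytest.approx(r.total_intensity["asma"], rel=1e-6)
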