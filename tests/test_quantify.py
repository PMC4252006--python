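"""Segmentation, positivity, region measurement and study-level summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihc_catscore.categorization import CategoryThresholds
from ihc_catscore.errors import ValidationError
from ihc_catscore.quantify import (
    categorize_nuclei,
    measure_regions,
    normalize_to_baseline,
    nucleus_positivity,
    percent_cv,
    percent_positive,
    region_mean_intensity,
    segment_nuclei,
    weighted_score,
)

HER2 = CategoryThresholds(t0=230, t1=85, t2=180)


class TestSegmentation:
    def test_blank_image_yields_no_labels(self):
        assert segment_nuclei(np.full((64, 64), 255, dtype=np.uint8)).max() == 0

    def test_recovers_synthetic_nuclei(self, noiseless_field, noiseless_stains):
        _, _, truth = noiseless_field
        labels = segment_nuclei(noiseless_stains["hematoxylin"], min_area=20)
        assert labels.max() == truth.n_cells
        # each segmented nucleus overlaps exactly one ground-truth cell well
        ious = []
        for lab in range(1, min(labels.max(), 50) + 1):
            seg = labels == lab
            gt_ids, counts = np.unique(truth.label_mask[seg], return_counts=True)
            gt = gt_ids[np.argmax(counts)]
            assert gt > 0
            gt_mask = truth.label_mask == gt
            ious.append((seg & gt_mask).sum() / (seg | gt_mask).sum())
        assert min(ious) > 0.7

    def test_min_area_filters_everything(self, noiseless_stains):
        labels = segment_nuclei(noiseless_stains["hematoxylin"], min_area=10**6)
        assert labels.max() == 0


class TestPositivity:
    def test_background_only_image(self):
        dab = np.full((32, 32), 255, dtype=np.uint8)
        labels = np.zeros((32, 32), dtype=int)
        labels[2:6, 2:6] = 1
        rec = nucleus_positivity(dab, labels, t0=230)
        assert not rec["positive"].any()

    def test_boundary_mean_exactly_t0_is_positive(self):
        dab = np.full((8, 8), 230.0)
        labels = np.ones((8, 8), dtype=int)
        rec = nucleus_positivity(dab, labels, t0=230)
        assert rec["positive"].all()

    def test_synthetic_percent_positive_recovered(self, noiseless_field, noiseless_stains):
        _, _, truth = noiseless_field
        labels = segment_nuclei(noiseless_stains["hematoxylin"], min_area=20)
        rec = nucleus_positivity(noiseless_stains["dab"], labels, t0=truth.thresholds.t0)
        measured = percent_positive(rec)
        assert measured == pytest.approx(truth.percent_positive, abs=2.0)


class TestPercentPositive:
    def test_single_field(self):
        rec = pd.DataFrame({"positive": [True] * 35 + [False] * 65})
        assert percent_positive(rec) == pytest.approx(35.0)

    def test_two_field_summary(self):
        rec = pd.DataFrame(
            {
                "field": [1] * 10 + [2] * 10,
                "positive": [True] * 3 + [False] * 7 + [True] * 4 + [False] * 6,
            }
        )
        s = percent_positive(rec, by="field")
        assert s.mean == pytest.approx(35.0)
        assert s.sd == pytest.approx(np.std([30, 40], ddof=1))

    def test_all_positive(self):
        rec = pd.DataFrame({"field": [1, 1, 2, 2], "positive": [True] * 4})
        s = percent_positive(rec, by="field")
        assert (s.mean, s.sd) == (100.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            percent_positive(pd.DataFrame({"positive": []}))


class TestRegionIntensity:
    def test_uniform_region_both_modes(self):
        dab = np.full((10, 10), 100.0)
        mask = np.ones((10, 10), dtype=bool)
        for mode in ("positive-pixels", "all-pixels"):
            assert region_mean_intensity(dab, mask, 230, mode=mode).mean == 100.0

    def test_mixed_region_modes_differ(self):
        dab = np.full((10, 10), 100.0)
        dab[5:] = 250.0
        mask = np.ones((10, 10), dtype=bool)
        assert region_mean_intensity(dab, mask, 230).mean == 100.0
        assert region_mean_intensity(dab, mask, 230, mode="all-pixels").mean == 175.0

    def test_no_positive_pixels_flagged(self):
        dab = np.full((4, 4), 250.0)
        res = region_mean_intensity(dab, np.ones((4, 4), bool), 230)
        assert res.undefined and np.isnan(res.mean)

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            region_mean_intensity(np.zeros((4, 4)), np.zeros((4, 4), bool), 230)


class TestWeightedScore:
    @pytest.mark.parametrize(
        "fractions,expected",
        [((0, 0, 1), 3.0), ((0, 0, 0), 0.0), ((1 / 3, 1 / 3, 1 / 3), 2.0), ((1, 0, 0), 1.0)],
    )
    def test_examples(self, fractions, expected):
        assert weighted_score(fractions) == pytest.approx(expected)

    def test_oversum_rejected(self):
        with pytest.raises(ValidationError):
            weighted_score((0.5, 0.5, 0.5))

    @given(
        f=st.lists(st.floats(0, 1), min_size=3, max_size=3).filter(lambda f: sum(f) <= 1),
        shift=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bounds_and_monotonicity(self, f, shift):
        s = weighted_score(f)
        assert 0.0 <= s <= 3.0
        # moving mass from weak to strong never decreases the score
        moved = min(f[0], shift)
        s2 = weighted_score((f[0] - moved, f[1], f[2] + moved))
        assert s2 >= s - 1e-12


class TestRegionMeasurement:
    def test_end_to_end_counts_match_ground_truth(self, noiseless_field, noiseless_stains):
        _, _, truth = noiseless_field
        labels = segment_nuclei(noiseless_stains["hematoxylin"], min_area=20)
        table = measure_regions(noiseless_stains["dab"], labels, truth.thresholds)
        assert len(table) == 1
        row = table.iloc[0]
        gt_counts = truth.cells["category"].value_counts()
        # counting conservation
        assert (
            row.n_negative + row.n_weak + row.n_moderate + row.n_strong == row.n_cells
        )
        assert row.n_cells == truth.n_cells
        for cat in ("negative", "weak", "moderate", "strong"):
            assert row[f"n_{cat}"] == pytest.approx(gt_counts.get(cat, 0), abs=3)
        assert 0.0 <= row.score <= 3.0

    def test_nucleus_categories_match_assignments(self, noiseless_field, noiseless_stains):
        _, _, truth = noiseless_field
        rec = categorize_nuclei(
            noiseless_stains["dab"], truth.label_mask, truth.thresholds
        )
        merged = rec.merge(truth.cells, on="label", suffixes=("_measured", "_true"))
        agreement = (merged["category_measured"] == merged["category_true"]).mean()
        assert agreement > 0.97  # boundary cells may flip by +-1 grey level


class TestNormalization:
    def _table(self, values_by_time, case=1):
        rows = []
        for t, vals in values_by_time.items():
            for i, v in enumerate(vals, 1):
                rows.append({"case": case, "marker": "ER", "time_h": t, "field": i, "value": v})
        return pd.DataFrame(rows)

    def test_constant_values_give_100_percent(self):
        t = self._table({0: [80, 80], 1: [80, 80]})
        norm = normalize_to_baseline(t)
        assert (norm["value_pct"] == 100.0).all()

    def test_arithmetic_example(self):
        t = self._table({0: [80], 1: [68]})
        norm = normalize_to_baseline(t).set_index("time_h")["value_pct"]
        assert norm[0] == 100.0
        assert norm[1] == pytest.approx(85.0)

    def test_missing_baseline_names_case(self):
        t = self._table({1: [68]})
        with pytest.raises(ValidationError, match="case 1"):
            normalize_to_baseline(t)

    def test_zero_baseline_rejected(self):
        t = self._table({0: [0.0], 1: [68]})
        with pytest.raises(ValidationError, match="zero baseline"):
            normalize_to_baseline(t)


class TestPercentCV:
    def test_identical_fields(self):
        assert percent_cv([5.0, 5.0, 5.0]) == 0.0

    def test_arithmetic_example(self):
        assert percent_cv([90.0, 110.0]) == pytest.approx(14.1421, abs=1e-3)

    def test_generator_cv_in_reported_band(self):
        from ihc_catscore import generate_timecourse

        t = generate_timecourse(field_cv=0.05, seed=0)
        cvs = t.groupby(["case", "time_h"])["value"].apply(lambda v: percent_cv(v.to_numpy()))
        assert 0.2 <= cvs.median() <= 11.0

    def test_zero_mean_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(percent_cv([1.0, -1.0]))
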