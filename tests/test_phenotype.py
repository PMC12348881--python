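"""Intensity normalization, percentile thresholds, classes, co-localization."""

import numpy as np
import pandas as pd
import pytest

from nichequant.phenotype import (
    CaspaseRule,
    MarkerThresholds,
    classify_cells,
    count_colocalized,
    extract_mask_intensities,
    normalize_intensities,
    pool_and_threshold,
    quantify_apoptosis,
    regions_adjacent,
)
from nichequant.simdata import SimParams, generate_coculture_stack
from nichequant.stack import ImageStack3D

MARKERS = ["CD19", "CD3", "CASP3"]


def _table(values, marker="CD19", stack_id="s0"):
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(values) + 1),
            "stack_id": stack_id,
            "voxel_count": 10,
            f"mean_{marker}": values,
        }
    )
    return df


# ---------------------------------------------------------------------------
# extraction

def test_extract_constant_mask_mean():
    labels = np.zeros((4, 5, 7), dtype=np.int32)
    labels[1, 1:3, 1:6] = 1  # 10 voxels
    chan = np.full((4, 5, 7), 100.0)
    stack = ImageStack3D({"CD19": chan})
    table = extract_mask_intensities(labels, stack, ["CD19"])
    assert table.voxel_count.tolist() == [10]
    assert table.mean_CD19.tolist() == [100.0]


def test_extract_mean_over_two_plateaus():
    labels = np.zeros((2, 5, 5), dtype=np.int32)
    labels[0, 0, :5] = 1
    labels[1, 0, :5] = 1
    chan = np.zeros((2, 5, 5))
    chan[0] = 10.0
    chan[1] = 30.0
    table = extract_mask_intensities(labels, ImageStack3D({"m": chan}), ["m"])
    assert table.mean_m.tolist() == [20.0]


def test_extract_matches_bruteforce(rng):
    labels = rng.integers(0, 5, size=(6, 8, 8)).astype(np.int32)
    chan = rng.uniform(0, 500, size=(6, 8, 8))
    table = extract_mask_intensities(labels, ImageStack3D({"m": chan}), ["m"])
    for row in table.itertuples():
        region = labels == row.cell_id
        assert row.voxel_count == int(region.sum())
        np.testing.assert_allclose(row.mean_m, chan[region].mean())
        np.testing.assert_allclose(
            [row.centroid_z, row.centroid_y, row.centroid_x],
            np.argwhere(region).mean(axis=0),
        )


def test_extract_rejects_grid_mismatch():
    labels = np.zeros((2, 3, 3), dtype=np.int32)
    stack = ImageStack3D({"m": np.zeros((2, 4, 4))})
    with pytest.raises(ValueError, match="grid"):
        extract_mask_intensities(labels, stack, ["m"])


# ---------------------------------------------------------------------------
# normalization

def test_normalize_two_cells():
    table = normalize_intensities(_table([10.0, 30.0]), ["CD19"])
    np.testing.assert_allclose(
        table.normlog_CD19, [np.log(0.25), np.log(0.75)]
    )


def test_normalize_single_cell_gives_log_one():
    table = normalize_intensities(_table([42.0]), ["CD19"])
    np.testing.assert_allclose(table.normlog_CD19, [0.0])


def test_normalize_zero_mean_uses_half_minimum_positive():
    table = normalize_intensities(_table([0.0, 10.0, 30.0]), ["CD19"])
    scaled = np.array([10.0, 30.0]) / 40.0
    expected_zero = np.log(0.5 * scaled.min())
    np.testing.assert_allclose(table.normlog_CD19.iloc[0], expected_zero)
    assert np.isfinite(table.normlog_CD19).all()


def test_normalize_all_zero_marker_flags_negative():
    table = normalize_intensities(_table([0.0, 0.0]), ["CD19"])
    assert table.normlog_CD19.isna().all()
    thr = MarkerThresholds({"CD19": 40.0}, {"CD19": -1.0}, {"CD19": 2})
    thr2 = MarkerThresholds(
        {"CD19": 40.0, "CD3": 95.0}, {"CD19": -1.0, "CD3": -1.0}, {"CD19": 2, "CD3": 2}
    )
    table["normlog_CD3"] = [-0.5, -2.0]
    classes = classify_cells(table, thr2)["class"]
    assert classes.tolist() == ["CD3pos", "negative"]


def test_scaled_intensities_sum_to_one_per_stack(default_run):
    _, _, _, tables, _ = default_run
    for table in tables:
        for marker in MARKERS:
            scaled = np.exp(table[f"normlog_{marker}"].to_numpy(dtype=float))
            # zero-substituted records break the exact sum; all-positive stacks hold it
            if (table[f"mean_{marker}"] > 0).all():
                np.testing.assert_allclose(scaled.sum(), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# thresholds

def test_percentile_threshold_matches_sorted_array_oracle():
    values = np.arange(1.0, 101.0)
    table = _table(values)
    table["normlog_CD19"] = values  # bypass normalization for the oracle check
    thr = pool_and_threshold([table], {"CD19": 40.0})
    # linear interpolation between the 40th and 41st order statistics
    assert 40.0 <= thr.thresholds["CD19"] <= 41.0
    np.testing.assert_allclose(thr.thresholds["CD19"], np.percentile(values, 40.0))
    assert thr.n_pooled["CD19"] == 100


def test_percentile_threshold_of_constant_values():
    table = _table([5.0] * 8)
    table["normlog_CD19"] = 5.0
    thr = pool_and_threshold([table], {"CD19": 95.0})
    assert thr.thresholds["CD19"] == 5.0


def test_default_percentiles_are_asymmetric(default_run):
    *_, thresholds = default_run
    assert thresholds.percentiles == {"CD19": 40.0, "CD3": 95.0}


def test_fraction_above_threshold_bounded(default_run):
    _, _, _, tables, thresholds = default_run
    for marker, pct in thresholds.percentiles.items():
        pooled = np.concatenate(
            [t[f"normlog_{marker}"].to_numpy(dtype=float) for t in tables]
        )
        pooled = pooled[np.isfinite(pooled)]
        frac = (pooled > thresholds.thresholds[marker]).mean()
        assert frac <= (100.0 - pct) / 100.0 + 1.0 / pooled.size


def test_empty_pool_is_an_error():
    table = _table([0.0, 0.0])
    table = normalize_intensities(table, ["CD19"])
    with pytest.raises(ValueError, match="empty pooled"):
        pool_and_threshold([table], {"CD19": 40.0})


# ---------------------------------------------------------------------------
# classification

def _thr(cd19, cd3):
    return MarkerThresholds(
        {"CD19": 40.0, "CD3": 95.0}, {"CD19": cd19, "CD3": cd3},
        {"CD19": 1, "CD3": 1},
    )


def test_cell_exactly_at_threshold_is_negative():
    table = _table([1.0])
    table["normlog_CD19"] = -1.0
    table["normlog_CD3"] = -5.0
    classes = classify_cells(table, _thr(-1.0, -2.0))["class"]
    assert classes.tolist() == ["negative"]


def test_classification_matches_bruteforce(rng):
    table = _table(rng.uniform(1, 100, size=20))
    table["normlog_CD19"] = rng.normal(size=20)
    table["normlog_CD3"] = rng.normal(size=20)
    thr = _thr(0.2, 0.4)
    got = classify_cells(table, thr)["class"].tolist()
    for cls, cd19, cd3 in zip(got, table.normlog_CD19, table.normlog_CD3):
        want = (
            "double_pos" if cd19 > 0.2 and cd3 > 0.4
            else "CD19pos" if cd19 > 0.2
            else "CD3pos" if cd3 > 0.4
            else "negative"
        )
        assert cls == want


def test_classes_invariant_under_uniform_linear_rescale(default_run):
    """Per-stack uniform gain changes cancel in sum-scaling."""
    _, _, _, tables, _ = default_run
    scaled_tables = []
    for i, table in enumerate(tables):
        t = table.copy()
        gain = [0.5, 3.0, 17.0][i]
        for marker in MARKERS:
            t[f"mean_{marker}"] = t[f"mean_{marker}"] * gain
        scaled_tables.append(
            normalize_intensities(t.drop(columns=[f"normlog_{m}" for m in MARKERS]),
                                  MARKERS)
        )
    thr_a = pool_and_threshold(tables)
    thr_b = pool_and_threshold(scaled_tables)
    for ta, tb in zip(tables, scaled_tables):
        ca = classify_cells(ta, thr_a)["class"]
        cb = classify_cells(tb, thr_b)["class"]
        assert ca.tolist() == cb.tolist()


# ---------------------------------------------------------------------------
# co-localization

def _two_sphere_labels(gap):
    labels = np.zeros((16, 16, 24), dtype=np.int32)
    zz, yy, xx = np.mgrid[:16, :16, :24]
    r = 3
    labels[(zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 6) ** 2 <= r * r] = 1
    x2 = 6 + 2 * r + 1 + gap  # surface gap in voxels along x
    labels[(zz - 8) ** 2 + (yy - 8) ** 2 + (xx - x2) ** 2 <= r * r] = 2
    return labels


def _pair_table(class_a, class_b):
    return pd.DataFrame(
        {
            "cell_id": [1, 2],
            "stack_id": "s0",
            "voxel_count": [10, 10],
            "class": [class_a, class_b],
        }
    )


def test_adjacency_at_one_voxel_gap():
    labels = _two_sphere_labels(gap=1)
    assert regions_adjacent(labels, 1, 2, max_gap=1)


def test_no_adjacency_at_two_voxel_gap():
    labels = _two_sphere_labels(gap=2)
    assert not regions_adjacent(labels, 1, 2, max_gap=1)


def test_coloc_without_cd3_equals_double_pos():
    labels = _two_sphere_labels(gap=2)  # not adjacent
    counts, _ = count_colocalized(labels, _pair_table("CD19pos", "CD19pos"))
    assert counts.n_coloc == 0
    counts, _ = count_colocalized(labels, _pair_table("double_pos", "CD19pos"))
    assert counts.n_coloc == 1
    assert counts.n_cd19 == 2 and counts.n_cd3 == 1


def test_adjacent_pair_flagged_in_adjacent_mode_only():
    labels = _two_sphere_labels(gap=1)
    table = _pair_table("CD19pos", "CD3pos")
    strict, _ = count_colocalized(labels, table, mode="double_pos_only")
    assert strict.n_coloc == 0
    loose, out = count_colocalized(labels, table, mode="double_pos_or_adjacent")
    assert loose.n_coloc == 2
    assert out.coloc.all()


def test_gap_two_pair_not_coloc():
    labels = _two_sphere_labels(gap=2)
    counts, _ = count_colocalized(labels, _pair_table("CD19pos", "CD3pos"))
    assert counts.n_coloc == 0


def test_adjacent_mode_superset_and_count_invariants(default_run):
    _, labels, _, tables, thresholds = default_run
    for lab, table in zip(labels, tables):
        cls = classify_cells(table, thresholds)
        strict, _ = count_colocalized(lab, cls, mode="double_pos_only")
        loose, _ = count_colocalized(lab, cls, mode="double_pos_or_adjacent")
        assert set(strict.coloc_ids) <= set(loose.coloc_ids)
        assert loose.n_coloc >= strict.n_coloc == strict.n_double_pos
        assert loose.n_coloc <= loose.n_cd19 + loose.n_cd3
        assert max(loose.n_cd19, loose.n_cd3) <= loose.n_total_masks


def test_planted_pairs_recovered(default_run):
    _, labels, truths, tables, thresholds = default_run
    for lab, truth, table in zip(labels, truths, tables):
        cls = classify_cells(table, thresholds)
        counts, _ = count_colocalized(lab, cls, mode="double_pos_or_adjacent")
        planted = set(
            truth.cells.loc[truth.cells.coloc_partner_id.notna(), "id"].astype(int)
        )
        assert planted == set(counts.coloc_ids)


# ---------------------------------------------------------------------------
# apoptosis

def _cond_tables(fracs, seed0=900, n_stacks=2):
    out = {}
    seed = seed0
    for name, frac in fracs.items():
        tabs = []
        for _ in range(n_stacks):
            stack, labels, _ = generate_coculture_stack(
                SimParams(frac_apoptotic_b=frac, seed=seed)
            )
            seed += 1
            t = extract_mask_intensities(labels, stack, MARKERS, stack_id=f"{name}{seed}")
            tabs.append(normalize_intensities(t, MARKERS))
        out[name] = tabs
    return out


@pytest.fixture(scope="module")
def apoptosis_run():
    conds = _cond_tables({"control": 0.1, "treated": 0.3})
    pooled = [t for ts in conds.values() for t in ts]
    thr = pool_and_threshold(pooled)
    conds = {k: [classify_cells(t, thr) for t in ts] for k, ts in conds.items()}
    return quantify_apoptosis(conds, control="control")


def test_apoptosis_recovers_planted_fractions(apoptosis_run):
    assert apoptosis_run.condition_means["control"] == pytest.approx(0.1, abs=0.05)
    assert apoptosis_run.condition_means["treated"] == pytest.approx(0.3, abs=0.05)
    assert apoptosis_run.ratios_vs_control["treated"] == pytest.approx(3.0, rel=0.2)


def test_apoptosis_control_ratio_is_one(apoptosis_run):
    assert apoptosis_run.ratios_vs_control["control"] == pytest.approx(1.0, abs=1e-9)


def test_apoptosis_without_caspase_signal_is_zero():
    conds = _cond_tables({"control": 0.0, "other": 0.0}, seed0=950, n_stacks=1)
    pooled = [t for ts in conds.values() for t in ts]
    thr = pool_and_threshold(pooled)
    conds = {k: [classify_cells(t, thr) for t in ts] for k, ts in conds.items()}
    res = quantify_apoptosis(conds, control="control")
    assert res.condition_means == {"control": 0.0, "other": 0.0}
    assert res.ratios_vs_control == {"control": 0.0, "other": 0.0}


def test_caspase_percentile_rule_available():
    values = np.concatenate([np.zeros(95), np.ones(5)])
    rule = CaspaseRule(method="percentile", percentile=95.0)
    thr = rule.threshold(values)
    assert (values > thr).sum() <= 5


def test_stack_without_cd19_cells_is_excluded():
    table = _table([1.0, 2.0])
    table["normlog_CASP3"] = [-1.0, -1.0]
    table["class"] = ["negative", "CD3pos"]
    res = quantify_apoptosis({"c": [table]}, control="c")
    assert res.per_stack["c"] == []
    assert np.isnan(res.condition_means["c"])
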