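"""Group averaging, per-parcel statistics and hemispheric asymmetry tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tdrm


def make_table(densities: dict[str, dict[int, float]], n_parcels=3):
    """Minimal per-subject parcel table: odd labels L, even labels R."""
    rows = []
    lobes = ["frontal", "parietal", "temporal"]
    for i in range(n_parcels):
        for side, lab in (("L", 2 * i + 1), ("R", 2 * i + 2)):
            row = {
                "label": lab,
                "name": f"parcel_{i + 1:03d}",
                "hemisphere": side,
                "lobe_group": lobes[i % 3],
                "piece_volume_mm3": 100.0,
            }
            total = 0.0
            for cname in tdrm.CHANNEL_ORDER:
                v = densities.get(cname, {}).get(lab, 0.0)
                row[f"relative_density_{cname}"] = v
                row[f"tracks_amount_{cname}"] = v * 100.0
                total += v
            row["relative_density_total"] = total
            row["tracks_amount_total"] = total * 100.0
            rows.append(row)
    return pd.DataFrame(rows)


def _dv(arr, affine=None):
    return tdrm.DensityVolume(
        counts=np.asarray(arr), affine=np.eye(4) if affine is None else affine
    )


def test_average_idempotent(scene, classified):
    dv = tdrm.voxel_density(classified, scene.tracks, scene.tissue)
    mean = tdrm.average_density_volumes([dv, dv, dv])
    np.testing.assert_allclose(mean.counts, dv.counts)


def test_average_simple_mean():
    a = np.zeros((4, 2, 2, 2))
    b = np.zeros((4, 2, 2, 2))
    b[0, 0, 0, 0] = 4.0
    mean = tdrm.average_density_volumes([_dv(a), _dv(b)])
    assert mean.counts[0, 0, 0, 0] == 2.0


def test_average_matches_brute_force():
    rng = np.random.default_rng(8)
    vols = [_dv(rng.integers(0, 5, size=(4, 6, 6, 6))) for _ in range(8)]
    mean = tdrm.average_density_volumes(vols)
    brute = np.zeros((4, 6, 6, 6))
    for v in vols:
        brute += v.counts
    brute /= 8
    np.testing.assert_allclose(mean.counts, brute)


def test_average_linearity(scene, classified):
    """Averaging then summing voxels equals summing then averaging."""
    rng = np.random.default_rng(9)
    vols = [_dv(rng.integers(0, 4, size=(4, 5, 5, 5))) for _ in range(5)]
    mean = tdrm.average_density_volumes(vols)
    assert mean.counts.sum() == pytest.approx(
        np.mean([v.counts.sum() for v in vols])
    )


def test_average_mismatched_grid_names_subject():
    a = _dv(np.zeros((4, 3, 3, 3)))
    b = _dv(np.zeros((4, 4, 4, 4)))
    with pytest.raises(ValueError, match="volume 1"):
        tdrm.average_density_volumes([a, b])
    c = _dv(np.zeros((4, 3, 3, 3)), affine=np.diag([2.0, 1, 1, 1]))
    with pytest.raises(ValueError, match="volume 1"):
        tdrm.average_density_volumes([a, c])


def test_group_stats_mean_sd():
    t1 = make_table({"projection": {1: 0.4}})
    t2 = make_table({"projection": {1: 0.6}})
    res = tdrm.group_parcel_stats([t1, t2])
    row = res.per_label[res.per_label["label"] == 1].iloc[0]
    assert row["mean_projection"] == pytest.approx(0.5)
    assert row["sd_projection"] == pytest.approx(np.std([0.4, 0.6], ddof=1))
    assert row["sd_projection"] == pytest.approx(0.14142, abs=1e-4)


def test_group_stats_identical_subjects_zero_sd():
    t = make_table({"commissural": {1: 0.3, 2: 0.2}})
    res = tdrm.group_parcel_stats([t.copy(), t.copy(), t.copy()])
    assert (res.per_label.filter(like="sd_").to_numpy() == 0).all()


def test_group_stats_order_invariance():
    rng = np.random.default_rng(10)
    tables = [
        make_table({"long_assoc": {lab: rng.uniform(0, 1) for lab in range(1, 7)}})
        for _ in range(6)
    ]
    a = tdrm.group_parcel_stats(tables)
    b = tdrm.group_parcel_stats(tables[::-1])
    pd.testing.assert_frame_equal(a.per_label, b.per_label)


def test_group_stats_label_mismatch():
    t1 = make_table({})
    t2 = make_table({}, n_parcels=4)
    with pytest.raises(ValueError, match="subject 1"):
        tdrm.group_parcel_stats([t1, t2])


def test_group_stats_hemisphere_means_recover_planted_offset():
    """Unweighted hemisphere means recover generator-set L/R levels."""
    rng = np.random.default_rng(11)
    lh_level, rh_level = 0.40, 0.45
    tables = []
    for _ in range(16):
        dens = {
            "long_assoc": {
                lab: (lh_level if lab % 2 else rh_level) + rng.normal(0, 0.01)
                for lab in range(1, 7)
            }
        }
        tables.append(make_table(dens))
    res = tdrm.group_parcel_stats(tables)
    # Monte-Carlo error of the mean over 16 subjects x 3 labels, sigma=0.01
    assert res.hemisphere_means.loc["L", "long_assoc"] == pytest.approx(
        lh_level, abs=0.005
    )
    assert res.hemisphere_means.loc["R", "long_assoc"] == pytest.approx(
        rh_level, abs=0.005
    )


def test_asymmetry_all_zero_differences():
    t = make_table({"long_assoc": {lab: 0.5 for lab in range(1, 7)}})
    res = tdrm.hemispheric_asymmetry([t.copy() for _ in range(5)], "long_assoc")
    assert res.p_value == 1.0 and res.direction == "none"


def test_asymmetry_constant_difference_degenerate():
    t = make_table({"long_assoc": {1: 0.6, 2: 0.5, 3: 0.6, 4: 0.5, 5: 0.6, 6: 0.5}})
    res = tdrm.hemispheric_asymmetry([t.copy() for _ in range(5)], "long_assoc")
    assert res.degenerate and np.isnan(res.p_value)
    assert res.direction == "LH>RH"


def test_asymmetry_matches_hand_computed_t():
    """The paired t statistic and p agree with the closed-form computation."""
    rng = np.random.default_rng(12)
    tables = []
    diffs = []
    for _ in range(10):
        lh = rng.uniform(0.4, 0.6)
        rh = rng.uniform(0.4, 0.6)
        diffs.append(lh - rh)
        dens = {"long_assoc": {lab: (lh if lab % 2 else rh) for lab in range(1, 7)}}
        tables.append(make_table(dens))
    res = tdrm.hemispheric_asymmetry(tables, "long_assoc")
    d = np.array(diffs)
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_hand = 2 * stats.t.sf(abs(t_hand), df=len(d) - 1)
    assert res.statistic == pytest.approx(t_hand, abs=1e-10)
    assert res.p_value == pytest.approx(p_hand, abs=1e-8)
    assert res.n_pairs == 10


def test_asymmetry_direction_matches_sign():
    rng = np.random.default_rng(13)
    tables = [
        make_table(
            {"short_assoc": {lab: 0.5 + (0.05 if lab % 2 == 0 else 0.0)
                             + rng.normal(0, 0.005) for lab in range(1, 7)}}
        )
        for _ in range(8)
    ]
    res = tdrm.hemispheric_asymmetry(tables, "short_assoc")
    assert res.direction == "RH>LH"
    assert res.p_value < 0.01


def test_asymmetry_total_association_and_name_subset():
    rng = np.random.default_rng(14)
    tables = [
        make_table(
            {
                "short_assoc": {lab: 0.3 + rng.normal(0, 0.01) for lab in range(1, 7)},
                "long_assoc": {lab: 0.2 + rng.normal(0, 0.01) for lab in range(1, 7)},
            }
        )
        for _ in range(6)
    ]
    res = tdrm.hemispheric_asymmetry(
        tables, "total_assoc", names=["parcel_001", "parcel_002"]
    )
    assert res.n_pairs == 6
    assert len(res.labels_lh) == 2 and len(res.labels_rh) == 2


def test_asymmetry_needs_subjects_and_pairs():
    t = make_table({})
    with pytest.raises(ValueError):
        tdrm.hemispheric_asymmetry([t, t], "long_assoc")
    with pytest.raises(ValueError, match="paired"):
        bad = t[t["hemisphere"] == "L"]
        tdrm.hemispheric_asymmetry([bad] * 4, "long_assoc")


def test_wilcoxon_variant_runs():
    rng = np.random.default_rng(15)
    tables = [
        make_table({"long_assoc": {lab: 0.5 + rng.normal(0, 0.02)
                                   for lab in range(1, 7)}})
        for _ in range(8)
    ]
    res = tdrm.hemispheric_asymmetry(tables, "long_assoc", test="wilcoxon")
    assert 0 <= res.p_value <= 1


def test_lobe_grouped_bars(tmp_path):
    tables = [
        make_table({"projection": {1: 0.1, 2: 0.2, 3: 0.3, 4: 0.4, 5: 0.5, 6: 0.6}})
        for _ in range(3)
    ]
    res = tdrm.group_parcel_stats(tables)
    lookup = tables[0][["label", "name", "hemisphere", "lobe_group"]]
    bars = tdrm.lobe_grouped_bars(res, lookup)
    assert bars["name"].tolist() == ["parcel_001", "parcel_002", "parcel_003"]
    assert bars["color"].tolist() == ["red", "blue", "green"]
    np.testing.assert_allclose(bars["lh_mean_projection"], [0.1, 0.3, 0.5])
    np.testing.assert_allclose(bars["rh_mean_projection"], [0.2, 0.4, 0.6])
    # round-trip through the TSV writer preserves values
    p = tmp_path / "bars.tsv"
    bars.to_csv(p, sep="\t", index=False)
    back = pd.read_csv(p, sep="\t")
    np.testing.assert_allclose(
        back["lh_mean_projection"], bars["lh_mean_projection"]
    )
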