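"""Group-level analysis: mean density volumes, per-parcel statistics and
hemispheric asymmetry tests.

All subjects are assumed to be in a common template space already (the warp
itself is upstream of this package).  Averaging operates on raw densities;
color transforms are applied afterwards by the mapping module.  Asymmetry is
assessed with a paired two-sided t-test across subjects on per-subject
left-minus-right differences — for a multi-label region each subject
contributes one pair, the unweighted mean over the region's labels per
hemisphere, keeping observations independent.  A Wilcoxon signed-rank
variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .density import CHANNEL_ORDER, DensityVolume

__all__ = [
    "GroupDensityResult",
    "AsymmetryResult",
    "average_density_volumes",
    "group_parcel_stats",
    "paired_difference_test",
    "hemispheric_asymmetry",
    "lobe_grouped_bars",
    "LOBE_COLORS",
]

LOBE_COLORS = {
    "frontal": "red",
    "parietal": "blue",
    "temporal": "green",
    "limbic": "magenta",
    "insular": "cyan",
    "occipital": "yellow",
}

_DENSITY_COLS = [f"relative_density_{c}" for c in CHANNEL_ORDER] + [
    "relative_density_total"
]


def average_density_volumes(volumes: list[DensityVolume]) -> DensityVolume:
    """Voxel-wise arithmetic mean of density volumes on a shared grid."""
    if not volumes:
        raise ValueError("no volumes to average")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if v.counts.shape != ref.counts.shape:
            raise ValueError(f"volume {i}: grid shape differs from volume 0")
        if not np.allclose(v.affine, ref.affine, atol=1e-6):
            raise ValueError(f"volume {i}: affine differs from volume 0")
    mean = np.mean([v.counts for v in volumes], axis=0)
    return DensityVolume(counts=mean, affine=ref.affine.copy())


@dataclass
class GroupDensityResult:
    """Per-parcel mean/SD of relative density across subjects."""

    per_label: pd.DataFrame   # label, name, hemisphere, lobe_group, mean_*/sd_*
    hemisphere_means: pd.DataFrame  # hemisphere x class unweighted label means
    n_subjects: int


def group_parcel_stats(tables: list[pd.DataFrame]) -> GroupDensityResult:
    """Mean and sample SD (ddof=1) of relative densities per parcel.

    Hemisphere-level means are unweighted means over the labels of each
    hemisphere.  All subjects must share the same parcel label set.
    """
    if len(tables) < 2:
        raise ValueError("group statistics need at least 2 subjects")
    ref_labels = tables[0]["label"].tolist()
    for i, t in enumerate(tables[1:], start=1):
        if t["label"].tolist() != ref_labels:
            raise ValueError(f"subject {i}: parcel label set differs from subject 0")
    stacked = pd.concat(
        [t.assign(_subject=i) for i, t in enumerate(tables)], ignore_index=True
    )
    parcels = stacked[stacked["label"] != 0]
    grouped = parcels.groupby("label", sort=True)
    meta = parcels.drop_duplicates("label").set_index("label")[
        ["name", "hemisphere", "lobe_group"]
    ]
    out = meta.copy()
    for col in _DENSITY_COLS:
        out[f"mean_{col.removeprefix('relative_density_')}"] = grouped[col].mean()
        out[f"sd_{col.removeprefix('relative_density_')}"] = grouped[col].std(ddof=1)
    out = out.reset_index()
    hemi = (
        out.groupby("hemisphere")[
            [f"mean_{c}" for c in CHANNEL_ORDER] + ["mean_total"]
        ]
        .mean()
        .rename(columns=lambda c: c.removeprefix("mean_"))
    )
    return GroupDensityResult(
        per_label=out, hemisphere_means=hemi, n_subjects=len(tables)
    )


def paired_difference_test(diffs: np.ndarray, test: str = "t", axis: int = -1):
    """Two-sided test of zero mean on paired differences.

    ``test="t"`` is a one-sample t-test on the differences (equivalent to a
    paired t-test); ``"wilcoxon"`` the signed-rank test.  Accepts stacked
    replicate arrays for the t-test via ``axis``.  Returns ``(stat, p)``.
    """
    diffs = np.asarray(diffs, dtype=float)
    if test == "t":
        res = stats.ttest_1samp(diffs, 0.0, axis=axis)
        return res.statistic, res.pvalue
    if test == "wilcoxon":
        res = stats.wilcoxon(diffs)
        return res.statistic, res.pvalue
    raise ValueError(f"unknown test {test!r}")


@dataclass
class AsymmetryResult:
    """Paired hemisphere-difference test for one fiber class and label set."""

    fiber_class: str
    labels_lh: list[int]
    labels_rh: list[int]
    statistic: float
    p_value: float
    direction: str  # "LH>RH", "RH>LH" or "none"
    n_pairs: int
    mean_difference: float
    degenerate: bool = False


def hemispheric_asymmetry(
    tables: list[pd.DataFrame],
    fiber_class: str = "long_assoc",
    names: list[str] | None = None,
    test: str = "t",
) -> AsymmetryResult:
    """Test LH vs RH relative density for a fiber class over a label set.

    Homotopic pairing is by parcel ``name`` (same name on both hemispheres).
    Each subject contributes a single (LH mean, RH mean) pair over the
    selected labels.  Degenerate inputs are reported, not hidden: all-zero
    differences give p = 1 and direction "none"; a constant nonzero
    difference (zero variance) is flagged degenerate with p = NaN.
    """
    if len(tables) < 3:
        raise ValueError("asymmetry testing needs at least 3 subjects")
    if fiber_class == "total_assoc":
        col = None  # sum of the two association classes
    else:
        col = f"relative_density_{fiber_class}"
        if col not in tables[0].columns:
            raise ValueError(f"unknown fiber class {fiber_class!r}")

    ref = tables[0][tables[0]["label"] != 0]
    if names is not None:
        ref = ref[ref["name"].isin(names)]
    lh_rows = ref[ref["hemisphere"] == "L"].sort_values("name")
    rh_rows = ref[ref["hemisphere"] == "R"].sort_values("name")
    if set(lh_rows["name"]) != set(rh_rows["name"]) or lh_rows.empty:
        raise ValueError("selected labels are not homotopically paired")
    lh_labels = lh_rows["label"].tolist()
    rh_labels = rh_rows["label"].tolist()

    def side_mean(t: pd.DataFrame, labels: list[int]) -> float:
        sub = t[t["label"].isin(labels)]
        if col is None:
            vals = (
                sub["relative_density_short_assoc"]
                + sub["relative_density_long_assoc"]
            )
        else:
            vals = sub[col]
        return float(vals.mean())

    lh = np.array([side_mean(t, lh_labels) for t in tables])
    rh = np.array([side_mean(t, rh_labels) for t in tables])
    diffs = lh - rh
    mean_diff = float(diffs.mean())
    if np.allclose(diffs, 0.0):
        return AsymmetryResult(
            fiber_class, lh_labels, rh_labels, 0.0, 1.0, "none", len(diffs), 0.0
        )
    if np.std(diffs) == 0.0:
        return AsymmetryResult(
            fiber_class,
            lh_labels,
            rh_labels,
            np.nan,
            np.nan,
            "LH>RH" if mean_diff > 0 else "RH>LH",
            len(diffs),
            mean_diff,
            degenerate=True,
        )
    stat, p = paired_difference_test(diffs, test=test)
    direction = "LH>RH" if mean_diff > 0 else ("RH>LH" if mean_diff < 0 else "none")
    return AsymmetryResult(
        fiber_class,
        lh_labels,
        rh_labels,
        float(stat),
        float(p),
        direction,
        len(diffs),
        mean_diff,
    )


def lobe_grouped_bars(result: GroupDensityResult, lookup: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: one row per homotopic parcel pair, LH/RH side by side.

    Rows follow atlas label order; each carries the lobe-group color key
    (frontal=red, parietal=blue, temporal=green, limbic=magenta,
    insular=cyan, occipital=yellow) and the LH (left bar) / RH (right bar)
    mean and SD per fiber class.
    """
    per = result.per_label.set_index("label")
    rows = []
    by_name: dict[str, dict] = {}
    for lab in lookup.sort_values("label")["label"]:
        if lab not in per.index:
            continue
        r = per.loc[lab]
        entry = by_name.setdefault(
            r["name"],
            {
                "name": r["name"],
                "lobe_group": r["lobe_group"],
                "color": LOBE_COLORS.get(r["lobe_group"], "gray"),
                "order": int(lab),
            },
        )
        side = "lh" if r["hemisphere"] == "L" else "rh"
        entry[f"label_{side}"] = int(lab)
        for c in list(CHANNEL_ORDER) + ["total"]:
            entry[f"{side}_mean_{c}"] = r[f"mean_{c}"]
            entry[f"{side}_sd_{c}"] = r[f"sd_{c}"]
    rows = sorted(by_name.values(), key=lambda e: e["order"])
    return pd.DataFrame(rows).drop(columns="order")
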