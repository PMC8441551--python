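"""Track validation and four-way fiber classification.

Every streamline is judged solely by the tissue compartments of its two
terminal points and by its arc length:

* validation — a track with a terminal in white matter is rejected as a
  *noise* track; a remaining track with no terminal in the cerebral cortex
  is rejected as *ineffective*;
* classification of the validated tracks — any subcortical terminal makes a
  *projection* fiber; one terminal in each cortical hemisphere makes a
  *commissural* fiber; two terminals in the same cortical hemisphere make an
  *association* fiber, split at 6 cm arc length into *short* (< 60 mm) and
  *long* (>= 60 mm).  A validated track whose second terminal resolves to
  background fits no category and is reclassified ineffective.

Precedence is explicit and deterministic: NOISE > INEFFECTIVE at validation,
PROJECTION > COMMISSURAL > association at classification, and exactly 60 mm
falls on the LONG side of the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .tracks_io import LabelVolume, TrackSet, label_at

__all__ = [
    "FiberClass",
    "Rejection",
    "ClassificationSummary",
    "LENGTH_SPLIT_MM",
    "streamline_length",
    "terminal_compartments",
    "validate",
    "classify",
    "classify_tracks",
    "summarize",
    "flag_outlier_subjects",
]

LENGTH_SPLIT_MM = 60.0  # the 6 cm short/long association boundary

CORTEX_LABELS = (2, 3)
WM_LABEL = 1
SUBCORTICAL_LABEL = 4


class FiberClass(str, Enum):
    PROJECTION = "projection"
    COMMISSURAL = "commissural"
    SHORT_ASSOC = "short_assoc"
    LONG_ASSOC = "long_assoc"


class Rejection(str, Enum):
    NOISE_WM = "noise_wm"
    INEFFECTIVE = "ineffective"


CLASS_ORDER = tuple(c.value for c in FiberClass)


def streamline_length(points: np.ndarray) -> float:
    """Arc length in mm: sum of Euclidean distances between consecutive points."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def terminal_compartments(points: np.ndarray, tissue: LabelVolume) -> tuple[int, int]:
    """Tissue labels at the first and last streamline point."""
    points = np.asarray(points, dtype=float)
    return int(label_at(tissue, points[0])), int(label_at(tissue, points[-1]))


def _terminal_table(trackset: TrackSet, tissue: LabelVolume) -> pd.DataFrame:
    firsts = np.array([s[0] for s in trackset.streamlines]).reshape(-1, 3)
    lasts = np.array([s[-1] for s in trackset.streamlines]).reshape(-1, 3)
    return pd.DataFrame(
        {
            "index": np.arange(len(trackset)),
            "terminal_label_a": np.asarray(label_at(tissue, firsts), dtype=int)
            if len(trackset)
            else np.array([], dtype=int),
            "terminal_label_b": np.asarray(label_at(tissue, lasts), dtype=int)
            if len(trackset)
            else np.array([], dtype=int),
            "length_mm": [streamline_length(s) for s in trackset.streamlines],
        }
    )


def validate(trackset: TrackSet, tissue: LabelVolume) -> pd.DataFrame:
    """Apply the noise / ineffective rejection rules.

    Returns a per-streamline table with columns ``index``,
    ``terminal_label_a``, ``terminal_label_b``, ``length_mm`` and
    ``category`` (rejection reason, or NA for tracks awaiting
    classification).  A white-matter terminal takes precedence over the
    no-cortical-terminal rule.
    """
    df = _terminal_table(trackset, tissue)
    la, lb = df["terminal_label_a"].to_numpy(), df["terminal_label_b"].to_numpy()
    noise = (la == WM_LABEL) | (lb == WM_LABEL)
    has_cortex = np.isin(la, CORTEX_LABELS) | np.isin(lb, CORTEX_LABELS)
    ineffective = ~noise & ~has_cortex
    category = np.full(len(df), None, dtype=object)
    category[noise] = Rejection.NOISE_WM.value
    category[ineffective] = Rejection.INEFFECTIVE.value
    df["category"] = category
    return df


def classify(
    validated: pd.DataFrame, length_split_mm: float = LENGTH_SPLIT_MM
) -> pd.DataFrame:
    """Assign fiber classes to the validated (non-rejected) tracks.

    Decision order: any subcortical terminal => PROJECTION; one terminal in
    each cortex => COMMISSURAL; both in the same cortex => association split
    at ``length_split_mm`` (>= boundary is LONG); anything else (a background
    terminal) => reclassified INEFFECTIVE.
    """
    df = validated.copy()
    pending = df["category"].isna().to_numpy()
    la = df["terminal_label_a"].to_numpy()
    lb = df["terminal_label_b"].to_numpy()
    length = df["length_mm"].to_numpy()
    cat = df["category"].to_numpy(dtype=object)

    proj = pending & ((la == SUBCORTICAL_LABEL) | (lb == SUBCORTICAL_LABEL))
    cat[proj] = FiberClass.PROJECTION.value
    pending &= ~proj

    both_cortex = np.isin(la, CORTEX_LABELS) & np.isin(lb, CORTEX_LABELS)
    comm = pending & both_cortex & (la != lb)
    cat[comm] = FiberClass.COMMISSURAL.value
    assoc = pending & both_cortex & (la == lb)
    cat[assoc & (length < length_split_mm)] = FiberClass.SHORT_ASSOC.value
    cat[assoc & (length >= length_split_mm)] = FiberClass.LONG_ASSOC.value
    pending &= ~both_cortex

    cat[pending] = Rejection.INEFFECTIVE.value  # cortex<->background leftovers
    df["category"] = cat
    return df


def classify_tracks(
    trackset: TrackSet,
    tissue: LabelVolume,
    length_split_mm: float = LENGTH_SPLIT_MM,
) -> pd.DataFrame:
    """Validation followed by classification in one call."""
    return classify(validate(trackset, tissue), length_split_mm=length_split_mm)


@dataclass
class ClassificationSummary:
    """Per-subject counts and fractions of the four fiber classes."""

    subject_id: str
    counts: dict[str, int]
    rejections: dict[str, int]
    fractions: dict[str, float] | None
    total_validated: int
    total_extracted: int
    exclusion_pct: float


def summarize(classified: pd.DataFrame, subject_id: str = "") -> ClassificationSummary:
    """Counts, validated fractions and the exclusion percentage.

    With zero validated tracks the fractions are reported as ``None`` rather
    than raising a division error.
    """
    cat = classified["category"]
    counts = {c: int((cat == c).sum()) for c in CLASS_ORDER}
    rejections = {r.value: int((cat == r.value).sum()) for r in Rejection}
    total_validated = sum(counts.values())
    total = len(classified)
    fractions = (
        {c: counts[c] / total_validated for c in CLASS_ORDER}
        if total_validated
        else None
    )
    exclusion_pct = 100.0 * (total - total_validated) / total if total else 0.0
    return ClassificationSummary(
        subject_id=subject_id,
        counts=counts,
        rejections=rejections,
        fractions=fractions,
        total_validated=total_validated,
        total_extracted=total,
        exclusion_pct=exclusion_pct,
    )


def flag_outlier_subjects(
    summaries: list[ClassificationSummary], k_mad: float = 3.5
) -> pd.DataFrame:
    """Advisory outlier screen on validated-track totals and commissural ratio.

    A subject is flagged when its total validated count or commissural
    fraction deviates from the group median by more than ``k_mad`` times the
    median absolute deviation.  Flags are reported, never auto-excluded —
    mirroring a by-inspection exclusion of anomalous subjects.
    """
    if len(summaries) < 3:
        raise ValueError("outlier screening needs at least 3 subjects")
    totals = np.array([s.total_validated for s in summaries], dtype=float)
    comm = np.array(
        [s.fractions["commissural"] if s.fractions else np.nan for s in summaries]
    )

    def deviant(x: np.ndarray) -> np.ndarray:
        med = np.nanmedian(x)
        mad = median_abs_deviation(x, nan_policy="omit", scale=1.0)
        return np.abs(x - med) > k_mad * mad

    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "total_validated": totals,
            "commissural_fraction": comm,
            "flag_total": deviant(totals),
            "flag_commissural": deviant(comm),
            "flagged": deviant(totals) | deviant(comm),
        }
    )
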