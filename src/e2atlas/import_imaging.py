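"""Peroxisomal protein-import quantification from multichannel images.

Peroxisomes are defined by PMP70 puncta; a PTS1 fluorescent reporter marks
matrix protein import.  Each PMP70 punctum is classified as *functional*
(sufficient pixel overlap with a PTS1 punctum) or *ghost* (import
defective, PMP70-positive but PTS1-negative).  Segmentation uses
deterministic classical operators — Gaussian smoothing, thresholding and
8-connected component labelling — and externally produced label maps can be
fed straight into the classification step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label, regionprops
from statsmodels.stats.proportion import proportion_confint

CHANNEL_NAMES = ("nuclei", "pts1", "pmp70")

#: A PMP70 punctum is functional iff this fraction of its pixels overlaps
#: any PTS1 punctum.
DEFAULT_MIN_OVERLAP = 0.1


@dataclass
class MultiChannelImage:
    """Named 2-D channels (nuclei / pts1 / pmp70) sharing one shape."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} has negative intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabeledPuncta:
    """Connected-component labelling of one channel.

    ``label_map`` holds consecutive positive integer labels (0 background);
    ``table`` has one row per punctum: label, area (pixels) and 0-based
    (row, col) centroid.
    """

    label_map: np.ndarray
    table: pd.DataFrame
    channel: str = ""

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class PeroxisomeCallSet:
    """Per-punctum overlap calls plus field-level totals.

    Conservation holds by construction: n_functional + n_ghost equals the
    number of PMP70 puncta in the field.
    """

    puncta: pd.DataFrame  # label, area, overlap_fraction, klass
    n_nuclei: int | None = None

    @property
    def n_functional(self) -> int:
        return int((self.puncta["klass"] == "functional").sum())

    @property
    def n_ghost(self) -> int:
        return int((self.puncta["klass"] == "ghost").sum())

    @property
    def n_peroxisomes(self) -> int:
        return len(self.puncta)


# ---------------------------------------------------------------------------
# segmentation (classical stand-in operators)
# ---------------------------------------------------------------------------

def _segment(channel: np.ndarray, sigma: float, threshold_rule: str,
             threshold: float | None, min_area: int, name: str) -> LabeledPuncta:
    channel = np.asarray(channel, float)
    if channel.size == 0:
        raise ValueError("empty image")
    smoothed = gaussian(channel, sigma=sigma, preserve_range=True) if sigma > 0 else channel
    if threshold_rule == "absolute":
        if threshold is None:
            raise ValueError("absolute thresholding needs a threshold value")
        cut = float(threshold)
    elif threshold_rule == "otsu":
        if np.ptp(smoothed) == 0:  # constant image: nothing to segment
            return LabeledPuncta(np.zeros(channel.shape, dtype=int),
                                 _empty_table(), name)
        cut = float(threshold_otsu(smoothed))
    else:
        raise ValueError("threshold_rule must be 'otsu' or 'absolute'")
    mask = smoothed > cut
    labels = sk_label(mask, connectivity=2)  # 8-connected
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        keep[prop.label] = next_id
        rows.append({"label": next_id, "area": int(prop.area),
                     "centroid_r": prop.centroid[0], "centroid_c": prop.centroid[1]})
        next_id += 1
    relabeled = keep[labels]
    table = pd.DataFrame(rows) if rows else _empty_table()
    return LabeledPuncta(relabeled, table, name)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "area", "centroid_r", "centroid_c"])


def segment_nuclei(nuclei_channel: np.ndarray, min_area: int = 50,
                   sigma_smooth: float = 2.0, threshold_rule: str = "otsu",
                   threshold: float | None = None) -> LabeledPuncta:
    """Label nuclei by smoothing, thresholding and connected components.

    An all-zero channel yields zero nuclei (not an error).  Objects below
    ``min_area`` pixels are dropped and the survivors relabelled 1..n.
    """
    return _segment(nuclei_channel, sigma_smooth, threshold_rule, threshold,
                    min_area, "nuclei")


def segment_puncta(channel: np.ndarray, sigma_smooth: float = 1.0,
                   threshold_rule: str = "otsu", threshold: float | None = None,
                   min_area: int = 3, name: str = "") -> LabeledPuncta:
    """Label fluorescent puncta; deterministic for fixed inputs."""
    return _segment(channel, sigma_smooth, threshold_rule, threshold,
                    min_area, name)


# ---------------------------------------------------------------------------
# classification and field statistics
# ---------------------------------------------------------------------------

def classify_peroxisomes(pmp70: LabeledPuncta, pts1: LabeledPuncta,
                         min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
                         n_nuclei: int | None = None) -> PeroxisomeCallSet:
    """Classify every PMP70 punctum as functional or ghost by PTS1 overlap.

    overlap_fraction is the fraction of the punctum's pixels covered by any
    PTS1 punctum; the punctum is functional iff overlap_fraction >=
    ``min_overlap_fraction``.  Only PMP70 defines peroxisomes: PTS1-only
    puncta never produce calls.
    """
    if pmp70.label_map.shape != pts1.label_map.shape:
        raise ValueError("label maps must share one shape")
    labels = pmp70.label_map
    n_labels = int(labels.max())
    pts1_mask = pts1.label_map > 0
    areas = np.bincount(labels.ravel(), minlength=n_labels + 1)
    overlaps = np.bincount(labels.ravel(), weights=pts1_mask.ravel().astype(float),
                           minlength=n_labels + 1)
    rows = []
    for lab in range(1, n_labels + 1):
        if areas[lab] == 0:
            continue
        frac = overlaps[lab] / areas[lab]
        rows.append({"label": lab, "area": int(areas[lab]),
                     "overlap_fraction": float(frac),
                     "klass": "functional" if frac >= min_overlap_fraction else "ghost"})
    table = (pd.DataFrame(rows) if rows
             else pd.DataFrame(columns=["label", "area", "overlap_fraction", "klass"]))
    return PeroxisomeCallSet(puncta=table, n_nuclei=n_nuclei)


def functional_fraction(calls: PeroxisomeCallSet, conf_level: float = 0.95
                        ) -> tuple[float, tuple[float, float]]:
    """Proportion of functional peroxisomes with a Wilson score interval."""
    total = calls.n_peroxisomes
    if total == 0:
        raise ValueError("no PMP70 puncta in the field")
    frac = calls.n_functional / total
    lo, hi = proportion_confint(calls.n_functional, total,
                                alpha=1 - conf_level, method="wilson")
    return frac, (float(lo), float(hi))


def peroxisomes_per_cell(calls: PeroxisomeCallSet) -> float:
    """Total PMP70 puncta normalised by the number of nuclei in the field."""
    if not calls.n_nuclei:
        raise ValueError("need at least one nucleus")
    return calls.n_peroxisomes / calls.n_nuclei


def puncta_size_stats(puncta: LabeledPuncta, pixel_size: float) -> dict:
    """Count and size summary of labelled puncta, areas in square microns."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    areas_um2 = puncta.table["area"].to_numpy(float) * pixel_size**2
    n = len(areas_um2)
    return {
        "count": n,
        "mean_area_um2": float(areas_um2.mean()) if n else np.nan,
        "median_area_um2": float(np.median(areas_um2)) if n else np.nan,
        "sd_area_um2": float(areas_um2.std(ddof=1)) if n > 1 else np.nan,
    }


def quantify_field(image: MultiChannelImage,
                   min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
                   nuclei_min_area: int = 50, puncta_min_area: int = 3,
                   sigma_smooth: float = 1.0,
                   threshold_rule: str = "otsu",
                   pts1_threshold: float | None = None,
                   pmp70_threshold: float | None = None,
                   nuclei_threshold: float | None = None) -> dict:
    """Segment all three channels of a field and summarise import status.

    Returns a flat record: n_functional, n_ghost, functional_fraction (NaN
    when the field has no peroxisomes), n_nuclei, puncta_per_cell and
    mean_area_um2 — the per-field row of the study's import read-out.
    """
    nuclei = segment_nuclei(image.channels["nuclei"], min_area=nuclei_min_area,
                            threshold_rule=threshold_rule, threshold=nuclei_threshold)
    pts1 = segment_puncta(image.channels["pts1"], sigma_smooth=sigma_smooth,
                          threshold_rule=threshold_rule, threshold=pts1_threshold,
                          min_area=puncta_min_area, name="pts1")
    pmp70 = segment_puncta(image.channels["pmp70"], sigma_smooth=sigma_smooth,
                           threshold_rule=threshold_rule, threshold=pmp70_threshold,
                           min_area=puncta_min_area, name="pmp70")
    calls = classify_peroxisomes(pmp70, pts1, min_overlap_fraction,
                                 n_nuclei=nuclei.n)
    frac = (calls.n_functional / calls.n_peroxisomes
            if calls.n_peroxisomes else np.nan)
    size = puncta_size_stats(pmp70, image.pixel_size)
    return {
        "n_functional": calls.n_functional,
        "n_ghost": calls.n_ghost,
        "n_peroxisomes": calls.n_peroxisomes,
        "functional_fraction": frac,
        "n_nuclei": nuclei.n,
        "puncta_per_cell": (calls.n_peroxisomes / nuclei.n if nuclei.n else np.nan),
        "mean_area_um2": size["mean_area_um2"],
    }
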