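"""Anchor-cell segmentation and polarity indices.

The dorso-ventral polarity index ``I_DV`` divides the segmented AC into
ventral and dorsal halves by a horizontal line through the AC nucleus
centre and takes the ratio of the mean intensities (ventral / dorsal), so
``I_DV > 1`` means ventral enrichment of the fluorescent signal.  The
anterior-posterior index ``I_AP`` splits the AC by a vertical line into
the halves proximal and distal to the nearest VPC, with the ratio oriented
so values > 1 mean proximal enrichment.

Pixels exactly on the split line belong to neither half (unbiased
tie-breaking); a line through the nucleus centroid need not split the mask
into equal areas, so results carry both half areas and an imbalance flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from vulquant.errors import (
    InfiniteIndexError,
    SegmentationError,
    UndefinedIndexError,
    VulquantError,
)
from vulquant.imaging import Projection
from vulquant.stats import bootstrap_mean, fisher_exact

log = logging.getLogger(__name__)

__all__ = [
    "ACMask",
    "AxisSplit",
    "PolarityResult",
    "segment_ac",
    "polarity_index",
    "classify_polarized",
    "fraction_polarized",
    "depolarization_crosstab",
    "compare_depolarization",
    "measure_polarity_stack",
    "LIGAND_THRESHOLD",
    "PIP2_THRESHOLD",
]

#: Default polarity-classification thresholds (approximately the 10th
#: percentile of the wild-type index distributions for each marker).
LIGAND_THRESHOLD = 1.1
PIP2_THRESHOLD = 1.2

#: Half areas differing by more than this fraction are flagged for review.
AREA_IMBALANCE_FLAG = 0.25


@dataclass
class ACMask:
    """Boolean AC footprint with the nucleus seed it was grown from."""

    pixels: np.ndarray
    seed_centroid: tuple[float, float]  # (y, x)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not self.pixels.any() or self.pixels.all():
            raise VulquantError(
                "AC mask must be non-empty and strictly smaller than the image"
            )

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class AxisSplit:
    """Polarity measurement along one axis (DV or AP)."""

    axis: str  # "DV" or "AP"
    index: float  # positive-half mean / negative-half mean
    positive_mean: float  # ventral (DV) or proximal (AP)
    negative_mean: float  # dorsal (DV) or distal (AP)
    positive_area: int
    negative_area: int
    area_imbalance_flag: bool


@dataclass(frozen=True)
class PolarityResult:
    """I_DV and I_AP with the half-compartment means they are built from."""

    i_dv: float | None = None
    i_ap: float | None = None
    ventral_mean: float | None = None
    dorsal_mean: float | None = None
    proximal_mean: float | None = None
    distal_mean: float | None = None
    marker: str = ""


def segment_ac(
    projection: Projection,
    seed_centroid: tuple[float, float],
    window_radius: int = 30,
    rim_fraction: float = 0.25,
) -> ACMask:
    """Segment the AC footprint by seeded local thresholding.

    An Otsu threshold is computed inside a square window of half-size
    ``window_radius`` around the seed (robust to other fluorescent cells in
    frame) and the seed must exceed it.  The final footprint threshold is
    relaxed to ``background + rim_fraction * (otsu - background)`` (with
    the background level estimated as the median of the sub-Otsu window
    pixels): a summed projection of a convex cell falls off gradually at
    the rim, and a strict Otsu cut through that graded rim removes rim
    pixels asymmetrically between the bright and dim halves, biasing the
    half-mean ratio toward 1.  The mask is the 8-connected component of
    the relaxed supra-threshold set containing the seed, holes filled.

    Raises
    ------
    SegmentationError
        If no pixel exceeds the threshold or the seed does not fall in a
        supra-threshold component; carries the threshold used.
    """
    img = np.asarray(projection.pixels, dtype=float)
    sy, sx = int(round(seed_centroid[0])), int(round(seed_centroid[1]))
    if not (0 <= sy < img.shape[0] and 0 <= sx < img.shape[1]):
        raise VulquantError(f"seed centroid {seed_centroid} outside image")
    if not 0 < rim_fraction <= 1:
        raise VulquantError(f"rim_fraction must be in (0, 1], got {rim_fraction}")
    y0, y1 = max(sy - window_radius, 0), min(sy + window_radius + 1, img.shape[0])
    x0, x1 = max(sx - window_radius, 0), min(sx + window_radius + 1, img.shape[1])
    window = img[y0:y1, x0:x1]
    if np.ptp(window) == 0:
        raise SegmentationError(
            "segmentation failure: window around seed is uniform", None
        )
    otsu = float(threshold_otsu(window))
    if img[sy, sx] <= otsu:
        raise SegmentationError(
            f"segmentation failure: seed pixel ({sy}, {sx}) below Otsu "
            f"threshold {otsu:.4g}", otsu,
        )
    below = window[window <= otsu]
    background = float(np.median(below)) if below.size else 0.0
    threshold = background + rim_fraction * (otsu - background)
    supra = img > threshold
    if not supra.any():
        raise SegmentationError(
            f"segmentation failure: no pixel above threshold "
            f"{threshold:.4g}", threshold,
        )
    labels = cc_label(supra, connectivity=2)
    seed_label = labels[sy, sx]
    if seed_label == 0:
        raise SegmentationError(
            f"segmentation failure: seed pixel ({sy}, {sx}) below "
            f"threshold {threshold:.4g}", threshold,
        )
    mask = ndimage.binary_fill_holes(labels == seed_label)
    return ACMask(mask, seed_centroid)


def _half_masks(
    mask: np.ndarray, split_centroid: tuple[float, float], axis: str
) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative half masks; on-line pixels excluded from both."""
    yy, xx = np.indices(mask.shape)
    if axis == "DV":
        coord, c = yy, split_centroid[0]
    elif axis == "AP":
        coord, c = xx, split_centroid[1]
    else:
        raise VulquantError(f"axis must be 'DV' or 'AP', got {axis!r}")
    return mask & (coord > c), mask & (coord < c)


def polarity_index(
    projection: Projection,
    mask: "ACMask | np.ndarray",
    split_centroid: tuple[float, float],
    axis: str = "DV",
    orientation: int = +1,
) -> AxisSplit:
    """Two-compartment mean-intensity ratio along one axis.

    The mask is split by the line through ``split_centroid`` (the AC
    nucleus centre) perpendicular to ``axis``.  With ``orientation=+1`` the
    positive half is increasing coordinate — ventral for DV under the
    package axis convention, posterior for AP.  Pass ``orientation=-1``
    when the proximal (nearest-VPC) side lies at decreasing x, so the
    returned index is always positive-half (= ventral or proximal) mean
    over negative-half (= dorsal or distal) mean.

    Raises
    ------
    UndefinedIndexError
        If either half contains no masked pixel.
    InfiniteIndexError
        If the denominator (dorsal/distal) mean is zero.
    """
    pix = np.asarray(projection.pixels, dtype=float)
    m = mask.pixels if isinstance(mask, ACMask) else np.asarray(mask, dtype=bool)
    if m.shape != pix.shape:
        raise VulquantError("mask and projection shapes differ")
    if orientation not in (+1, -1):
        raise VulquantError(f"orientation must be +1 or -1, got {orientation!r}")
    pos, neg = _half_masks(m, split_centroid, axis)
    if orientation == -1:
        pos, neg = neg, pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedIndexError(
            f"{axis} index undefined: half areas are {n_pos} and {n_neg} "
            "masked pixels"
        )
    pos_mean = float(pix[pos].mean())
    neg_mean = float(pix[neg].mean())
    if neg_mean == 0:
        raise InfiniteIndexError(
            f"{axis} index infinite: denominator half mean is zero"
        )
    imbalance = abs(n_pos - n_neg) / max(n_pos, n_neg)
    flagged = imbalance > AREA_IMBALANCE_FLAG
    if flagged:
        log.info(
            "%s split half areas %d / %d differ by %.0f%%; flagged",
            axis, n_pos, n_neg, 100 * imbalance,
        )
    return AxisSplit(
        axis=axis,
        index=pos_mean / neg_mean,
        positive_mean=pos_mean,
        negative_mean=neg_mean,
        positive_area=n_pos,
        negative_area=n_neg,
        area_imbalance_flag=flagged,
    )


def classify_polarized(index: float, threshold: float = LIGAND_THRESHOLD) -> bool:
    """True iff the polarity index strictly exceeds the threshold."""
    if not np.isfinite(index) or index <= 0:
        raise VulquantError(f"index must be finite and positive, got {index}")
    return index > threshold


def fraction_polarized(
    indices: "np.ndarray | list[float]",
    threshold: float = LIGAND_THRESHOLD,
    n_resamples: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, tuple[float, float]]:
    """Fraction of a cohort classified polarized, with a bootstrap 95% CI.

    The CI is the percentile bootstrap interval of the mean of the
    polarized-indicator variable.
    """
    arr = np.asarray(indices, dtype=float)
    if arr.size == 0:
        raise VulquantError("empty cohort")
    hits = (arr > threshold).astype(float)
    boot = bootstrap_mean(hits, n_resamples=n_resamples, seed=seed)
    return float(hits.mean()), boot.ci95


def measure_polarity_stack(
    stack,
    nucleus_centroid_zyx: tuple[float, float, float],
    proximal_direction: int = +1,
    window_radius: int = 30,
    marker: str = "",
) -> PolarityResult:
    """Full polarity measurement of one AC stack.

    Pipeline: summed z-projection over the whole stack, Otsu segmentation
    seeded at the nucleus centre, median background subtraction outside
    the mask, then I_DV and I_AP with the split lines through the nucleus
    centre.  ``proximal_direction=+1`` means the nearest VPC lies at
    increasing x (the AC sits anterior of it); pass -1 for the opposite
    case so I_AP stays proximal/distal.
    """
    from vulquant.imaging import subtract_background, sum_projection

    proj = sum_projection(stack)
    seed_yx = (nucleus_centroid_zyx[1], nucleus_centroid_zyx[2])
    mask = segment_ac(proj, seed_yx, window_radius=window_radius)
    proj = subtract_background(proj, mask.pixels)
    dv = polarity_index(proj, mask, seed_yx, axis="DV", orientation=+1)
    ap = polarity_index(proj, mask, seed_yx, axis="AP",
                        orientation=proximal_direction)
    return PolarityResult(
        i_dv=dv.index,
        i_ap=ap.index,
        ventral_mean=dv.positive_mean,
        dorsal_mean=dv.negative_mean,
        proximal_mean=ap.positive_mean,
        distal_mean=ap.negative_mean,
        marker=marker,
    )


def _classify_pairs(
    paired: "list[tuple[str, float, float]]",
    ligand_threshold: float,
    pip2_threshold: float,
) -> np.ndarray:
    bad = [
        aid for aid, lig, pip in paired
        if lig is None or pip is None
        or not (np.isfinite(lig) and np.isfinite(pip))
    ]
    if bad:
        raise VulquantError(f"unpaired polarity records for animals: {bad}")
    table = np.zeros((2, 2), dtype=int)
    for _, lig, pip in paired:
        table[0 if lig > ligand_threshold else 1,
              0 if pip > pip2_threshold else 1] += 1
    return table


def depolarization_crosstab(
    paired: "list[tuple[str, float, float]]",
    ligand_threshold: float = LIGAND_THRESHOLD,
    pip2_threshold: float = PIP2_THRESHOLD,
) -> np.ndarray:
    """2x2 cross-tabulation of per-animal polarity calls.

    ``paired`` holds ``(animal_id, ligand_i_dv, pip2_i_dv)`` per animal.
    Rows: ligand polarized / depolarized; columns: PIP2 polarized /
    depolarized.  The bottom-right cell counts animals depolarized in both
    channels.
    """
    return _classify_pairs(paired, ligand_threshold, pip2_threshold)


def compare_depolarization(
    cohort_a: "list[tuple[str, float, float]]",
    cohort_b: "list[tuple[str, float, float]]",
    ligand_threshold: float = LIGAND_THRESHOLD,
    pip2_threshold: float = PIP2_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fisher's exact comparison of the both-depolarized fractions.

    Returns the per-cohort 2x2 cross-tabs and the two-sided Fisher p for
    the 2x2 table (both-depolarized vs rest) across the two cohorts.
    """
    ta = _classify_pairs(cohort_a, ligand_threshold, pip2_threshold)
    tb = _classify_pairs(cohort_b, ligand_threshold, pip2_threshold)
    both_a, both_b = int(ta[1, 1]), int(tb[1, 1])
    contingency = np.array(
        [[both_a, int(ta.sum()) - both_a], [both_b, int(tb.sum()) - both_b]]
    )
    return ta, tb, fisher_exact(contingency)
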