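"""ERK-KTR biosensor quantification per vulval precursor cell.

MPK-1 (ERK) activity drives nuclear export of the KTR::mClover sensor, so
activity is read out as the nuclear mCherry::H2B (red) mean intensity
divided by the nuclear KTR::mClover (green) mean — higher ratio, higher
activity.  Ratios are measured in summed projections of the five central
slices around the H2B focus, on a nucleus mask segmented from the red
channel only (the green signal varies with activity) and applied
identically to both channels.  P3.p is excluded structurally: it adopts a
VPC fate in only about half of all animals.

Per animal, each VPC's ratio is normalized to the mean of the P4.p–P8.p
ratios of the same animal, so normalized profiles average to exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from vulquant.errors import VulquantError
from vulquant.imaging import ImageStack, central_slices, sum_projection
from vulquant.polarity import segment_ac
from vulquant.stats import bootstrap_mean
from vulquant.synthgen import BIOSENSOR_VPCS

log = logging.getLogger(__name__)

__all__ = [
    "BiosensorProfile",
    "measure_nuclear_ratio",
    "normalize_profile",
    "call_highest_p6p",
    "cohort_highest_fraction",
    "profile_from_stacks",
]


@dataclass
class BiosensorProfile:
    """Per-VPC nuclear red/green ratios for one animal (P4.p–P8.p)."""

    animal_id: str
    red_means: dict[str, float]
    green_means: dict[str, float]
    ratios: dict[str, float]
    normalized_ratios: dict[str, float]

    @property
    def highest_is_p6p(self) -> bool:
        return call_highest_p6p(self)


def measure_nuclear_ratio(
    red_stack: ImageStack,
    green_stack: ImageStack,
    nucleus_centroid: tuple[float, float],
    focus_z: int,
    k_slices: int = 5,
    window_radius: int = 12,
) -> tuple[float, float, float]:
    """Nuclear (red mean, green mean, red/green ratio) at one VPC.

    Both channels are summed over the ``k_slices`` central slices around
    ``focus_z``; the nucleus mask is the Otsu component of the red (H2B)
    projection containing ``nucleus_centroid`` and is applied unchanged to
    the green projection.
    """
    if red_stack.shape != green_stack.shape:
        raise VulquantError(
            f"channel shapes differ: {red_stack.shape} vs {green_stack.shape}"
        )
    z_range = central_slices(red_stack, focus_z, k_slices)
    red_proj = sum_projection(red_stack, z_range)
    green_proj = sum_projection(green_stack, z_range)
    mask = segment_ac(red_proj, nucleus_centroid, window_radius=window_radius)
    red_mean = float(red_proj.pixels[mask.pixels].mean())
    green_mean = float(green_proj.pixels[mask.pixels].mean())
    if green_mean == 0:
        raise VulquantError("nuclear green mean is zero; ratio undefined")
    return red_mean, green_mean, red_mean / green_mean


def normalize_profile(ratios: dict[str, float]) -> dict[str, float]:
    """Divide each VPC's ratio by the P4.p–P8.p mean of the same animal.

    The output averages to exactly 1; normalizing twice equals normalizing
    once (idempotent up to the scalar already applied).
    """
    missing = [lbl for lbl in BIOSENSOR_VPCS if lbl not in ratios]
    if missing:
        raise VulquantError(f"missing VPC ratio(s): {missing}")
    values = np.array([ratios[lbl] for lbl in BIOSENSOR_VPCS], dtype=float)
    if np.any(values <= 0):
        raise VulquantError("all ratios must be strictly positive")
    mean = values.mean()
    return {lbl: float(ratios[lbl] / mean) for lbl in BIOSENSOR_VPCS}


def call_highest_p6p(profile: "BiosensorProfile | dict[str, float]") -> bool:
    """True iff P6.p's normalized ratio is the strict maximum.

    Exact ties with P6.p are counted as not-highest (conservative) and
    logged.
    """
    ratios = (
        profile.normalized_ratios
        if isinstance(profile, BiosensorProfile)
        else profile
    )
    p6 = ratios["P6.p"]
    others = [ratios[lbl] for lbl in BIOSENSOR_VPCS if lbl != "P6.p"]
    top = max(others)
    if p6 == top:
        log.info("P6.p tied for the maximum ratio; counted as not highest")
        return False
    return p6 > top


def cohort_highest_fraction(
    profiles: "list[BiosensorProfile]",
    n_resamples: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, tuple[float, float]]:
    """Fraction of animals with highest activity in P6.p, with 95% CI.

    The CI is a percentile bootstrap over the per-animal boolean calls.
    """
    if not profiles:
        raise VulquantError("empty biosensor cohort")
    calls = np.array([p.highest_is_p6p for p in profiles], dtype=float)
    boot = bootstrap_mean(calls, n_resamples=n_resamples, seed=seed)
    return float(calls.mean()), boot.ci95


def profile_from_stacks(
    red_stack: ImageStack,
    green_stack: ImageStack,
    nucleus_centroids: dict[str, tuple[float, float]],
    focus_z: int,
    animal_id: str = "",
    k_slices: int = 5,
    window_radius: int = 12,
) -> BiosensorProfile:
    """Measure and normalize the full P4.p–P8.p profile of one animal."""
    red_means: dict[str, float] = {}
    green_means: dict[str, float] = {}
    ratios: dict[str, float] = {}
    for lbl in BIOSENSOR_VPCS:
        if lbl not in nucleus_centroids:
            raise VulquantError(f"{animal_id}: no centroid for {lbl}")
        r, g, ratio = measure_nuclear_ratio(
            red_stack, green_stack, nucleus_centroids[lbl], focus_z,
            k_slices=k_slices, window_radius=window_radius,
        )
        red_means[lbl], green_means[lbl], ratios[lbl] = r, g, ratio
    return BiosensorProfile(
        animal_id=animal_id,
        red_means=red_means,
        green_means=green_means,
        ratios=ratios,
        normalized_ratios=normalize_profile(ratios),
    )
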