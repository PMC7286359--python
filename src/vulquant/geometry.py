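"""Animal staging and anchor-cell-to-VPC alignment geometry.

The anchor cell (AC) normally sits directly over P6.p, the vulval
precursor cell (VPC) that adopts the primary fate.  The alignment index

    R = d(AC, target VPC) / d(target VPC, reference VPC)

with reference P5.p when the AC lies anterior of the target and P7.p when
posterior, measures how far the AC has migrated toward alignment: R = 0
means the AC is directly over the target; R = 0.5 puts it at the midpoint
between target and reference.  Developmental stage is assigned from gonad
length.  All distances are centroid-to-centroid Euclidean distances in the
projection plane, in micrometres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from vulquant.errors import DegenerateInputError, GeometryError

log = logging.getLogger(__name__)

__all__ = [
    "VPC_LABELS",
    "AnnotatedAnimal",
    "AlignmentResult",
    "stage_from_gonad_length",
    "alignment_index",
    "classify_alignment",
    "nearest_vpc",
    "correlate_polarity_alignment",
]

#: Anterior-to-posterior order of the vulval precursor cells.
VPC_LABELS = ("P3.p", "P4.p", "P5.p", "P6.p", "P7.p", "P8.p")

# Staging bins (gonad length, µm) — half-open lower-inclusive, with the
# upper end of the last bin closed at 150 µm.
_STAGE_BINS = (
    (30.0, 70.0, "early/mid-L2"),
    (70.0, 110.0, "late-L2"),
    (110.0, 150.0, "early/mid-L3"),
)


@dataclass
class AnnotatedAnimal:
    """One animal's annotation record.

    Centroids are ``(y, x)`` in pixel coordinates of the projection plane;
    ``pixel_size`` converts them to micrometres (isotropic in-plane pixels
    are assumed for distance measurements).  ``induced_count`` is the
    number of VPCs that adopted a vulval fate (steps of 0.5; at most 6).
    """

    animal_id: str
    genotype: str = "wild-type"
    gonad_length: float | None = None  # µm
    ac_centroid: tuple[float, float] | None = None  # (y, x) pixels
    vpc_centroids: dict[str, tuple[float, float]] = field(default_factory=dict)
    pixel_size: float = 1.0  # µm per pixel in the projection plane
    induced_count: float | None = None
    primary_fate_vpc: str | None = None
    stacks: dict[str, object] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.vpc_centroids) - set(VPC_LABELS)
        if unknown:
            raise GeometryError(f"unknown VPC labels: {sorted(unknown)}")
        # Anterior = decreasing x: P3.p ... P8.p must be strictly x-ordered.
        xs = [self.vpc_centroids[lbl][1] for lbl in VPC_LABELS
              if lbl in self.vpc_centroids]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise GeometryError(
                f"{self.animal_id}: VPC x-coordinates must be strictly "
                "increasing from P3.p (anterior) to P8.p (posterior)"
            )
        if self.induced_count is not None:
            if not 0 <= self.induced_count <= 6:
                raise GeometryError(
                    f"{self.animal_id}: induced_count {self.induced_count} "
                    "outside [0, 6]"
                )
            if (2 * self.induced_count) % 1 != 0:
                raise GeometryError(
                    f"{self.animal_id}: induced_count must be a multiple "
                    f"of 0.5, got {self.induced_count}"
                )


@dataclass(frozen=True)
class AlignmentResult:
    """Alignment index R and the geometry it was computed from."""

    r_index: float
    nearest_vpc: str
    reference_vpc: str
    d_ac_vpc: float  # µm
    d_ref: float  # µm
    target_vpc: str = "P6.p"


def stage_from_gonad_length(length_um: float) -> str:
    """Developmental stage label from gonad length in micrometres.

    Bins: [30, 70) early/mid-L2, [70, 110) late-L2, [110, 150]
    early/mid-L3; lengths outside [30, 150] map to ``"out-of-range"``.
    """
    if length_um <= 0:
        raise GeometryError(f"gonad length must be positive, got {length_um}")
    for lo, hi, label in _STAGE_BINS:
        if lo <= length_um < hi:
            return label
    if length_um == _STAGE_BINS[-1][1]:
        return _STAGE_BINS[-1][2]
    return "out-of-range"


def _dist_um(a: tuple[float, float], b: tuple[float, float], px: float) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1])) * px


def alignment_index(animal: AnnotatedAnimal, target_vpc: str = "P6.p") -> AlignmentResult:
    """Alignment index R of the AC relative to ``target_vpc``.

    The reference for the denominator is the anterior neighbour (P5.p for
    target P6.p) when the AC lies anterior of the target (smaller x), the
    posterior neighbour otherwise; an exact tie in x resolves to the
    anterior neighbour and is logged.
    """
    if animal.ac_centroid is None:
        raise GeometryError(f"{animal.animal_id}: no AC centroid annotated")
    if target_vpc not in animal.vpc_centroids:
        raise GeometryError(f"{animal.animal_id}: {target_vpc} not annotated")
    idx = VPC_LABELS.index(target_vpc)
    ac = animal.ac_centroid
    target = animal.vpc_centroids[target_vpc]

    if ac[1] <= target[1]:  # AC anterior of (or tied with) the target
        ref_label = VPC_LABELS[idx - 1] if idx > 0 else None
        if ac[1] == target[1]:
            log.info(
                "%s: AC exactly at target x; anterior reference %s used",
                animal.animal_id, ref_label,
            )
    else:
        ref_label = VPC_LABELS[idx + 1] if idx + 1 < len(VPC_LABELS) else None
    if ref_label is None or ref_label not in animal.vpc_centroids:
        raise GeometryError(
            f"{animal.animal_id}: reference VPC "
            f"{ref_label or 'beyond the VPC row'} missing for target "
            f"{target_vpc}"
        )
    d_ac = _dist_um(ac, target, animal.pixel_size)
    d_ref = _dist_um(target, animal.vpc_centroids[ref_label], animal.pixel_size)
    return AlignmentResult(
        r_index=d_ac / d_ref,
        nearest_vpc=nearest_vpc(animal),
        reference_vpc=ref_label,
        d_ac_vpc=d_ac,
        d_ref=d_ref,
        target_vpc=target_vpc,
    )


def classify_alignment(
    result: AlignmentResult,
    misaligned_threshold: float = 0.4,
    unaligned_floor: float = 0.09,
) -> str:
    """Categorise an alignment result.

    ``aligned`` if R <= 0.09, ``pre-aligned`` if 0.09 < R <= 0.4,
    ``misaligned`` if R > 0.4 (strict comparisons).
    """
    r = result.r_index
    if r > misaligned_threshold:
        return "misaligned"
    if r > unaligned_floor:
        return "pre-aligned"
    return "aligned"


def nearest_vpc(animal: AnnotatedAnimal) -> str:
    """Label of the VPC nearest the AC (exact tie -> the more anterior)."""
    if animal.ac_centroid is None:
        raise GeometryError(f"{animal.animal_id}: no AC centroid annotated")
    if len(animal.vpc_centroids) < 2:
        raise GeometryError(
            f"{animal.animal_id}: need >= 2 annotated VPCs, have "
            f"{len(animal.vpc_centroids)}"
        )
    dists = {
        lbl: _dist_um(animal.ac_centroid, c, animal.pixel_size)
        for lbl, c in animal.vpc_centroids.items()
    }
    best = min(dists.values())
    winners = [lbl for lbl in VPC_LABELS if lbl in dists and dists[lbl] == best]
    if len(winners) > 1:
        log.info(
            "%s: AC equidistant from %s; anterior %s chosen",
            animal.animal_id, winners, winners[0],
        )
    return winners[0]


def correlate_polarity_alignment(
    pairs: "np.ndarray | list[tuple[float, float]]",
) -> tuple[float, float]:
    """Spearman rank correlation between I_AP and R over a cohort.

    ``pairs`` is a sequence of ``(i_ap, r_index)`` per animal.  A negative
    coefficient indicates that ligand polarity toward the nearest VPC
    increases as the AC approaches alignment.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise GeometryError("need >= 3 (i_ap, r_index) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise DegenerateInputError(
            "rank correlation undefined: one variable is constant"
        )
    rho, p = sps.spearmanr(arr[:, 0], arr[:, 1])
    return float(rho), float(p)
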