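"""Synthetic microscopy and cohort generation with known ground truth.

The generator emulates the study geometry at desk scale:

* a polarized anchor cell as an ellipsoid of elevated intensity over
  background, with intracellular punctae, Poisson shot noise and Gaussian
  read noise.  Polarization is a two-compartment step in expected
  intensity — the quantity the polarity indices measure is a
  two-compartment mean ratio, so the step (not a gradient) is the
  reference construction.  Per-compartment factors are solved on the
  rasterized ellipsoid so that the noiseless ventral/dorsal and
  posterior/anterior mean-intensity ratios equal the requested ``rho_dv``
  and ``rho_ap`` to machine precision;
* annotated animals with the P3.p–P8.p row collinear along the AP axis and
  a configurable AC offset, with the true alignment index recorded;
* two-channel biosensor images in which higher ERK activity lowers the
  nuclear green (KTR export) while the red H2B reference is unchanged, so
  the nuclear red/green ratio equals the injected activity;
* cohorts of per-animal vulval fate patterns with configurable phenotype
  probabilities.

Every generator is a pure function of its parameters and seed: identical
inputs give bit-identical outputs.  Axis convention: arrays (z, y, x);
ventral = increasing y; anterior = decreasing x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from vulquant.errors import VulquantError
from vulquant.geometry import AnnotatedAnimal, alignment_index
from vulquant.imaging import ImageStack
from vulquant.polarity import PolarityResult

__all__ = [
    "ACStackParams",
    "LayoutParams",
    "BiosensorImageParams",
    "CohortParams",
    "generate_ac_stack",
    "generate_animal",
    "generate_biosensor_image",
    "generate_induction_cohort",
    "write_animal",
    "read_annotation",
    "BIOSENSOR_VPCS",
]

#: VPCs carried by the biosensor generator and profile (P3.p excluded).
BIOSENSOR_VPCS = ("P4.p", "P5.p", "P6.p", "P7.p", "P8.p")


@dataclass(frozen=True)
class ACStackParams:
    """Parameters of one synthetic anchor-cell stack.

    ``rho_dv`` is the true ventral/dorsal mean-intensity ratio of the
    noiseless signal inside the AC ellipsoid; ``rho_ap`` the analogous
    posterior/anterior (nearest-VPC-directed) ratio.  Intensities are in
    photons; noise is Poisson on signal + background followed by additive
    Gaussian read noise.
    """

    shape_zyx: tuple[int, int, int] = (26, 72, 72)
    voxel_size: tuple[float, float, float] = (0.13, 0.1, 0.1)  # µm
    ac_center: tuple[float, float, float] = (13.0, 36.0, 36.0)  # voxels
    ac_radii: tuple[float, float, float] = (9.0, 14.0, 14.0)  # voxels
    base_intensity: float = 200.0
    rho_dv: float = 1.0
    rho_ap: float = 1.0
    n_punctae: int = 10
    puncta_amplitude: float = 100.0
    puncta_sigma: float = 1.2  # voxels
    background: float = 10.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho_dv <= 0 or self.rho_ap <= 0:
            raise VulquantError("rho_dv and rho_ap must be strictly positive")
        if any(r <= 0 for r in self.ac_radii):
            raise VulquantError("ellipsoid radii must be strictly positive")
        if self.background < 0 or self.gaussian_noise_sd < 0:
            raise VulquantError("background and noise SD must be >= 0")
        if self.n_punctae < 0:
            raise VulquantError("n_punctae must be >= 0")
        for axis, dim, c, r in zip(
            "zyx", self.shape_zyx, self.ac_center, self.ac_radii
        ):
            if c - r < 0 or c + r > dim - 1:
                raise VulquantError(
                    f"ellipsoid exceeds the volume along the {axis} axis: "
                    f"center {c} ± {r} outside [0, {dim - 1}]"
                )


def _ellipsoid_mask(params: ACStackParams) -> np.ndarray:
    zz, yy, xx = np.indices(params.shape_zyx, dtype=float)
    cz, cy, cx = params.ac_center
    rz, ry, rx = params.ac_radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + (
        (xx - cx) / rx
    ) ** 2 <= 1.0


def _step_field(params: ACStackParams, mask: np.ndarray) -> np.ndarray:
    """Relative intensity field with exact rasterized compartment ratios.

    Multiplicative ventral/dorsal and posterior/anterior step factors,
    refined by fixed-point iteration until the measured voxel-mean ratios
    on the discrete mask equal rho_dv / rho_ap (voxels exactly on a split
    plane carry factor 1 and belong to neither compartment).
    """
    _, yy, xx = np.indices(params.shape_zyx, dtype=float)
    _, cy, cx = params.ac_center
    ventral, dorsal = mask & (yy > cy), mask & (yy < cy)
    post, ant = mask & (xx > cx), mask & (xx < cx)
    for name, half in [("ventral", ventral), ("dorsal", dorsal),
                       ("posterior", post), ("anterior", ant)]:
        if not half.any():
            raise VulquantError(f"rasterized ellipsoid has an empty {name} half")
    ru, rw = params.rho_dv, params.rho_ap
    for _ in range(100):
        u = np.where(yy > cy, np.sqrt(ru), np.where(yy < cy, 1 / np.sqrt(ru), 1.0))
        w = np.where(xx > cx, np.sqrt(rw), np.where(xx < cx, 1 / np.sqrt(rw), 1.0))
        rel = u * w
        m_dv = rel[ventral].mean() / rel[dorsal].mean()
        m_ap = rel[post].mean() / rel[ant].mean()
        if (abs(m_dv - params.rho_dv) <= 1e-13 * params.rho_dv
                and abs(m_ap - params.rho_ap) <= 1e-13 * params.rho_ap):
            break
        ru *= params.rho_dv / m_dv
        rw *= params.rho_ap / m_ap
    return rel


def _sample_in_ellipsoid(rng: np.random.Generator, params: ACStackParams) -> np.ndarray:
    """One point uniform inside the ellipsoid (rejection sampling)."""
    c = np.asarray(params.ac_center)
    r = np.asarray(params.ac_radii)
    while True:
        p = rng.uniform(-1.0, 1.0, size=3)
        if (p**2).sum() <= 1.0:
            return c + p * r


def generate_ac_stack(params: ACStackParams) -> tuple[ImageStack, PolarityResult]:
    """Synthesize one anchor-cell stack and its noiseless ground truth.

    The ground truth reports the compartment means and ratios of the
    noiseless signal (ellipsoid step field plus punctae, no background):
    exactly the quantity a background-subtracted polarity measurement
    estimates.
    """
    rng = np.random.default_rng(params.seed)
    mask = _ellipsoid_mask(params)
    if params.rho_dv == 1.0 and params.rho_ap == 1.0:
        signal = params.base_intensity * mask.astype(float)
    else:
        signal = params.base_intensity * _step_field(params, mask) * mask

    if params.n_punctae > 0 and params.puncta_amplitude != 0:
        zz, yy, xx = np.indices(params.shape_zyx, dtype=float)
        blobs = np.zeros(params.shape_zyx)
        for _ in range(params.n_punctae):
            pz, py, px = _sample_in_ellipsoid(rng, params)
            d2 = (zz - pz) ** 2 + (yy - py) ** 2 + (xx - px) ** 2
            blobs += params.puncta_amplitude * np.exp(
                -d2 / (2.0 * params.puncta_sigma**2)
            )
        signal = signal + blobs * mask  # punctae confined to the AC

    _, yy, xx = np.indices(params.shape_zyx, dtype=float)
    _, cy, cx = params.ac_center
    ventral_mean = float(signal[mask & (yy > cy)].mean())
    dorsal_mean = float(signal[mask & (yy < cy)].mean())
    post_mean = float(signal[mask & (xx > cx)].mean())
    ant_mean = float(signal[mask & (xx < cx)].mean())
    truth = PolarityResult(
        i_dv=ventral_mean / dorsal_mean,
        i_ap=post_mean / ant_mean,
        ventral_mean=ventral_mean,
        dorsal_mean=dorsal_mean,
        proximal_mean=post_mean,
        distal_mean=ant_mean,
        marker="synthetic-ligand",
    )

    image = signal + params.background
    if params.poisson_noise:
        image = rng.poisson(image).astype(float)
    if params.gaussian_noise_sd > 0:
        image = image + rng.normal(0.0, params.gaussian_noise_sd, image.shape)
    image = np.clip(image, 0.0, None)
    return ImageStack(image, params.voxel_size, "synthetic-ligand"), truth


@dataclass(frozen=True)
class LayoutParams:
    """Annotation-plane layout of the VPC row and the AC.

    Coordinates are pixels in the projection plane (``pixel_size_um`` per
    pixel); the VPC row is collinear along x (anterior = decreasing x).
    The AC offset is relative to P6.p: negative ``ac_dx_px`` displaces the
    AC anteriorly, negative ``ac_dy_px`` dorsally.  With jitter > 0 the
    offsets are drawn uniformly from ± the jitter around the fixed offset.
    """

    vpc_spacing_px: float = 77.0  # ~10 µm at 0.13 µm/px
    vpc_row_y_px: float = 120.0
    first_vpc_x_px: float = 40.0  # P3.p
    ac_dx_px: float = 0.0
    ac_dy_px: float = 0.0
    ac_dx_jitter_px: float = 0.0
    ac_dy_jitter_px: float = 0.0
    pixel_size_um: float = 0.13
    gonad_length_um: float = 90.0

    def __post_init__(self) -> None:
        if self.vpc_spacing_px <= 0:
            raise VulquantError("VPC spacing must be strictly positive")
        if self.gonad_length_um <= 0:
            raise VulquantError("gonad length must be strictly positive")


def generate_animal(
    stack_params: ACStackParams | None = None,
    layout_params: LayoutParams | None = None,
    seed: int = 0,
    animal_id: str | None = None,
    genotype: str = "wild-type",
) -> AnnotatedAnimal:
    """One annotated animal: VPC row geometry plus an AC ligand stack.

    The AC stack (a zoomed crop around the AC, generated with a seed
    derived from ``seed``) is attached under ``stacks["ligand"]``; the
    annotation-plane centroids and the true alignment index R, polarity
    ratios and stage geometry go to ``ground_truth``.
    """
    layout = layout_params or LayoutParams()
    sp = stack_params or ACStackParams()
    rng = np.random.default_rng(seed)
    dx, dy = layout.ac_dx_px, layout.ac_dy_px
    if layout.ac_dx_jitter_px > 0:
        dx += rng.uniform(-layout.ac_dx_jitter_px, layout.ac_dx_jitter_px)
    if layout.ac_dy_jitter_px > 0:
        dy += rng.uniform(-layout.ac_dy_jitter_px, layout.ac_dy_jitter_px)

    from vulquant.geometry import VPC_LABELS  # avoid cycle at import time

    vpcs = {
        lbl: (layout.vpc_row_y_px, layout.first_vpc_x_px + i * layout.vpc_spacing_px)
        for i, lbl in enumerate(VPC_LABELS)
    }
    p6y, p6x = vpcs["P6.p"]
    stack_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    stack, truth = generate_ac_stack(replace(sp, seed=stack_seed))
    animal = AnnotatedAnimal(
        animal_id=animal_id or f"sim{seed:06d}",
        genotype=genotype,
        gonad_length=layout.gonad_length_um,
        ac_centroid=(p6y + dy, p6x + dx),
        vpc_centroids=vpcs,
        pixel_size=layout.pixel_size_um,
        stacks={"ligand": stack},
    )
    animal.ground_truth = {
        "rho_dv": sp.rho_dv,
        "rho_ap": sp.rho_ap,
        "polarity": truth,
        "R_true": alignment_index(animal).r_index,
        "ac_center_zyx": sp.ac_center,
        "stack_seed": stack_seed,
    }
    return animal


@dataclass(frozen=True)
class BiosensorImageParams:
    """Geometry and noise of the two-channel biosensor image.

    Five nuclei (P4.p–P8.p) sit in a row at the focal plane.  The red
    (H2B) nuclear amplitude is activity-independent; the green (KTR)
    amplitude is ``green_amplitude / activity``, emulating activity-driven
    nuclear export, so the noiseless nuclear red/green mean ratio equals
    the injected activity exactly when ``red_amplitude == green_amplitude``.
    """

    shape_zyx: tuple[int, int, int] = (9, 48, 180)
    voxel_size: tuple[float, float, float] = (0.13, 0.16, 0.16)
    nucleus_spacing_px: float = 30.0
    nucleus_row_y_px: float = 24.0
    first_nucleus_x_px: float = 30.0
    nucleus_radius_px: float = 6.0
    red_amplitude: float = 150.0
    green_amplitude: float = 150.0
    background: float = 4.0
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True


def _nucleus_profile(params: BiosensorImageParams) -> np.ndarray:
    """Shared nuclear intensity profile: a soft-edged ball at focus."""
    zz, yy, xx = np.indices(params.shape_zyx, dtype=float)
    focus_z = (params.shape_zyx[0] - 1) / 2.0
    profile = np.zeros(params.shape_zyx)
    for i in range(len(BIOSENSOR_VPCS)):
        cx = params.first_nucleus_x_px + i * params.nucleus_spacing_px
        r2 = (
            ((zz - focus_z) / (params.nucleus_radius_px * 0.6)) ** 2
            + ((yy - params.nucleus_row_y_px) / params.nucleus_radius_px) ** 2
            + ((xx - cx) / params.nucleus_radius_px) ** 2
        )
        profile += np.exp(-(r2**3))  # near-flat core, steep rim
    return profile


def generate_biosensor_image(
    activity: "np.ndarray | list[float]",
    params: BiosensorImageParams | None = None,
    seed: int = 0,
    animal_id: str | None = None,
    genotype: str = "wild-type",
) -> tuple[ImageStack, ImageStack, AnnotatedAnimal]:
    """Red (H2B) and green (KTR) stacks for an injected activity vector.

    ``activity`` covers P4.p–P8.p in anterior-to-posterior order; all
    values must be strictly positive (a KTR ratio is a positive quantity).
    Per-channel noise seeds are split deterministically from ``seed``.
    """
    p = params or BiosensorImageParams()
    act = np.asarray(activity, dtype=float)
    if act.shape != (len(BIOSENSOR_VPCS),):
        raise VulquantError(
            f"activity must cover {BIOSENSOR_VPCS} "
            f"({len(BIOSENSOR_VPCS)} values); got shape {act.shape}"
        )
    if np.any(act <= 0):
        raise VulquantError("activities must be strictly positive")

    zz, yy, xx = np.indices(p.shape_zyx, dtype=float)
    focus_z = (p.shape_zyx[0] - 1) / 2.0
    red = np.zeros(p.shape_zyx)
    green = np.zeros(p.shape_zyx)
    centroids: dict[str, tuple[float, float]] = {}
    for i, lbl in enumerate(BIOSENSOR_VPCS):
        cx = p.first_nucleus_x_px + i * p.nucleus_spacing_px
        r2 = (
            ((zz - focus_z) / (p.nucleus_radius_px * 0.6)) ** 2
            + ((yy - p.nucleus_row_y_px) / p.nucleus_radius_px) ** 2
            + ((xx - cx) / p.nucleus_radius_px) ** 2
        )
        profile = np.exp(-(r2**3))
        red += p.red_amplitude * profile
        green += (p.green_amplitude / act[i]) * profile
        centroids[lbl] = (p.nucleus_row_y_px, cx)

    red_rng, green_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    ]

    def _apply_noise(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = img + p.background
        if p.poisson_noise:
            out = rng.poisson(out).astype(float)
        if p.gaussian_noise_sd > 0:
            out = out + rng.normal(0.0, p.gaussian_noise_sd, out.shape)
        return np.clip(out, 0.0, None)

    red_stack = ImageStack(_apply_noise(red, red_rng), p.voxel_size, "mCherry::H2B")
    green_stack = ImageStack(
        _apply_noise(green, green_rng), p.voxel_size, "ERK-nKTR::mClover"
    )
    animal = AnnotatedAnimal(
        animal_id=animal_id or f"ktr{seed:06d}",
        genotype=genotype,
        vpc_centroids=centroids,
        pixel_size=p.voxel_size[2],
        stacks={"red": red_stack, "green": green_stack},
    )
    animal.ground_truth = {
        "activity": act.tolist(),
        "focus_z": int(round(focus_z)),
    }
    return red_stack, green_stack, animal


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_VPC_COLUMN = {
    "P3.p": "p3p", "P4.p": "p4p", "P5.p": "p5p",
    "P6.p": "p6p", "P7.p": "p7p", "P8.p": "p8p",
}
_COLUMN_VPC = {v: k for k, v in _VPC_COLUMN.items()}


def write_animal(animal: AnnotatedAnimal, outdir) -> dict[str, "object"]:
    """Write one animal's stacks, annotation table and ground-truth sidecar.

    Emits ``<id>_<channel>.tif`` per attached stack (with calibration
    sidecars), ``<id>_annotation.tsv`` (one wide row: identity, stage
    fields, centroids in pixel coordinates, gonad length, induction) and
    ``<id>_groundtruth.json`` with the generator's true parameter values.
    Returns the paths written, keyed by role.
    """
    import json
    from pathlib import Path

    import pandas as pd

    from vulquant.geometry import stage_from_gonad_length
    from vulquant.imaging import write_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    for channel, stack in animal.stacks.items():
        p = outdir / f"{animal.animal_id}_{channel}.tif"
        write_stack(stack, p)
        paths[f"stack:{channel}"] = p

    row: dict[str, object] = {
        "animal_id": animal.animal_id,
        "genotype": animal.genotype,
        "gonad_length_um": animal.gonad_length,
        "stage": (
            stage_from_gonad_length(animal.gonad_length)
            if animal.gonad_length else ""
        ),
        "pixel_size_um": animal.pixel_size,
        "ac_y": animal.ac_centroid[0] if animal.ac_centroid else None,
        "ac_x": animal.ac_centroid[1] if animal.ac_centroid else None,
        "induced_count": animal.induced_count,
        "primary_fate_vpc": animal.primary_fate_vpc,
    }
    for lbl, col in _VPC_COLUMN.items():
        c = animal.vpc_centroids.get(lbl)
        row[f"{col}_y"], row[f"{col}_x"] = (c if c else (None, None))
    ann_path = outdir / f"{animal.animal_id}_annotation.tsv"
    pd.DataFrame([row]).to_csv(ann_path, sep="\t", index=False)
    paths["annotation"] = ann_path

    truth = {k: v for k, v in animal.ground_truth.items() if k != "polarity"}
    pol = animal.ground_truth.get("polarity")
    if pol is not None:
        truth["i_dv_true"] = pol.i_dv
        truth["i_ap_true"] = pol.i_ap
    gt_path = outdir / f"{animal.animal_id}_groundtruth.json"
    gt_path.write_text(json.dumps({"animal_id": animal.animal_id, **truth},
                                  indent=1, default=str))
    paths["ground_truth"] = gt_path
    return paths


def read_annotation(path) -> AnnotatedAnimal:
    """Read one animal's annotation table written by :func:`write_animal`."""
    import pandas as pd

    row = pd.read_csv(path, sep="\t").iloc[0]

    def _opt(key):
        v = row.get(key)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    vpcs = {}
    for col, lbl in _COLUMN_VPC.items():
        y, x = _opt(f"{col}_y"), _opt(f"{col}_x")
        if y is not None and x is not None:
            vpcs[lbl] = (float(y), float(x))
    ac = (
        (float(row["ac_y"]), float(row["ac_x"]))
        if _opt("ac_y") is not None else None
    )
    return AnnotatedAnimal(
        animal_id=str(row["animal_id"]),
        genotype=str(row["genotype"]),
        gonad_length=(None if _opt("gonad_length_um") is None
                      else float(row["gonad_length_um"])),
        ac_centroid=ac,
        vpc_centroids=vpcs,
        pixel_size=float(row.get("pixel_size_um", 1.0)),
        induced_count=(None if _opt("induced_count") is None
                       else float(row["induced_count"])),
        primary_fate_vpc=(None if _opt("primary_fate_vpc") is None
                          else str(row["primary_fate_vpc"])),
    )


# ---------------------------------------------------------------------------
# Fate-pattern cohorts
# ---------------------------------------------------------------------------

#: Default per-pattern distribution over induced-cell counts.
DEFAULT_COUNT_DISTRIBUTIONS: dict[str, dict[float, float]] = {
    "wild-type": {3.0: 1.0},
    "hyperinduced": {3.5: 0.3, 4.0: 0.4, 4.5: 0.15, 5.0: 0.1, 6.0: 0.05},
    "hypo-induced": {2.5: 0.3, 2.0: 0.4, 1.5: 0.15, 1.0: 0.1, 0.0: 0.05},
    "shifted": {3.0: 1.0},
}


@dataclass(frozen=True)
class CohortParams:
    """Size and fate-pattern composition of a scored cohort."""

    n_animals: int = 50
    fate_pattern_probs: dict[str, float] = field(
        default_factory=lambda: {"wild-type": 1.0}
    )
    induced_count_distribution: dict[str, dict[float, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COUNT_DISTRIBUTIONS.items()
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise VulquantError("n_animals must be >= 1")
        if abs(sum(self.fate_pattern_probs.values()) - 1.0) > 1e-9:
            raise VulquantError("fate pattern probabilities must sum to 1")
        unknown = set(self.fate_pattern_probs) - set(self.induced_count_distribution)
        if unknown:
            raise VulquantError(
                f"no induced-count distribution for patterns {sorted(unknown)}"
            )
        for pattern, dist in self.induced_count_distribution.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise VulquantError(
                    f"induced-count probabilities for {pattern!r} must sum to 1"
                )
            for count in dist:
                if not (0 <= count <= 6) or (2 * count) % 1 != 0:
                    raise VulquantError(
                        f"invalid induced count {count} for {pattern!r}"
                    )


def generate_induction_cohort(params: CohortParams) -> list[AnnotatedAnimal]:
    """Cohort of animals with fate pattern and induced count populated.

    Patterns and counts are drawn per animal from the configured
    distributions; with all probability on the wild-type pattern every
    animal carries exactly three induced cells with the primary fate at
    P6.p.  The ``shifted`` pattern moves the 1° fate to P5.p or P7.p with
    equal probability.
    """
    rng = np.random.default_rng(params.seed)
    patterns = sorted(params.fate_pattern_probs)
    probs = np.array([params.fate_pattern_probs[k] for k in patterns])
    probs = probs / probs.sum()  # exact normalization within the 1e-9 check
    animals: list[AnnotatedAnimal] = []
    for i in range(params.n_animals):
        pattern = patterns[rng.choice(len(patterns), p=probs)]
        dist = params.induced_count_distribution[pattern]
        counts = sorted(dist)
        cprobs = np.array([dist[c] for c in counts])
        count = float(counts[rng.choice(len(counts), p=cprobs / cprobs.sum())])
        if pattern == "shifted":
            primary = "P5.p" if rng.random() < 0.5 else "P7.p"
        elif count == 0:
            primary = None
        else:
            primary = "P6.p"
        animals.append(
            AnnotatedAnimal(
                animal_id=f"sim{i:04d}",
                genotype=pattern,
                induced_count=count,
                primary_fate_vpc=primary,
            )
        )
    return animals
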