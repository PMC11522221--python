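"""Synthetic axial-CT phantoms with exact ground truth.

Each phantom slice emulates the tissue/HU structure the pipeline acts on:
an air background (-1000 HU), an elliptical soft-tissue body (~40 HU),
cortical-bone annuli (~700 HU) enclosing low-intensity marrow (~100 HU), and
a curved high-intensity stretcher band (~250 HU) hugging the left image
edge, whose inner-edge profile follows the three-zone couch shape (recessed
extremes, inclined transitions, protruding centre) so the three separating
lines i1 > i2 > i3 are exercised nondegenerately.  Optional accessory blobs
(~150 HU) attach to the couch on selected slices.

Because labels and masks derive from the same rasterization, the ground
truth is pixel-exact: at zero noise, thresholding at 300 HU recovers the
cortical label set exactly, and every stretcher pixel exceeds the 98 HU
binarization threshold.

The default geometry is 64 x 64 (not clinical 512 x 512) so the full
pipeline, including U-Net training, runs in minutes on one CPU; resolution
is a spec field, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .volume_io import CTVolume, MaskRole, MaskVolume

__all__ = ["PhantomSpec", "PhantomTruth", "Tissue", "generate_phantom", "phantom_cohort"]

HU_AIR = -1000.0
HU_SOFT = 40.0
HU_MARROW = 100.0
HU_CORTICAL = 700.0
HU_STRETCHER = 250.0
HU_ACCESSORY = 150.0


class Tissue:
    """Integer labels of the per-pixel truth map."""

    AIR = 0
    SOFT = 1
    MARROW = 2
    CORTICAL = 3
    STRETCHER = 4
    ACCESSORY = 5


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic patient."""

    image_size: tuple[int, int] = (64, 64)
    n_slices: int = 10
    body_center: tuple[float, float] = (32.0, 40.0)  # (row, col)
    body_axes: tuple[float, float] = (27.0, 18.0)  # semi-axes (row, col)
    # annuli: (center_row, center_col, outer_radius, inner_radius)
    bones: tuple[tuple[float, float, float, float], ...] = (
        (32.0, 44.0, 6.0, 3.0),
        (20.0, 36.0, 4.0, 2.0),
        (44.0, 36.0, 4.0, 2.0),
    )
    stretcher: bool = True
    stretcher_inner_central: int = 14  # inner-edge column in the central zone
    stretcher_inner_extreme: int = 6  # inner-edge column at the extremes
    stretcher_thickness: int = 4
    accessory_slices: tuple[int, ...] = ()  # slices carrying an accessory blob
    accessory_radius: int = 2
    soft_tissue_hu: float = HU_SOFT
    air_hu: float = HU_AIR
    cortical_hu: float = HU_CORTICAL
    marrow_hu: float = HU_MARROW
    stretcher_hu: float = HU_STRETCHER
    accessory_hu: float = HU_ACCESSORY
    noise_sd: float = 5.0
    min_gap: int = 6  # minimum stretcher-to-body clearance, columns
    spacing: tuple[float, float, float] = (2.5, 0.9766, 0.9766)
    patient_id: str = "phantom"
    seed: int = 0


@dataclass
class PhantomTruth:
    """Exact per-pixel ground truth of a generated phantom."""

    skeleton: MaskVolume
    stretcher: MaskVolume
    labels: np.ndarray  # (slice, row, col) Tissue codes


def _stretcher_inner_profile(spec: PhantomSpec) -> np.ndarray:
    """Inner-edge column per row: extremes low, centre high, linear ramps."""
    rows = spec.image_size[0]
    b = [(k * rows) // 8 for k in range(9)]
    lo, hi = spec.stretcher_inner_extreme, spec.stretcher_inner_central
    inner = np.full(rows, lo, dtype=float)
    inner[b[3] : b[5]] = hi
    ramp_up = np.arange(b[2], b[3])
    if ramp_up.size:
        inner[ramp_up] = np.linspace(lo, hi, ramp_up.size + 2)[1:-1]
    ramp_down = np.arange(b[5], b[6])
    if ramp_down.size:
        inner[ramp_down] = np.linspace(hi, lo, ramp_down.size + 2)[1:-1]
    return np.rint(inner).astype(int)


def _rasterize_slice(spec: PhantomSpec, with_accessory: bool) -> np.ndarray:
    rows, cols = spec.image_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    labels = np.full((rows, cols), Tissue.AIR, dtype=np.uint8)

    (cy, cx), (ay, ax) = spec.body_center, spec.body_axes
    body = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    labels[body] = Tissue.SOFT

    for by, bx, outer, inner in spec.bones:
        d2 = (rr - by) ** 2 + (cc - bx) ** 2
        disk = d2 <= outer**2
        if not body[disk].all():
            raise GeometryError(
                f"bone at ({by}, {bx}) r={outer} extends outside the body ellipse"
            )
        labels[disk] = Tissue.CORTICAL
        labels[d2 <= inner**2] = Tissue.MARROW

    if spec.stretcher:
        inner_profile = _stretcher_inner_profile(spec)
        body_left = np.where(body.any(axis=1), body.argmax(axis=1), cols)
        clearance = body_left - inner_profile
        if int(clearance.min()) < spec.min_gap:
            raise GeometryError(
                f"stretcher-to-body clearance {int(clearance.min())} < {spec.min_gap}"
            )
        band = (cc <= inner_profile[:, None]) & (
            cc > (inner_profile - spec.stretcher_thickness)[:, None]
        )
        labels[band] = Tissue.STRETCHER
        if with_accessory:
            mid = rows // 2
            acc_c = inner_profile[mid] + spec.accessory_radius
            d2 = (rr - mid) ** 2 + (cc - acc_c) ** 2
            acc = (d2 <= spec.accessory_radius**2) & ~body
            labels[acc] = Tissue.ACCESSORY
    return labels


_HU_OF = {
    Tissue.AIR: "air_hu",
    Tissue.SOFT: "soft_tissue_hu",
    Tissue.MARROW: "marrow_hu",
    Tissue.CORTICAL: "cortical_hu",
    Tissue.STRETCHER: "stretcher_hu",
    Tissue.ACCESSORY: "accessory_hu",
}


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate one phantom volume plus its exact truth, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    slices, label_stack = [], []
    for s in range(spec.n_slices):
        labels = _rasterize_slice(spec, with_accessory=s in spec.accessory_slices)
        hu = np.empty(labels.shape, dtype=np.float64)
        for tissue, attr in _HU_OF.items():
            hu[labels == tissue] = getattr(spec, attr)
        if spec.noise_sd > 0:
            hu += rng.normal(0.0, spec.noise_sd, size=hu.shape)
        slices.append(hu)
        label_stack.append(labels)
    voxels = np.stack(slices)
    labels3 = np.stack(label_stack)

    skeleton = np.isin(labels3, (Tissue.CORTICAL, Tissue.MARROW)).astype(np.uint8)
    stretch = np.isin(labels3, (Tissue.STRETCHER, Tissue.ACCESSORY)).astype(np.uint8)
    ct = CTVolume(voxels=voxels, spacing=spec.spacing, patient_id=spec.patient_id)
    truth = PhantomTruth(
        skeleton=MaskVolume(skeleton, MaskRole.SKELETON, spec.spacing, spec.patient_id),
        stretcher=MaskVolume(stretch, MaskRole.STRETCHER, spec.spacing, spec.patient_id),
        labels=labels3,
    )
    return ct, truth


def random_spec(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (64, 64),
    slice_range: tuple[int, int] = (8, 16),
    patient_id: str = "phantom",
    accessories: bool = True,
) -> PhantomSpec:
    """Draw a feasible randomized phantom geometry (64x64 reference frame)."""
    rows, cols = image_size
    sy, sx = rows / 64.0, cols / 64.0
    n_slices = int(rng.integers(slice_range[0], slice_range[1] + 1))
    cy = 32 * sy + rng.uniform(-2, 2) * sy
    cx = 40 * sx + rng.uniform(-1, 2) * sx
    ay = (27 + rng.uniform(-2, 1)) * sy
    ax = (18 + rng.uniform(-1, 1)) * sx
    bones = []
    for _ in range(int(rng.integers(1, 4))):
        outer = rng.uniform(3.0, 6.0) * min(sy, sx)
        inner = outer * rng.uniform(0.35, 0.6)
        # keep the annulus well inside the body ellipse
        theta = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.55)
        by = cy + rad * (ay - outer - 2) * np.sin(theta)
        bx = cx + rad * (ax - outer - 2) * np.cos(theta)
        bones.append((by, bx, outer, inner))
    accessory_slices: tuple[int, ...] = ()
    if accessories and rng.random() < 0.5:
        accessory_slices = (int(rng.integers(0, n_slices)),)
    return PhantomSpec(
        image_size=image_size,
        n_slices=n_slices,
        body_center=(cy, cx),
        body_axes=(ay, ax),
        bones=tuple(bones),
        stretcher_inner_central=int(round(14 * sx)),
        stretcher_inner_extreme=int(round(6 * sx)),
        stretcher_thickness=max(2, int(round(4 * sx))),
        accessory_slices=accessory_slices,
        noise_sd=5.0,
        patient_id=patient_id,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def phantom_cohort(
    n_patients: int,
    seed: int,
    image_size: tuple[int, int] = (64, 64),
    slice_range: tuple[int, int] = (8, 16),
    accessories: bool = True,
) -> list[tuple[CTVolume, MaskVolume]]:
    """Generate a cohort of randomized phantoms with skeleton ground truth.

    Per-patient geometry is drawn within feasible ranges and slice counts
    vary across ``slice_range``, emulating the between-patient variation of
    a clinical cohort at reduced scale.  Deterministic in ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for p in range(n_patients):
        spec = random_spec(
            rng,
            image_size=image_size,
            slice_range=slice_range,
            patient_id=f"P{p:03d}",
            accessories=accessories,
        )
        ct, truth = generate_phantom(spec)
        cohort.append((ct, truth.skeleton))
    return cohort
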