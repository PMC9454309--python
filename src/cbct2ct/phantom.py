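"""Digital pelvis phantom: paired clean-CT / degraded-CBCT slice generator.

Real paired CBCT/planning-CT data cannot be shipped, so every downstream
stage (training, inference, metrics) is exercised on an analytic 2D pelvis
cartoon: an elliptical body on a zeroed background, two circular femoral
heads, an elliptical bladder and a rectum disk with a gas pocket, each at a
nominal Hounsfield value plus a small seeded smooth texture.  The CBCT
degradation adds, inside the body only, the classic cone-beam artifact
phenomenology: a radial cupping depression, photon-starvation streaks
through bone, a beam-hardening band on the chord between the femoral
heads, zero-mean noise, and a global HU shift.

All randomness is driven by explicit integer seeds; identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

DEFAULT_HU = {
    "air": -1000.0,
    "soft_tissue": 40.0,
    "bladder": 10.0,
    "rectal_gas": -800.0,
    "bone": 700.0,
}


class PhantomConfigError(ValueError):
    """Invalid phantom geometry or HU table."""


@dataclass(frozen=True)
class ImageSlice:
    """One 2D HU image with pixel spacing and its body mask."""

    values: np.ndarray                      # (H, W) float32, HU
    spacing: tuple[float, float] = (1.0, 1.0)   # mm per pixel (row, col)
    body_mask: np.ndarray | None = None     # bool (H, W)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class ContourMask:
    """Binary organ mask on the slice/volume grid."""

    mask: np.ndarray                        # bool
    spacing: tuple[float, ...] = (1.0, 1.0)  # mm per voxel

    @property
    def shape(self):
        return self.mask.shape

    def __bool__(self):
        return bool(self.mask.any())


@dataclass(frozen=True)
class DoseGrid:
    """3D dose distribution in Gy with voxel spacing and prescription."""

    values: np.ndarray                      # (D, H, W) float, Gy, >= 0
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    prescription: float = 50.0              # Gy

    def __post_init__(self):
        if self.prescription <= 0:
            raise ValueError("prescription dose must be positive")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry (as fractions of image size), HU table and seed."""

    image_size: int = 128
    pixel_spacing: float = 1.0              # mm, isotropic
    body_center: tuple[float, float] = (0.5, 0.5)
    body_radii: tuple[float, float] = (0.36, 0.45)      # (row, col)
    bladder_center: tuple[float, float] = (0.40, 0.50)
    bladder_radii: tuple[float, float] = (0.10, 0.13)
    rectum_center: tuple[float, float] = (0.68, 0.50)
    rectum_radius: float = 0.075
    rectum_gas_radius: float = 0.04
    bone_centers: tuple[tuple[float, float], ...] = ((0.55, 0.23),
                                                     (0.55, 0.77))
    bone_radius: float = 0.08
    hu_table: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    texture_sigma_px: float = 3.0           # smoothing of the texture field
    texture_amplitude: float = 8.0          # HU
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32 or self.image_size % 16:
            raise PhantomConfigError(
                "image_size must be >= 32 and divisible by 16")
        radii = (*self.body_radii, *self.bladder_radii, self.rectum_radius,
                 self.rectum_gas_radius, self.bone_radius)
        if any(r <= 0 for r in radii):
            raise PhantomConfigError("all radii must be positive")
        hu = np.asarray(list(self.hu_table.values()), dtype=float)
        if not np.all(np.isfinite(hu)) or hu.min() < -1024 or hu.max() > 3000:
            raise PhantomConfigError(
                "HU table must be finite and within [-1024, 3000]")


@dataclass(frozen=True)
class ArtifactParams:
    """Magnitudes of the CBCT degradation model (all in HU, all >= 0)."""

    cupping_amplitude: float = 40.0
    streak_count: int = 6
    streak_amplitude: float = 60.0
    streak_sigma_px: float = 1.5            # Gaussian cross-profile width
    beam_hardening_amplitude: float = 50.0
    beam_hardening_sigma_px: float = 3.0
    noise_sigma: float = 15.0
    global_shift: float = 25.0
    seed: int = 0

    def __post_init__(self):
        amps = (self.cupping_amplitude, self.streak_amplitude,
                self.beam_hardening_amplitude, self.noise_sigma)
        if any(a < 0 for a in amps) or self.streak_count < 0:
            raise ValueError("artifact amplitudes/counts must be >= 0")


@dataclass(frozen=True)
class PairedSample:
    """A CT/CBCT slice pair sharing grid and spacing, plus organ masks."""

    ct: ImageSlice
    cbct: ImageSlice
    masks: dict[str, ContourMask]

    def __post_init__(self):
        if self.ct.shape != self.cbct.shape:
            raise ValueError("CT and CBCT must share shape")
        if self.ct.spacing != self.cbct.spacing:
            raise ValueError("CT and CBCT must share spacing")


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             radii: tuple[float, float]) -> np.ndarray:
    n = shape[0]
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    cr, ccol = center[0] * n, center[1] * n
    ar, ac = radii[0] * n, radii[1] * n
    return ((rr - cr) / ar) ** 2 + ((cc - ccol) / ac) ** 2 <= 1.0


def generate_anatomy(config: PhantomConfig
                     ) -> tuple[ImageSlice, dict[str, ContourMask]]:
    """Build the clean CT slice and its organ masks.

    Raises :class:`PhantomConfigError` if any organ leaves the body ellipse.
    """
    n = config.image_size
    shape = (n, n)
    body = _ellipse(shape, config.body_center, config.body_radii)
    bladder = _ellipse(shape, config.bladder_center, config.bladder_radii)
    rectum = _ellipse(shape, config.rectum_center,
                      (config.rectum_radius, config.rectum_radius))
    gas = _ellipse(shape, config.rectum_center,
                   (config.rectum_gas_radius, config.rectum_gas_radius))
    bone = np.zeros(shape, bool)
    for c in config.bone_centers:
        bone |= _ellipse(shape, c, (config.bone_radius, config.bone_radius))

    for name, organ in (("bladder", bladder), ("rectum", rectum),
                        ("bone", bone)):
        if not organ.any():
            raise PhantomConfigError(f"{name} mask is empty")
        if np.any(organ & ~body):
            raise PhantomConfigError(f"{name} extends outside the body")
    if np.any(bladder & rectum) or np.any(bladder & bone) \
            or np.any(rectum & bone):
        raise PhantomConfigError("organ masks overlap")

    hu = config.hu_table
    img = np.zeros(shape, np.float32)
    img[body] = hu["soft_tissue"]
    img[bladder] = hu["bladder"]
    img[bone] = hu["bone"]
    img[gas & rectum] = hu["rectal_gas"]

    rng = np.random.default_rng(config.seed)
    texture = ndimage.gaussian_filter(
        rng.standard_normal(shape), config.texture_sigma_px)
    std = texture.std()
    if std > 0:
        texture *= config.texture_amplitude / (std * 3.0)
    img[body] += texture[body].astype(np.float32)
    img[~body] = 0.0

    spacing = (config.pixel_spacing, config.pixel_spacing)
    masks = {
        "body": ContourMask(body, spacing),
        "bladder": ContourMask(bladder, spacing),
        "rectum": ContourMask(rectum, spacing),
        "bone": ContourMask(bone, spacing),
    }
    ct = ImageSlice(img, spacing, body_mask=body)
    return ct, masks


def _line_distance(shape, point, angle) -> np.ndarray:
    """Distance of each pixel to the infinite line through `point` at `angle`."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    nr, nc = -np.sin(angle), np.cos(angle)     # unit normal to the direction
    return np.abs((rr - point[0]) * nc - (cc - point[1]) * nr)


def _segment_distance(shape, p0, p1) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))


def degrade_to_cbct(ct: ImageSlice, masks: dict[str, ContourMask],
                    params: ArtifactParams) -> ImageSlice:
    """Apply the CBCT artifact model inside the body; background stays 0.

    With all amplitudes zero the output equals the input exactly.
    """
    body = masks["body"].mask
    if body.shape != ct.shape:
        raise ValueError("mask grid does not match the CT grid")
    if masks["body"].spacing != ct.spacing:
        raise ValueError("mask spacing does not match the CT spacing")
    shape = ct.shape
    rng = np.random.default_rng(params.seed)
    out = ct.values.astype(np.float64).copy()
    bias = np.zeros(shape, np.float64)

    if params.cupping_amplitude > 0:
        # scatter depresses central HU: -c * (1 - (r/R)^2), with (r/R) the
        # ellipse-normalized radius estimated from the body mask itself
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
        cy, cx = ndimage.center_of_mass(body)
        rows = np.flatnonzero(body.any(axis=1))
        cols = np.flatnonzero(body.any(axis=0))
        ar = max((rows[-1] - rows[0]) / 2.0, 1.0)
        ac = max((cols[-1] - cols[0]) / 2.0, 1.0)
        rho2 = ((rr - cy) / ar) ** 2 + ((cc - cx) / ac) ** 2
        bias -= params.cupping_amplitude * np.clip(1.0 - rho2, 0.0, 1.0)

    bone = masks.get("bone")
    if params.streak_count > 0 and params.streak_amplitude > 0 \
            and bone is not None and bone.mask.any():
        pts = np.argwhere(bone.mask)
        for _ in range(params.streak_count):
            p = pts[rng.integers(len(pts))]
            ang = rng.uniform(0, np.pi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            d = _line_distance(shape, p, ang)
            bias += sign * params.streak_amplitude * \
                np.exp(-0.5 * (d / params.streak_sigma_px) ** 2)

    if params.beam_hardening_amplitude > 0 and bone is not None:
        lbl, nlbl = ndimage.label(bone.mask)
        if nlbl >= 2:
            centers = ndimage.center_of_mass(bone.mask, lbl, [1, 2])
            d = _segment_distance(shape, centers[0], centers[1])
            bias -= params.beam_hardening_amplitude * \
                np.exp(-0.5 * (d / params.beam_hardening_sigma_px) ** 2)

    if params.noise_sigma > 0:
        bias += rng.normal(0.0, params.noise_sigma, size=shape)

    bias += params.global_shift
    out[body] += bias[body]
    out[~body] = 0.0
    return ImageSlice(out.astype(np.float32), ct.spacing, body_mask=body)


def perturb_mask(mask: ContourMask, magnitude: float, seed: int = 0,
                 within: ContourMask | None = None) -> ContourMask:
    """Morphological dilation/erosion plus seeded boundary jitter.

    ``magnitude`` bounds the perturbation in pixels; 0 is the identity.
    When ``within`` is given the result is clipped to it.
    """
    if not mask.mask.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    m = mask.mask.copy()
    if magnitude > 0:
        rng = np.random.default_rng(seed)
        it = max(1, int(round(magnitude)))
        if rng.random() < 0.5:
            m = ndimage.binary_dilation(m, iterations=it)
        else:
            eroded = ndimage.binary_erosion(m, iterations=it)
            if eroded.any():
                m = eroded
        boundary = ndimage.binary_dilation(m) & ~ndimage.binary_erosion(m)
        flip = boundary & (rng.random(m.shape) < 0.25)
        m = m ^ flip
        m = ndimage.binary_closing(m)
        if not m.any():
            m = mask.mask.copy()
    if within is not None:
        m = m & within.mask
        if not m.any():
            raise ValueError("clipping region removed the entire mask")
    return ContourMask(m, mask.spacing)


def make_dose_pair(shape: tuple[int, int, int],
                   spacing_mm: tuple[float, float, float],
                   prescription: float,
                   perturbation: float,
                   sigma_frac: float = 0.25) -> tuple[DoseGrid, DoseGrid]:
    """Smooth Gaussian-bell reference dose plus a uniformly scaled copy.

    The reference peaks at exactly ``prescription``; the evaluated grid is
    reference * (1 + perturbation).
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    axes = [np.arange(s, dtype=np.float64) - (s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    q = sum((g / (sigma_frac * s)) ** 2
            for g, s in zip(grids, shape))
    ref = np.exp(-0.5 * q)
    ref *= prescription / ref.max()
    spacing = tuple(float(s) for s in spacing_mm)
    return (DoseGrid(ref, spacing, prescription),
            DoseGrid(ref * (1.0 + perturbation), spacing, prescription))


def generate_pair(config: PhantomConfig, params: ArtifactParams
                  ) -> PairedSample:
    """Anatomy + degradation in one call (seeds from the two configs)."""
    ct, masks = generate_anatomy(config)
    cbct = degrade_to_cbct(ct, masks, params)
    return PairedSample(ct, cbct, masks)


def _jitter_config(config: PhantomConfig, rng: np.random.Generator,
                   seed: int) -> PhantomConfig:
    """Per-sample anatomical variation: organ sizes/positions wiggle a little."""
    def scale(v, lo=0.9, hi=1.1):
        return v * rng.uniform(lo, hi)

    return replace(
        config,
        bladder_radii=(scale(config.bladder_radii[0]),
                       scale(config.bladder_radii[1])),
        bladder_center=(config.bladder_center[0] + rng.uniform(-0.02, 0.02),
                        config.bladder_center[1] + rng.uniform(-0.02, 0.02)),
        rectum_radius=scale(config.rectum_radius),
        rectum_center=(config.rectum_center[0] + rng.uniform(-0.02, 0.02),
                       config.rectum_center[1] + rng.uniform(-0.02, 0.02)),
        body_radii=(scale(config.body_radii[0], 0.95, 1.05),
                    scale(config.body_radii[1], 0.95, 1.05)),
        seed=seed,
    )


def generate_dataset(n_pairs: int, config: PhantomConfig,
                     params: ArtifactParams, out_dir,
                     split: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     master_seed: int | None = None):
    """Write ``n_pairs`` NIfTI sample pairs plus a CSV manifest.

    Returns the manifest as a pandas DataFrame (also saved as
    ``manifest.csv`` with columns id, split, seed, and file paths).
    """
    import pandas as pd

    from .io import write_volume

    if n_pairs < 1:
        raise ValueError("need at least one pair")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed0 = config.seed if master_seed is None else master_seed
    rng = np.random.default_rng(seed0)
    sample_seeds = rng.integers(0, 2 ** 31 - 1, size=n_pairs)

    n_train = int(round(split[0] * n_pairs))
    n_val = int(round(split[1] * n_pairs))
    labels = (["train"] * n_train + ["val"] * n_val
              + ["test"] * (n_pairs - n_train - n_val))

    rows = []
    for i in range(n_pairs):
        s = int(sample_seeds[i])
        srng = np.random.default_rng(s)
        cfg_i = _jitter_config(config, srng, seed=s)
        par_i = replace(params, seed=s + 1)
        pair = generate_pair(cfg_i, par_i)
        stem = f"sample_{i:04d}"
        paths = {}
        sp = pair.ct.spacing
        for key, arr in (("ct", pair.ct.values), ("cbct", pair.cbct.values)):
            p = out / f"{stem}_{key}.nii.gz"
            write_volume(arr, p, spacing=sp)
            paths[key] = p.name
        for key, cm in pair.masks.items():
            p = out / f"{stem}_mask_{key}.nii.gz"
            write_volume(cm.mask.astype(np.uint8), p, spacing=sp)
            paths[f"mask_{key}"] = p.name
        rows.append({"id": stem, "split": labels[i], "seed": s, **paths})

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
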