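"""Synthetic pelvic phantom: co-registered CT, T2-like MR, contours and plan.

The generator emulates the male pelvis as seen in an axial planning CT for
prostate radiotherapy: an elliptical body with a subcutaneous fat ring,
femoral heads and a sacral block (cortical shell + spongy interior), bladder,
prostate (CTV) with dilated PTVs, and a gently curved rectal tube that may
contain gas pockets.  CT and MR are painted from one shared tissue label
map, so the two modalities are co-registered by construction; a smooth
deformation can be applied to the MR afterwards to emulate residual
CT<->MR registration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import (ConfigurationError, Contour, GeometryError, ImageGrid,
                      StructureSet, rasterize)
from .dose_engine import PlanConfig

# integer codes of the tissue label map
LABELS = ("air", "gas", "fat", "muscle", "spongy_bone", "cortical_bone",
          "bladder", "prostate", "calcification")
LABEL_CODE = {name: i for i, name in enumerate(LABELS)}

# realistic-CT tissue means (HU); bladder/prostate are soft tissue near water
DEFAULT_HU_MEANS = {
    "air": -1000.0, "gas": -950.0, "fat": -90.0, "muscle": 45.0,
    "spongy_bone": 250.0, "cortical_bone": 1200.0,
    "bladder": 10.0, "prostate": 35.0, "calcification": 800.0,
}

# tissue-stratification nominal values (water-equivalent soft tissue at 0 HU)
NOMINAL_HU_MEANS = {
    "air": -1000.0, "gas": -500.0, "fat": -75.0, "muscle": 0.0,
    "spongy_bone": 204.0, "cortical_bone": 1067.0,
    "bladder": 0.0, "prostate": 0.0, "calcification": 800.0,
}

# T2-like relative intensities: fat/urine bright, bone and air dark.
# Deliberately not an affine function of the HU means.
T2_INTENSITY = {
    "air": 0.02, "gas": 0.04, "fat": 0.90, "muscle": 0.40,
    "spongy_bone": 0.45, "cortical_bone": 0.08,
    "bladder": 0.95, "prostate": 0.52, "calcification": 0.10,
}


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise parameters of the pelvic phantom."""

    grid_shape: tuple = (40, 128, 128)
    spacing: tuple = (2.5, 0.98, 0.98)
    body_semiaxes_mm: tuple = (48.0, 58.0)   # (row/AP, col/LR)
    fat_ring_mm: float = 8.0
    prostate_radius_mm: float = 12.0
    prostate_center_mm: tuple = (45.0, 0.0, 0.0)  # (z, row, col) rel. to body axis
    ptv60_margin_mm: float = 5.0
    ptv48_margin_mm: float = 9.0
    bladder_radius_mm: float = 15.0
    bladder_center_mm: tuple = (62.5, 18.0, 0.0)
    rectum_radius_mm: float = 7.0
    rectum_row_mm: float = -25.0             # tube axis AP offset
    rectum_curve_mm: float = 2.0             # AP curvature amplitude
    rectum_wiggle_mm: float = 2.0            # LR curvature amplitude
    rectum_slices: tuple = (4, 36)
    femur_radius_mm: float = 11.0
    femur_cortex_mm: float = 2.5
    femur_col_mm: float = 38.0
    femur_row_mm: float = -2.0
    femur_slices: tuple = (6, 30)
    sacrum_rows_mm: tuple = (-44.0, -34.0)
    sacrum_halfwidth_mm: float = 16.0
    sacrum_cortex_mm: float = 2.0
    sacrum_slices: tuple = (8, 38)
    gas_probability: float = 0.5
    gas_radius_mm: float = 4.0
    n_gas_candidates: int = 3
    n_calcifications: int = 3
    calcification_radius_mm: float = 1.6
    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_noise_sd: float = 10.0
    mr_bias_amplitude: float = 0.2
    mr_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        missing = {"air", "gas", "fat", "muscle", "spongy_bone",
                   "cortical_bone"} - set(self.hu_means)
        if missing:
            raise ConfigurationError(f"hu_means missing tissues: {sorted(missing)}")
        for r in (self.prostate_radius_mm, self.bladder_radius_mm,
                  self.rectum_radius_mm, self.femur_radius_mm):
            if r <= 0:
                raise ConfigurationError("all organ radii must be positive")
        a, b = self.body_semiaxes_mm
        half_r = (self.grid_shape[1] - 1) * self.spacing[1] / 2
        half_c = (self.grid_shape[2] - 1) * self.spacing[2] / 2
        if a >= half_r or b >= half_c:
            raise ConfigurationError("body ellipse exceeds the grid extent")
        if abs(self.rectum_row_mm) + self.rectum_radius_mm + self.rectum_curve_mm > a:
            raise ConfigurationError("rectum exceeds the body extent")

    @classmethod
    def nominal(cls, **overrides) -> "PhantomConfig":
        """Noiseless phantom painted with the stratification nominal HUs.

        Tissue stratification of this CT recovers it exactly, which makes it
        the null phantom for end-to-end zero-error checks.
        """
        kw = dict(hu_means=dict(NOMINAL_HU_MEANS), hu_noise_sd=0.0,
                  n_calcifications=0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def small(cls, **overrides) -> "PhantomConfig":
        """Desk-scale grid (28 x 64 x 64 at ~2x coarser in-plane pitch)."""
        kw = dict(grid_shape=(28, 64, 64), spacing=(2.5, 1.96, 1.96),
                  prostate_center_mm=(35.0, 0.0, 0.0),
                  bladder_center_mm=(50.0, 18.0, 0.0),
                  rectum_slices=(3, 25), femur_slices=(4, 22),
                  sacrum_slices=(5, 26))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class DeformationField:
    """Smooth per-voxel displacement (mm) used to emulate misregistration."""

    displacement: np.ndarray  # (3, slices, rows, cols) in mm, axes (z, row, col)
    max_magnitude: float

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        mag = np.sqrt((self.displacement ** 2).sum(axis=0))
        if mag.max() > self.max_magnitude + 1e-9:
            raise ConfigurationError("displacement exceeds declared max_magnitude")


@dataclass
class Phantom:
    """Co-registered CT + MR + structures + plan from one label map."""

    ct: ImageGrid
    mr: ImageGrid
    structures: StructureSet
    plan: PlanConfig
    labels: ImageGrid          # integer codes into LABELS
    config: PhantomConfig


def _rngs(seed: int) -> dict:
    """Named independent generators so sub-processes stay reproducible."""
    return {name: np.random.default_rng([int(seed), i])
            for i, name in enumerate(["anatomy", "ct_noise", "mr_noise", "calc"])}


def _grid_coords(config: PhantomConfig):
    ns, nr, nc = config.grid_shape
    sz, sr, sc = config.spacing
    z = np.arange(ns) * sz
    r = (np.arange(nr) - (nr - 1) / 2) * sr   # mm from body axis, +anterior
    c = (np.arange(nc) - (nc - 1) / 2) * sc   # mm from body axis, +left
    return np.meshgrid(z, r, c, indexing="ij")


def rectum_centerline(config: PhantomConfig, z_mm: np.ndarray):
    """(row_mm, col_mm) of the rectal tube axis as a function of z."""
    z0 = config.rectum_slices[0] * config.spacing[0]
    z1 = config.rectum_slices[1] * config.spacing[0]
    t = (np.asarray(z_mm, dtype=float) - z0) / max(z1 - z0, 1e-9)
    row = config.rectum_row_mm + config.rectum_curve_mm * np.cos(2 * np.pi * t)
    col = config.rectum_wiggle_mm * np.sin(2 * np.pi * t)
    return row, col


def _rectum_contours(config: PhantomConfig, n_vertices: int = 72) -> list:
    contours = []
    sz = config.spacing[0]
    nr, nc = config.grid_shape[1], config.grid_shape[2]
    r_off = (nr - 1) / 2 * config.spacing[1]
    c_off = (nc - 1) / 2 * config.spacing[2]
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    for i in range(config.rectum_slices[0], config.rectum_slices[1] + 1):
        row0, col0 = rectum_centerline(config, i * sz)
        pts = np.column_stack([
            row0 + r_off + config.rectum_radius_mm * np.cos(theta),
            col0 + c_off + config.rectum_radius_mm * np.sin(theta)])
        contours.append(Contour("RECTUM", i, pts))
    return contours


def _body_contours(config: PhantomConfig, n_vertices: int = 96) -> list:
    a, b = config.body_semiaxes_mm
    nr, nc = config.grid_shape[1], config.grid_shape[2]
    r_off = (nr - 1) / 2 * config.spacing[1]
    c_off = (nc - 1) / 2 * config.spacing[2]
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    pts = np.column_stack([r_off + a * np.cos(theta), c_off + b * np.sin(theta)])
    return [Contour("BODY", i, pts) for i in range(config.grid_shape[0])]


def _margin_mask(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Isotropic mm expansion via the Euclidean distance transform."""
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def build_label_map(config: PhantomConfig, rng_anatomy, rng_calc):
    """Paint the integer tissue label map and return it with organ masks."""
    z, r, c = _grid_coords(config)
    a, b = config.body_semiaxes_mm
    body = (r / a) ** 2 + (c / b) ** 2 <= 1.0
    inner = (r / (a - config.fat_ring_mm)) ** 2 + \
            (c / (b - config.fat_ring_mm)) ** 2 <= 1.0

    labels = np.full(config.grid_shape, LABEL_CODE["air"], dtype=np.int16)
    labels[body] = LABEL_CODE["fat"]
    labels[body & inner] = LABEL_CODE["muscle"]

    # femoral heads: vertical cylinders with a cortical shell
    masks = {}
    bones = np.zeros(config.grid_shape, dtype=bool)
    spongy_interior = np.zeros(config.grid_shape, dtype=bool)
    fz0, fz1 = (s * config.spacing[0] for s in config.femur_slices)
    for side in (-1, 1):
        d = np.sqrt((r - config.femur_row_mm) ** 2 +
                    (c - side * config.femur_col_mm) ** 2)
        inz = (z >= fz0) & (z <= fz1)
        outer = (d <= config.femur_radius_mm) & inz
        innerb = (d <= config.femur_radius_mm - config.femur_cortex_mm) & inz
        bones |= outer
        spongy_interior |= innerb
    # sacrum: posterior block with an elliptical cross-section
    sz0, sz1 = (s * config.spacing[0] for s in config.sacrum_slices)
    s_rc = (config.sacrum_rows_mm[0] + config.sacrum_rows_mm[1]) / 2
    s_ra = (config.sacrum_rows_mm[1] - config.sacrum_rows_mm[0]) / 2
    d2 = ((r - s_rc) / s_ra) ** 2 + (c / config.sacrum_halfwidth_mm) ** 2
    outer = (d2 <= 1.0) & (z >= sz0) & (z <= sz1)
    shrink = 1 - config.sacrum_cortex_mm / max(s_ra, 1e-9)
    innerb = (d2 <= shrink ** 2) & (z >= sz0) & (z <= sz1)
    bones |= outer
    spongy_interior |= innerb
    bones &= body
    spongy_interior &= body
    labels[bones] = LABEL_CODE["cortical_bone"]
    labels[spongy_interior] = LABEL_CODE["spongy_bone"]

    # bladder then prostate (prostate wins a small overlap)
    zb, rb, cb = config.bladder_center_mm
    bladder = ((z - zb) ** 2 + (r - rb) ** 2 + (c - cb) ** 2
               <= config.bladder_radius_mm ** 2) & body
    labels[bladder] = LABEL_CODE["bladder"]
    zp, rp, cp = config.prostate_center_mm
    prostate = ((z - zp) ** 2 + (r - rp) ** 2 + (c - cp) ** 2
                <= config.prostate_radius_mm ** 2) & body
    labels[prostate] = LABEL_CODE["prostate"]

    masks["BODY"] = body
    masks["BONES"] = bones
    masks["BLADDER"] = bladder & ~prostate
    masks["CTV"] = prostate
    return labels, masks, spongy_interior


def generate_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Generate one deterministic phantom from the config seed."""
    config = config or PhantomConfig()
    rngs = _rngs(config.seed)
    labels, masks, _ = build_label_map(config, rngs["anatomy"], rngs["calc"])
    ref = ImageGrid(np.zeros(config.grid_shape), spacing=config.spacing,
                    modality="MASK", units="bool")

    rectum_contours = _rectum_contours(config)
    body_contours = _body_contours(config)
    rectum_mask = rasterize(rectum_contours, ref).voxels
    if masks["CTV"].any() and (rectum_mask & masks["CTV"]).any():
        raise ConfigurationError("rectum overlaps the CTV; adjust geometry")
    labels[rectum_mask] = LABEL_CODE["muscle"]

    # gas pockets: candidate spheres on the rectal centerline
    rng = rngs["anatomy"]
    z_lo = config.rectum_slices[0] * config.spacing[0]
    z_hi = config.rectum_slices[1] * config.spacing[0]
    z, r, c = _grid_coords(config)
    gas = np.zeros(config.grid_shape, dtype=bool)
    for k in range(config.n_gas_candidates):
        present = rng.random() < config.gas_probability
        zk = rng.uniform(z_lo + config.gas_radius_mm, z_hi - config.gas_radius_mm)
        if not present:
            continue
        rowk, colk = rectum_centerline(config, zk)
        gas |= ((z - zk) ** 2 + (r - rowk) ** 2 + (c - colk) ** 2
                <= config.gas_radius_mm ** 2)
    gas &= rectum_mask
    labels[gas] = LABEL_CODE["gas"]

    # calcification / fiducial speckles inside the CTV
    rng = rngs["calc"]
    zp, rp, cp = config.prostate_center_mm
    for k in range(config.n_calcifications):
        while True:
            off = rng.uniform(-1, 1, size=3)
            if np.sum(off ** 2) <= 1:
                break
        off *= max(config.prostate_radius_mm - config.calcification_radius_mm - 1, 1)
        d2 = ((z - zp - off[0]) ** 2 + (r - rp - off[1]) ** 2 +
              (c - cp - off[2]) ** 2)
        labels[(d2 <= config.calcification_radius_mm ** 2) & masks["CTV"]] = \
            LABEL_CODE["calcification"]

    hu = np.empty(len(LABELS))
    for name, code in LABEL_CODE.items():
        hu[code] = config.hu_means.get(name, config.hu_means["muscle"])
    ct = hu[labels]
    if config.hu_noise_sd > 0:
        noise = rngs["ct_noise"].normal(0, config.hu_noise_sd, size=ct.shape)
        ct = ct + noise * masks["BODY"]

    ptv60 = _margin_mask(masks["CTV"], config.ptv60_margin_mm, config.spacing)
    ptv48 = _margin_mask(masks["CTV"], config.ptv48_margin_mm, config.spacing)

    grids = dict(spacing=config.spacing, origin=(0.0, 0.0, 0.0))
    ct_grid = ImageGrid(ct, modality="CT", units="HU", **grids)

    structures = StructureSet(contours=rectum_contours + body_contours,
                              reference=ref)
    as_grid = lambda m: ImageGrid(m, modality="MASK", units="bool", **grids)
    structures.add_mask("BODY", as_grid(masks["BODY"]))
    structures.add_mask("RECTUM", as_grid(rectum_mask))
    structures.add_mask("RECTAL_GAS", as_grid(gas))
    structures.add_mask("BLADDER", as_grid(masks["BLADDER"]))
    structures.add_mask("CTV", as_grid(masks["CTV"]))
    structures.add_mask("PTV60", as_grid(ptv60 & masks["BODY"]))
    structures.add_mask("PTV48", as_grid(ptv48 & masks["BODY"]))
    structures.add_mask("BONES", as_grid(masks["BONES"]))
    structures.add_mask("FAT", as_grid(labels == LABEL_CODE["fat"]))
    structures.add_mask("MUSCLE", as_grid(labels == LABEL_CODE["muscle"]))

    plan = PlanConfig.default(isocenter_mm=(zp, 0.0, 0.0))
    label_grid = ImageGrid(labels, modality="MASK", units="arbitrary", **grids)
    phantom = Phantom(ct=ct_grid, mr=None, structures=structures, plan=plan,
                      labels=label_grid, config=config)
    phantom.mr = synthesize_mr(phantom, config)
    return phantom


def synthesize_mr(phantom: Phantom, config: PhantomConfig) -> ImageGrid:
    """T2-like MR from the label map: bright fat/urine, dark bone, bias field.

    The tissue -> intensity mapping is monotone-broken with respect to HU on
    purpose, so learning MR -> CT is a genuine image-translation task rather
    than a linear rescale.
    """
    rng = _rngs(config.seed)["mr_noise"]
    t2 = np.empty(len(LABELS))
    for name, code in LABEL_CODE.items():
        t2[code] = T2_INTENSITY[name]
    mr = t2[phantom.labels.voxels]
    if config.mr_bias_amplitude > 0:
        coarse = rng.standard_normal((4, 8, 8))
        zoomed = ndimage.zoom(coarse, np.array(mr.shape) / np.array(coarse.shape),
                              order=3)
        zoomed /= max(np.abs(zoomed).max(), 1e-12)
        mr = mr * (1 + config.mr_bias_amplitude * zoomed)
    if config.mr_noise_sd > 0:
        n1 = rng.normal(0, config.mr_noise_sd, mr.shape)
        n2 = rng.normal(0, config.mr_noise_sd, mr.shape)
        mr = np.sqrt((mr + n1) ** 2 + n2 ** 2)   # Rician-like magnitude noise
    return ImageGrid(mr, spacing=config.spacing, origin=(0.0, 0.0, 0.0),
                     modality="MR", units="arbitrary")


def random_deformation(config: PhantomConfig, max_magnitude_mm: float,
                       seed: int) -> DeformationField:
    """Band-limited random displacement field with a hard magnitude cap."""
    rng = np.random.default_rng(seed)
    coarse = rng.standard_normal((3, 3, 5, 5))
    disp = np.stack([
        ndimage.zoom(coarse[i], np.array(config.grid_shape) / np.array([3, 5, 5]),
                     order=3) for i in range(3)])
    mag = np.sqrt((disp ** 2).sum(axis=0))
    disp *= max_magnitude_mm / max(mag.max(), 1e-12)
    return DeformationField(disp, max_magnitude=max_magnitude_mm)


def uniform_shift(config: PhantomConfig, shift_mm) -> DeformationField:
    shape = (3,) + tuple(config.grid_shape)
    disp = np.zeros(shape)
    for ax in range(3):
        disp[ax] = shift_mm[ax]
    return DeformationField(disp, max_magnitude=float(np.linalg.norm(shift_mm)))


def perturb_registration(phantom: Phantom, field: DeformationField) -> Phantom:
    """Warp the MR (only) by ``field``; the CT stays put.

    Models residual CT<->MR mismatch after deformable registration: the
    stratification and learning inputs no longer align perfectly with the
    planning CT ground truth.
    """
    if field.displacement.shape[1:] != phantom.mr.shape:
        raise GeometryError("deformation field must live on the phantom grid")
    if field.max_magnitude > 10.0:
        raise ConfigurationError(
            "deformations beyond 10 mm are not a plausible residual "
            "registration error")
    sp = np.asarray(phantom.mr.spacing)[:, None, None, None]
    idx = np.indices(phantom.mr.shape, dtype=float)
    coords = idx + field.displacement / sp
    warped = ndimage.map_coordinates(phantom.mr.voxels, coords, order=1,
                                     mode="nearest")
    new_mr = phantom.mr.copy(voxels=warped)
    return Phantom(ct=phantom.ct, mr=new_mr, structures=phantom.structures,
                   plan=phantom.plan, labels=phantom.labels,
                   config=phantom.config)
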