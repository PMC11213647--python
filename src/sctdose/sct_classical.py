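"""Bulk-density and tissue-stratification synthetic CTs, plus HU accuracy.

Two classical sCT families are built here.  Bulk density assigns one HU to
the whole body (0 HU for water, or a population-average HU pooled over
training patients).  Tissue stratification thresholds a CT-like volume into
inside-air / fat / muscle / spongy bone / cortical bone, applies two
clean-up overrides (calcifications and fiducial markers inside the CTV
become muscle; fat or muscle pockets inside spongy-bone structures become
spongy bone) and paints each class with its nominal HU.  Applying the
stratification to the planning CT itself yields the ground-truth-
stratification control that isolates stratification error from
registration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import ConfigurationError, GeometryError, ImageGrid, StructureSet

STRAT_CLASSES = ("outside", "inside_air", "fat", "muscle", "spongy_bone",
                 "cortical_bone")
STRAT_CODE = {name: i for i, name in enumerate(STRAT_CLASSES)}

#: nominal class HUs of the stratified synthetic CT
NOMINAL_HU = {"inside_air": -500.0, "fat": -75.0, "muscle": 0.0,
              "spongy_bone": 204.0, "cortical_bone": 1067.0}


@dataclass
class StratificationRules:
    """Threshold breakpoints and nominal HUs for tissue stratification.

    ``thresholds`` are the ordered HU breakpoints separating
    inside-air | fat | muscle | spongy bone | cortical bone.
    """

    thresholds: tuple = (-200.0, -30.0, 100.0, 400.0)
    nominal_hu: dict = field(default_factory=lambda: dict(NOMINAL_HU))
    ctv_override: bool = True
    spongy_interior_override: bool = True
    bone_interior_erosion_mm: float = 2.5

    def __post_init__(self):
        if np.any(np.diff(self.thresholds) <= 0):
            raise ConfigurationError("thresholds must be strictly increasing")
        missing = set(NOMINAL_HU) - set(self.nominal_hu)
        if missing:
            raise ConfigurationError(f"nominal_hu missing classes: {sorted(missing)}")


@dataclass
class HUErrorSummary:
    """ME / MAE / SD of HU errors (sct - ct) over one region."""

    me: float
    mae: float
    sd: float
    n_voxels: int
    region: str = "BODY"


def make_bd_sct(body_mask: ImageGrid, fill_hu: float) -> ImageGrid:
    """Bulk-density sCT: ``fill_hu`` inside the body, -1000 outside.

    ``fill_hu=0`` gives the water bulk density sCT; filling with the
    population mean gives the population bulk density variant.
    """
    mask = body_mask.voxels.astype(bool)
    if not mask.any():
        raise ValueError("body mask is empty")
    sct = np.where(mask, float(fill_hu), -1000.0)
    return ImageGrid(sct, spacing=body_mask.spacing, origin=body_mask.origin,
                     modality="CT", units="HU")


def population_mean_hu(training_cts, body_masks) -> float:
    """Mean HU over the pooled body voxels of all training volumes."""
    if not training_cts or len(training_cts) != len(body_masks):
        raise ValueError("need equal-length, non-empty CT and mask lists")
    total, count = 0.0, 0
    for ct, mask in zip(training_cts, body_masks):
        m = mask.voxels.astype(bool)
        if not m.any():
            raise ValueError("a body mask is empty")
        total += float(ct.voxels[m].sum())
        count += int(m.sum())
    return total / count


def stratify_tissues(ct: ImageGrid, rules: StratificationRules,
                     structures: StructureSet) -> ImageGrid:
    """Threshold a CT into stratification classes inside the body.

    Overrides: voxels inside the CTV thresholded as fat, spongy or cortical
    bone (calcification / fiducial analogues) are re-assigned muscle; fat or
    muscle voxels in the interior of bone structures are re-assigned spongy
    bone.
    """
    body = structures.masks.get("BODY")
    if body is None:
        raise ConfigurationError("stratification requires a BODY mask")
    if not ct.same_geometry(body):
        raise GeometryError("CT and structure masks must share geometry")
    t = rules.thresholds
    hu = ct.voxels
    labels = np.full(ct.shape, STRAT_CODE["outside"], dtype=np.int16)
    inside = body.voxels.astype(bool)
    cls = np.digitize(hu, t)  # 0: inside_air .. 4: cortical, offset by 1
    labels[inside] = cls[inside] + 1

    if rules.ctv_override:
        ctv = structures.masks.get("CTV")
        if ctv is None:
            raise ConfigurationError("ctv_override requires a CTV structure")
        hard = np.isin(labels, [STRAT_CODE["fat"], STRAT_CODE["spongy_bone"],
                                STRAT_CODE["cortical_bone"]])
        labels[ctv.voxels.astype(bool) & hard] = STRAT_CODE["muscle"]
    if rules.spongy_interior_override:
        bones = structures.masks.get("BONES")
        if bones is None:
            raise ConfigurationError("spongy_interior_override requires a "
                                     "BONES structure")
        interior = _bone_interior(bones, rules.bone_interior_erosion_mm)
        soft = np.isin(labels, [STRAT_CODE["fat"], STRAT_CODE["muscle"]])
        labels[interior & soft] = STRAT_CODE["spongy_bone"]
    return ImageGrid(labels, spacing=ct.spacing, origin=ct.origin,
                     modality="MASK", units="arbitrary")


def _bone_interior(bones: ImageGrid, erosion_mm: float) -> np.ndarray:
    """Interior of bone structures: eroded in-plane by the cortical depth."""
    mask = bones.voxels.astype(bool)
    if not mask.any():
        return mask
    inverse_dist = ndimage.distance_transform_edt(mask, sampling=bones.spacing)
    return inverse_dist > erosion_mm


def make_ts_sct(labels: ImageGrid, rules: StratificationRules | None = None) -> ImageGrid:
    """Paint stratification classes with their nominal HU (outside -> -1000)."""
    rules = rules or StratificationRules()
    lab = labels.voxels
    if lab.min() < 0 or lab.max() >= len(STRAT_CLASSES):
        raise ValueError("unknown stratification label code")
    lut = np.empty(len(STRAT_CLASSES))
    lut[STRAT_CODE["outside"]] = -1000.0
    for name, value in rules.nominal_hu.items():
        lut[STRAT_CODE[name]] = value
    return ImageGrid(lut[lab], spacing=labels.spacing, origin=labels.origin,
                     modality="CT", units="HU")


def ts_sct_from_ct(ct: ImageGrid, structures: StructureSet,
                   rules: StratificationRules | None = None) -> ImageGrid:
    """Stratify a CT and re-paint it: the ground-truth stratification control."""
    rules = rules or StratificationRules()
    return make_ts_sct(stratify_tissues(ct, rules, structures), rules)


def hu_error_metrics(sct: ImageGrid, ct: ImageGrid, region: ImageGrid,
                     region_name: str = "BODY") -> HUErrorSummary:
    """ME, MAE and sample SD (n-1) of sct - ct over a region."""
    if not (sct.same_geometry(ct) and sct.same_geometry(region)):
        raise GeometryError("sCT, CT and region must share geometry")
    mask = region.voxels.astype(bool)
    if not mask.any():
        raise ValueError("region mask is empty")
    diff = sct.voxels[mask].astype(float) - ct.voxels[mask].astype(float)
    return HUErrorSummary(me=float(diff.mean()),
                          mae=float(np.abs(diff).mean()),
                          sd=float(diff.std(ddof=1)) if diff.size > 1 else 0.0,
                          n_voxels=int(diff.size), region=region_name)
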