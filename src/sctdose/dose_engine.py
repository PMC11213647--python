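"""Simplified multi-beam photon dose model and 3D local gamma analysis.

The engine is a declared stand-in for a clinical dose algorithm: each
coplanar beam delivers a parallel primary fluence through a beam's-eye-view
aperture, attenuated by the radiological path length (line integral of
relative electron density), with a Gaussian penumbra.  It is deliberately
simple, but density-sensitive, so that HU errors in a synthetic CT propagate
to dose exactly as the study design requires.  Monitor units are represented
by ``mu_scale``: fixed at planning time and reused verbatim when
recalculating on a synthetic CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core_io import ConfigurationError, GeometryError, ImageGrid


@dataclass
class CalibrationCurve:
    """Monotone piecewise-linear HU -> relative electron density mapping."""

    points: tuple = ((-1000.0, 0.0), (-75.0, 0.97), (0.0, 1.0),
                     (204.0, 1.10), (1067.0, 1.60))

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if np.any(np.diff(pts[:, 0]) <= 0) or np.any(np.diff(pts[:, 1]) <= 0):
            raise ConfigurationError("calibration curve must be strictly "
                                     "increasing in HU and density")
        self.points = tuple(map(tuple, pts))

    def __call__(self, hu):
        pts = np.asarray(self.points)
        return np.interp(hu, pts[:, 0], pts[:, 1])


def hu_to_red(ct: ImageGrid, curve: CalibrationCurve | None = None) -> ImageGrid:
    """Convert a CT (HU) to relative electron density; ends are clamped."""
    curve = curve or CalibrationCurve()
    red = curve(ct.voxels)
    return ct.copy(voxels=red, modality="CT", units="arbitrary")


@dataclass
class Beam:
    """One coplanar parallel beam: gantry angle (deg) and relative weight.

    ``aperture`` is the BEV fluence mask over (slice, lateral) in the
    beam-rotated frame, filled in at planning time from the PTV projection.
    """

    gantry_deg: float
    weight: float = 1.0
    aperture: np.ndarray | None = None


@dataclass
class PlanConfig:
    """Prescription, beam arrangement and the fixed fluence scale."""

    prescription_gy: float = 60.0
    fractions: int = 20
    beams: list = field(default_factory=list)
    isocenter_mm: tuple = (0.0, 0.0, 0.0)
    aperture_margin_mm: float = 6.0
    penumbra_sigma_mm: float = 4.0
    mu_eff_per_mm: float = 0.005
    mu_scale: float | None = None        # set by plan_on_ct, then frozen
    target_structure: str = "PTV60"

    def __post_init__(self):
        if self.prescription_gy <= 0 or self.fractions < 1:
            raise ConfigurationError("prescription and fractions must be positive")
        if self.beams and len(self.beams) < 2:
            raise ConfigurationError("a plan needs at least 2 beams")
        if any(b.weight <= 0 for b in self.beams):
            raise ConfigurationError("beam weights must be positive")

    @classmethod
    def default(cls, isocenter_mm=(0.0, 0.0, 0.0), n_beams: int = 7,
                **overrides) -> "PlanConfig":
        """Equispaced coplanar beams emulating a VMAT-like arrangement."""
        beams = [Beam(gantry_deg=i * 360.0 / n_beams) for i in range(n_beams)]
        return cls(beams=beams, isocenter_mm=tuple(isocenter_mm), **overrides)

    def has_apertures(self) -> bool:
        return bool(self.beams) and all(b.aperture is not None for b in self.beams)


def _rotate(vol: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    if angle_deg % 360.0 == 0.0:
        return vol.astype(float, copy=True)
    return ndimage.rotate(vol, angle_deg, axes=(1, 2), reshape=False,
                          order=order, mode="constant", cval=0.0, prefilter=False)


def set_apertures(plan: PlanConfig, target_mask: ImageGrid) -> PlanConfig:
    """Fill per-beam BEV apertures from the target projection + margin."""
    sz, sr, sc = target_mask.spacing
    beams = []
    for beam in plan.beams:
        rot = _rotate(target_mask.voxels.astype(float), beam.gantry_deg) > 0.5
        bev = rot.any(axis=1)  # (slice, lateral-col)
        if bev.any():
            dist = ndimage.distance_transform_edt(~bev, sampling=(sz, sc))
            bev = dist <= plan.aperture_margin_mm
        beams.append(replace(beam, aperture=bev.astype(float)))
    return replace(plan, beams=beams)


def compute_dose(red: ImageGrid, plan: PlanConfig) -> ImageGrid:
    """Sum weighted attenuated beam fluences; requires apertures and MU set.

    Per beam: the density grid is rotated so the beam travels along the row
    axis, the radiological depth is the running line integral of density,
    the primary is ``exp(-mu_eff * depth)`` through the aperture, a Gaussian
    penumbra blurs the field edges, and the result is rotated back.
    """
    if not plan.has_apertures():
        raise ConfigurationError("plan has no beam apertures; run set_apertures "
                                 "or plan_on_ct first")
    if plan.mu_scale is None:
        raise ConfigurationError("plan has no mu_scale; run plan_on_ct first")
    if sum(b.weight for b in plan.beams) <= 0:
        raise ConfigurationError("zero total fluence")
    sz, sr, sc = red.spacing
    total = np.zeros(red.shape)
    sigma_vox = (plan.penumbra_sigma_mm / sz, 0.0, plan.penumbra_sigma_mm / sc)
    for beam in plan.beams:
        rho = _rotate(red.voxels, beam.gantry_deg)
        depth = (np.cumsum(rho, axis=1) - rho / 2.0) * sr
        fluence = np.exp(-plan.mu_eff_per_mm * depth)
        fluence *= beam.aperture[:, None, :]
        if plan.penumbra_sigma_mm > 0:
            fluence = ndimage.gaussian_filter(fluence, sigma=sigma_vox,
                                              mode="constant")
        total += beam.weight * _rotate(fluence, -beam.gantry_deg)
    dose = plan.mu_scale * total
    return ImageGrid(dose, spacing=red.spacing, origin=red.origin,
                     modality="DOSE", units="Gy")


def plan_on_ct(ct: ImageGrid, plan: PlanConfig, target_mask: ImageGrid,
               curve: CalibrationCurve | None = None):
    """Planning run: build apertures, renormalize MU so the target median
    equals the prescription, and return (dose, plan-with-frozen-MU)."""
    curve = curve or CalibrationCurve()
    plan = set_apertures(plan, target_mask)
    plan = replace(plan, mu_scale=1.0)
    raw = compute_dose(hu_to_red(ct, curve), plan)
    med = float(np.median(raw.voxels[target_mask.voxels]))
    if med <= 0:
        raise ConfigurationError("target receives no dose; check geometry")
    scale = plan.prescription_gy / med
    plan = replace(plan, mu_scale=scale)
    dose = raw.copy(voxels=raw.voxels * scale)
    return dose, plan


def recalc_fixed_mu(sct: ImageGrid, plan_with_mu: PlanConfig,
                    curve: CalibrationCurve | None = None) -> ImageGrid:
    """Recalculate dose on a synthetic CT with identical beams and MU."""
    if plan_with_mu.mu_scale is None or not plan_with_mu.has_apertures():
        raise ConfigurationError(
            "recalculation requires the frozen plan from plan_on_ct")
    return compute_dose(hu_to_red(sct, curve or CalibrationCurve()), plan_with_mu)


def save_plan(plan: PlanConfig, directory) -> None:
    """Persist a frozen plan (beam table, apertures, MU) to a directory."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "prescription_gy": plan.prescription_gy, "fractions": plan.fractions,
        "isocenter_mm": list(plan.isocenter_mm),
        "aperture_margin_mm": plan.aperture_margin_mm,
        "penumbra_sigma_mm": plan.penumbra_sigma_mm,
        "mu_eff_per_mm": plan.mu_eff_per_mm, "mu_scale": plan.mu_scale,
        "target_structure": plan.target_structure,
        "beams": [{"gantry_deg": b.gantry_deg, "weight": b.weight}
                  for b in plan.beams],
    }
    (directory / "plan.json").write_text(json.dumps(meta, indent=1))
    arrays = {f"aperture_{i}": b.aperture for i, b in enumerate(plan.beams)
              if b.aperture is not None}
    if arrays:
        np.savez(directory / "apertures.npz", **arrays)


def load_plan(directory) -> PlanConfig:
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "plan.json").read_text())
    beam_meta = meta.pop("beams")
    beams = [Beam(**b) for b in beam_meta]
    ap_file = directory / "apertures.npz"
    if ap_file.exists():
        with np.load(ap_file) as data:
            for i, beam in enumerate(beams):
                key = f"aperture_{i}"
                if key in data:
                    beam.aperture = data[key]
    return PlanConfig(beams=beams, **{k: tuple(v) if k == "isocenter_mm" else v
                                      for k, v in meta.items()})


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

@dataclass
class GammaCriteria:
    """Local gamma criteria: 2%/2 mm over points above 20% of max dose."""

    dose_tol: float = 0.02
    dta_mm: float = 2.0
    threshold: float = 0.20
    step_mm: float = 0.5
    search_radius_factor: float = 3.0
    normalization: str = "local"

    def __post_init__(self):
        if min(self.dose_tol, self.dta_mm, self.threshold, self.step_mm) <= 0:
            raise ConfigurationError("gamma criteria must all be positive")


@dataclass
class GammaResult:
    gamma_map: ImageGrid     # gamma where evaluated, -1 where excluded
    pass_rate: float         # percent of evaluated voxels with gamma <= 1
    n_evaluated: int


def _search_offsets(criteria: GammaCriteria):
    radius = criteria.search_radius_factor * criteria.dta_mm
    ax = np.arange(-radius, radius + 1e-9, criteria.step_mm)
    dz, dr, dc = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.column_stack([dz.ravel(), dr.ravel(), dc.ravel()])
    norms = np.linalg.norm(offs, axis=1)
    keep = norms <= radius + 1e-9
    offs, norms = offs[keep], norms[keep]
    order = np.argsort(norms, kind="stable")
    return offs[order], norms[order]


def gamma_analysis(reference: ImageGrid, evaluated: ImageGrid,
                   criteria: GammaCriteria | None = None) -> GammaResult:
    """3D local-normalization gamma index with sub-voxel search.

    For each reference voxel above the low-dose threshold, the evaluated
    dose is trilinearly interpolated on a sphere of radius 3 x DTA sampled
    every ``step_mm``; gamma is the minimum over the sphere of
    ``sqrt(dose_term^2 + distance_term^2)`` with the dose difference
    normalized to the local reference dose.
    """
    criteria = criteria or GammaCriteria()
    if not reference.same_geometry(evaluated):
        raise GeometryError("gamma requires identical grids; resample first")
    ref = reference.voxels.astype(float)
    cutoff = criteria.threshold * ref.max()
    eval_mask = (ref >= cutoff) & (ref > 0)
    if not eval_mask.any():
        raise ValueError("all voxels below the gamma dose threshold")
    idx = np.argwhere(eval_mask).astype(float)     # (n, 3) voxel indices
    d_ref = ref[eval_mask]
    denom = criteria.dose_tol * d_ref              # local normalization
    spacing = np.asarray(reference.spacing)
    offsets, norms = _search_offsets(criteria)

    best = np.full(len(idx), np.inf)
    active = np.ones(len(idx), dtype=bool)
    ev = evaluated.voxels.astype(float)
    for off, dist in zip(offsets, norms):
        spatial2 = (dist / criteria.dta_mm) ** 2
        active &= best > spatial2      # further offsets cannot improve these
        if not active.any():
            break
        coords = (idx[active] + off / spacing).T
        d_ev = ndimage.map_coordinates(ev, coords, order=1, mode="nearest")
        g2 = ((d_ev - d_ref[active]) / denom[active]) ** 2 + spatial2
        best[active] = np.minimum(best[active], g2)
    gamma = np.sqrt(best)
    gmap = np.full(ref.shape, -1.0)
    gmap[eval_mask] = gamma
    pass_rate = 100.0 * float(np.mean(gamma <= 1.0 + 1e-9))
    out = ImageGrid(gmap, spacing=reference.spacing, origin=reference.origin,
                    modality="DOSE", units="arbitrary")
    return GammaResult(gamma_map=out, pass_rate=pass_rate,
                       n_evaluated=int(len(idx)))
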