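"""Rectal dose-surface maps and their binary-map parameterization.

On every axial slice the rectal contour is unwrapped starting at its
posterior-most point and traversed clockwise (viewed from inferior),
sampling the planar dose at equal arc-length steps.  Stacking slices
inferior -> superior gives the raw DSM, which is bilinearly interpolated to
a square 42 x 42 array (circumference treated as periodic) and converted to
EQD2.  Binary maps at 51 and 61 Gy are parameterized by the relative area
of the 51 Gy region and the relative lateral extent of a moment-equivalent
ellipse fitted to the largest 61 Gy cluster; the published cut-offs
associated with grade-2 rectal bleeding are 0.374 and 0.591 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import ImageGrid
from .rectal_metrics import eqd2

#: binary-map decision thresholds associated with G2 rectal bleeding
AREA_51_CUTOFF = 0.374
LAT_EXTENT_61_CUTOFF = 0.591
DSM_SHAPE = (42, 42)


@dataclass
class DoseSurfaceMap:
    raw: np.ndarray                    # (n_slices, n_samples) Gy
    interpolated: np.ndarray | None = None   # (42, 42) Gy
    is_eqd2: bool = False
    slice_indices: tuple = ()


@dataclass
class EllipseFit:
    center: tuple
    semi_axes: tuple
    orientation_deg: float
    lateral_extent: float
    relative_lateral_extent: float
    n_cells: int = 0


def _anchor_index(points: np.ndarray) -> int:
    """Posterior-most vertex; ties broken toward patient-right (low col)."""
    rows = points[:, 0]
    candidates = np.flatnonzero(rows <= rows.min() + 1e-12)
    return int(candidates[np.argmin(points[candidates, 1])])


def _clockwise(points: np.ndarray) -> np.ndarray:
    """Orient the vertex list clockwise in the (col, row) frame."""
    r, c = points[:, 0], points[:, 1]
    area2 = np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)
    return points[::-1] if area2 > 0 else points


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """n equal-arc-length samples along a closed polygon from vertex 0."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(n) * total / n
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.interp(targets, s, closed[:, k])
    return out


def unwrap_surface(dose: ImageGrid, rectum_contours, n_samples: int = 100) -> DoseSurfaceMap:
    """Sample the planar dose around each rectal contour.

    Rows are ordered inferior -> superior; column 0 is anchored at the
    posterior-most contour point of every slice.
    """
    contours = sorted(rectum_contours, key=lambda c: c.slice_index)
    if not contours:
        raise ValueError("no rectal contours supplied")
    rows = []
    indices = []
    for contour in contours:
        pts = np.asarray(contour.points, dtype=float)
        if len(pts) < 3:
            raise ValueError("degenerate contour with fewer than 3 points")
        pts = _clockwise(pts)
        a = _anchor_index(pts)
        pts = np.roll(pts, -a, axis=0)
        samples = _resample_closed(pts, n_samples)
        # bilinear in-plane dose interpolation at the sample points
        ridx = (samples[:, 0] - dose.origin[1]) / dose.spacing[1]
        cidx = (samples[:, 1] - dose.origin[2]) / dose.spacing[2]
        plane = dose.voxels[contour.slice_index].astype(float)
        vals = ndimage.map_coordinates(plane, np.vstack([ridx, cidx]),
                                       order=1, mode="nearest")
        rows.append(vals)
        indices.append(contour.slice_index)
    return DoseSurfaceMap(raw=np.vstack(rows), slice_indices=tuple(indices))


def _interp_axis(arr: np.ndarray, positions: np.ndarray, axis: int,
                 periodic: bool) -> np.ndarray:
    arr = np.moveaxis(arr, axis, 0)
    n = arr.shape[0]
    if periodic:
        src = np.vstack([arr, arr[:1]])
        x = np.arange(n + 1, dtype=float)
    else:
        src, x = arr, np.arange(n, dtype=float)
    lo = np.clip(np.floor(positions).astype(int), 0, len(x) - 2)
    t = positions - lo
    out = (1 - t)[:, None] * src[lo] + t[:, None] * src[lo + 1]
    return np.moveaxis(out, 0, axis)


def interpolate_dsm(dsm: DoseSurfaceMap | np.ndarray,
                    target: tuple = DSM_SHAPE) -> DoseSurfaceMap:
    """Bilinear interpolation to the square target shape.

    The cranio-caudal axis interpolates between end rows; the
    circumferential axis is periodic.
    """
    if isinstance(dsm, np.ndarray):
        dsm = DoseSurfaceMap(raw=np.asarray(dsm, dtype=float))
    raw = np.asarray(dsm.raw, dtype=float)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValueError("raw DSM must be at least 2 x 2")
    rpos = np.linspace(0.0, raw.shape[0] - 1, target[0])
    out = _interp_axis(raw, rpos, axis=0, periodic=False)
    cpos = np.linspace(0.0, raw.shape[1], target[1], endpoint=False)
    out = _interp_axis(out.reshape(target[0], raw.shape[1]), cpos, axis=1,
                       periodic=True)
    return DoseSurfaceMap(raw=raw, interpolated=out, is_eqd2=dsm.is_eqd2,
                          slice_indices=dsm.slice_indices)


def dsm_to_eqd2(dsm: DoseSurfaceMap, fractions: int = 20,
                alpha_beta: float = 3.0) -> DoseSurfaceMap:
    """EQD2-convert the interpolated map (per cell, d = D / fractions)."""
    if dsm.interpolated is None:
        raise ValueError("interpolate the DSM before EQD2 conversion")
    conv = eqd2(dsm.interpolated, fractions, alpha_beta)
    return DoseSurfaceMap(raw=dsm.raw, interpolated=conv, is_eqd2=True,
                          slice_indices=dsm.slice_indices)


def binarize_dsm(dsm: DoseSurfaceMap, threshold_gy: float):
    """Binary map (cell >= threshold) and its area relative to the full DSM."""
    if not dsm.is_eqd2:
        raise ValueError("binary DSM parameters are defined on EQD2 maps")
    binary = dsm.interpolated >= threshold_gy
    return binary, float(binary.sum()) / binary.size


def _wrap_label(binary: np.ndarray) -> np.ndarray:
    """8-connected components with circumferential (column) wrap-around."""
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels
    parent = list(range(n + 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    nrows = binary.shape[0]
    for r in range(nrows):
        if not binary[r, -1]:
            continue
        for dr in (-1, 0, 1):
            rr = r + dr
            if 0 <= rr < nrows and binary[rr, 0]:
                a, b = find(labels[r, -1]), find(labels[rr, 0])
                if a != b:
                    parent[max(a, b)] = min(a, b)
    lut = np.array([find(i) for i in range(n + 1)])
    return lut[labels]


def largest_cluster_ellipse(binary: np.ndarray) -> EllipseFit:
    """Moment-equivalent ellipse of the largest connected cluster.

    Clusters use 8-connectivity with wrap-around across the circumferential
    seam.  The lateral extent is the length of the ellipse's projection on
    the circumferential axis; an empty map yields the all-zero fit.
    """
    binary = np.asarray(binary, dtype=bool)
    width = binary.shape[1]
    labels = _wrap_label(binary)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return EllipseFit(center=(0.0, 0.0), semi_axes=(0.0, 0.0),
                          orientation_deg=0.0, lateral_extent=0.0,
                          relative_lateral_extent=0.0, n_cells=0)
    best, best_key = None, None
    for i in ids:
        rows, cols = np.nonzero(labels == i)
        key = (-len(rows), rows.mean(), cols.mean())
        if best_key is None or key < best_key:
            best, best_key = (rows, cols), key
    rows, cols = best

    # unwrap seam-crossing clusters so column moments are contiguous
    present = np.zeros(width, dtype=bool)
    present[cols] = True
    if present[0] and present[-1] and not present.all():
        gap_start = int(np.flatnonzero(~present)[0])
        cols = np.where(cols < gap_start, cols + width, cols)

    rbar, cbar = rows.mean(), cols.mean()
    mrr = rows.var() + 1.0 / 12.0       # + cell second moment (unit squares)
    mcc = cols.var() + 1.0 / 12.0
    mrc = float(np.mean((rows - rbar) * (cols - cbar)))
    cov = np.array([[mrr, mrc], [mrc, mcc]])
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = tuple(2.0 * np.sqrt(np.maximum(evals, 0.0)))
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    lateral = 4.0 * float(np.sqrt(mcc))  # projection on the column axis
    return EllipseFit(center=(float(rbar), float(cbar % width)),
                      semi_axes=semi, orientation_deg=angle,
                      lateral_extent=lateral,
                      relative_lateral_extent=lateral / width,
                      n_cells=len(rows))


def export_dsm(dsm: DoseSurfaceMap, csv_path, png_path=None) -> None:
    """Write the interpolated 42x42 map as CSV and optionally a heat map."""
    if dsm.interpolated is None:
        raise ValueError("interpolate the DSM before exporting")
    np.savetxt(csv_path, dsm.interpolated, delimiter=",", fmt="%.6g")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(dsm.interpolated, origin="lower", cmap="inferno",
                       aspect="auto")
        ax.set_xlabel("circumference (posterior -> clockwise)")
        ax.set_ylabel("inferior -> superior")
        fig.colorbar(im, ax=ax, label="EQD2 (Gy)" if dsm.is_eqd2 else "Gy")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def dsm_parameters(dose: ImageGrid, rectum_contours, fractions: int = 20,
                   alpha_beta: float = 3.0, n_samples: int = 100) -> dict:
    """Full DSM chain: unwrap, 42x42 interpolation, EQD2, binary parameters."""
    dsm = unwrap_surface(dose, rectum_contours, n_samples=n_samples)
    dsm = dsm_to_eqd2(interpolate_dsm(dsm), fractions, alpha_beta)
    _, rel_area_51 = binarize_dsm(dsm, 51.0)
    binary61, _ = binarize_dsm(dsm, 61.0)
    fit = largest_cluster_ellipse(binary61)
    return {
        "rel_area_51": rel_area_51,
        "rel_lat_extent_61": fit.relative_lateral_extent,
        "area_flag": rel_area_51 > AREA_51_CUTOFF,
        "extent_flag": fit.relative_lateral_extent > LAT_EXTENT_61_CUTOFF,
    }
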