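"""DVH computation, fractionation correction and LKB NTCP.

The normal-tissue complication probability follows the Lyman-Kutcher-Burman
model: voxel doses are converted to the equivalent dose in 2 Gy fractions
(EQD2, linear-quadratic with alpha/beta), reduced to a generalized
equivalent uniform dose gEUD = (sum_i v_i D_i^(1/n))^n, and mapped through
the probit NTCP = Phi((gEUD - TD50) / (m TD50)).  Published parameter sets
for grade-2 rectal bleeding and late faecal incontinence ship as defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core_io import GeometryError, ImageGrid


@dataclass
class LKBParams:
    """LKB parameters for one toxicity endpoint."""

    td50: float
    m: float
    n: float
    alpha_beta: float
    endpoint: str = ""

    def __post_init__(self):
        if self.td50 <= 0 or self.m <= 0 or not 0 < self.n <= 1 \
                or self.alpha_beta <= 0:
            raise ValueError("invalid LKB parameters")


#: grade-2 late rectal bleeding
G2_RECTAL_BLEEDING = LKBParams(td50=97.7, m=0.27, n=0.085, alpha_beta=3.0,
                               endpoint="G2 rectal bleeding")
#: late faecal incontinence (n = 1: pure mean-dose effect)
LATE_FAECAL_INCONTINENCE = LKBParams(td50=105.0, m=0.43, n=1.0, alpha_beta=3.0,
                                     endpoint="late faecal incontinence")


@dataclass
class DVHCurve:
    """Differential + cumulative dose-volume histogram (volume fractions)."""

    bin_edges: np.ndarray        # (k+1,) Gy
    v_diff: np.ndarray           # (k,) fractions, sums to 1
    cumulative: np.ndarray       # (k+1,) V(d) at the bin edges, V(0)=1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def compute_dvh(dose: ImageGrid, mask: ImageGrid, bin_width: float = 0.1) -> DVHCurve:
    """Voxel-count DVH of the dose within a mask (equal voxel volumes)."""
    if not dose.same_geometry(mask):
        raise GeometryError("dose and mask must share geometry")
    m = mask.voxels.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    return dvh_from_doses(dose.voxels[m], bin_width)


def dvh_from_doses(doses: np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    doses = np.asarray(doses, dtype=float).ravel()
    top = max(float(doses.max()), bin_width)
    n_bins = int(np.ceil(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    v = counts / doses.size
    # V(d) at each edge: fraction of volume receiving >= d
    cum = np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])
    cum[0] = 1.0
    return DVHCurve(bin_edges=edges, v_diff=v, cumulative=cum)


def dvh_metric(dvh: DVHCurve, metric: str):
    """Point metrics on the cumulative curve.

    ``"D95"`` / ``"D50"`` / ``"Dmedian"`` give the maximum dose with
    V >= the quantile (linear interpolation between edges, right-continuous
    at jumps); ``"V60"``-style names give the interpolated V(d) fraction.
    """
    metric = metric.strip()
    if metric.upper().startswith("D"):
        q = 50.0 if metric.lower() == "dmedian" else float(metric[1:])
        return _dose_at_volume(dvh, q / 100.0)
    if metric.upper().startswith("V"):
        return volume_at_dose(dvh, float(metric[1:]))
    raise ValueError(f"unknown DVH metric {metric!r}")


def _dose_at_volume(dvh: DVHCurve, fraction: float) -> float:
    edges, cum = dvh.bin_edges, dvh.cumulative
    if fraction > cum[0]:
        return float(edges[0])
    # last edge index with V >= fraction (cum is non-increasing)
    i = int(np.searchsorted(-cum, -fraction, side="right")) - 1
    if i >= len(edges) - 1:
        return float(edges[-1])
    if cum[i] == cum[i + 1]:
        return float(edges[i])
    if cum[i + 1] >= fraction:          # flat-above region, step to the right
        return float(edges[i + 1])
    t = (cum[i] - fraction) / (cum[i] - cum[i + 1])
    return float(edges[i] + t * (edges[i + 1] - edges[i]))


def volume_at_dose(dvh: DVHCurve, dose: float) -> float:
    edges, cum = dvh.bin_edges, dvh.cumulative
    if dose <= edges[0]:
        return float(cum[0])
    if dose >= edges[-1]:
        return float(cum[-1])
    return float(np.interp(dose, edges, cum))


def eqd2(dose, fractions: int, alpha_beta: float = 3.0):
    """Equivalent dose in 2 Gy fractions; element-wise on arrays.

    With d = dose/fractions per fraction, EQD2 = dose (d + ab) / (2 + ab).
    """
    dose = np.asarray(dose, dtype=float)
    if fractions < 1:
        raise ValueError("fractions must be >= 1")
    d = dose / fractions
    out = dose * (d + alpha_beta) / (2.0 + alpha_beta)
    return float(out) if out.ndim == 0 else out


def geud(dvh: DVHCurve, n: float) -> float:
    """Power-mean gEUD over the DVH bin centers; n=1 is the mean dose."""
    if n <= 0:
        raise ValueError("volume exponent n must be positive")
    d = dvh.bin_centers
    v = dvh.v_diff
    if n == 1.0:
        return float(np.sum(v * d))
    return float(np.sum(v * d ** (1.0 / n)) ** n)


def write_dvh_csv(dvh: DVHCurve, path) -> None:
    """Export as (dose_gy, v_diff, V_cum) rows; V_cum at the left bin edge."""
    rows = np.column_stack([dvh.bin_edges[:-1], dvh.v_diff,
                            dvh.cumulative[:-1]])
    np.savetxt(path, rows, delimiter=",", fmt="%.8g",
               header="dose_gy,v_diff,V_cum", comments="")


@dataclass
class RiskResult:
    geud: float
    ntcp: float
    endpoint: str

    def to_json(self) -> str:
        import json

        return json.dumps({"endpoint": self.endpoint, "geud_gy": self.geud,
                           "ntcp": self.ntcp})


def lkb_ntcp(geud_gy: float, params: LKBParams) -> RiskResult:
    """Probit LKB response: NTCP = Phi((gEUD - TD50) / (m TD50))."""
    t = (geud_gy - params.td50) / (params.m * params.td50)
    return RiskResult(geud=float(geud_gy), ntcp=float(norm.cdf(t)),
                      endpoint=params.endpoint)


def ntcp_from_dose(dose: ImageGrid, mask: ImageGrid, params: LKBParams,
                   fractions: int = 20, bin_width: float = 0.1,
                   eqd2_per_voxel: bool = True) -> RiskResult:
    """Full chain: voxel doses -> EQD2 -> DVH -> gEUD -> NTCP.

    EQD2 is applied per voxel by default; per-DVH-bin conversion is kept as
    an option for parity with DVH-level tooling.
    """
    if not dose.same_geometry(mask):
        raise GeometryError("dose and mask must share geometry")
    m = mask.voxels.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    doses = dose.voxels[m].astype(float)
    if eqd2_per_voxel:
        curve = dvh_from_doses(eqd2(doses, fractions, params.alpha_beta),
                               bin_width)
    else:
        curve = dvh_from_doses(doses, bin_width)
        centers = eqd2(curve.bin_centers, fractions, params.alpha_beta)
        curve = DVHCurve(bin_edges=curve.bin_edges, v_diff=curve.v_diff,
                         cumulative=curve.cumulative)
        if params.n == 1.0:
            g = float(np.sum(curve.v_diff * centers))
        else:
            g = float(np.sum(curve.v_diff * centers ** (1.0 / params.n))
                      ** params.n)
        return lkb_ntcp(g, params)
    return lkb_ntcp(geud(curve, params.n), params)
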