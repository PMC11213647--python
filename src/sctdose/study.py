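"""End-to-end study orchestration on synthetic phantoms.

One "case" mirrors the clinical workflow: a plan is optimized on the ground
truth CT (apertures from the PTV, monitor units frozen so the PTV median
equals the prescription), synthetic CTs are built by each method, the dose
is recalculated with identical beams and MU, and DVH-, NTCP- and
DSM-derived rectal toxicity predictors plus a local gamma pass rate are
extracted for every dose distribution.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import dsm as dsm_mod
from .core_io import ImageGrid
from .dose_engine import (CalibrationCurve, GammaCriteria, gamma_analysis,
                          plan_on_ct, recalc_fixed_mu)
from .phantom import Phantom, PhantomConfig, generate_phantom, random_deformation
from .rectal_metrics import (G2_RECTAL_BLEEDING, LATE_FAECAL_INCONTINENCE,
                             compute_dvh, dvh_metric, ntcp_from_dose)
from .sct_classical import (StratificationRules, make_bd_sct, population_mean_hu,
                            ts_sct_from_ct)
from .sct_unet import UNetConfig, infer_sct, make_pair, train_unet

METHODS = ("identity", "bdw", "bdp", "ts", "ts_ct", "ai")

#: metrics reported per dose distribution (percent-scaled where noted)
METRIC_NAMES = ("ptv60_median_gy", "ptv60_d95_gy", "ptv48_d95_gy",
                "rectum_v60_pct", "g2rb_ntcp_pct", "lfi_ntcp_pct",
                "rel_area_51_pct", "rel_lat_extent_61_pct")


def toxicity_metrics(dose: ImageGrid, phantom: Phantom) -> dict:
    """DVH, LKB-NTCP and DSM predictors of one dose distribution."""
    masks = phantom.structures.masks
    fractions = phantom.plan.fractions
    out = {}
    ptv60_dvh = compute_dvh(dose, masks["PTV60"])
    out["ptv60_median_gy"] = dvh_metric(ptv60_dvh, "Dmedian")
    out["ptv60_d95_gy"] = dvh_metric(ptv60_dvh, "D95")
    out["ptv48_d95_gy"] = dvh_metric(compute_dvh(dose, masks["PTV48"]), "D95")
    rect_dvh = compute_dvh(dose, masks["RECTUM"])
    out["rectum_v60_pct"] = 100.0 * dvh_metric(rect_dvh, "V60")
    for key, params in (("g2rb", G2_RECTAL_BLEEDING),
                        ("lfi", LATE_FAECAL_INCONTINENCE)):
        risk = ntcp_from_dose(dose, masks["RECTUM"], params, fractions=fractions)
        out[f"{key}_ntcp_pct"] = 100.0 * risk.ntcp
    pars = dsm_mod.dsm_parameters(dose, phantom.structures.contours_for("RECTUM"),
                                  fractions=fractions)
    out["rel_area_51_pct"] = 100.0 * pars["rel_area_51"]
    out["rel_lat_extent_61_pct"] = 100.0 * pars["rel_lat_extent_61"]
    return out


def _warp_ct(phantom: Phantom, magnitude_mm: float, seed: int) -> ImageGrid:
    """CT as seen through a residual-misregistration deformation."""
    from scipy import ndimage

    field = random_deformation(phantom.config, magnitude_mm, seed)
    sp = np.asarray(phantom.ct.spacing)[:, None, None, None]
    coords = np.indices(phantom.ct.shape, dtype=float) + field.displacement / sp
    warped = ndimage.map_coordinates(phantom.ct.voxels.astype(float), coords,
                                     order=1, mode="nearest")
    return phantom.ct.copy(voxels=warped)


#: desk-scale overfit recipe: converges to sub-TS risk error in minutes on CPU
DEFAULT_AI_CONFIG = UNetConfig(base_filters=8, dropout=0.0, lr=3e-3, epochs=800)


def build_sct(phantom: Phantom, method: str, *,
              population_hu: float | None = None,
              rules: StratificationRules | None = None,
              unet_config: UNetConfig | None = None,
              train_stride: int = 4,
              misregistration_mm: float = 2.0) -> ImageGrid:
    """Build one synthetic CT for a phantom.

    ``ts`` stratifies the CT seen through a small random deformation
    (residual registration error); ``ts_ct`` stratifies the planning CT
    itself (the ground-truth-stratification control).  ``ai`` trains an
    overfit U-Net on the phantom's own MR/CT pair unless a model is
    injected via :func:`run_case`.
    """
    body = phantom.structures.masks["BODY"]
    if method == "identity":
        return phantom.ct.copy()
    if method == "bdw":
        return make_bd_sct(body, 0.0)
    if method == "bdp":
        if population_hu is None:
            population_hu = population_mean_hu([phantom.ct], [body])
        return make_bd_sct(body, population_hu)
    if method == "ts":
        warped = _warp_ct(phantom, misregistration_mm,
                          seed=phantom.config.seed + 10_000)
        return ts_sct_from_ct(warped, phantom.structures, rules)
    if method == "ts_ct":
        return ts_sct_from_ct(phantom.ct, phantom.structures, rules)
    if method == "ai":
        from dataclasses import replace as _replace

        from .sct_unet import NormalizedPair

        cfg = unet_config or _replace(DEFAULT_AI_CONFIG,
                                      seed=phantom.config.seed)
        pair = make_pair(phantom.mr, phantom.ct)
        if train_stride > 1:   # train on a slice subset, infer on the volume
            sl = slice(train_stride // 2, None, train_stride)
            pair = NormalizedPair(pair.mr_norm[sl], pair.ct_norm[sl],
                                  pair.mr_scale)
        model = train_unet([pair], cfg)
        return infer_sct(model, phantom.mr)
    raise ValueError(f"unknown sCT method {method!r}")


def run_case(phantom: Phantom, methods=METHODS, *, population_hu=None,
             unet_config: UNetConfig | None = None,
             gamma_criteria: GammaCriteria | None = None,
             curve: CalibrationCurve | None = None,
             misregistration_mm: float = 2.0, train_stride: int = 4,
             with_gamma: bool = True) -> dict:
    """Plan on the CT, recalculate on each sCT, extract all predictors."""
    curve = curve or CalibrationCurve()
    truth_dose, plan = plan_on_ct(phantom.ct, phantom.plan,
                                  phantom.structures.masks["PTV60"], curve)
    phantom = replace(phantom, plan=plan)
    results = {"truth": toxicity_metrics(truth_dose, phantom)}
    results["truth"]["gamma_pass_pct"] = 100.0
    for method in methods:
        sct = build_sct(phantom, method, population_hu=population_hu,
                        unet_config=unet_config, train_stride=train_stride,
                        misregistration_mm=misregistration_mm)
        dose = recalc_fixed_mu(sct, plan, curve)
        metrics = toxicity_metrics(dose, phantom)
        if with_gamma:
            g = gamma_analysis(truth_dose, dose,
                               gamma_criteria or GammaCriteria())
            metrics["gamma_pass_pct"] = g.pass_rate
        results[method] = metrics
    return results


def run_study(seeds, methods=METHODS, *, config_factory=None,
              unet_config: UNetConfig | None = None, with_gamma: bool = False,
              misregistration_mm: float = 2.0) -> dict:
    """Run one case per seed; returns {method: {metric: per-seed values}}.

    The population HU for the bulk-density variant is pooled over the
    cohort's own bodies (standing in for the non-test training patients).
    """
    config_factory = config_factory or (lambda s: PhantomConfig.small(seed=s))
    phantoms = [generate_phantom(config_factory(s)) for s in seeds]
    population_hu = population_mean_hu(
        [p.ct for p in phantoms],
        [p.structures.masks["BODY"] for p in phantoms])
    collected = {}
    for phantom in phantoms:
        case = run_case(phantom, methods, population_hu=population_hu,
                        unet_config=unet_config, with_gamma=with_gamma,
                        misregistration_mm=misregistration_mm)
        for method, metrics in case.items():
            for name, value in metrics.items():
                collected.setdefault(method, {}).setdefault(name, []).append(value)
    return collected
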