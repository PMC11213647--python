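"""Per-method error statistics and report assembly.

For every synthetic-CT method and toxicity metric the study compares
per-case values against the ground-truth planning-CT value: mean (absolute)
error and sample SD, Bland-Altman 95% limits of agreement
(mean +/- 1.96 SD), a paired two-sided t-test and a Shapiro-Wilk normality
check.  ``build_report`` assembles the per-case tables, the summary JSON and
box plots of the error distributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairedErrors:
    """Ground-truth vs sCT values of one metric for one method."""

    method: str
    metric: str
    truth: np.ndarray
    sct: np.ndarray

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=float)
        self.sct = np.asarray(self.sct, dtype=float)
        if self.truth.shape != self.sct.shape or self.truth.size < 2:
            raise ValueError("need matched value lists with n >= 2")
        if not np.all(np.isfinite(self.truth)) or not np.all(np.isfinite(self.sct)):
            raise ValueError("values must be finite")

    @property
    def differences(self) -> np.ndarray:
        return self.sct - self.truth


@dataclass
class ErrorSummary:
    mean_abs_error: float
    sd: float
    loa_lower: float
    loa_upper: float
    p_value: float
    normality_p: float


def error_summary_stats(differences, absolute: bool = True):
    """Mean and sample SD of the (absolute) differences."""
    diffs = np.asarray(differences, dtype=float)
    if diffs.size < 2:
        raise ValueError("need n >= 2 differences")
    vals = np.abs(diffs) if absolute else diffs
    return float(vals.mean()), float(vals.std(ddof=1))


def limits_of_agreement(mean: float, sd: float):
    """Bland-Altman 95% limits: mean +/- 1.96 SD."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return mean - 1.96 * sd, mean + 1.96 * sd


def paired_t(differences) -> float:
    """Two-sided p of the paired t-test on the differences.

    Degenerate zero-variance samples: p = 1 when all differences are zero,
    else p = 0 with a warning (an offset the test cannot quantify).
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.size < 2:
        raise ValueError("need n >= 2 differences")
    if np.allclose(diffs.std(ddof=0), 0.0):
        if np.allclose(diffs, 0.0):
            return 1.0
        warnings.warn("zero-variance nonzero differences: p reported as 0")
        return 0.0
    t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
    return float(2.0 * stats.t.sf(abs(t), df=diffs.size - 1))


def shapiro_wilk(values) -> float:
    """Shapiro-Wilk normality p-value for 3 <= n <= 50 samples."""
    vals = np.asarray(values, dtype=float)
    if not 3 <= vals.size <= 50:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 50")
    if np.allclose(vals, vals[0]):
        raise ValueError("identical values: normality test undefined")
    return float(stats.shapiro(vals).pvalue)


def summarize(errors: PairedErrors, absolute: bool = True) -> ErrorSummary:
    diffs = errors.differences
    mean, sd = error_summary_stats(diffs, absolute=absolute)
    lo, hi = limits_of_agreement(mean, sd)
    try:
        normality = shapiro_wilk(diffs)
    except ValueError:
        normality = float("nan")
    return ErrorSummary(mean_abs_error=mean, sd=sd, loa_lower=lo, loa_upper=hi,
                        p_value=paired_t(diffs), normality_p=normality)


def build_report(errors_by_metric: dict, out_dir, metadata: dict | None = None,
                 absolute: bool = True, make_figures: bool = True) -> dict:
    """Write per-metric CSVs, a summary JSON and error box plots.

    ``errors_by_metric`` maps metric name -> list of :class:`PairedErrors`
    (one per method).  Missing methods simply do not appear; the summary
    records how many statistical tests were run (no multiplicity
    correction is applied, matching single-comparison reporting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {"metadata": metadata or {}, "metrics": {}, "n_tests": 0}
    for metric, error_list in sorted(errors_by_metric.items()):
        rows = {}
        summary["metrics"][metric] = {}
        for err in error_list:
            s = summarize(err, absolute=absolute)
            summary["metrics"][metric][err.method] = asdict(s)
            summary["n_tests"] += 1
            rows["truth"] = err.truth
            rows[f"{err.method}"] = err.sct
            rows[f"{err.method}_diff"] = err.differences
        frame = pd.DataFrame(rows)
        frame.index.name = "case"
        frame.to_csv(out_dir / f"{metric}.csv")
        if make_figures and error_list:
            _boxplot(metric, error_list, out_dir)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
    return summary


def _boxplot(metric: str, error_list, out_dir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(error_list), 3.2))
    data = [e.differences for e in error_list]
    ax.boxplot(data, tick_labels=[e.method for e in error_list],
               showmeans=True)
    ax.axhline(0.0, lw=0.6, color="0.4")
    ax.set_ylabel(f"error in {metric} (sCT - truth)")
    fig.tight_layout()
    (out_dir / "figs").mkdir(exist_ok=True)
    fig.savefig(out_dir / "figs" / f"{metric}_errors.png", dpi=120)
    plt.close(fig)
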