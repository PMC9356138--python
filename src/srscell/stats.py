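"""Dose-response, regression, ROC and assay arithmetic for resistance calls.

Resistance to platinum is quantified by the IC50 of a 4-parameter logistic
(4PL) viability curve; the metabolic index is related to IC50 by ordinary
least squares; and a per-sample index classifies resistant vs sensitive
samples through a ROC analysis whose operating threshold maximizes
Youden's J.  The small arithmetic conventions of the supporting assays
(plate-reader oxygen consumption, FAO rate, qPCR delta-Ct, caliper tumor
volume, Seahorse respiration metrics, group t tests) live here too so every
number the pipeline reports has a tested definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit",
    "RegressionResult",
    "RocResult",
    "SeahorseMetrics",
    "fit_dose_response",
    "four_pl",
    "linear_fit",
    "roc_analysis",
    "ocr_slope",
    "fao_rate",
    "delta_ct",
    "tumor_volume",
    "group_test",
    "seahorse_metrics",
    "seahorse_reduction",
]


# ---------------------------------------------------------------------------
# 4PL dose-response


def four_pl(dose, top, bottom, log10_ic50, hill):
    """Viability (%) of the 4-parameter logistic on log10 dose.

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill); with hill > 0 the
    curve falls from ``top`` at low dose to ``bottom`` at high dose, and
    v(ic50) = (top + bottom) / 2.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill * (np.log10(dose) - log10_ic50))
    )


@dataclass
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    ci_ic50: tuple[float, float] | None = None

    def predict(self, dose):
        return four_pl(dose, self.top, self.bottom, np.log10(self.ic50), self.hill)


_BOUNDS = ([50.0, -10.0, -np.inf, 0.2], [120.0, 50.0, np.inf, 5.0])


def _fit_once(logd, v, p0, bounds):
    popt, _ = optimize.curve_fit(
        lambda ld, top, bottom, lic50, hill: bottom
        + (top - bottom) / (1.0 + 10.0 ** (hill * (ld - lic50))),
        logd,
        v,
        p0=p0,
        bounds=bounds,
        maxfev=5000,
        xtol=1e-12,
        ftol=1e-12,
    )
    pred = popt[1] + (popt[0] - popt[1]) / (1.0 + 10.0 ** (popt[3] * (logd - popt[2])))
    return popt, float(((v - pred) ** 2).sum())


def fit_dose_response(
    doses,
    viabilities,
    n_boot: int = 200,
    seed: int = 0,
    ci: bool = True,
) -> DoseResponseFit:
    """Fit the 4PL model and bootstrap a 95% CI for IC50 over replicates.

    Fitting is bounded (top in [50, 120] %, bottom in [-10, 50] %, hill in
    [0.2, 5], log10 IC50 within two decades of the dosed range) with
    multi-start initialization at the dose quartiles, which converges
    deterministically without fitter tuning.  The bootstrap resamples
    replicate wells within each dose and refits from the point estimate.
    Flat curves (no dynamic range) return ``converged=False``.
    """
    doses = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if doses.shape != v.shape:
        raise ValueError("doses and viabilities must align")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if not np.all(np.isfinite(v)):
        raise ValueError("viabilities must be finite")
    distinct = np.unique(doses)
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct doses")

    logd = np.log10(doses)
    span = v.max() - v.min()
    if span < 1e-6:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"), top=float(v.mean()),
            bottom=float(v.mean()), rss=0.0, converged=False,
        )

    lo = list(_BOUNDS[0])
    hi = list(_BOUNDS[1])
    lo[2] = np.log10(distinct.min()) - 2.0
    hi[2] = np.log10(distinct.max()) + 2.0
    bounds = (lo, hi)
    top0 = float(np.clip(v.max(), lo[0] + 1e-6, hi[0] - 1e-6))
    bot0 = float(np.clip(v.min(), lo[1] + 1e-6, hi[1] - 1e-6))

    best = None
    for q in (0.25, 0.5, 0.75):
        lic0 = float(np.quantile(logd, q))
        for hill0 in (0.7, 1.5):
            try:
                popt, rss = _fit_once(logd, v, [top0, bot0, lic0, hill0], bounds)
            except RuntimeError:
                continue
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"), top=top0, bottom=bot0,
            rss=float("inf"), converged=False,
        )
    popt, rss = best
    top, bottom, lic50, hill = popt

    # gross monotonicity check: mean viability should fall with dose
    means = np.array([v[doses == d].mean() for d in distinct])
    if distinct.size >= 3 and stats.spearmanr(distinct, means).statistic > 0.5:
        warnings.warn("viability rises with dose; 4PL fit may be meaningless",
                      stacklevel=2)

    ci_ic50 = None
    if ci:
        rng = np.random.default_rng(seed)
        groups = [np.flatnonzero(doses == d) for d in distinct]
        boot = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [g[rng.integers(0, len(g), len(g))] for g in groups]
            )
            try:
                bopt, _ = _fit_once(logd[idx], v[idx], popt, bounds)
            except RuntimeError:
                continue
            boot.append(bopt[2])
        if len(boot) >= max(20, n_boot // 2):
            # normal-theory interval on log10 IC50.  Case-resampling n
            # replicates within a dose deflates variance by (n-1)/n, so the
            # bootstrap SE is inflated by sqrt(n/(n-1)) (finite-sample
            # correction), keeping the nominal 95% level at 6 replicates.
            n_rep = float(np.mean([len(g) for g in groups]))
            infl = np.sqrt(n_rep / max(n_rep - 1.0, 1.0))
            se = float(np.std(boot, ddof=1)) * infl
            lo_b, hi_b = lic50 - 1.96 * se, lic50 + 1.96 * se
            ci_ic50 = (float(10.0**lo_b), float(10.0**hi_b))

    return DoseResponseFit(
        ic50=float(10.0**lic50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        rss=rss,
        converged=True,
        ci_ic50=ci_ic50,
    )


# ---------------------------------------------------------------------------
# linear regression


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    constant_y: bool = False


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares with R^2 = 1 - RSS/TSS.

    Constant x is a degenerate design (error); constant y returns slope 0
    with R^2 defined as 0 and flagged (the TSS = 0 convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.all(x == x[0]):
        raise ValueError("degenerate design: x is constant")
    if np.all(y == y[0]):
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, n=x.size, constant_y=True
        )
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=x.size,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    curve: pd.DataFrame  # threshold, sensitivity, specificity


def roc_analysis(scores, labels, positive: str = "resistant") -> RocResult:
    """ROC of a score that rises with the positive (resistant) class.

    AUC uses the rank (Mann-Whitney U) formulation with half credit for
    ties, so it equals the concordant-pair fraction and is invariant under
    strictly monotone score transforms.  The operating threshold maximizes
    Youden's J = sensitivity + specificity - 1 and is reported as the
    midpoint between adjacent distinct scores (ties in J break toward the
    lower threshold, i.e. higher sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(scores)  # average ranks give the tie credit
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    rows = []
    for t in thresholds:
        pred = scores >= t
        sens = float((pred & pos).sum() / n_pos)
        spec = float((~pred & ~pos).sum() / n_neg)
        rows.append({"threshold": float(t), "sensitivity": sens, "specificity": spec})
    curve = pd.DataFrame(rows)
    j = curve["sensitivity"] + curve["specificity"] - 1.0
    best = int(np.argmax(j.to_numpy()))  # first (lowest threshold) among ties
    return RocResult(
        auc=float(auc),
        threshold=float(curve.loc[best, "threshold"]),
        sensitivity=float(curve.loc[best, "sensitivity"]),
        specificity=float(curve.loc[best, "specificity"]),
        curve=curve,
    )


# ---------------------------------------------------------------------------
# assay arithmetic


def ocr_slope(time_min, fluorescence, n_cells) -> float:
    """Oxygen consumption rate as the fluorescence slope per minute per cell."""
    t = np.asarray(time_min, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 time points")
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    slope = np.polyfit(t, f, 1)[0]
    return float(slope / n_cells)


def fao_rate(ocr_total: float, ocr_etomoxir: float) -> float:
    """FAO rate = OCR_total - OCR_etomoxir (etomoxir blocks CPT1).

    A negative rate is biologically impossible but returned with a warning —
    it is useful QC for noisy traces.
    """
    rate = float(ocr_total) - float(ocr_etomoxir)
    if rate < 0:
        warnings.warn("negative FAO rate (etomoxir OCR exceeds total)", stacklevel=2)
    return rate


def delta_ct(ct_target: float, ct_control: float) -> float:
    """qPCR expression: control-gene Ct minus target-gene Ct (higher = more)."""
    return float(ct_control) - float(ct_target)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume: length * width^2 / 2 (mm^3)."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("dimensions must be non-negative")
    if length_mm < width_mm:
        warnings.warn("length < width; swapping (length is the long axis)",
                      stacklevel=2)
        length_mm, width_mm = width_mm, length_mm
    return float(length_mm) * float(width_mm) ** 2 / 2.0


def group_test(a, b, sides: int = 2, equal_var: bool = True):
    """Student's t test between two groups.

    ``sides=2`` is the two-tailed test; ``sides=1`` tests a > b.  Pooled
    variance by default (classic Student's t); set ``equal_var=False`` for
    Welch.  Returns ``(statistic, p_value)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    alternative = "two-sided" if sides == 2 else "greater"
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SeahorseMetrics:
    basal: float
    atp_linked: float
    maximal: float
    non_mito: float


def seahorse_metrics(ocr_trace, injection_indices) -> SeahorseMetrics:
    """Standard mitochondrial-stress-test metrics from an OCR trace.

    ``injection_indices`` are the first trace indices after the oligomycin,
    FCCP and rotenone/antimycin injections, splitting the trace into four
    segments.  Convention: non-mito = mean after rotenone/antimycin;
    basal = last pre-injection point - non-mito; ATP-linked = basal -
    (oligomycin mean - non-mito); maximal = FCCP mean - non-mito.
    """
    trace = np.asarray(ocr_trace, dtype=float)
    i_oligo, i_fccp, i_rot = (int(i) for i in injection_indices)
    if not 0 < i_oligo < i_fccp < i_rot < trace.size:
        raise ValueError("injection indices must be increasing and inside the trace")
    segments = {
        "basal": trace[:i_oligo],
        "oligomycin": trace[i_oligo:i_fccp],
        "FCCP": trace[i_fccp:i_rot],
        "rotenone/antimycin": trace[i_rot:],
    }
    for name, seg in segments.items():
        if seg.size == 0:
            raise ValueError(f"missing {name} segment in trace")
    non_mito = float(segments["rotenone/antimycin"].mean())
    basal = float(segments["basal"][-1]) - non_mito
    atp_linked = basal - (float(segments["oligomycin"].mean()) - non_mito)
    maximal = float(segments["FCCP"].mean()) - non_mito
    return SeahorseMetrics(
        basal=basal, atp_linked=atp_linked, maximal=maximal, non_mito=non_mito
    )


def seahorse_reduction(control: SeahorseMetrics, etomoxir: SeahorseMetrics) -> SeahorseMetrics:
    """Etomoxir-induced reduction of each respiration metric (control - treated)."""
    return SeahorseMetrics(
        basal=control.basal - etomoxir.basal,
        atp_linked=control.atp_linked - etomoxir.atp_linked,
        maximal=control.maximal - etomoxir.maximal,
        non_mito=control.non_mito - etomoxir.non_mito,
    )
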