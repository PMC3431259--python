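"""Study-level cohort analysis: trephine correlation screen, graft-to-
cornea ratio / undersizing analysis, sizing recommendation, and the
structured cohort report.

The central clinical quantity is the ratio of posterior graft arc length
to posterior cornea arc length (PGAL/PCAL): an eye is flagged
"undersized" when its posterior cornea arc length exceeds the cohort's
75th percentile while its ratio falls below the cohort mean — the two
reference lines of the ratio-versus-PCAL scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .agreement import (AgreementResult, PairedMeasurements, RegressionResult,
                        bland_altman, coefficient_of_variation, fit_regression,
                        icc, paired_test, select_model, spearman_rho)
from .core import ConstantInputError

SCREEN_PARAMETERS = ("pcal_mm", "curvature_mm", "acw_mm", "agal_mm",
                     "agcl_mm", "pgal_mm", "pgcl_mm", "thickness_um")

TREPHINE_GRID = np.round(np.arange(7.0, 9.51, 0.25), 2)

RATIO_DEFINITIONS = {
    "ratio_pgal_pcal": ("pgal_mm", "pcal_mm"),
    "ratio_agal_pcal": ("agal_mm", "pcal_mm"),
    "ratio_pgal_pgcl": ("pgal_mm", "pgcl_mm"),
    "ratio_agal_agcl": ("agal_mm", "agcl_mm"),
    "ratio_agal_pgal": ("agal_mm", "pgal_mm"),
    "ratio_agcl_pgcl": ("agcl_mm", "pgcl_mm"),
}


def add_ratio_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the six dimensionless ratio columns appended."""
    out = cohort.copy()
    for name, (num, den) in RATIO_DEFINITIONS.items():
        out[name] = out[num] / out[den]
    return out


def correlation_screen(cohort: pd.DataFrame, parameters=SCREEN_PARAMETERS) -> pd.DataFrame:
    """Spearman correlation of trephine diameter against each parameter.

    Returns a table (parameter, rho, p) sorted by |rho| descending, so the
    first row names the best-correlated parameter.
    """
    if len(cohort) < 10:
        raise ValueError("need at least 10 rows for the correlation screen")
    t = cohort["trephine_mm"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ConstantInputError("trephine diameter is constant")
    rows = []
    for p in parameters:
        rho, pval = spearman_rho(t, cohort[p].to_numpy(dtype=float))
        rows.append({"parameter": p, "rho": rho, "p": pval})
    out = pd.DataFrame(rows)
    return out.reindex(out["rho"].abs().sort_values(ascending=False).index
                       ).reset_index(drop=True)


def quantile(values, q: float) -> float:
    """Linear-interpolation quantile between order statistics (q in [0,1])."""
    return float(np.quantile(np.asarray(values, dtype=float), q,
                             method="linear"))


def ratio_analysis(cohort: pd.DataFrame) -> dict:
    """Graft/cornea ratio summary and per-eye undersizing classification.

    An eye is "undersized" iff its PCAL strictly exceeds the cohort's 75th
    percentile AND its PGAL/PCAL ratio falls strictly below the cohort
    mean ratio.  The reported fraction is taken among the large-PCAL eyes.
    """
    if len(cohort) < 4:
        raise ValueError("need at least 4 rows")
    pcal = cohort["pcal_mm"].to_numpy(dtype=float)
    ratio = cohort["pgal_mm"].to_numpy(dtype=float) / pcal
    mean_ratio = float(np.mean(ratio))
    sd_ratio = float(np.std(ratio, ddof=1))
    p75 = quantile(pcal, 0.75)
    large = pcal > p75
    undersized = large & (ratio < mean_ratio)
    frac = float(undersized.sum() / large.sum()) if large.any() else 0.0
    return {
        "ratio_pgal_pcal": ratio,
        "mean_ratio": mean_ratio,
        "sd_ratio": sd_ratio,
        "p75_pcal_mm": p75,
        "undersized": undersized,
        "n_large_pcal": int(large.sum()),
        "undersized_fraction": frac,
    }


@dataclass
class SizingRecommendation:
    """Trephine diameter recommended for a target graft/cornea ratio."""

    recommended_trephine_mm: float
    raw_trephine_mm: float
    target_ratio: float
    predicted_pgal_mm: float
    clamped: bool
    model: RegressionResult


def recommend_trephine(pcal_mm: float, acw_mm: float, curvature_mm: float,
                       target_ratio: float, model: RegressionResult,
                       covariates: Optional[dict] = None) -> SizingRecommendation:
    """Invert a fitted PGAL model for the trephine diameter that achieves
    ``target_ratio x pcal``, snapping to the 0.25 mm surgical grid and
    clamping to [7.00, 9.50] mm.

    ``covariates`` supplies values for any model predictors beyond
    trephine/ACW/curvature."""
    if not 0 < target_ratio < 1:
        raise ValueError("target_ratio must lie in (0, 1)")
    if "trephine_mm" not in model.predictors:
        raise ValueError("model must include trephine_mm as a predictor")
    beta = model.coefficients["trephine_mm"]
    if beta <= 0:
        raise ValueError("non-invertible model: trephine coefficient <= 0")
    values = {"acw_mm": acw_mm, "curvature_mm": curvature_mm, "pcal_mm": pcal_mm}
    if covariates:
        values.update(covariates)
    target_pgal = target_ratio * pcal_mm
    offset = model.coefficients.get("const", 0.0)
    for name in model.predictors:
        if name != "trephine_mm":
            if name not in values:
                raise ValueError(f"no value supplied for model predictor {name!r}")
            offset += model.coefficients[name] * values[name]
    raw = (target_pgal - offset) / beta
    snapped = round(raw / 0.25) * 0.25
    clamped = not (TREPHINE_GRID[0] <= snapped <= TREPHINE_GRID[-1])
    rec = float(np.clip(snapped, TREPHINE_GRID[0], TREPHINE_GRID[-1]))
    predicted = model.predict({**values, "trephine_mm": rec})
    return SizingRecommendation(rec, float(raw), target_ratio, predicted, clamped, model)


def disc_area_increase(d_small_mm: float, d_large_mm: float):
    """Percent extra surface area of a larger circular graft.

    Returns ``(percent, truncated_percent)``: the exact value
    ``100 x ((d_large/d_small)^2 - 1)`` and its integer truncation (the
    rounding convention under which an 8.0 to 9.0 mm upsizing reads as
    26% more endothelial area)."""
    if d_small_mm <= 0 or d_large_mm <= 0:
        raise ValueError("diameters must be positive")
    pct = 100.0 * ((d_large_mm / d_small_mm) ** 2 - 1.0)
    return pct, int(pct)


def _percent(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 1)


def agreement_table(duplicates: pd.DataFrame, *, seed: int = 0) -> list:
    """Per-parameter repeatability statistics from a duplicate-session table."""
    results = []
    for param in duplicates["parameter"].unique():
        pairs = PairedMeasurements.from_long(duplicates, param)
        p, test = paired_test(pairs)
        md, md_ci, loa = bland_altman(pairs)
        cov, cov_ci = coefficient_of_variation(pairs, seed=seed)
        icc_val, icc_ci = icc(pairs)
        results.append(AgreementResult(
            parameter=param, n=pairs.n,
            mean1=float(pairs.obs1.mean()), mean2=float(pairs.obs2.mean()),
            p_paired=p, test_used=test, mean_diff=md, mean_diff_ci=md_ci,
            loa_lower=loa[0], loa_upper=loa[1],
            cov_percent=cov, cov_ci=cov_ci, icc=icc_val, icc_ci=icc_ci))
    return results


def cohort_report(cohort: pd.DataFrame, pairs: Optional[pd.DataFrame] = None, *,
                  n_input_images: Optional[int] = None,
                  target_ratio: float = 0.712, seed: int = 0) -> dict:
    """Assemble the study-shaped structured report.

    Covers demographics (percentages = 100 x count/denominator, 1 dp),
    parameter means +/- SD, the six ratios, the trephine correlation
    screen, stepwise regression of PGAL, the ratio/undersizing analysis
    and, when a duplicate-session table is supplied, the repeatability
    table.  ``n_input_images`` (>= cohort size) adds the QC exclusion
    percentage."""
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    rich = add_ratio_columns(cohort)
    report: dict = {"n": n}

    demo = {"age_mean": float(cohort["age"].mean()),
            "age_sd": float(cohort["age"].std(ddof=1))}
    for key, col, value in (("male", "sex", "M"), ("od", "side", "OD"),
                            ("glide", "insertion_technique", "glide")):
        if col in cohort:
            cnt = int((cohort[col] == value).sum())
            demo[f"{key}_n"] = cnt
            demo[f"{key}_percent"] = _percent(cnt, n)
    report["demographics"] = demo

    if n_input_images is not None:
        excluded = n_input_images - n
        report["qc"] = {"n_input": n_input_images, "n_excluded": excluded,
                        "excluded_percent": _percent(excluded, n_input_images)}

    params = ["trephine_mm", "pcal_mm", "acw_mm", "agal_mm", "agcl_mm",
              "pgal_mm", "pgcl_mm", "curvature_mm", "thickness_um"]
    report["parameters"] = {
        p: {"mean": float(rich[p].mean()), "sd": float(rich[p].std(ddof=1))}
        for p in params if p in rich}
    report["ratios"] = {
        r: {"mean": float(rich[r].mean()), "sd": float(rich[r].std(ddof=1))}
        for r in RATIO_DEFINITIONS}

    report["correlation_screen"] = correlation_screen(cohort).to_dict("records")

    candidates = [c for c in ("age", "sex", "pcal_mm", "acw_mm", "curvature_mm",
                              "thickness_um", "trephine_mm") if c in cohort]
    winner = select_model(cohort, "pgal_mm", candidates)
    report["regression"] = winner.to_dict()

    ra = ratio_analysis(cohort)
    report["ratio_analysis"] = {k: (float(v) if np.isscalar(v) or isinstance(v, (int, float))
                                    else None)
                                for k, v in ra.items()
                                if k not in ("ratio_pgal_pcal", "undersized")}
    report["ratio_analysis"]["undersized_percent"] = _percent(
        int((ra["undersized"]).sum()), ra["n_large_pcal"]) if ra["n_large_pcal"] else 0.0

    if "trephine_mm" in winner.predictors:
        med = cohort.median(numeric_only=True)
        covariates = {}
        for c in winner.predictors:
            if c == "trephine_mm":
                continue
            if c in med.index:
                covariates[c] = float(med[c])
            else:  # categorical predictors enter as factorised codes
                codes, _ = pd.factorize(cohort[c])
                covariates[c] = float(np.median(codes))
        rec = recommend_trephine(float(med["pcal_mm"]), float(med["acw_mm"]),
                                 float(med["curvature_mm"]), target_ratio, winner,
                                 covariates=covariates)
        report["sizing_example"] = {
            "target_ratio": target_ratio,
            "median_pcal_mm": float(med["pcal_mm"]),
            "recommended_trephine_mm": rec.recommended_trephine_mm,
            "raw_trephine_mm": rec.raw_trephine_mm,
            "predicted_pgal_mm": rec.predicted_pgal_mm,
            "clamped": rec.clamped,
        }

    if pairs is not None:
        report["agreement"] = [a.to_dict() for a in agreement_table(pairs, seed=seed)]
    return report
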