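"""Precision statistics for intra-/inter-operator reproducibility.

Per vertebra: coefficient of variation CV = SD / mean (sample SD, n-1
denominator).  Across vertebrae: precision error PE = sqrt(mean(CV_j^2))
(root-mean-square CV).  Per comparison pair: absolute relative difference
ARD = |(A - B) / ((A + B)/2)| * 100, in percent.  Intra vs inter means are
compared with a paired t-test (alpha = 0.05) after normality and
equal-variance checks, which are reported as flags but never silently gate
the test.  Geometric-vs-mechanical relationships are explored with OLS
regressions of SD(geometric metric) on CV(mechanical metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mask_metrics import METRIC_NAMES, GeometricReport

__all__ = [
    "coefficient_of_variation",
    "precision_error",
    "absolute_relative_difference",
    "paired_intra_inter_test",
    "geometric_mechanical_regression",
    "build_repro_report",
    "ReproReport",
]

MECH_METRICS = ("F_U_N", "sigma_U_MPa", "K_N_per_mm", "E_APP_MPa")


def coefficient_of_variation(values) -> float:
    """Sample SD over mean; requires >= 2 values and a nonzero mean."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m)


def precision_error(cv_per_vertebra) -> float:
    """Root-mean-square of the per-vertebra CVs."""
    cv = np.asarray(cv_per_vertebra, float)
    if cv.size == 0:
        raise ValueError("PE needs at least one CV")
    return float(np.sqrt((cv ** 2).mean()))


def absolute_relative_difference(a: float, b: float) -> float:
    """|(a - b) / mean(a, b)| * 100, percent."""
    m = (a + b) / 2.0
    if m == 0:
        raise ValueError("ARD undefined for zero pair mean")
    return abs((a - b) / m) * 100.0


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_intra_inter_test(intra_means, inter_means) -> dict:
    """Paired t-test of per-vertebra intra vs inter means.

    Returns t, two-sided p, significance stars, and assumption flags
    (Shapiro normality of the paired differences, Levene equal variance).
    Degenerate zero-variance differences are flagged; identical vectors
    give t = 0, p = 1.
    """
    a = np.asarray(intra_means, float)
    b = np.asarray(inter_means, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired test needs equal-length vectors, n >= 3")
    d = a - b
    out: dict = {"n": int(a.size)}
    if np.allclose(d.std(ddof=1), 0.0):
        out.update(t=0.0 if np.allclose(d, 0) else float("inf"),
                   p=1.0 if np.allclose(d, 0) else 0.0,
                   degenerate=True, normal=None, equal_variance=None)
        out["stars"] = "" if np.allclose(d, 0) else "***"
        return out
    sh_p = float(sps.shapiro(d).pvalue)
    lev_p = float(sps.levene(a, b).pvalue)
    t_res = sps.ttest_rel(a, b)
    out.update(t=float(t_res.statistic), p=float(t_res.pvalue),
               degenerate=False,
               normal=sh_p >= 0.05, shapiro_p=sh_p,
               equal_variance=lev_p >= 0.05, levene_p=lev_p,
               stars=significance_stars(float(t_res.pvalue)))
    return out


def geometric_mechanical_regression(sd_geometric, cv_mechanical) -> dict:
    """Exploratory OLS of CV(mechanical) on SD(geometric) across vertebrae."""
    x = np.asarray(sd_geometric, float)
    y = np.asarray(cv_mechanical, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs n >= 3 paired values")
    if np.allclose(x.std(), 0.0):
        raise ValueError("zero variance in predictor")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope), "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2), "p": float(res.pvalue),
        "n": int(x.size), "exploratory": True,
    }


def _pairwise_ards(values) -> list[float]:
    return [absolute_relative_difference(values[i], values[j])
            for i, j in combinations(range(len(values)), 2)]


@dataclass
class ReproReport:
    """Assembled per-study reproducibility report."""

    geometric: pd.DataFrame          # per vertebra x mode, Table-4 shape
    mechanical: pd.DataFrame         # per vertebra x mode: mean, SD, CV, ARD
    precision: pd.DataFrame          # PE per metric x mode
    t_tests: pd.DataFrame
    regressions: pd.DataFrame
    missing: list = field(default_factory=list)

    def save(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.geometric.to_csv(out / "geometric_table.csv", index=False)
        self.mechanical.to_csv(out / "mechanical_cv.csv", index=False)
        self.precision.to_csv(out / "precision_error.csv", index=False)
        self.t_tests.to_csv(out / "t_tests.csv", index=False)
        self.regressions.to_csv(out / "regressions.csv", index=False)
        report = {
            "precision_error": self.precision.to_dict(orient="records"),
            "t_tests": self.t_tests.to_dict(orient="records"),
            "regressions": self.regressions.to_dict(orient="records"),
            "missing": self.missing,
        }
        import json
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=str))


def build_repro_report(
    geometric_reports: dict[tuple[int, str], GeometricReport],
    mechanical_values: dict[tuple[int, str], dict[str, list[float]]],
) -> ReproReport:
    """Assemble the study-level report.

    Parameters
    ----------
    geometric_reports
        ``{(vertebra_id, mode): GeometricReport}`` with mode intra/inter.
    mechanical_values
        ``{(vertebra_id, mode): {metric: [3 values]}}`` — the three repeat
        (intra) or three operator (inter) model outcomes per metric.

    Missing cells are listed explicitly, never silently skipped.
    """
    vids = sorted({k[0] for k in geometric_reports} |
                  {k[0] for k in mechanical_values})
    modes = ("intra", "inter")
    missing = []

    geo_rows = []
    for mode in modes:
        block = []
        for vid in vids:
            rep = geometric_reports.get((vid, mode))
            if rep is None:
                missing.append(("geometric", vid, mode))
                continue
            row = {"vertebra": vid, **rep.as_row()}
            geo_rows.append(row)
            block.append(row)
        if block:   # pooled row: mean/SD across vertebra means
            pooled = {"vertebra": "all", "mode": mode,
                      "scope": block[0]["scope"]}
            for m in METRIC_NAMES:
                vals = np.array([r[f"{m}_mean"] for r in block])
                pooled[f"{m}_mean"] = vals.mean()
                pooled[f"{m}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            geo_rows.append(pooled)
    geometric = pd.DataFrame(geo_rows)

    mech_rows, pe_rows = [], []
    cv_store: dict[tuple[str, str], dict[int, float]] = {}
    for mode in modes:
        for metric in MECH_METRICS:
            cvs = {}
            for vid in vids:
                cell = mechanical_values.get((vid, mode))
                if cell is None or metric not in cell:
                    missing.append(("mechanical", vid, mode, metric))
                    continue
                vals = np.asarray(cell[metric], float)
                m, sd = vals.mean(), vals.std(ddof=1)
                cv = coefficient_of_variation(vals)
                ards = _pairwise_ards(vals)
                cvs[vid] = cv
                mech_rows.append({
                    "vertebra": vid, "mode": mode, "metric": metric,
                    "mean": m, "sd": sd, "cv": cv,
                    "ard_mean_pct": float(np.mean(ards)),
                    "ard_sd_pct": float(np.std(ards, ddof=1))
                    if len(ards) > 1 else 0.0,
                })
            if cvs:
                pe_rows.append({"mode": mode, "metric": metric,
                                "pe": precision_error(list(cvs.values())),
                                "n": len(cvs)})
                cv_store[(mode, metric)] = cvs
    mechanical = pd.DataFrame(mech_rows)
    precision = pd.DataFrame(pe_rows)

    # intra vs inter paired t-tests per metric (mechanical CVs + geometric means)
    t_rows = []
    for metric in MECH_METRICS:
        intra = cv_store.get(("intra", metric), {})
        inter = cv_store.get(("inter", metric), {})
        common = sorted(set(intra) & set(inter))
        if len(common) >= 3:
            res = paired_intra_inter_test([intra[v] for v in common],
                                          [inter[v] for v in common])
            t_rows.append({"quantity": f"cv_{metric}", **res})
    for m in METRIC_NAMES:
        by_mode = {}
        for mode in modes:
            sub = geometric[(geometric["mode"] == mode)
                            & (geometric["vertebra"] != "all")]
            by_mode[mode] = dict(zip(sub["vertebra"], sub[f"{m}_mean"]))
        common = sorted(set(by_mode["intra"]) & set(by_mode["inter"]))
        if len(common) >= 3:
            res = paired_intra_inter_test(
                [by_mode["intra"][v] for v in common],
                [by_mode["inter"][v] for v in common])
            t_rows.append({"quantity": f"geo_{m}", **res})
    t_tests = pd.DataFrame(t_rows)

    # SD(geometric) vs CV(mechanical) regressions, per mode
    reg_rows = []
    for mode in modes:
        sub = geometric[(geometric["mode"] == mode)
                        & (geometric["vertebra"] != "all")]
        for gm in METRIC_NAMES:
            sd_map = dict(zip(sub["vertebra"], sub[f"{gm}_sd"]))
            for metric in MECH_METRICS:
                cvs = cv_store.get((mode, metric), {})
                common = sorted(set(sd_map) & set(cvs))
                if len(common) < 3:
                    continue
                x = [sd_map[v] for v in common]
                y = [cvs[v] for v in common]
                try:
                    res = geometric_mechanical_regression(x, y)
                except ValueError:
                    continue
                reg_rows.append({"mode": mode, "geometric_sd": gm,
                                 "mechanical_cv": metric, **res})
    regressions = pd.DataFrame(reg_rows)

    return ReproReport(geometric=geometric, mechanical=mechanical,
                       precision=precision, t_tests=t_tests,
                       regressions=regressions, missing=missing)
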