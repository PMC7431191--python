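"""Genotype-level statistics and report rendering for per-larva metrics.

Group comparison follows the original analysis style: an ordinary least
squares linear model of each metric with genotype as a fixed effect
(treatment coding, control as reference, individual larva as the
statistical unit), two-sided contrasts, no multiple-testing correction.
Summaries are mean +/- SEM plus Tukey box-plot descriptors (median,
quartiles, 1.5*IQR whiskers) with a median notch of 1.57*IQR/sqrt(n).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

METRICS = ("walking_rate", "stride_length_mean", "stride_duration_mean")


def fit_genotype_model(metrics: pd.DataFrame, metric_name: str,
                       reference_genotype: str) -> pd.DataFrame:
    """OLS of one metric on genotype (treatment-coded vs reference).

    Returns one row per non-reference genotype with the effect estimate
    (difference vs reference), its SE, t and two-sided p.  Degenerate
    zero-residual fits report t = 0, p = 1 for null effects.
    """
    df = metrics[["genotype", metric_name]].dropna().copy()
    genos = df["genotype"].unique()
    if len(genos) < 2:
        raise ValueError("need at least 2 genotypes")
    if reference_genotype not in genos:
        raise ValueError(f"reference genotype {reference_genotype!r} absent")
    counts = df.groupby("genotype").size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"genotype(s) with n < 2: {small}")
    df = df.rename(columns={metric_name: "y"})
    model = smf.ols(
        f"y ~ C(genotype, Treatment(reference={reference_genotype!r}))", df
    ).fit()
    scale = float(np.abs(df["y"]).mean()) or 1.0
    degenerate = float(model.mse_resid) <= (1e-10 * scale) ** 2
    rows = []
    prefix = "C(genotype, Treatment(reference="
    for name, est in model.params.items():
        if not name.startswith(prefix):
            continue
        geno = name.split("[T.")[1].rstrip("]")
        se = float(model.bse[name])
        t, p = float(model.tvalues[name]), float(model.pvalues[name])
        if degenerate or se == 0 or not np.isfinite(t):
            # zero residual variance: a (numerically) zero effect carries
            # no evidence of difference; a non-zero one is unambiguous
            if abs(est) < 1e-9 * scale:
                est, se, t, p = 0.0, 0.0, 0.0, 1.0
            else:
                t, p = float("inf"), 0.0
        rows.append({"metric": metric_name, "genotype": geno,
                     "reference": reference_genotype, "effect": float(est),
                     "se": se, "t": t, "p": p,
                     "n": int(counts[geno]), "n_ref": int(counts[reference_genotype])})
    return pd.DataFrame(rows)


def summarize_cohort(metrics: pd.DataFrame,
                     metric_names=METRICS) -> pd.DataFrame:
    """Per-genotype, per-metric descriptive summary.

    Columns: mean, sem, n, median, q1, q3, whisker_low/high (Tukey, most
    extreme data point within 1.5*IQR of the quartiles), notch_low/high
    (median +/- 1.57*IQR/sqrt(n)).  Groups with n = 1 get NaN sem and the
    ``degenerate`` flag.
    """
    rows = []
    for metric in metric_names:
        if metric not in metrics.columns:
            continue
        for genotype, g in metrics.groupby("genotype", sort=True):
            x = g[metric].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            in_lo = x[x >= q1 - 1.5 * iqr]
            in_hi = x[x <= q3 + 1.5 * iqr]
            notch = 1.57 * iqr / np.sqrt(x.size)
            rows.append({
                "metric": metric, "genotype": genotype, "n": int(x.size),
                "mean": float(x.mean()),
                "sem": float(sps.sem(x)) if x.size > 1 else float("nan"),
                "median": float(med), "q1": float(q1), "q3": float(q3),
                "whisker_low": float(in_lo.min()), "whisker_high": float(in_hi.max()),
                "notch_low": float(med - notch), "notch_high": float(med + notch),
                "degenerate": bool(x.size < 2),
            })
    return pd.DataFrame(rows)


def render_report(metrics: pd.DataFrame, out_dir,
                  reference_genotype=None, metric_names=METRICS) -> dict:
    """Write summary tables (CSV/JSON), contrasts and box plots.

    Deterministic given inputs.  Returns a manifest of written paths.
    An empty metric table still produces a header-only report.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    summary = summarize_cohort(metrics, metric_names) if len(metrics) else \
        pd.DataFrame(columns=["metric", "genotype", "n", "mean", "sem"])
    summary_csv = out / "summary.csv"
    summary.to_csv(summary_csv, index=False)
    manifest["summary_csv"] = str(summary_csv)

    payload = {"version": 1, "summary": summary.to_dict(orient="records")}
    if reference_genotype is not None and len(metrics):
        contrasts = pd.concat(
            [fit_genotype_model(metrics, m, reference_genotype)
             for m in metric_names if m in metrics.columns],
            ignore_index=True)
        ccsv = out / "contrasts.csv"
        contrasts.to_csv(ccsv, index=False)
        manifest["contrasts_csv"] = str(ccsv)
        payload["contrasts"] = contrasts.to_dict(orient="records")

    sjson = out / "summary.json"
    sjson.write_text(json.dumps(payload, indent=2, default=float))
    manifest["summary_json"] = str(sjson)

    for metric in metric_names:
        if metric not in getattr(metrics, "columns", []):
            continue
        sub = metrics[["genotype", metric]].dropna()
        if sub.empty:
            continue
        genos = sorted(sub["genotype"].unique())
        data = [sub.loc[sub["genotype"] == g, metric].to_numpy() for g in genos]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.boxplot(data, notch=True, tick_labels=genos, whis=1.5)
        ax.set_ylabel(metric)
        fig.tight_layout()
        png = out / f"box_{metric}.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        manifest[f"box_{metric}"] = str(png)
    return manifest
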