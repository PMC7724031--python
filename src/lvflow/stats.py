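"""Paired rest-vs-stress statistics, observer-agreement ICC, and reporting.

The comparison protocol follows the study's statistical plan: paired
differences are first checked for normality (Kolmogorov–Smirnov with the
Lilliefors correction, since mean and SD are estimated from the data); if
normality is not rejected at alpha a paired t-test is used, otherwise the
Wilcoxon signed-rank test.  Summaries are group mean ± SD; per-variable
two-sided p-values without multiple-testing correction.

Observer variability uses the two-way random-effects, absolute-agreement,
single-measures intraclass correlation coefficient, ICC(2,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR/MSC/MSE the rows (subjects), columns (raters) and error mean
squares of the two-way ANOVA decomposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import LVFlowError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedComparison:
    variable: str
    rest_mean: float
    rest_sd: float
    stress_mean: float
    stress_sd: float
    normality_p: float
    test_used: str  # "paired_t" or "wilcoxon"
    p_value: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


def paired_compare(rest, stress, alpha: float = 0.05,
                   variable: str = "") -> PairedComparison:
    """Compare paired rest/stress samples with a normality-gated paired test.

    The gate applies the Lilliefors-corrected Kolmogorov–Smirnov test to the
    paired differences; ``paired_t`` is used iff normality is not rejected at
    ``alpha``, otherwise the Wilcoxon signed-rank test (exact null
    distribution for small n without ties at zero).
    """
    rest = np.asarray(rest, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if rest.shape != stress.shape or rest.ndim != 1:
        raise LVFlowError("rest and stress must be equal-length 1-D samples")
    n = rest.size
    if n < 3:
        raise LVFlowError(f"need at least 3 pairs, got {n}")
    diffs = stress - rest

    if np.allclose(diffs, diffs[0]) and diffs[0] == 0:
        # degenerate: no variation and no effect
        normality_p = 1.0
        test_used, p = "paired_t", 1.0
    else:
        try:
            normality_p = float(lilliefors(diffs, dist="norm")[1])
        except ValueError:  # zero-variance differences with nonzero mean
            normality_p = 0.0
        if normality_p > alpha:
            test_used = "paired_t"
            p = float(sps.ttest_rel(stress, rest).pvalue)
        else:
            test_used = "wilcoxon"
            p = signed_rank_pvalue(diffs)
    return PairedComparison(
        variable=variable,
        rest_mean=float(rest.mean()), rest_sd=float(rest.std(ddof=1)),
        stress_mean=float(stress.mean()), stress_sd=float(stress.std(ddof=1)),
        normality_p=float(normality_p), test_used=test_used,
        p_value=float(min(max(p, 0.0), 1.0)), n=n,
    )


def signed_rank_pvalue(diffs) -> float:
    """Two-sided Wilcoxon signed-rank p-value of paired differences.

    Zero differences are discarded; the exact null distribution is used for
    up to 25 non-zero pairs, a normal approximation beyond.
    """
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "auto"
    return float(sps.wilcoxon(nz, method=method).pvalue)


def icc(ratings) -> ICCResult:
    """ICC(2,1): two-way random, absolute agreement, single measures.

    ``ratings`` is subjects x raters with no missing cells.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise LVFlowError("ratings must be a 2-D subjects x raters array")
    if np.isnan(x).any():
        raise LVFlowError("ratings contain missing cells")
    n, k = x.shape
    if n < 3 or k < 2:
        raise LVFlowError("need >= 3 subjects and >= 2 raters")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_rows == 0 or denom <= 0:
        log.warning("zero between-subject variance; ICC reported as 0")
        value = 0.0
    else:
        value = (msr - mse) / denom
    return ICCResult(icc=float(value),
                     model="two-way random, absolute agreement, single measures (ICC 2,1)",
                     n_subjects=n, n_raters=k)


# ---------------------------------------------------------------------------
# report generation


#: component-fraction and KE variables compared rest vs stress, CSV order
REPORT_FLOW_VARIABLES = [
    "df_pct", "ri_pct", "def_pct", "rv_pct",
    "ke_ed_df_uj_ml", "ke_ed_ri_uj_ml", "ke_ed_def_uj_ml", "ke_ed_rv_uj_ml",
]
REPORT_VOLUME_VARIABLES = ["edv_ml", "esv_ml", "sv_ml", "ef_pct", "co_l_min"]


def _comparison_frame(comparisons):
    import pandas as pd

    rows = [
        {
            "variable": c.variable,
            "rest_mean": c.rest_mean, "rest_sd": c.rest_sd,
            "stress_mean": c.stress_mean, "stress_sd": c.stress_sd,
            "normality_p": c.normality_p, "test": c.test_used,
            "p_value": c.p_value, "n": c.n,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)


def build_report(results, comparisons, out_dir, ke_curves=None) -> dict[str, Path]:
    """Emit the study report: volumetric and 4D-flow tables plus figures.

    ``results`` is a list of per-dataset ComponentResult; ``comparisons`` the
    PairedComparison list (may be empty for a single-condition run, in which
    case tables are emitted without p-value columns).  Figures: a stacked
    component-fraction bar chart, a DF-vs-RV scatter, and (when ``ke_curves``
    is given) per-component diastolic KE curves.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    from .io import write_results

    results = list(results)
    if not results:
        raise LVFlowError("no datasets to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_results(results, out_dir)

    comp_df = pd.read_csv(paths["components"])
    vol_df = pd.read_csv(paths["volumetrics"])

    # Table analogs: group mean +/- SD per condition (+ p-values when paired)
    def _summary(df, variables):
        rows = []
        for v in variables:
            row = {"variable": v}
            for cond, sub in df.groupby("condition"):
                row[f"{cond}_mean"] = sub[v].mean()
                row[f"{cond}_sd"] = sub[v].std(ddof=1)
            rows.append(row)
        return pd.DataFrame(rows)

    vol_tab = _summary(vol_df, REPORT_VOLUME_VARIABLES)
    flow_tab = _summary(comp_df, REPORT_FLOW_VARIABLES)
    if comparisons:
        pmap = {c.variable: c.p_value for c in comparisons}
        tmap = {c.variable: c.test_used for c in comparisons}
        for tab in (vol_tab, flow_tab):
            tab["p_value"] = tab["variable"].map(pmap)
            tab["test"] = tab["variable"].map(tmap)
        paths["comparisons"] = out_dir / "comparisons.csv"
        _comparison_frame(comparisons).to_csv(paths["comparisons"], index=False)
    paths["volumetrics_table"] = out_dir / "table_volumetrics.csv"
    paths["flow_table"] = out_dir / "table_4dflow.csv"
    vol_tab.to_csv(paths["volumetrics_table"], index=False)
    flow_tab.to_csv(paths["flow_table"], index=False)

    # stacked component-fraction bars per condition
    fig, ax = plt.subplots(figsize=(6, 4))
    conds = sorted(comp_df["condition"].unique())
    bottoms = np.zeros(len(conds))
    colors = {"df_pct": "#d62728", "ri_pct": "#1f77b4",
              "def_pct": "#2ca02c", "rv_pct": "#7f7f7f"}
    for var in ("df_pct", "ri_pct", "def_pct", "rv_pct"):
        means = [comp_df[comp_df.condition == c][var].mean() for c in conds]
        ax.bar(conds, means, bottom=bottoms, label=var[:-4].upper(), color=colors[var])
        bottoms += np.asarray(means)
    ax.set_ylabel("share of EDV (%)")
    ax.legend()
    paths["fig_fractions"] = out_dir / "fig_fractions.png"
    fig.savefig(paths["fig_fractions"], dpi=120)
    plt.close(fig)

    # DF vs RV scatter per subject/condition
    fig, ax = plt.subplots(figsize=(5, 5))
    for cond, marker in zip(conds, ("o", "s", "^")):
        sub = comp_df[comp_df.condition == cond]
        ax.scatter(sub["rv_pct"], sub["df_pct"], marker=marker, label=cond)
    ax.set_xlabel("Residual volume (% of EDV)")
    ax.set_ylabel("Direct flow (% of EDV)")
    ax.legend()
    paths["fig_df_rv"] = out_dir / "fig_df_vs_rv.png"
    fig.savefig(paths["fig_df_rv"], dpi=120)
    plt.close(fig)

    if ke_curves:
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=False)
        for ax, (name, curves) in zip(axes.ravel(), ke_curves.items()):
            for label, curve in curves.items():
                t = curve.times_ms - curve.times_ms[0]
                ax.plot(t, curve.ke_per_ml_uj, label=label)
                ax.axvline(t[-1], ls=":", color="k", lw=0.8)
            ax.set_title(name)
            ax.set_xlabel("time since preceding ES (ms)")
            ax.set_ylabel("KE/mL (uJ/mL)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        paths["fig_ke_curves"] = out_dir / "fig_ke_diastole.png"
        fig.savefig(paths["fig_ke_curves"], dpi=120)
        plt.close(fig)

    summary = {
        "n_datasets": len(results),
        "conditions": conds,
        "excluded_subjects": sorted(
            {r.subject_id for r in results if r.qc.excluded}
        ),
        "comparisons": [
            {"variable": c.variable, "test": c.test_used, "p_value": c.p_value}
            for c in (comparisons or [])
        ],
    }
    paths["summary"] = out_dir / "run_summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    return paths
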