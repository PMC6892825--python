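"""Group-level inference: rank-sum demographics tests, log-ANCOVA on
microstate features with age and gender covariates, and Spearman
correlations between features and the DSQIID dementia-screening score.

The ANCOVA is an ordinary least squares fit of log(feature) on a group
indicator plus covariates; the reported test is the group-coefficient t
with its two-sided p from the residual-df t distribution. Significance is
read at alpha = 0.05 without multiple-comparison correction, in keeping
with the exploratory design the package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


@dataclass
class GroupTestResult:
    """Result of one group-difference test on one feature."""

    feature: str
    estimate: float          # group coefficient on the log scale
    statistic: float         # t value of the group coefficient
    p_value: float
    covariates: list[str] = field(default_factory=list)
    dropped_covariates: list[str] = field(default_factory=list)
    df_resid: float = np.nan


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Uses exact enumeration when both samples have at most 10 observations
    and no ties straddle the groups, otherwise the normal approximation
    with tie correction. Returns ``(statistic, p)`` with the statistic the
    Mann-Whitney U of the first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    exact = (len(a) <= 10 and len(b) <= 10
             and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b))
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def ancova(feature_values, meta: pd.DataFrame,
           feature_name: str = "feature",
           group_col: str = "group",
           covariate_cols: tuple[str, ...] = ("age", "gender"),
           log_transform: bool = True) -> GroupTestResult:
    """Log-transformed ANCOVA of one feature on group + covariates.

    `meta` must align row-wise with `feature_values` and contain the group
    column (two levels) plus the covariates. Constant covariates are
    dropped (a flat column carries no information and would make the
    design rank deficient) and reported in ``dropped_covariates``.
    """
    import statsmodels.api as sm

    y = np.asarray(feature_values, dtype=float)
    if len(y) != len(meta):
        raise ValueError("feature values and metadata must align")
    if log_transform:
        bad = np.flatnonzero(y <= 0)
        if len(bad):
            ids = (meta.iloc[bad]["subject_id"].tolist()
                   if "subject_id" in meta else bad.tolist())
            raise ValueError(
                f"log transform requires positive values; offending "
                f"subjects: {ids}")
        y = np.log(y)

    groups = meta[group_col].to_numpy()
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    if min((groups == g).sum() for g in levels) < 2:
        raise ValueError("need at least 2 subjects per group")
    indicator = (groups == levels[1]).astype(float)

    cols, used, dropped = [indicator], ["group"], []
    for cov in covariate_cols:
        v = meta[cov].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            dropped.append(cov)
        else:
            cols.append(v)
            used.append(cov)
    design = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear "
                         "covariates)")
    fit = sm.OLS(y, design).fit()
    # column 1 is the group indicator
    return GroupTestResult(
        feature=feature_name, estimate=float(fit.params[1]),
        statistic=float(fit.tvalues[1]), p_value=float(fit.pvalues[1]),
        covariates=used[1:], dropped_covariates=dropped,
        df_resid=float(fit.df_resid))


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho with average ranks for ties; two-sided p.

    Raises on constant input, where the rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sp_stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# cohort-level analysis and reporting
# ---------------------------------------------------------------------------

FEATURE_COLS = ("duration_ms", "occurrence_hz", "coverage")


def _wide_features(features: pd.DataFrame,
                   class_names: list[str] | None = None) -> pd.DataFrame:
    """Pivot the tidy per-class feature table to one row per subject."""
    k = int(features["class"].max()) + 1
    names = class_names or [chr(ord("A") + i) for i in range(k)]
    wide = {}
    for col in FEATURE_COLS:
        pv = features.pivot(index="subject_id", columns="class", values=col)
        for c in pv.columns:
            wide[f"{col}_{names[int(c)]}"] = pv[c]
    out = pd.DataFrame(wide)
    if "gev" in features.columns:
        out["gev"] = features.groupby("subject_id")["gev"].first()
    return out.reset_index()


def analyze_cohort(features: pd.DataFrame, meta: pd.DataFrame,
                   class_names: list[str] | None = None
                   ) -> pd.DataFrame:
    """Run the log-ANCOVA on every per-class feature of a cohort.

    `features` is the tidy table from the stats stage; `meta` the subject
    metadata. Returns one row per feature with the group estimate, t and p.
    """
    wide = _wide_features(features, class_names)
    missing = set(wide["subject_id"]) - set(meta["subject_id"])
    if missing:
        raise ValueError(f"subjects missing from metadata: {sorted(missing)}")
    merged = wide.merge(meta, on="subject_id", how="inner")
    rows = []
    for col in [c for c in wide.columns if c != "subject_id"]:
        vals = merged[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            continue  # absent classes or undefined GEV
        res = ancova(vals, merged, feature_name=col)
        rows.append({
            "feature": col, "estimate_log": res.estimate,
            "t_value": res.statistic, "p_value": res.p_value,
            "covariates": "+".join(res.covariates),
        })
    return pd.DataFrame(rows)


def summary_table(features: pd.DataFrame, meta: pd.DataFrame,
                  results: pd.DataFrame | None = None,
                  class_names: list[str] | None = None) -> pd.DataFrame:
    """Group mean (SD) per feature and class, with optional p-values.

    The layout mirrors a clinical feature table: one row per group with
    mean and SD columns for duration, occurrence and coverage of each
    class, plus a p-value row when `results` is given.
    """
    wide = _wide_features(features, class_names).merge(
        meta, on="subject_id", how="inner")
    feature_cols = [c for c in wide.columns
                    if c.startswith(tuple(FEATURE_COLS))]
    rows = []
    for group, sub in wide.groupby("group", sort=False):
        row = {"row": str(group)}
        for col in feature_cols:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1))
        rows.append(row)
    table = pd.DataFrame(rows)
    if results is not None and len(results):
        prow = {"row": "p_value"}
        for col in feature_cols:
            hit = results.loc[results["feature"] == col, "p_value"]
            prow[f"{col}_mean"] = float(hit.iloc[0]) if len(hit) else np.nan
            prow[f"{col}_sd"] = np.nan
        table = pd.concat([table, pd.DataFrame([prow])], ignore_index=True)
    return table


def dsqiid_correlations(features: pd.DataFrame, meta: pd.DataFrame,
                        classes: tuple[int, ...] = (0, 3),
                        feature_col: str = "duration_ms") -> pd.DataFrame:
    """Spearman correlation of DSQIID with selected per-class features.

    Defaults to the durations of classes A and D, the two classes the
    dementia contrast is expected to move.
    """
    rows = []
    for k in classes:
        sub = features[features["class"] == k][["subject_id", feature_col]]
        merged = sub.merge(meta, on="subject_id", how="inner")
        rho, p = spearman(merged["dsqiid"], merged[feature_col])
        rows.append({"class": k, "feature": feature_col,
                     "rho": rho, "p_value": p, "n": len(merged)})
    return pd.DataFrame(rows)


def scatter_plots(features: pd.DataFrame, meta: pd.DataFrame,
                  out_dir: str | Path, classes: tuple[int, ...] = (0, 3),
                  feature_col: str = "duration_ms") -> list[Path]:
    """DSQIID-vs-feature scatterplots, one PNG per class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in classes:
        sub = features[features["class"] == k][["subject_id", feature_col]]
        merged = sub.merge(meta, on="subject_id", how="inner")
        fig, ax = plt.subplots(figsize=(4, 3))
        for group, g in merged.groupby("group", sort=False):
            ax.scatter(g["dsqiid"], g[feature_col], label=str(group), s=18)
        ax.set_xlabel("DSQIID score")
        name = chr(ord("A") + k)
        ax.set_ylabel(f"{feature_col} (class {name})")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = out_dir / f"dsqiid_vs_{feature_col}_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
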