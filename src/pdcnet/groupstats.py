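"""Group-level statistics.

Every comparison is gated by a Shapiro-Wilk normality check at 0.05:
parametric tests (paired / unpaired two-sided t) are used when the gate
passes, otherwise Wilcoxon signed-rank / Mann-Whitney U. Connectivity
contrasts declare significance at a fixed alpha of 0.01 (a modified
Bonferroni allowance for the three planned comparisons); effect sizes are
Cohen's d (mean difference over the sample SD of the differences for paired
data, pooled-SD standardization for unpaired). A small clinical motor-score
table (Fugl-Meyer Assessment, 34-point lower-extremity motor domain, 22
patients in two rehabilitation arms) ships with the package for the clinical
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

CONNECTIVITY_ALPHA = 0.01
GATE_ALPHA = 0.05
FMA_MAX = 34


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    effect_size_d: float
    test_used: str            # "t" | "wilcoxon" | "mannwhitney" | "degenerate"
    significant: bool
    alpha: float
    n: tuple
    zero_variance: bool = False


def load_fma_table(path=None) -> pd.DataFrame:
    """Load the packaged clinical scores table (or a user-supplied CSV)."""
    if path is None:
        src = resources.files("pdcnet.data").joinpath("fma_scores.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"subject_id", "group", "fma_pre", "fma_post"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")
    for col in ("fma_pre", "fma_post"):
        if df[col].isna().any():
            raise ValueError(f"missing values in {col}")
        if (df[col] < 0).any() or (df[col] > FMA_MAX).any():
            raise ValueError(f"{col} outside the 0-{FMA_MAX} motor scale")
    return df


def normality_gate(sample, alpha: float = GATE_ALPHA) -> str:
    """"parametric" iff Shapiro-Wilk does not reject normality."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    return "parametric" if stats.shapiro(x).pvalue >= alpha else "nonparametric"


def cohens_d_paired(x_pre, x_post) -> float:
    d = np.asarray(x_post, float) - np.asarray(x_pre, float)
    sd = d.std(ddof=1)
    return float(d.mean() / sd) if sd > 0 else 0.0


def cohens_d_unpaired(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def compare_paired(x_pre, x_post,
                   alpha: float = CONNECTIVITY_ALPHA) -> ComparisonResult:
    """Two-sided paired comparison (post vs pre), normality-gated."""
    x_pre = np.asarray(x_pre, float)
    x_post = np.asarray(x_post, float)
    if x_pre.shape != x_post.shape:
        raise ValueError("paired samples must have equal length")
    if x_pre.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x_post - x_pre
    d = cohens_d_paired(x_pre, x_post)
    if np.ptp(diff) == 0:
        # identical pre/post (or constant shift of zero variance)
        if np.all(diff == 0):
            return ComparisonResult(0.0, 1.0, 0.0, "degenerate", False,
                                    alpha, (x_pre.size,), zero_variance=True)
        return ComparisonResult(np.inf, 0.0, d, "degenerate", True,
                                alpha, (x_pre.size,), zero_variance=True)
    if normality_gate(diff) == "parametric":
        res = stats.ttest_rel(x_post, x_pre)
        test = "t"
    else:
        res = stats.wilcoxon(x_post, x_pre)
        test = "wilcoxon"
    p = float(res.pvalue)
    return ComparisonResult(float(res.statistic), p, d, test, p < alpha,
                            alpha, (x_pre.size,))


def compare_unpaired(a, b, alpha: float = CONNECTIVITY_ALPHA,
                     ) -> ComparisonResult:
    """Two-sided unpaired comparison (a vs b), normality-gated."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    d = cohens_d_unpaired(a, b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = a[0] == b[0]
        return ComparisonResult(0.0 if same else np.inf,
                                1.0 if same else 0.0,
                                d, "degenerate", not same, alpha,
                                (a.size, b.size), zero_variance=True)
    pooled = np.concatenate([a - a.mean(), b - b.mean()])
    if np.ptp(pooled) == 0 or normality_gate(pooled) == "parametric":
        res = stats.ttest_ind(a, b)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mannwhitney"
    p = float(res.pvalue)
    return ComparisonResult(float(res.statistic), p, d, test, p < alpha,
                            alpha, (a.size, b.size))


def delta_correlation(fma_table: pd.DataFrame,
                      connectivity_pre: dict[str, float],
                      connectivity_post: dict[str, float],
                      method: str = "pearson") -> tuple[float, float]:
    """Correlate intervention-induced changes: Delta(FMA) vs
    Delta(regional out-strength), matched by subject_id.

    ``connectivity_pre/post`` map subject_id -> the region's out-strength.
    """
    subjects = list(fma_table["subject_id"])
    missing = [s for s in subjects
               if s not in connectivity_pre or s not in connectivity_post]
    if missing:
        raise ValueError(f"unmatched subjects: {missing}")
    d_fma = (fma_table["fma_post"] - fma_table["fma_pre"]).to_numpy(float)
    d_conn = np.array([connectivity_post[s] - connectivity_pre[s]
                       for s in subjects])
    if method == "pearson":
        r, p = stats.pearsonr(d_fma, d_conn)
    elif method == "spearman":
        r, p = stats.spearmanr(d_fma, d_conn)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def fma_summary(fma_table: pd.DataFrame) -> dict:
    """Clinical summary: pre/post means and SDs, mean change, per-arm
    changes, and the paired pre-vs-post comparison."""
    pre = fma_table["fma_pre"].to_numpy(float)
    post = fma_table["fma_post"].to_numpy(float)
    change = post - pre
    per_group = {}
    for g, sub in fma_table.groupby("group"):
        gc = (sub["fma_post"] - sub["fma_pre"]).to_numpy(float)
        per_group[g] = {"mean_change": float(gc.mean()),
                        "sd_change": float(gc.std(ddof=1)),
                        "n": int(gc.size)}
    return {
        "n": int(pre.size),
        "mean_pre": float(pre.mean()),
        "sd_pre": float(pre.std(ddof=1)),
        "mean_post": float(post.mean()),
        "sd_post": float(post.std(ddof=1)),
        "mean_change": float(change.mean()),
        "sd_change": float(change.std(ddof=1)),
        "per_group": per_group,
        "paired": compare_paired(pre, post, alpha=0.05),
    }


def mixed_anova(fma_table: pd.DataFrame) -> pd.DataFrame:
    """Two-way mixed (split-plot) ANOVA: between factor group, within factor
    time (pre/post). Returns a table with F and p for group, time and the
    interaction."""
    if fma_table["group"].nunique() < 2:
        raise ValueError("mixed ANOVA requires two groups")
    import pingouin as pg

    long = pd.melt(
        fma_table, id_vars=["subject_id", "group"],
        value_vars=["fma_pre", "fma_post"],
        var_name="time", value_name="fma",
    )
    long["time"] = long["time"].str.replace("fma_", "")
    aov = pg.mixed_anova(data=long, dv="fma", within="time",
                         subject="subject_id", between="group")
    aov = aov.rename(columns={"Source": "effect", "p-unc": "p",
                              "p_unc": "p"})
    aov.loc[aov["effect"] == "Interaction", "effect"] = "group x time"
    aov.loc[aov["effect"] == "group", "effect"] = "group"
    return aov[["effect", "F", "p", "DF1", "DF2"]]
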