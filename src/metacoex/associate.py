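"""Module- and metabolite-level association with change in depression
severity, outcome classification, and remitter-vs-failure contrasts.

Module eigenvectors and individual metabolite change scores are related to
the per-subject change in HAM-D17 (week 12 minus baseline) with Pearson
correlations; a module is called significant when |r| exceeds 0.3 at an
uncorrected p below 0.10, the convention for small pilot cohorts. A
covariate-adjusted fixed-effects linear model (metabolite change on HAM-D
change, age, and sex) provides per-metabolite coefficients with
Benjamini-Hochberg adjusted q-values. With a single change score per
subject a per-subject random effect is unidentifiable, so the adjusted
model is ordinary least squares by design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from metacoex.types import BASELINE, WEEK12, DataError

DEFAULT_R_CUT = 0.3
DEFAULT_P_CUT = 0.1
DEFAULT_TRAJECTORY_ALPHA = 0.10
_Z975 = float(stats.norm.ppf(0.975))

SEX_CODES = {"female": 0, "male": 1}


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p-value from t = r sqrt((n-2)/(1-r^2))."""
    n = len(x)
    if n < 4:
        raise DataError("need at least 4 observations for a correlation test")
    sx, sy = x.std(), y.std()
    if sy == 0:
        raise DataError("zero-variance trait")
    if sx == 0:
        raise DataError("zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait_correlation(
    eigenvectors: pd.DataFrame,
    trait: pd.Series,
    r_cut: float = DEFAULT_R_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate each module eigenvector with the trait.

    A module is flagged significant iff |r| > r_cut and p < p_cut. Returns
    the association table and a modules x 1 heatmap matrix of r values (p in
    a parallel column) for plotting or CSV export.
    """
    aligned = eigenvectors.loc[trait.index]
    rows = []
    for module in eigenvectors.columns:
        r, p = _pearson_with_p(
            aligned[module].to_numpy(dtype=float), trait.to_numpy(dtype=float)
        )
        rows.append(
            {
                "unit": module,
                "r": r,
                "p": p,
                "significant": bool(abs(r) > r_cut and p < p_cut),
            }
        )
    table = pd.DataFrame(rows)
    heatmap = table.set_index("unit")[["r", "p"]]
    heatmap.index.name = "module"
    return table, heatmap


def metabolite_trait_correlation(
    changes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Per-metabolite Pearson correlation of change scores with the trait."""
    aligned = changes.loc[trait.index]
    y = trait.to_numpy(dtype=float)
    rows = []
    for met in changes.columns:
        r, p = _pearson_with_p(aligned[met].to_numpy(dtype=float), y)
        rows.append({"unit": met, "r": r, "p": p})
    return pd.DataFrame(rows)


def univariate_model(
    changes: pd.DataFrame,
    trait: pd.Series,
    age: pd.Series,
    sex: pd.Series,
) -> pd.DataFrame:
    """Covariate-adjusted per-metabolite association (OLS, shared design).

    Fits ``change = b0 + b1 * dHAMD + b2 * age + b3 * sex`` for every
    metabolite at once, reporting b1, a normal-approximation 95% CI, the
    two-sided t-test p-value, and Benjamini-Hochberg q-values across all
    metabolites. Sex is coded female=0, male=1.
    """
    subjects = changes.index
    y = changes.loc[subjects].to_numpy(dtype=float)
    sex_num = (
        sex.map(SEX_CODES) if sex.dtype == object else sex
    ).loc[subjects].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(subjects)),
            trait.loc[subjects].to_numpy(dtype=float),
            age.loc[subjects].to_numpy(dtype=float),
            sex_num,
        ]
    )
    names = ["intercept", "dhamd", "age", "sex"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the collinear columns for the error message
        bad = []
        for i in range(1, X.shape[1]):
            others = np.delete(X, i, axis=1)
            resid = X[:, i] - others @ np.linalg.lstsq(others, X[:, i], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-10):
                bad.append(names[i])
        raise DataError(f"collinear covariates: {bad or names[1:]}")
    n, p = X.shape
    if n <= p:
        raise DataError("more covariates than subjects")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ y  # p x m coefficient matrix
    resid = y - X @ B
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se_b1 = np.sqrt(sigma2 * XtX_inv[1, 1])
    b1 = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se_b1 > 0, b1 / se_b1, np.inf * np.sign(b1))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    pvals = np.where(se_b1 > 0, pvals, 0.0)
    q = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "unit": changes.columns,
            "coefficient": b1,
            "ci_low": b1 - _Z975 * se_b1,
            "ci_high": b1 + _Z975 * se_b1,
            "p": pvals,
            "q": q,
        }
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def classify_outcome(hamd_baseline: int, hamd_wk10: int, hamd_wk12: int) -> str:
    """Classify a HAM-D17 trajectory into the four outcome categories.

    Remission (score <=7 at both week 10 and week 12) takes precedence;
    otherwise percent reduction from baseline to week 12 places the subject
    into responder (>=50%), partial responder (30-49%), or failure (<30%,
    including worsening).
    """
    scores = (hamd_baseline, hamd_wk10, hamd_wk12)
    if any(s < 0 for s in scores):
        raise DataError("HAM-D scores must be nonnegative")
    if hamd_baseline <= 0:
        raise DataError("baseline HAM-D must be positive")
    if hamd_wk10 <= 7 and hamd_wk12 <= 7:
        return "remitter"
    reduction = (hamd_baseline - hamd_wk12) / hamd_baseline
    if reduction >= 0.50:
        return "responder"
    if reduction >= 0.30:
        return "partial_responder"
    return "failure"


def trajectory_summary(
    log2_levels: pd.DataFrame,
    sample_map: pd.DataFrame,
    metadata: pd.DataFrame,
    groups: tuple = ("remitter", "failure"),
) -> pd.DataFrame:
    """Mean +/- SEM trajectories for the extreme outcome groups.

    For each metabolite and group, reports mean and SEM (sd/sqrt(n), sample
    sd) of log2 levels at baseline and week 12, plus the two-sided Welch
    t-test p-value contrasting the groups' baseline levels. Intermediate
    outcome groups are excluded.
    """
    meta = metadata.set_index("subject_id")
    sm = sample_map.set_index("sample_id")
    rows = []
    group_baseline = {}
    for group in groups:
        subjects = meta.index[meta["outcome"] == group]
        if len(subjects) < 2:
            raise DataError(f"group {group!r} has fewer than 2 subjects")
        for tp in (BASELINE, WEEK12):
            ids = sm.index[
                sm["subject_id"].isin(subjects) & (sm["timepoint"] == tp)
            ]
            block = log2_levels.loc[log2_levels.index.intersection(ids)]
            if tp == BASELINE:
                group_baseline[group] = block
            mean = block.mean(axis=0)
            sem = block.std(axis=0, ddof=1) / np.sqrt(len(block))
            for met in log2_levels.columns:
                rows.append(
                    {
                        "metabolite_id": met,
                        "group": group,
                        "timepoint": tp,
                        "mean": float(mean[met]),
                        "sem": float(sem[met]),
                        "n": int(len(block)),
                    }
                )
    table = pd.DataFrame(rows)
    a, b = groups
    pvals = {}
    for met in log2_levels.columns:
        res = stats.ttest_ind(
            group_baseline[a][met], group_baseline[b][met], equal_var=False
        )
        pvals[met] = float(res.pvalue)
    table["baseline_p"] = table["metabolite_id"].map(pvals)
    return table


def cohort_summary(metadata: pd.DataFrame) -> dict:
    """Table-1-style cohort description.

    Counts and percentages (one decimal) per outcome category and sex, plus
    mean (SD) age and HAM-D at baseline and week 12, rounded to one decimal.
    """
    if metadata.empty:
        raise DataError("empty cohort")
    n = len(metadata)

    def _pct(count: int) -> float:
        return round(100.0 * count / n, 1)

    def _mean_sd(col: str) -> dict:
        vals = metadata[col].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        return {"mean": round(float(vals.mean()), 1), "sd": round(sd, 1)}

    outcome_counts = metadata["outcome"].value_counts()
    outcomes = {
        cat: {"count": int(outcome_counts.get(cat, 0)), "pct": _pct(int(outcome_counts.get(cat, 0)))}
        for cat in ("remitter", "responder", "partial_responder", "failure")
    }
    sex_counts = metadata["sex"].value_counts()
    return {
        "n": n,
        "age": _mean_sd("age"),
        "sex": {
            s: {"count": int(sex_counts.get(s, 0)), "pct": _pct(int(sex_counts.get(s, 0)))}
            for s in ("female", "male")
        },
        "outcomes": outcomes,
        "hamd_baseline": _mean_sd("hamd_baseline"),
        "hamd_wk12": _mean_sd("hamd_wk12"),
    }
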