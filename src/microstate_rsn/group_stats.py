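"""Group comparison of microstate parameters.

The confirmatory test is a repeated-measures multivariate ANOVA of the
group x microstate interaction: the K per-state values of a parameter
form the within-subject vector, age and gender enter as covariates, and
the interaction is tested on the K-1 within-subject difference
contrasts via Wilks' Lambda (Rao's F approximation).  Post hoc
per-state comparisons are two-sample t-tests on the unstandardized
residuals after regressing the parameter on the covariates, with a
Bonferroni-adjusted threshold of 0.05/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.multivariate.manova import MANOVA

#: multivariate alpha for the confirmatory parameter (mean duration)
ALPHA_CONFIRMATORY = 0.05
#: multivariate alpha for the exploratory parameters (GEV, RTT, transitions)
ALPHA_EXPLORATORY = 0.1


@dataclass
class GroupStatsResult:
    parameter: str
    wilks_lambda: float
    F: float
    df_num: float
    df_den: float
    p_multivariate: float
    posthoc: pd.DataFrame  # per state: t, p, group means
    posthoc_threshold: float
    degenerate: bool = False
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame({
            "parameter": [self.parameter],
            "wilks_lambda": [self.wilks_lambda],
            "F": [self.F],
            "df_num": [self.df_num],
            "df_den": [self.df_den],
            "p_multivariate": [self.p_multivariate],
            "posthoc_threshold": [self.posthoc_threshold],
        })
        return head


_PARAM_COLUMNS = {
    "mean_duration": "mean_duration_ms",
    "gev": "gev",
    "rtt": "ratio_total_time",
    "occurrence": "occurrence_per_s",
}


def parameter_matrix(metrics_table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Pivot the long metrics table to one row per subject, one column per state.

    For ``parameter="transition"`` the columns are the flattened
    off-diagonal entries of the row-normalized transition matrix and
    must already be present as columns named ``trans_<i>_<j>``.
    """
    if parameter == "transition":
        cols = [c for c in metrics_table.columns if c.startswith("trans_")]
        if not cols:
            raise ValueError("no trans_i_j columns in metrics table")
        wide = metrics_table.drop_duplicates("subject_id").set_index("subject_id")
        return wide[cols]
    col = _PARAM_COLUMNS[parameter]
    wide = metrics_table.pivot(index="subject_id", columns="state", values=col)
    return wide


def transition_columns(metrics: list) -> pd.DataFrame:
    """Flatten each subject's off-diagonal transition probabilities."""
    rows = []
    for m in metrics:
        K = m.K
        entry = {"subject_id": m.subject_id, "group": m.group}
        for i in range(K):
            for j in range(K):
                if i != j:
                    entry[f"trans_{i}_{j}"] = m.transition_matrix[i, j]
        rows.append(entry)
    return pd.DataFrame(rows)


def _merge_design(wide: pd.DataFrame, subjects) -> pd.DataFrame:
    sub = subjects.table.set_index("subject_id")
    df = wide.join(sub[["group", "age", "gender"]], how="inner")
    if df.isna().any().any():
        raise ValueError("missing parameter or covariate values after merge")
    counts = df["group"].value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise ValueError("need two groups with >= 2 subjects each")
    return df


def rm_anova(
    metrics_table: pd.DataFrame,
    subjects,
    parameter: str = "mean_duration",
) -> GroupStatsResult:
    """Multivariate test of the group x state interaction with covariates.

    The K state values per subject are reduced to K-1 within-subject
    differences (state_k - state_K); the multivariate group effect on
    those differences is exactly the group x state interaction of the
    repeated-measures ANOVA.  Wilks' Lambda and its F approximation come
    from the MANOVA of the difference vector on group + age + gender.
    """
    wide = parameter_matrix(metrics_table, parameter)
    df = _merge_design(wide, subjects)
    value_cols = [c for c in wide.columns]
    Y = df[value_cols].to_numpy(dtype=float)
    K = Y.shape[1]
    D = Y[:, :-1] - Y[:, [-1]]  # within-subject difference contrasts

    design = pd.DataFrame({
        "group": pd.Categorical(df["group"]).codes.astype(float),
        "age": df["age"].astype(float).to_numpy(),
        "gender": pd.Categorical(df["gender"]).codes.astype(float),
    }, index=df.index)
    for j in range(D.shape[1]):
        design[f"d{j}"] = D[:, j]

    dvars = " + ".join(f"d{j}" for j in range(D.shape[1]))
    formula = f"{dvars} ~ group + age + gender"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mv = MANOVA.from_formula(formula, data=design)
            table = mv.mv_test().results["group"]["stat"]
        wl = float(table.loc["Wilks' lambda", "Value"])
        F = float(table.loc["Wilks' lambda", "F Value"])
        df_num = float(table.loc["Wilks' lambda", "Num DF"])
        df_den = float(table.loc["Wilks' lambda", "Den DF"])
        p = float(table.loc["Wilks' lambda", "Pr > F"])
        degenerate, note = False, ""
    except Exception as exc:  # singular design (e.g., constant covariate)
        wl, F, df_num, df_den, p = np.nan, np.nan, np.nan, np.nan, np.nan
        degenerate, note = True, f"degenerate design: {exc}"

    posthoc = posthoc_residual_t(metrics_table, subjects, parameter)
    return GroupStatsResult(
        parameter=parameter,
        wilks_lambda=wl,
        F=F,
        df_num=df_num,
        df_den=df_den,
        p_multivariate=p,
        posthoc=posthoc,
        posthoc_threshold=0.05 / K,
        degenerate=degenerate,
        note=note,
    )


def posthoc_residual_t(
    metrics_table: pd.DataFrame,
    subjects,
    parameter: str = "mean_duration",
) -> pd.DataFrame:
    """Per-state two-sample t-tests on covariate-adjusted residuals.

    For each state the parameter is regressed on age and gender with
    both groups pooled; the unstandardized residuals are compared
    between groups with an equal-variance two-sample t-test.
    """
    wide = parameter_matrix(metrics_table, parameter)
    df = _merge_design(wide, subjects)
    groups = sorted(df["group"].unique())
    g_mask = df["group"] == groups[0]

    X = np.column_stack([
        np.ones(len(df)),
        df["age"].astype(float).to_numpy(),
        pd.Categorical(df["gender"]).codes.astype(float),
    ])
    rows = []
    for col in wide.columns:
        y = df[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        a, b = resid[g_mask.to_numpy()], resid[~g_mask.to_numpy()]
        if np.ptp(resid) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sstats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "state": col,
            "t": float(t),
            "p": float(p),
            f"mean_{groups[0]}": float(df.loc[g_mask, col].mean()),
            f"mean_{groups[1]}": float(df.loc[~g_mask, col].mean()),
        })
    return pd.DataFrame(rows)
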