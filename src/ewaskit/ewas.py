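"""Two-stage PCA-adjusted epigenome-wide association analysis.

The adjustment strategy regresses per-probe methylation on phenotype and
nuisance covariates while absorbing technical and global confounding with
two principal-component bases:

1. *Control-probe PCs* — PCA of log control-probe intensities captures
   batch/technical variation that the control probes carry by design; the
   top 30 scores enter the model as covariates.
2. *Residual PCs* — after a first regression of beta on the nuisance
   covariates plus control PCs (no phenotype term), PCA of the residual
   matrix captures residual global structure; the top 5 scores join the
   final model.

The final per-probe model is ordinary least squares of beta on
[group + nuisance covariates + control PCs + residual PCs]; the group
coefficient is reported in delta-beta units with its SE, t, two-sided
p (t distribution with residual df) and Benjamini-Hochberg q.  Genomic
inflation (lambda) summarizes test calibration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_N_CONTROL_PCS = 30
DEFAULT_N_RESIDUAL_PCS = 5
DISCOVERY_P_THRESHOLD = 5e-7
REPLICATION_P_THRESHOLD = 0.05
CHI2_1_MEDIAN = 0.4549364231195724  # median of the 1-df chi-square

#: Covariate columns of the standard nuisance design (plus six cell types).
NUISANCE_COVARIATES = ["age", "smoker", "audit_c", "adherence", "log10_vl", "wbc"]


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------


def _drop_aliased(D: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop zero-variance / linearly dependent columns (keeps the first)."""
    keep: list[int] = []
    for j in range(D.shape[1]):
        cand = D[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    dropped = [names[j] for j in range(D.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=3)
    return D[:, keep], [names[j] for j in keep]


def build_design(
    covariates: pd.DataFrame,
    control_pcs: pd.DataFrame | None = None,
    residual_pcs: pd.DataFrame | None = None,
    group: pd.Series | None = None,
) -> tuple[np.ndarray, list[str], pd.Index]:
    """Assemble [intercept | group | covariates | PCs] over complete samples.

    Samples with any missing term are dropped listwise (with a warning
    reporting the count).  Returns the design matrix after aliased-column
    removal, the retained column names, and the sample index used.
    """
    parts = [covariates.astype(float)]
    if control_pcs is not None:
        parts.append(control_pcs.add_prefix("ctl_"))
    if residual_pcs is not None:
        parts.append(residual_pcs.add_prefix("res_"))
    X = pd.concat(parts, axis=1, join="inner")
    if group is not None:
        g = group.reindex(X.index)
        gnum = (
            g.map({"case": 1.0, "control": 0.0})
            if g.dtype == object
            else g.astype(float)
        )
        X.insert(0, "group", gnum)
    complete = X.notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"dropping {int((~complete).sum())} samples with missing model terms",
            stacklevel=2,
        )
        X = X.loc[complete]
    names = ["intercept"] + list(X.columns)
    D = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    D, names = _drop_aliased(D, names)
    return D, names, X.index


# ---------------------------------------------------------------------------
# PCA bases
# ---------------------------------------------------------------------------


def _pca_scores(matrix: np.ndarray, sample_ids: pd.Index, k: int, prefix: str) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA over samples of a (features x samples) matrix, rows centered.

    Scores are the sample coordinates (U*S of the SVD of the centered,
    transposed matrix).  Sign is fixed by making each component's largest-
    magnitude feature loading positive, for cross-platform determinism.
    """
    n = matrix.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    total_var = float(np.sum(centered**2))
    if total_var <= 0:
        raise ValueError("matrix has zero variance; PCA undefined")
    # SVD of samples x features
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    k = min(k, int(np.sum(s > 1e-12 * s[0])))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            scores[:, j] *= -1
            loadings[j] *= -1
    var_frac = (s[:k] ** 2) / total_var
    df = pd.DataFrame(
        scores, index=sample_ids, columns=[f"{prefix}{j + 1}" for j in range(k)]
    )
    return df, var_frac


@dataclasses.dataclass
class PcaBasis:
    scores: pd.DataFrame  # samples x k
    variance_fraction: np.ndarray


def control_probe_pcs(control_intensities: pd.DataFrame, k: int = DEFAULT_N_CONTROL_PCS) -> PcaBasis:
    """Top-k PCs of log-transformed, per-probe-centered control intensities."""
    X = np.log(control_intensities.to_numpy(float) + 1.0)
    scores, var_frac = _pca_scores(X, control_intensities.columns, k, "PC")
    return PcaBasis(scores=scores, variance_fraction=var_frac)


def stage1_residuals(
    beta: pd.DataFrame, covariates: pd.DataFrame, control_pcs: pd.DataFrame
) -> pd.DataFrame:
    """Per-probe OLS residuals of beta on nuisance covariates + control PCs.

    No phenotype term enters this model: the residuals carry whatever
    global biological structure the covariates and control PCs missed,
    which the second PCA then summarizes.
    """
    D, _, idx = build_design(covariates, control_pcs)
    Y = beta.loc[:, idx].to_numpy(float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    return pd.DataFrame(resid.T, index=beta.index, columns=idx)


def residual_pcs(residual_matrix: pd.DataFrame, k: int = DEFAULT_N_RESIDUAL_PCS) -> PcaBasis:
    """Top-k PCs over samples of the probe x sample residual matrix."""
    scores, var_frac = _pca_scores(
        residual_matrix.to_numpy(float), residual_matrix.columns, k, "PC"
    )
    return PcaBasis(scores=scores, variance_fraction=var_frac)


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EwasResult:
    """Per-probe group-term statistics plus global diagnostics.

    ``table`` is indexed by probe id with columns coefficient, se, t, p, q
    and n; ``lambda_`` is the genomic inflation factor of the p-values;
    ``terms`` lists the design columns actually used.
    """

    table: pd.DataFrame
    lambda_: float
    terms: list[str]

    def significant(self, p_threshold: float = DISCOVERY_P_THRESHOLD) -> pd.DataFrame:
        return self.table.loc[self.table["p"] < p_threshold]


def _group_term_ols(D: np.ndarray, Y: np.ndarray, g: int) -> tuple[np.ndarray, ...]:
    """Vectorized per-probe OLS; returns (coef, se, t, p) for column ``g``."""
    n, p = D.shape
    if n < p + 2:
        raise ValueError(f"n={n} too small for {p} design columns")
    XtX_inv = np.linalg.inv(D.T @ D)
    H = XtX_inv @ D.T
    coef_all = H @ Y  # p x m
    resid = Y - D @ coef_all
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[g, g], 1e-300))
    coef = coef_all[g]
    t = coef / se
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef, se, t, np.clip(pval, np.finfo(float).tiny, 1.0)


def fit_final_glm(
    beta: pd.DataFrame,
    group: pd.Series,
    covariates: pd.DataFrame,
    control_pcs: pd.DataFrame | None = None,
    residual_pcs: pd.DataFrame | None = None,
) -> EwasResult:
    """Fit the final adjusted per-probe model and report the group term.

    Estimation is OLS on beta values, so coefficients read directly as
    case-minus-control methylation differences.  (An M-value analysis can
    be run by passing logit-transformed values; beta is the default so
    printed coefficients stay in delta-beta units.)
    """
    D, names, idx = build_design(covariates, control_pcs, residual_pcs, group=group)
    if "group" not in names:
        raise ValueError("group term aliased out of the design")
    g = names.index("group")
    Y = beta.loc[:, idx].to_numpy(float).T
    coef, se, t, pval = _group_term_ols(D, Y, g)
    q = adjust_fdr(pval)
    table = pd.DataFrame(
        {"coefficient": coef, "se": se, "t": t, "p": pval, "q": q, "n": len(idx)},
        index=beta.index,
    )
    lam = genomic_inflation(pval) if len(pval) >= 100 else float("nan")
    return EwasResult(table=table, lambda_=lam, terms=names)


def genomic_inflation(p_values: np.ndarray | pd.Series) -> float:
    """lambda = median observed 1-df chi-square / its null median (0.4549)."""
    p = np.asarray(p_values, float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def adjust_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Permutation robustness check and three-group ANOVA
# ---------------------------------------------------------------------------


def permutation_check(
    beta: pd.DataFrame,
    group: pd.Series,
    covariates: pd.DataFrame,
    probe_ids: list[str],
    control_pcs: pd.DataFrame | None = None,
    residual_pcs: pd.DataFrame | None = None,
    B: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Empirical per-probe p from refitting the final model under permuted labels.

    Guards the headline hits against outlier-driven artifacts: the group
    labels are permuted ``B`` times, the adjusted model refit each time,
    and empirical p = (1 + #{|t_perm| >= |t_obs|}) / (B + 1).
    """
    if B < 20:
        warnings.warn("B < 20 gives very coarse empirical p-values", stacklevel=2)
    missing = [p for p in probe_ids if p not in beta.index]
    if missing:
        raise ValueError(f"probes not in matrix: {missing[:3]}")
    rng = np.random.default_rng(seed)
    sub = beta.loc[probe_ids]
    D, names, idx = build_design(covariates, control_pcs, residual_pcs, group=group)
    g = names.index("group")
    Y = sub.loc[:, idx].to_numpy(float).T
    _, _, t_obs, _ = _group_term_ols(D, Y, g)
    exceed = np.zeros(len(probe_ids))
    gcol = D[:, g].copy()
    for _ in range(B):
        D[:, g] = rng.permutation(gcol)
        _, _, t_perm, _ = _group_term_ols(D, Y, g)
        exceed += np.abs(t_perm) >= np.abs(t_obs)
    D[:, g] = gcol
    emp_p = (1.0 + exceed) / (B + 1.0)
    return pd.Series(emp_p, index=probe_ids, name="empirical_p")


def three_group_anova(
    beta: pd.DataFrame, probe_ids: list[str], groups: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA across exposure-recency groups plus pairwise contrasts.

    ``groups`` maps sample id to a label (e.g. current/past/none).  Returns
    per-probe F and p, and two-sided pairwise t-test p-values for each pair
    of labels (columns like ``p_current_vs_past``).
    """
    labels = [l for l in pd.unique(groups) if pd.notna(l)]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    members = {l: groups.index[groups == l] for l in labels}
    for l, ids in members.items():
        if len(ids) < 2:
            raise ValueError(f"group {l!r} has fewer than 2 samples")
    rows = []
    for pid in probe_ids:
        vals = [beta.loc[pid, ids].to_numpy(float) for ids in members.values()]
        F, p = stats.f_oneway(*vals)
        row = {"probe_id": pid, "F": F, "p": p}
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                tt = stats.ttest_ind(vals[i], vals[j], equal_var=True)
                row[f"p_{labels[i]}_vs_{labels[j]}"] = tt.pvalue
        rows.append(row)
    return pd.DataFrame(rows).set_index("probe_id")


# ---------------------------------------------------------------------------
# Convenience: the full two-stage pipeline
# ---------------------------------------------------------------------------


def run_cpacor_ewas(
    beta: pd.DataFrame,
    group: pd.Series,
    covariates: pd.DataFrame,
    control_intensities: pd.DataFrame,
    n_control_pcs: int = DEFAULT_N_CONTROL_PCS,
    n_residual_pcs: int = DEFAULT_N_RESIDUAL_PCS,
) -> EwasResult:
    """Control-probe PCA -> stage-1 residuals -> residual PCA -> final model.

    ``n_residual_pcs=0`` (or ``n_control_pcs=0``) skips that basis.
    """
    cpcs = (
        control_probe_pcs(control_intensities, k=n_control_pcs).scores
        if n_control_pcs > 0
        else None
    )
    rpcs = None
    if n_residual_pcs > 0:
        resid = stage1_residuals(
            beta, covariates, cpcs if cpcs is not None else covariates.iloc[:, :0]
        )
        rpcs = residual_pcs(resid, k=n_residual_pcs).scores
    return fit_final_glm(beta, group, covariates, cpcs, rpcs)
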