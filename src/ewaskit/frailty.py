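"""Methylation panels, cumulative risk scores and frailty discrimination.

From a single-site association scan this module selects a probe panel
(p < 1e-3 by default, with a smallest-p-per-gene representative map),
residualizes panel methylation against the nuisance design (coefficients
fitted on training samples only, so the recipe can be re-applied to new
samples without leakage), clusters samples on the residuals
(complete-linkage, Euclidean), forms a coefficient-weighted cumulative
methylation score, correlates it with a disease-burden index in [0, 120],
and trains/evaluates a maximum-margin classifier for the high- and
low-frailty binary tasks, with a random-panel permutation null for the
observed AUC.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .ewas import EwasResult, build_design

DEFAULT_P_CUT = 1e-3
DEFAULT_HIGH_CUT = 50
DEFAULT_LOW_CUT = 16
DEFAULT_FOLDS = 10
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


# ---------------------------------------------------------------------------
# Residualization recipe (train-once, apply-anywhere)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Residualizer:
    """OLS nuisance regression fitted on training samples.

    ``transform`` subtracts the *training-fitted* linear predictor, so
    residuals for held-out samples never see their own outcome structure.
    """

    columns: list[str] | None = None
    coef_: pd.DataFrame | None = None  # design columns x probes

    def fit(self, beta: pd.DataFrame, covariates: pd.DataFrame) -> "Residualizer":
        D, names, idx = build_design(covariates)
        Y = beta.loc[:, idx].to_numpy(float).T
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        self.columns = names
        self.coef_ = pd.DataFrame(coef, index=names, columns=beta.index)
        return self

    def transform(self, beta: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
        if self.coef_ is None:
            raise ValueError("residualizer not fitted")
        needed = [c for c in self.columns if c != "intercept"]
        missing = [c for c in needed if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariates missing fitted design columns: {missing}")
        # reuse the training design columns verbatim (no re-aliasing), so a
        # single held-out sample transforms exactly like a training sample
        X = covariates[needed].astype(float).dropna()
        D = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
        probes = self.coef_.columns
        Y = beta.loc[probes, X.index].to_numpy(float).T
        resid = Y - D @ self.coef_.to_numpy()
        return pd.DataFrame(resid.T, index=probes, columns=X.index)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "coef": None if self.coef_ is None else self.coef_.to_dict(),
        }


# ---------------------------------------------------------------------------
# Panel selection and the cumulative score
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PanelModel:
    """A probe panel with association-coefficient weights.

    ``gene_map`` maps gene symbol to its representative probe (smallest
    association p among the gene's panel probes).
    """

    probe_ids: list[str]
    weights: pd.Series
    gene_map: dict[str, str]
    residualizer: Residualizer | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("panel weights must be finite")


def select_panel(
    ewas_result: EwasResult,
    p_cut: float = DEFAULT_P_CUT,
    manifest: pd.DataFrame | None = None,
) -> PanelModel:
    """Probes with association p < ``p_cut``; weights are their coefficients.

    When a manifest is supplied, a gene-representative map is built with
    the smallest-p-per-gene rule (intergenic probes are skipped).
    """
    tab = ewas_result.table
    sel = tab.loc[tab["p"] < p_cut]
    if sel.empty:
        raise ValueError(f"no probes pass p < {p_cut}; loosen the cut")
    gene_map: dict[str, str] = {}
    if manifest is not None:
        ann = manifest.set_index("probe_id")
        genes = ann.reindex(sel.index)["gene"].fillna("")
        for gene, probes in genes.groupby(genes).groups.items():
            if gene == "":
                continue
            best = sel.loc[list(probes), "p"].idxmin()
            gene_map[str(gene)] = best
    return PanelModel(
        probe_ids=list(sel.index),
        weights=sel["coefficient"].copy(),
        gene_map=gene_map,
    )


def residualize_panel(
    beta: pd.DataFrame, panel: PanelModel, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Fit the panel's nuisance recipe on these samples and return residuals.

    Stores the fitted :class:`Residualizer` on the panel so the same
    recipe can be re-applied to held-out samples via ``transform``.
    """
    missing = [p for p in panel.probe_ids if p not in beta.index]
    if missing:
        raise ValueError(f"panel probes missing from beta: {missing[:5]}")
    rz = Residualizer().fit(beta.loc[panel.probe_ids], covariates)
    panel.residualizer = rz
    return rz.transform(beta.loc[panel.probe_ids], covariates)


def cumulative_score(values: pd.DataFrame, panel: PanelModel) -> pd.Series:
    """score(sample) = sum_i w_i * v_i(sample) / panel size.

    ``values`` may hold residual methylation (default downstream choice)
    or raw beta; rows must cover the panel probes.
    """
    missing = [p for p in panel.probe_ids if p not in values.index]
    if missing:
        raise ValueError(f"values missing panel probes: {missing[:5]}")
    V = values.loc[panel.probe_ids]
    w = panel.weights.loc[panel.probe_ids]
    return (w @ V) / len(panel.probe_ids)


def correlate_score_index(scores: pd.Series, vacs_index: pd.Series) -> tuple[float, float, int]:
    """Pearson correlation of score with the frailty index; (r, p, n)."""
    joined = pd.concat([scores, vacs_index], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    a, b = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in scores or index")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def hierarchical_cluster(
    residuals: pd.DataFrame, k: int = 2
) -> tuple[pd.Series, np.ndarray]:
    """Complete-linkage Euclidean clustering of samples; cut at k clusters.

    ``residuals`` is probes x samples.  Returns integer labels (1..k) per
    sample and the dendrogram merge heights.  SciPy's linkage resolves
    ties deterministically by observation order, giving a stable rule.
    """
    X = residuals.to_numpy(float).T
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=residuals.columns, name="cluster"), Z[:, 2]


def cluster_phenotype_association(
    labels: pd.Series,
    samples: pd.DataFrame,
    categorical: tuple[str, ...] = ("group", "smoker"),
    continuous: tuple[str, ...] = ("age", "wbc", "log10_vl", "adherence"),
) -> pd.DataFrame:
    """Chi-square (categorical) / one-way ANOVA (continuous) per variable.

    Tests whether sample clusters track each phenotype; low expected cell
    counts (< 5) attach a warning flag rather than an error.
    """
    if labels.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    joined = samples.loc[labels.index]
    for var in categorical:
        if var not in joined.columns:
            continue
        table = pd.crosstab(labels, joined[var])
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        low = bool((expected < 5).any())
        if low:
            warnings.warn(f"{var}: expected cell counts < 5", stacklevel=2)
        rows.append({"variable": var, "test": "chi-square", "statistic": chi2, "p": p,
                     "low_expected_counts": low})
    for var in continuous:
        if var not in joined.columns:
            continue
        groups = [joined.loc[labels == l, var].dropna().to_numpy(float)
                  for l in sorted(labels.unique())]
        F, p = stats.f_oneway(*groups)
        rows.append({"variable": var, "test": "anova", "statistic": F, "p": p,
                     "low_expected_counts": False})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Frailty labels
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FrailtyLabels:
    """Index bands and the two binary tasks derived from the frailty index.

    The binary tasks are unambiguous: high = index > high_cut, low =
    index < low_cut.  Five-band edges follow the documented convention
    (-inf, low_cut], (low_cut, 24], (24, 34], (34, high_cut], (high_cut,
    inf) — boundary indices land in the lower band.
    """

    index: pd.Series
    band: pd.Series
    high: pd.Series  # 1 if index > high_cut
    low: pd.Series  # 1 if index < low_cut
    high_cut: float
    low_cut: float


def define_frailty_labels(
    vacs_index: pd.Series,
    high_cut: float = DEFAULT_HIGH_CUT,
    low_cut: float = DEFAULT_LOW_CUT,
    derive_cuts_quantile: bool = False,
) -> FrailtyLabels:
    """Band and binary frailty labels from an index in [0, 120].

    With ``derive_cuts_quantile`` the cuts are re-derived as the 80%/20%
    quantiles of the supplied (training) indices instead of the fixed
    defaults.
    """
    v = vacs_index.astype(float)
    if ((v < 0) | (v > 120)).any():
        raise ValueError("index values must lie in [0, 120]")
    if derive_cuts_quantile:
        low_cut = float(np.quantile(v, 0.2))
        high_cut = float(np.quantile(v, 0.8))
    if high_cut >= v.max() or low_cut <= v.min():
        warnings.warn("a cut falls outside the observed index range; degenerate task",
                      stacklevel=2)
    inner = sorted({low_cut, 24.0, 34.0, high_cut})
    edges = [-np.inf] + inner + [np.inf]
    band = pd.cut(v, bins=edges, labels=False) + 1
    return FrailtyLabels(
        index=v,
        band=pd.Series(band, index=v.index, name="band"),
        high=(v > high_cut).astype(int).rename("high_frailty"),
        low=(v < low_cut).astype(int).rename("low_frailty"),
        high_cut=high_cut,
        low_cut=low_cut,
    )


# ---------------------------------------------------------------------------
# Classifier, ROC, permutation null
# ---------------------------------------------------------------------------


def train_frailty_classifier(
    train_residuals: pd.DataFrame,
    train_labels: pd.Series,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    kernel: str = "linear",
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> SVC:
    """Maximum-margin classifier with stratified k-fold CV over C.

    ``train_residuals`` is probes x samples.  The linear kernel is the
    default (reproducible, interpretable weights); ``kernel='rbf'`` adds a
    gamma grid.  Classes are inverse-frequency weighted: the binary
    frailty tasks put ~15-20% of samples in the positive class, and an
    unweighted margin on such data concentrates on the majority class.
    If the minority class cannot fill ``folds`` folds the fold count is
    reduced (error if below 2).
    """
    X = train_residuals.to_numpy(float).T
    y = train_labels.loc[train_residuals.columns].to_numpy(int)
    counts = np.bincount(y)
    if (counts > 0).sum() < 2:
        raise ValueError("both classes must be present in training data")
    min_class = counts[counts > 0].min()
    eff_folds = min(folds, int(min_class))
    if eff_folds < 2:
        raise ValueError("minority class too small for cross-validation")
    if eff_folds < folds:
        warnings.warn(f"reducing CV folds to {eff_folds} (minority class size)",
                      stacklevel=2)
    grid: dict[str, list] = {"C": list(c_grid)}
    if kernel == "rbf":
        grid["gamma"] = ["scale", 0.01, 0.001]
    cv = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(SVC(kernel=kernel, class_weight="balanced"), grid, cv=cv,
                      scoring="roc_auc", refit=True)
    gs.fit(X, y)
    return gs.best_estimator_


@dataclasses.dataclass
class RocSummary:
    """AUC with bootstrap CI and ROC curve points; optional permutation null."""

    auc: float
    ci_lower: float
    ci_upper: float
    fpr: np.ndarray
    tpr: np.ndarray
    null_aucs: np.ndarray | None = None
    permutation_p: float | None = None


def evaluate_roc(
    model: SVC,
    test_residuals: pd.DataFrame,
    test_labels: pd.Series,
    ci_reps: int = 2000,
    seed: int = 0,
) -> RocSummary:
    """AUC on held-out samples with a stratified-bootstrap 95% CI.

    Decision scores come from the margin (``decision_function``); the CI
    resamples positives and negatives separately so both classes survive
    every replicate.
    """
    X = test_residuals.to_numpy(float).T
    y = test_labels.loc[test_residuals.columns].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes")
    scores = model.decision_function(X)
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    boots = np.empty(ci_reps)
    for b in range(ci_reps):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        boots[b] = roc_auc_score(y[idx], scores[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocSummary(auc=auc, ci_lower=float(lo), ci_upper=float(hi), fpr=fpr, tpr=tpr)


def _fixed_svm_auc(
    probe_ids: list[str],
    beta_train: pd.DataFrame,
    beta_test: pd.DataFrame,
    cov_train: pd.DataFrame,
    cov_test: pd.DataFrame,
    y_train: pd.Series,
    y_test: pd.Series,
    C: float = 1.0,
) -> float:
    """Residualize -> linear SVM at fixed C -> test AUC for one probe set."""
    rz = Residualizer().fit(beta_train.loc[probe_ids], cov_train)
    Xtr = rz.transform(beta_train.loc[probe_ids], cov_train)
    Xte = rz.transform(beta_test.loc[probe_ids], cov_test)
    clf = SVC(kernel="linear", C=C, class_weight="balanced")
    clf.fit(Xtr.to_numpy(float).T, y_train.loc[Xtr.columns].to_numpy(int))
    scores = clf.decision_function(Xte.to_numpy(float).T)
    return float(roc_auc_score(y_test.loc[Xte.columns].to_numpy(int), scores))


def permutation_panel_null(
    beta_train: pd.DataFrame,
    beta_test: pd.DataFrame,
    cov_train: pd.DataFrame,
    cov_test: pd.DataFrame,
    y_train: pd.Series,
    y_test: pd.Series,
    panel_size: int,
    observed_panel: list[str] | None = None,
    B: int = 200,
    seed: int = 0,
    C: float = 1.0,
) -> RocSummary | np.ndarray:
    """Random-panel null for the observed classification AUC.

    Draws ``B`` random probe panels of ``panel_size`` without replacement
    from all probes, runs the full residualize -> train -> test pass for
    each (linear SVM at fixed C for observed and null alike, so the
    comparison isolates the probe choice), and reports
    p = (1 + #{null AUC >= observed}) / (B + 1).  With ``observed_panel``
    None, returns just the null AUC array.
    """
    if B < 100:
        warnings.warn(f"B={B} below 100; permutation p resolution is coarse",
                      stacklevel=2)
    all_probes = np.asarray(beta_train.index)
    if panel_size > len(all_probes):
        raise ValueError("panel_size exceeds the number of available probes")
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(B)
    for b in range(B):
        pick = rng.choice(all_probes, size=panel_size, replace=False)
        null_aucs[b] = _fixed_svm_auc(
            list(pick), beta_train, beta_test, cov_train, cov_test, y_train, y_test, C=C
        )
    if observed_panel is None:
        return null_aucs
    observed = _fixed_svm_auc(
        observed_panel, beta_train, beta_test, cov_train, cov_test, y_train, y_test, C=C
    )
    p = (1.0 + float(np.sum(null_aucs >= observed))) / (B + 1.0)
    return RocSummary(
        auc=observed,
        ci_lower=float("nan"),
        ci_upper=float("nan"),
        fpr=np.array([]),
        tpr=np.array([]),
        null_aucs=null_aucs,
        permutation_p=p,
    )
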