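"""Phenotype and environment statistics.

Trait preprocessing (population-mean imputation, ratio derivation, log
transform), standardized PCA, PERMANOVA, disparity, discriminant analyses,
per-trait random-intercept mixed models with sequential F-tests, and
partial eta-squared effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEFAULT_RATIOS, LOG_EXEMPT, TraitTable

logger = logging.getLogger("parallodrome")

ALPHA = 0.05


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess_traits(raw: TraitTable, ratios=None, log_exempt=LOG_EXEMPT) -> TraitTable:
    """Impute, derive ratios, and log-transform a raw trait table.

    Order of operations: population-mean imputation of missing cells;
    derivation of the configured ratios from the untransformed
    measurements; natural-log transform of every column not in
    ``log_exempt``.  The exempt columns are carried through unchanged.
    """
    if raw.transformed:
        raise ValueError("trait table is already transformed")
    ratios = DEFAULT_RATIOS if ratios is None else ratios
    df = raw.data.copy()
    measured = list(raw.trait_names)
    for t in measured:
        means = df.groupby("population")[t].transform("mean")
        all_missing = df.loc[means.isna(), "population"].unique().tolist()
        if all_missing:
            raise ValueError(
                f"trait {t!r} entirely missing in population(s) {all_missing}"
            )
        df[t] = df[t].fillna(means)
    for name, (num, den) in ratios.items():
        if num not in measured or den not in measured:
            raise ValueError(f"ratio {name} references unknown trait(s) {num}/{den}")
        df[name] = df[num] / df[den]
    trait_names = measured + list(ratios)
    to_log = [t for t in trait_names if t not in log_exempt]
    bad = {t: int((df[t] <= 0).sum()) for t in to_log if (df[t] <= 0).any()}
    if bad:
        raise ValueError(f"non-positive values in log-transformed column(s): {bad}")
    df[to_log] = np.log(df[to_log])
    return TraitTable(data=df, dataset=raw.dataset, trait_names=trait_names,
                      transformed=True)


# --------------------------------------------------------------------------
# ordination
# --------------------------------------------------------------------------

@dataclass
class TraitPca:
    scores: np.ndarray
    loadings: np.ndarray                  # traits x axes
    explained_variance_ratio: np.ndarray
    trait_names: list
    mean: np.ndarray
    sd: np.ndarray


def trait_pca(T: TraitTable) -> TraitPca:
    """PCA of column-standardized (zero mean, unit variance) trait values."""
    X = T.values()
    if np.isnan(X).any():
        raise ValueError("trait table contains missing values; preprocess first")
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 individuals")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = [t for t, s in zip(T.trait_names, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance trait(s): {zero}")
    Z = (X - mean) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    return TraitPca(scores=U * s, loadings=Vt.T,
                    explained_variance_ratio=var / var.sum(),
                    trait_names=list(T.trait_names), mean=mean, sd=sd)


def euclidean_distances(X) -> np.ndarray:
    """Square symmetric Euclidean distance matrix of row vectors."""
    X = np.asarray(X, dtype=float)
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    d2 = 0.5 * (d2 + d2.T)   # exact symmetry despite BLAS rounding
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    partial_r2: float
    p_perm: float
    n_perm: int
    df: tuple


def _permanova_ss_within(D2: np.ndarray, labels: np.ndarray) -> float:
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ssw += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ssw


def permanova(D: np.ndarray, labels, n_perm: int = 30_000,
              seed: int | None = None, factor: str = "group") -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d^2 / N; SS_within = sum_g sum_{i<j in g} d^2 /
    n_g; pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)); the p-value is
    the proportion of label permutations with F at least as large,
    (#{F_perm >= F_obs} + 1)/(n_perm + 1).
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    N = len(labels)
    if D.shape != (N, N):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    ulabels, counts = np.unique(labels, return_counts=True)
    a = len(ulabels)
    if a < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if counts.min() == 0:
        raise ValueError("empty group")
    D2 = D**2
    ss_total = D2.sum() / (2 * N)
    ss_within = _permanova_ss_within(D2, labels)
    ss_between = ss_total - ss_within
    # SS_within = 0 (coincident groups) legitimately gives F = inf
    with np.errstate(divide="ignore"):
        F_obs = (ss_between / (a - 1)) / (ss_within / (N - a))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ssw = _permanova_ss_within(D2, perm)
        with np.errstate(divide="ignore"):
            F = ((ss_total - ssw) / (a - 1)) / (ssw / (N - a))
        if F >= F_obs:
            count += 1
    return PermanovaResult(
        factor=factor,
        pseudo_F=float(F_obs),
        partial_r2=float(ss_between / ss_total),
        p_perm=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
        df=(a - 1, N - a),
    )


# --------------------------------------------------------------------------
# disparity
# --------------------------------------------------------------------------

@dataclass
class DisparityResult:
    medians: dict                 # group -> median distance to own centroid
    distances: np.ndarray         # per individual
    anova_F: float
    anova_df: tuple
    p: float
    singleton_groups: list


def disparity(scores, labels) -> DisparityResult:
    """Median distance of individuals to their group centroid.

    Uses all supplied ordination axes; group differences in the individual
    distances are tested by one-way ANOVA with df (g-1, N-g).
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    dist = np.empty(len(labels))
    singletons = []
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        cent = X[idx].mean(axis=0)
        dist[idx] = np.linalg.norm(X[idx] - cent, axis=1)
        if len(idx) == 1:
            singletons.append(g)
            logger.warning("disparity: group %r has a single individual", g)
    medians = {g: float(np.median(dist[labels == g])) for g in groups}
    F, p = stats.f_oneway(*[dist[labels == g] for g in groups])
    return DisparityResult(medians=medians, distances=dist, anova_F=float(F),
                           anova_df=(len(groups) - 1, len(labels) - len(groups)),
                           p=float(p), singleton_groups=singletons)


# --------------------------------------------------------------------------
# discriminant analyses
# --------------------------------------------------------------------------

@dataclass
class DAResult:
    grouping: str
    success_percent: float
    per_group_success: dict
    confusion: pd.DataFrame       # rows true, columns predicted
    loadings: np.ndarray | None   # traits x discriminant axes
    cross_validated: bool


def _trait_matrix(T, labels=None):
    if isinstance(T, TraitTable):
        X = T.values()
        if labels is None:
            raise ValueError("labels required")
    else:
        X = np.asarray(T, dtype=float)
    return X, np.asarray(labels)


def _check_da_inputs(X, labels):
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("discriminant analysis needs >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs > 1 individual")
    if X.shape[1] >= X.shape[0]:
        raise ValueError(
            "more traits than individuals; reduce dimensionality (e.g. PCA) first"
        )
    return groups


def _make_lda(n_groups):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    return LinearDiscriminantAnalysis(
        solver="svd", priors=np.full(n_groups, 1.0 / n_groups)
    )


def lda(T, labels, grouping: str = "group") -> DAResult:
    """Constrained ordination: Fisher LDA with equal priors.

    Classification success here is resubstitution; ``loadings`` are the
    discriminant-axis coefficients (min(g-1, traits) axes, sign arbitrary).
    """
    X, labels = _trait_matrix(T, labels)
    groups = _check_da_inputs(X, labels)
    model = _make_lda(len(groups)).fit(X, labels)
    pred = model.predict(X)
    return _da_result(labels, pred, groups, grouping,
                      loadings=model.scalings_, cv=False)


def classificatory_da_cv(T, labels, grouping: str = "group") -> DAResult:
    """Leave-one-out cross-validated linear discriminant classification."""
    X, labels = _trait_matrix(T, labels)
    groups = _check_da_inputs(X, labels)
    n = len(labels)
    pred = np.empty(n, dtype=object)
    for i in range(n):
        keep = np.arange(n) != i
        model = _make_lda(len(groups)).fit(X[keep], labels[keep])
        pred[i] = model.predict(X[i:i + 1])[0]
    return _da_result(labels, pred, groups, grouping, loadings=None, cv=True)


def _da_result(labels, pred, groups, grouping, loadings, cv):
    confusion = pd.DataFrame(0, index=groups, columns=groups)
    for t, p in zip(labels, pred):
        confusion.loc[t, p] += 1
    correct = np.asarray(pred) == labels
    per_group = {g: 100.0 * correct[labels == g].mean() for g in groups}
    return DAResult(
        grouping=grouping,
        success_percent=100.0 * correct.mean(),
        per_group_success=per_group,
        confusion=confusion,
        loadings=loadings,
        cross_validated=cv,
    )


# --------------------------------------------------------------------------
# linear mixed model per trait
# --------------------------------------------------------------------------

@dataclass
class TraitModelFit:
    trait: str
    dataset: str
    p_ecotype: float
    p_region: float
    p_interaction: float
    F_ecotype: float
    F_region: float
    F_interaction: float
    eta2_ecotype: float
    eta2_region: float
    eta2_interaction: float
    sigma2_u: float               # population random-intercept variance
    sigma2_e: float               # residual variance
    lambda_ratio: float           # sigma2_u / sigma2_e
    denom_df: int
    reml_criterion: float


def _design_matrices(df: pd.DataFrame):
    """Treatment-coded fixed-design blocks: intercept | ecotype | region |
    interaction, in the sequential-testing order."""
    eco = pd.get_dummies(df["ecotype"], drop_first=True).to_numpy(float)
    reg = pd.get_dummies(df["region"], drop_first=True).to_numpy(float)
    inter = np.einsum("ij,ik->ijk", eco, reg).reshape(len(df), -1)
    blocks = [np.ones((len(df), 1)), eco, reg, inter]
    return blocks


def _whiten(y, X, pop_codes, pop_sizes, lam):
    """Multiply by (I + lam Z Z^T)^{-1/2}; Z = population indicators.

    The matrix is block diagonal per population, with the block mean
    direction scaled by 1/sqrt(1 + lam n_j) and within-block deviations
    untouched, so the transform is a per-population shrink of the mean.
    """
    shrink = 1.0 - 1.0 / np.sqrt(1.0 + lam * pop_sizes)
    def w(v):
        means = np.zeros((len(pop_sizes),) + v.shape[1:])
        np.add.at(means, pop_codes, v)
        means /= pop_sizes.reshape((-1,) + (1,) * (v.ndim - 1))
        return v - shrink.reshape((-1,) + (1,) * (v.ndim - 1))[pop_codes] * means[pop_codes]
    return w(y), w(X)


def _reml_criterion(y, X, pop_codes, pop_sizes, lam):
    """-2 restricted log-likelihood, up to an additive constant."""
    n, p = X.shape
    yw, Xw = _whiten(y[:, None], X, pop_codes, pop_sizes, lam)
    beta, rss, rank, _ = np.linalg.lstsq(Xw, yw[:, 0], rcond=None)
    resid = yw[:, 0] - Xw @ beta
    rss = float(resid @ resid)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient fixed-effect design")
    sigma2 = rss / (n - p)
    if sigma2 <= 0:
        raise ValueError("perfect fit: residual variance is zero")
    logdet_v = float(np.log1p(lam * pop_sizes).sum())
    sign, logdet_xvx = np.linalg.slogdet(Xw.T @ Xw)
    return (n - p) * np.log(sigma2) + logdet_v + logdet_xvx, rss, sigma2


def fit_trait_lmm(df: pd.DataFrame, trait: str, dataset: str = "field",
                  alpha: float = ALPHA) -> TraitModelFit:
    """Random-intercept LMM y = ecotype * region + (1 | population).

    Fitted by REML with the variance ratio lambda = sigma2_u/sigma2_e
    profiled by one-dimensional optimization; fixed effects tested by
    sequential (Type I) F-tests in the order ecotype, region, interaction,
    against the residual mean square with containment denominator df
    (number of populations minus number of ecotype x region cells).
    Effect sizes are partial eta-squared from the Type II fixed-effects
    decomposition of the same data.

    ``df`` must carry columns population, region, ecotype and the trait.
    """
    need = {"population", "region", "ecotype", trait}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    df = df.reset_index(drop=True)
    if df["region"].nunique() < 2:
        raise ValueError("need >= 2 regions")
    if df["ecotype"].nunique() < 2:
        raise ValueError("need both ecotypes")
    n_pops = df["population"].nunique()
    if n_pops < 2:
        raise ValueError("population random effect inestimable with one population")
    y = df[trait].to_numpy(float)
    pop_codes, pop_labels = pd.factorize(df["population"])
    pop_sizes = np.bincount(pop_codes).astype(float)
    blocks = _design_matrices(df)
    X = np.column_stack(blocks)

    from scipy.optimize import minimize_scalar

    def crit(u):
        return _reml_criterion(y, X, pop_codes, pop_sizes, np.exp(u))[0]

    res = minimize_scalar(crit, bounds=(np.log(1e-8), np.log(1e4)),
                          method="bounded", options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    c0 = _reml_criterion(y, X, pop_codes, pop_sizes, 0.0)
    if c0[0] <= res.fun:
        lam = 0.0
        criterion, rss_full, sigma2 = c0
    else:
        criterion, rss_full, sigma2 = _reml_criterion(y, X, pop_codes, pop_sizes, lam)

    # sequential F-tests on the whitened data
    yw, Xw = _whiten(y[:, None], X, pop_codes, pop_sizes, lam)
    yw = yw[:, 0]
    widths = [b.shape[1] for b in blocks]
    edges = np.cumsum([0] + widths)
    rss_seq = []
    for stop in edges[1:]:
        beta, _, _, _ = np.linalg.lstsq(Xw[:, :stop], yw, rcond=None)
        r = yw - Xw[:, :stop] @ beta
        rss_seq.append(float(r @ r))
    n, p = X.shape
    n_cells = df.groupby(["ecotype", "region"], observed=True).ngroups
    ddf = n_pops - n_cells
    if ddf < 1:
        raise ValueError(
            f"containment df {ddf} < 1: need more populations than design cells"
        )
    Fs, ps = [], []
    for j in (1, 2, 3):   # ecotype, region, interaction
        num = (rss_seq[j - 1] - rss_seq[j]) / widths[j]
        F = num / sigma2
        Fs.append(float(F))
        ps.append(float(stats.f.sf(F, widths[j], ddf)))
    eta = partial_eta_squared(df, trait)
    return TraitModelFit(
        trait=trait, dataset=dataset,
        p_ecotype=ps[0], p_region=ps[1], p_interaction=ps[2],
        F_ecotype=Fs[0], F_region=Fs[1], F_interaction=Fs[2],
        eta2_ecotype=eta[0], eta2_region=eta[1], eta2_interaction=eta[2],
        sigma2_u=lam * sigma2, sigma2_e=sigma2, lambda_ratio=lam,
        denom_df=ddf, reml_criterion=float(criterion),
    )


def fit_all_traits(T: TraitTable, alpha: float = ALPHA) -> dict:
    """Per-trait LMM fits of a preprocessed trait table, keyed by trait."""
    if not T.transformed:
        raise ValueError("preprocess the trait table first")
    return {t: fit_trait_lmm(T.data, t, dataset=T.dataset, alpha=alpha)
            for t in T.trait_names}


# --------------------------------------------------------------------------
# effect sizes
# --------------------------------------------------------------------------

def partial_eta_squared(df: pd.DataFrame, trait: str):
    """Partial eta-squared of ecotype, region and their interaction.

    eta2_p(effect) = SS_effect / (SS_effect + SS_residual) with Type II
    sums of squares from the fixed-effects model trait ~ ecotype * region
    on individual data.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df[["ecotype", "region", trait]].rename(columns={trait: "_y"})
    cells = d.groupby(["ecotype", "region"], observed=True).size()
    expected_cells = d["ecotype"].nunique() * d["region"].nunique()
    if len(cells) < expected_cells:
        logger.warning("partial_eta_squared: empty design cell(s); "
                       "Type II SS remain defined")
    model = smf.ols("_y ~ C(ecotype) * C(region)", data=d).fit()
    if model.df_resid <= 0:
        raise ValueError("rank-deficient design: no residual df")
    table = sm.stats.anova_lm(model, typ=2)
    ss_resid = table.loc["Residual", "sum_sq"]
    out = []
    for key in ("C(ecotype)", "C(region)", "C(ecotype):C(region)"):
        ss = table.loc[key, "sum_sq"]
        out.append(float(ss / (ss + ss_resid)))
    return tuple(out)
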