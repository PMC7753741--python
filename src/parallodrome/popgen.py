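"""Population-genetic statistics and clustering on a GenotypeMatrix.

Diversity (pi, Watterson's theta, Tajima's D), Hudson FST, hierarchical
AMOVA, filtering (allele subsampling of tetraploids, per-window thinning,
singleton removal), PCA on individual allele frequencies, and the
lowest-BIC K-means scan.

All per-locus statistics are lineage-based: a diploid contributes 2 and a
tetraploid 4 lineages, so mixed-ploidy data need no special casing.  pi is
reported per SNP (mean over the loci present in the matrix); converting to
per-site values requires the number of callable invariant sites, which the
matrix does not carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("parallodrome")


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def subsample_alleles(G: GenotypeMatrix, target_ploidy: int = 2,
                      seed: int | None = None) -> GenotypeMatrix:
    """Randomly draw ``target_ploidy`` alleles per higher-ploidy individual.

    For a tetraploid with derived dosage d the reduced dosage is
    hypergeometric(d derived, 4-d ancestral; 2 drawn).  Samples already at
    the target ploidy pass through unchanged; missing stays missing.
    """
    ploidy = G.ploidy
    if np.any(ploidy < target_ploidy):
        bad = G.samples.loc[ploidy < target_ploidy, "sample_id"].tolist()
        raise ValueError(f"target_ploidy {target_ploidy} exceeds sample ploidy: {bad}")
    rng = np.random.default_rng(seed)
    dosages = G.dosages.copy()
    samples = G.samples.copy()
    for i in np.flatnonzero(ploidy > target_ploidy):
        row = dosages[i]
        ok = row != MISSING
        row[ok] = rng.hypergeometric(row[ok], ploidy[i] - row[ok], target_ploidy)
        samples.loc[samples.index[i], "ploidy"] = target_ploidy
    return GenotypeMatrix(samples=samples, loci=G.loci.copy(), dosages=dosages,
                          polarized=G.polarized)


def ld_thin(G: GenotypeMatrix, window_bp: int = 150_000,
            seed: int | None = None) -> GenotypeMatrix:
    """Keep one uniformly chosen SNP per non-overlapping window per chromosome."""
    rng = np.random.default_rng(seed)
    window = (G.loci["pos"].to_numpy() - 1) // window_bp
    keys = pd.DataFrame({"chrom": G.loci["chrom"], "win": window})
    keep = []
    for _, idx in keys.groupby(["chrom", "win"], sort=True).groups.items():
        keep.append(rng.choice(np.asarray(idx)))
    keep = np.sort(np.array(keep, dtype=int))
    if len(keep) == 0:
        logger.warning("ld_thin produced an empty matrix")
    return G.take_loci(keep)


def remove_singletons(G: GenotypeMatrix) -> GenotypeMatrix:
    """Drop loci whose minor allele occurs on exactly one lineage overall."""
    derived, lineages = G.allele_counts(np.arange(G.n_samples))
    minor = np.minimum(derived, lineages - derived)
    keep = np.flatnonzero(minor != 1)
    if len(keep) == 0:
        logger.warning("remove_singletons produced an empty matrix")
    return G.take_loci(keep)


# --------------------------------------------------------------------------
# diversity
# --------------------------------------------------------------------------

@dataclass
class DiversityStats:
    population: str
    n_lineages: int
    pi: float            # mean per-SNP pairwise diversity
    S: int               # segregating sites
    theta_w: float       # Watterson estimate per SNP set (S / a1)
    tajimas_d: float     # NaN when S = 0


def _per_locus_pi(derived, lineages):
    """Unbiased per-locus pairwise diversity n/(n-1) * 2 p q."""
    n = lineages.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, derived / n, 0.0)
        pi = np.where(n > 1, n / (n - 1.0) * 2.0 * p * (1.0 - p), np.nan)
    return pi


def nucleotide_diversity(G: GenotypeMatrix, population: str) -> float:
    """Mean per-SNP pairwise diversity pi of one population.

    Per locus pi_l = n/(n-1) * 2 p (1-p) with n the genotyped lineages and
    p the derived/alt frequency; aggregated as the mean over loci.
    """
    idx = G.sample_index(population=population)
    derived, lineages = G.allele_counts(idx)
    if len(idx) == 0 or (lineages < 2).all():
        raise ValueError(f"population {population!r} has fewer than 2 lineages")
    pi = _per_locus_pi(derived, lineages)
    return float(np.nanmean(pi))


def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(G: GenotypeMatrix, population: str) -> float:
    """Tajima's D over the population's segregating loci (NaN when S = 0).

    Constants are computed from the total lineage count, so a 4-individual
    tetraploid population enters with n = 16.
    """
    idx = G.sample_index(population=population)
    derived, lineages = G.allele_counts(idx)
    n = int(G.ploidy[idx].sum())
    if n < 4:
        raise ValueError(f"population {population!r} has n = {n} < 4 lineages")
    seg = (derived > 0) & (derived < lineages)
    S = int(seg.sum())
    if S == 0:
        logger.warning("tajimas_d: no segregating sites in %s", population)
        return float("nan")
    pi_total = float(np.nansum(_per_locus_pi(derived[seg], lineages[seg])))
    a1, e1, e2 = _tajima_constants(n)
    return (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def diversity_stats(G: GenotypeMatrix, population: str) -> DiversityStats:
    idx = G.sample_index(population=population)
    derived, lineages = G.allele_counts(idx)
    n = int(G.ploidy[idx].sum())
    seg = (derived > 0) & (derived < lineages)
    S = int(seg.sum())
    a1, _, _ = _tajima_constants(n) if n >= 2 else (np.nan,) * 3
    return DiversityStats(
        population=population,
        n_lineages=n,
        pi=nucleotide_diversity(G, population),
        S=S,
        theta_w=float(S / a1) if S else 0.0,
        tajimas_d=tajimas_d(G, population) if S and n >= 4 else float("nan"),
    )


# --------------------------------------------------------------------------
# differentiation
# --------------------------------------------------------------------------

def hudson_fst(G: GenotypeMatrix, popA: str, popB: str) -> float:
    """Hudson's FST, ratio of averages over loci.

    FST = sum_l (Hb_l - Hw_l) / sum_l Hb_l, with Hb the between-population
    and Hw the mean within-population heterozygosity (both with the
    unbiased n/(n-1) correction within populations).  NaN when both
    populations are monomorphic everywhere (sum Hb = 0).
    """
    dA, nA = G.allele_counts(G.sample_index(population=popA))
    dB, nB = G.allele_counts(G.sample_index(population=popB))
    usable = (nA >= 2) & (nB >= 2)
    if not usable.any():
        raise ValueError("need >= 2 genotyped lineages per side at some locus")
    dA, nA, dB, nB = dA[usable], nA[usable].astype(float), dB[usable], nB[usable].astype(float)
    pA, pB = dA / nA, dB / nB
    hw = 0.5 * (nA / (nA - 1) * 2 * pA * (1 - pA) + nB / (nB - 1) * 2 * pB * (1 - pB))
    hb = pA * (1 - pB) + pB * (1 - pA)
    denom = hb.sum()
    if denom == 0:
        logger.warning("hudson_fst: no between-population heterozygosity (%s, %s)",
                       popA, popB)
        return float("nan")
    return float((hb - hw).sum() / denom)


def fst_matrix(G: GenotypeMatrix, populations) -> pd.DataFrame:
    """Symmetric pairwise Hudson-FST matrix (diagonal 0)."""
    pops = list(populations)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            f = hudson_fst(G, a, b)
            out.loc[a, b] = out.loc[b, a] = f
    return out


# --------------------------------------------------------------------------
# AMOVA
# --------------------------------------------------------------------------

@dataclass
class AmovaResult:
    levels: tuple                     # hierarchy labels, top first
    variance_components: np.ndarray   # (among groups, among pops in groups, within)
    percent_variance: np.ndarray      # sums to 100 after truncation
    phi_statistics: dict              # Phi_CT, Phi_SC, Phi_ST
    permutation_p: dict               # p per tested component
    df: tuple
    sums_of_squares: tuple


def _amova_ss(X, groups, pops):
    """Sums of squares at the three levels from individual vectors X.

    Uses the identity sum_{i<j in S} d^2_ij / |S| = sum_{i in S}
    ||x_i - mean_S||^2 for squared Euclidean distances, so no explicit
    distance matrix is formed.
    """
    N = len(X)
    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_wp = 0.0
    ss_wg = 0.0
    for g in np.unique(groups):
        Xg = X[groups == g]
        ss_wg += float(((Xg - Xg.mean(axis=0)) ** 2).sum())
    for p in np.unique(pops):
        Xp = X[pops == p]
        ss_wp += float(((Xp - Xp.mean(axis=0)) ** 2).sum())
    ss_ag = ss_total - ss_wg            # among groups
    ss_ap = ss_wg - ss_wp               # among populations within groups
    return ss_ag, ss_ap, ss_wp


def _amova_components(X, groups, pops):
    N = len(X)
    glabels = np.unique(groups)
    plabels = np.unique(pops)
    G_, P_ = len(glabels), len(plabels)
    ss_ag, ss_ap, ss_wp = _amova_ss(X, groups, pops)
    df = (G_ - 1, P_ - G_, N - P_)
    ms_ag = ss_ag / df[0]
    ms_ap = ss_ap / df[1] if df[1] > 0 else 0.0
    ms_wp = ss_wp / df[2] if df[2] > 0 else 0.0
    # unequal-size coefficients (Excoffier et al. 1992)
    n_p = np.array([(pops == p).sum() for p in plabels], dtype=float)
    N_g = np.array([(groups == g).sum() for g in glabels], dtype=float)
    sum_np2_per_g = np.array([
        sum((pops == p).sum() ** 2 for p in plabels
            if groups[pops == p][0] == g)
        for g in glabels
    ], dtype=float)
    n1 = (N - (sum_np2_per_g / N_g).sum()) / df[1] if df[1] > 0 else 1.0
    n2 = ((sum_np2_per_g / N_g).sum() - (n_p ** 2).sum() / N) / df[0]
    n3 = (N - (N_g ** 2).sum() / N) / df[0]
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if df[1] > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return np.array([sigma_a, sigma_b, sigma_c]), df, (ss_ag, ss_ap, ss_wp)


def amova(G: GenotypeMatrix, hierarchy=("region", "population"),
          n_perm: int = 999, seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA (groups / populations within groups / within).

    Distances are squared Euclidean between individual dosage vectors
    normalized to allele frequencies (dosage/ploidy, per-locus mean
    imputation of missing cells).  Negative variance components are
    truncated to 0 before percentages.  Permutation p-values: whole
    populations permuted across groups for the among-group component;
    individuals permuted across populations within their group for the
    among-population component.
    """
    group_label, pop_label = hierarchy
    groups = G.samples[group_label].to_numpy()
    pops = G.samples[pop_label].to_numpy()
    for p in np.unique(pops):
        if len(np.unique(groups[pops == p])) > 1:
            raise ValueError(f"population {p!r} spans multiple {group_label} groups")
    if len(np.unique(groups)) < 2:
        raise ValueError("AMOVA needs >= 2 groups at the top level")
    X = G.frequencies(impute=True)
    comp, df, ss = _amova_components(X, groups, pops)
    total_raw = comp.sum()
    if total_raw <= 0:
        # degenerate: all individuals identical
        trunc = np.zeros(3)
        pct = np.array([0.0, 0.0, 100.0])
        phi = {"Phi_CT": 0.0, "Phi_SC": 0.0, "Phi_ST": 0.0}
    else:
        trunc = np.maximum(comp, 0.0)
        pct = 100.0 * trunc / trunc.sum()
        tot = trunc.sum()
        phi = {
            "Phi_CT": float(trunc[0] / tot),
            "Phi_SC": float(trunc[1] / (trunc[1] + trunc[2])) if trunc[1] + trunc[2] > 0 else 0.0,
            "Phi_ST": float((trunc[0] + trunc[1]) / tot),
        }
    rng = np.random.default_rng(seed)
    p_among_groups = _perm_p_groups(X, groups, pops, comp[0], n_perm, rng)
    p_among_pops = _perm_p_pops(X, groups, pops, comp[1], n_perm, rng)
    return AmovaResult(
        levels=(f"among {group_label}s",
                f"among {pop_label}s within {group_label}s",
                f"within {pop_label}s"),
        variance_components=comp,
        percent_variance=pct,
        phi_statistics=phi,
        permutation_p={"among_groups": p_among_groups,
                       "among_pops_within_groups": p_among_pops},
        df=df,
        sums_of_squares=ss,
    )


def _perm_p_groups(X, groups, pops, obs, n_perm, rng):
    """Permute whole populations across groups; keep group sizes in pops."""
    plabels = np.unique(pops)
    pop_group = np.array([groups[pops == p][0] for p in plabels])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pop_group)
        gmap = dict(zip(plabels, perm))
        g_new = np.array([gmap[p] for p in pops])
        comp, _, _ = _amova_components(X, g_new, pops)
        if comp[0] >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def _perm_p_pops(X, groups, pops, obs, n_perm, rng):
    """Permute individuals across populations within their group."""
    count = 0
    for _ in range(n_perm):
        p_new = pops.copy()
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            p_new[idx] = p_new[rng.permutation(idx)]
        comp, _, _ = _amova_components(X, groups, p_new)
        if comp[1] >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


# --------------------------------------------------------------------------
# ordination and clustering
# --------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray              # n_samples x n_axes
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray            # loci x axes

    def axes_for_variance(self, fraction: float = 0.9) -> int:
        """Smallest number of leading axes explaining >= fraction of variance."""
        cum = np.cumsum(self.explained_variance_ratio)
        return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def genotype_pca(G: GenotypeMatrix, scale: bool = False) -> PcaResult:
    """PCA of per-individual allele frequencies (dosage/ploidy, centered).

    Missing genotypes are replaced by the locus mean frequency before
    centering.  With ``scale`` columns are also scaled to unit variance.
    """
    if G.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = G.frequencies(impute=True)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    if np.allclose(X, 0):
        raise ValueError("all-constant matrix: PCA undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    return PcaResult(
        scores=U * s,
        explained_variance_ratio=var / var.sum(),
        loadings=Vt.T,
    )


@dataclass
class ClusterScan:
    K_values: np.ndarray
    bic: np.ndarray
    best_K: int
    assignments: np.ndarray   # at best K
    n_pca_axes: int
    n_starts: int


def kmeans_bic_scan(scores, K_range=range(1, 21), n_starts: int = 1000,
                    seed: int | None = None, n_pca_axes: int | None = None) -> ClusterScan:
    """Lowest-BIC K-means over PCA scores.

    For each K the best of ``n_starts`` runs by within-cluster sum of
    squares is kept and scored as BIC(K) = n ln(WSS/n) + K ln(n); the
    returned partition is the argmin-BIC one.  K values exceeding the
    sample count are skipped with a warning.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(scores, dtype=float)
    if n_pca_axes is not None:
        X = X[:, :n_pca_axes]
    n = X.shape[0]
    Ks, bics, assignments = [], [], []
    for K in K_range:
        if K > n:
            logger.warning("kmeans_bic_scan: K=%d > n=%d samples, skipped", K, n)
            continue
        if K == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=n_starts, random_state=seed)
            labels = km.fit_predict(X)
            wss = float(km.inertia_)
        bic = n * np.log(max(wss, 1e-300) / n) + K * np.log(n)
        Ks.append(K)
        bics.append(bic)
        assignments.append(labels)
    best = int(np.argmin(bics))
    return ClusterScan(
        K_values=np.array(Ks),
        bic=np.array(bics),
        best_K=int(Ks[best]),
        assignments=assignments[best],
        n_pca_axes=X.shape[1],
        n_starts=n_starts,
    )


# --------------------------------------------------------------------------
# rank-sum test
# --------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Returns (W, p) with W the Mann-Whitney U of the first sample.  Exact
    enumeration when n1 + n2 <= 12 and there are no ties; tie-corrected
    normal approximation otherwise.  Two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2), 1.0
    method = "exact" if (len(x) + len(y) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
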