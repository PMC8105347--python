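"""Statistical toolkit for the morphometric analysis.

Covers the repeatability analysis (measurement-error percentage from
one-way ANOVA variance components), non-parametric group comparisons
(Kruskal-Wallis, pairwise Wilcoxon rank-sum), PCA with supplementary
projection, permutational MANOVA on Euclidean distances between Fourier
coefficients, per-taxon mean shapes, and UPGMA clustering exported as
Newick.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .efa import EFTCoefficients, inverse_efourier

__all__ = [
    "MEResult",
    "PCAModel",
    "PermanovaResult",
    "measurement_error",
    "shape_measurement_error",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "pca_fit",
    "pca_project",
    "permutational_manova",
    "mean_shapes",
    "upgma_tree",
]


# ---------------------------------------------------------------------------
# measurement error

@dataclass
class MEResult:
    """Repeatability ANOVA summary for one scalar variable.

    pct_me is the within-measurement variance component over the sum of
    within- and among-individual components, times 100: 0 when repeats are
    perfectly reproducible, 100 when repeat noise swamps the differences
    between individuals.
    """

    F: float
    p: float
    pct_me: float
    ms_within: float
    ms_among: float
    m: int


def measurement_error(values, individual_ids, m: int | None = None) -> MEResult:
    """Measurement-error percentage from a balanced repeated-measures ANOVA.

    ``values`` holds one scalar per acquisition and ``individual_ids`` the
    individual each acquisition belongs to; every individual must be
    measured the same number of times (``m``, inferred when omitted).
    The among-individual variance component (MS_among - MS_within)/m is
    clamped at zero, the standard ANOVA estimator guard.
    """
    values = np.asarray(values, dtype=float)
    ids = np.asarray(individual_ids)
    uniq, inv = np.unique(ids, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 individuals")
    counts = np.bincount(inv)
    if not np.all(counts == counts[0]):
        raise ValueError("unbalanced design: unequal repeats per individual")
    m_obs = int(counts[0])
    if m is not None and m != m_obs:
        raise ValueError(f"m={m} does not match the data ({m_obs} repeats)")
    m = m_obs
    if m < 2:
        raise ValueError("each individual needs at least 2 repeats")
    n = len(values)
    grand = values.mean()
    group_means = np.bincount(inv, weights=values) / counts
    ss_among = float(m * ((group_means - grand) ** 2).sum())
    ss_within = float(((values - group_means[inv]) ** 2).sum())
    df_among = g - 1
    df_within = n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_among == 0:
            return MEResult(F=0.0, p=1.0, pct_me=0.0, ms_within=0.0,
                            ms_among=0.0, m=m)
        return MEResult(F=np.inf, p=0.0, pct_me=0.0, ms_within=0.0,
                        ms_among=ms_among, m=m)
    F = ms_among / ms_within
    p = float(stats.f.sf(F, df_among, df_within))
    s2_within = ms_within
    s2_among = max(0.0, (ms_among - ms_within) / m)
    pct_me = 100.0 * s2_within / (s2_within + s2_among)
    return MEResult(F=float(F), p=p, pct_me=float(pct_me),
                    ms_within=float(ms_within), ms_among=float(ms_among), m=m)


def shape_measurement_error(coeff_matrix, individual_ids,
                            n_pcs: int | None = None) -> pd.DataFrame:
    """%ME of a multivariate shape dataset, per principal component.

    The repeated-measures coefficient matrix is decomposed by PCA; %ME is
    reported for each retained PC and pooled across PCs by summing the
    within- and among-individual variance components (rows ``PC1..PCk`` and
    ``pooled``).  Which scalar a repeatability ANOVA should summarize shape
    by is genuinely ambiguous; exposing both views makes the choice visible.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    model = pca_fit(X)
    if n_pcs is None:
        n_pcs = int(np.searchsorted(np.cumsum(model.explained), 0.95) + 1)
    n_pcs = min(n_pcs, model.scores.shape[1])
    rows = []
    sw_sum = sa_sum = 0.0
    for j in range(n_pcs):
        res = measurement_error(model.scores[:, j], individual_ids)
        s2w = res.ms_within
        s2a = max(0.0, (res.ms_among - res.ms_within) / res.m)
        sw_sum += s2w
        sa_sum += s2a
        rows.append({"component": f"PC{j + 1}", "F": res.F, "p": res.p,
                     "pct_me": res.pct_me,
                     "explained": float(model.explained[j])})
    pooled = 100.0 * sw_sum / (sw_sum + sa_sum) if (sw_sum + sa_sum) else 0.0
    rows.append({"component": "pooled", "F": np.nan, "p": np.nan,
                 "pct_me": pooled, "explained": float(np.sum(
                     model.explained[:n_pcs]))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate group tests

def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test; returns (chi2-distributed H, df, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == u] for u in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    df = len(uniq) - 1
    if np.all(values == values[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


def pairwise_wilcoxon(values, groups, correction: str | None = None
                      ) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum P-values for every pair of groups.

    Exact P-values for small tie-free samples, normal approximation with
    tie and continuity correction otherwise.  Raw P-values by default;
    ``correction="bonferroni"`` multiplies them by the number of pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = {u: values[groups == u] for u in uniq}
    if any(len(s) == 0 for s in samples.values()):
        raise ValueError("empty group")
    mat = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    pairs = list(itertools.combinations(uniq, 2))
    for a, b in pairs:
        _, p = stats.mannwhitneyu(samples[a], samples[b],
                                  alternative="two-sided", method="auto")
        if correction == "bonferroni":
            p = min(1.0, p * len(pairs))
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


# ---------------------------------------------------------------------------
# PCA with supplementary projection

@dataclass
class PCAModel:
    center: np.ndarray
    loadings: np.ndarray    # (p, k) orthonormal columns
    explained: np.ndarray   # variance fractions, sums to 1
    scores: np.ndarray      # training projections (n, k)


def pca_fit(X) -> PCAModel:
    """Centered (not scaled) PCA via SVD.

    Component signs are fixed so the largest-magnitude loading of each axis
    is positive, making results reproducible across runs and platforms.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    center = X.mean(axis=0)
    Xc = X - center
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: no variance to decompose")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention
    signs = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    u = u * signs[None, :]
    var = s ** 2
    explained = var / var.sum()
    return PCAModel(center=center, loadings=vt.T, explained=explained,
                    scores=u * s)


def pca_project(model: PCAModel, new_rows) -> np.ndarray:
    """Project supplementary rows onto a fitted PCA.

    The rows are centered with the training means and multiplied by the
    training loadings, so they do not influence the axes.
    """
    new_rows = np.atleast_2d(np.asarray(new_rows, dtype=float))
    if new_rows.shape[1] != len(model.center):
        raise ValueError("variable count mismatch with the fitted model")
    return (new_rows - model.center) @ model.loadings


# ---------------------------------------------------------------------------
# permutational MANOVA

@dataclass
class PermanovaResult:
    F: float
    r2: float
    adj_r2: float
    p: float
    df_between: int
    df_within: int
    n_perm: int


def _permanova_ss(d2: np.ndarray, inv: np.ndarray, counts: np.ndarray,
                  ss_total: float, n: int):
    """SS partition from the squared-distance matrix for one labelling."""
    ss_within = 0.0
    for g in range(len(counts)):
        idx = np.nonzero(inv == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * counts[g])
    return ss_total - ss_within, ss_within


def permutational_manova(X, labels, n_perm: int = 999,
                         seed: int | None = None) -> PermanovaResult:
    """Distance-based MANOVA on Euclidean distances between rows of X.

    The pseudo-F statistic partitions the total sum of squared distances
    into between- and within-group parts; its null distribution is built by
    permuting group labels with a seeded RNG.  P-values use the
    (1 + #extreme) / (n_perm + 1) estimator.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    n = len(labels)
    d2 = squareform(pdist(X, metric="euclidean")) ** 2
    ss_total = d2.sum() / (2 * n)
    ss_between, ss_within = _permanova_ss(d2, inv, counts, ss_total, n)
    df_b, df_w = g - 1, n - g
    F_obs = (ss_between / df_b) / (ss_within / df_w)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(inv)
        ssb, ssw = _permanova_ss(d2, perm, counts, ss_total, n)
        F = (ssb / df_b) / (ssw / df_w)
        if F >= F_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    r2 = ss_between / ss_total
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - g)
    return PermanovaResult(F=float(F_obs), r2=float(r2), adj_r2=float(adj_r2),
                           p=float(p), df_between=df_b, df_within=df_w,
                           n_perm=n_perm)


# ---------------------------------------------------------------------------
# mean shapes and UPGMA tree

def mean_shapes(coeff_by_taxon: dict, k: int = 360) -> dict:
    """Average Fourier coefficients per taxon and reconstruct each outline.

    ``coeff_by_taxon`` maps taxon -> iterable of EFTCoefficients (or flat
    vectors); returns taxon -> (mean EFTCoefficients, reconstructed Outline).
    """
    out = {}
    for taxon, coeffs in coeff_by_taxon.items():
        flats = np.vstack([
            c.flatten() if isinstance(c, EFTCoefficients) else np.asarray(c)
            for c in coeffs])
        mean = EFTCoefficients.from_flat(flats.mean(axis=0))
        out[taxon] = (mean, inverse_efourier(mean, k=k))
    return out


def upgma_tree(mean_coeff_by_taxon: dict) -> str:
    """UPGMA (average-linkage) tree on Euclidean distances, as Newick.

    Node heights are half the merge distance, so cophenetic distances on
    the tree reproduce ultrametric inputs exactly; the tree is written with
    branch lengths and is meant to be displayed unrooted.
    """
    names = list(mean_coeff_by_taxon.keys())
    if len(names) != len(set(names)):
        raise ValueError("duplicate taxon names")
    if len(names) < 2:
        raise ValueError("need at least 2 taxa")
    M = np.vstack([
        c.flatten() if isinstance(c, EFTCoefficients) else np.asarray(c)
        for c in mean_coeff_by_taxon.values()])
    Z = linkage(pdist(M, metric="euclidean"), method="average")

    heights = {i: 0.0 for i in range(len(names))}
    newick = {i: names[i] for i in range(len(names))}
    for step, (a, b, dist, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        node = len(names) + step
        h = dist / 2.0
        la = h - heights[a]
        lb = h - heights[b]
        newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        heights[node] = h
    return newick[len(names) + len(Z) - 1] + ";"
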