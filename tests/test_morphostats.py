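"""Statistical suite: oracles, invariances and calibration checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from seedmorph import morphostats as ms
from seedmorph.efa import EFTCoefficients


# ---------------------------------------------------------------------------
# measurement error

def test_me_zero_when_repeats_identical():
    values = [1, 1, 1, 5, 5, 5, 9, 9, 9]
    ids = list("aaabbbccc")
    res = ms.measurement_error(values, ids)
    assert res.pct_me == 0.0
    assert res.p < 0.05


def test_me_hundred_when_individuals_indistinguishable():
    """Equal individual means with pure repeat noise: the among-individual
    variance component clamps at zero and %ME is exactly 100."""
    ids = np.repeat(np.arange(20), 3)
    values = np.tile([-1.0, 0.0, 1.0], 20)
    res = ms.measurement_error(values, ids)
    assert res.pct_me == 100.0
    assert res.ms_among == pytest.approx(0.0, abs=1e-12)


def test_me_recovers_variance_components():
    """sigma2_within=1, sigma2_among=3, m=3, N=200 -> %ME = 25 +/- 3.

    A single N=200 draw estimates %ME with sd ~2.5, so the estimate is
    averaged over independent replicates of the same design; the tolerance
    then tests the estimator, not one draw's sampling luck.
    """
    rng = np.random.default_rng(123)
    n, m = 200, 3
    ids = np.repeat(np.arange(n), m)
    estimates = []
    for _ in range(20):
        truth = rng.normal(0.0, np.sqrt(3.0), n)
        values = np.repeat(truth, m) + rng.normal(0.0, 1.0, n * m)
        res = ms.measurement_error(values, ids)
        assert res.m == 3
        estimates.append(res.pct_me)
    assert np.mean(estimates) == pytest.approx(25.0, abs=3.0)


def test_me_requires_balanced_design():
    with pytest.raises(ValueError, match="unbalanced"):
        ms.measurement_error([1, 2, 3, 4, 5], ["a", "a", "a", "b", "b"])
    with pytest.raises(ValueError):
        ms.measurement_error([1, 2, 3], ["a", "a", "a"])


@given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
def test_me_invariant_to_affine_value_changes(shift, scale):
    rng = np.random.default_rng(7)
    ids = np.repeat(np.arange(10), 3)
    values = rng.normal(0, 2, 30) + np.repeat(rng.normal(0, 3, 10), 3)
    base = ms.measurement_error(values, ids).pct_me
    moved = ms.measurement_error(values * scale + shift, ids).pct_me
    assert moved == pytest.approx(base, abs=1e-6)


# ---------------------------------------------------------------------------
# rank tests

def _kw_oracle(groups):
    """Brute-force Kruskal-Wallis H from first principles (no ties)."""
    values = np.concatenate(groups)
    ranks = sps.rankdata(values)
    n = len(values)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx:idx + len(g)]
        idx += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
    return 12.0 / (n * (n + 1)) * h


def test_kruskal_wallis_matches_rank_oracle():
    groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
              np.array([7.0, 8, 9])]
    h, df, p = ms.kruskal_wallis(np.concatenate(groups),
                                 np.repeat(["a", "b", "c"], 3))
    assert h == pytest.approx(_kw_oracle(groups))
    assert h == pytest.approx(7.2)
    assert df == 2


def test_kruskal_wallis_equal_rank_sums_give_zero():
    h, df, p = ms.kruskal_wallis([1, 6, 2, 5, 3, 4],
                                 ["a", "a", "b", "b", "c", "c"])
    assert h == pytest.approx(0.0, abs=1e-12)


def test_kruskal_wallis_identical_values_guarded():
    h, df, p = ms.kruskal_wallis([2.0] * 9, np.repeat(["a", "b", "c"], 3))
    assert (h, df, p) == (0.0, 2, 1.0)


def _wilcoxon_exact_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of label splits."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    sums = [sum(ranks[list(c)]) for c in
            itertools.combinations(range(len(pooled)), nx)]
    mu = np.mean(sums)
    extreme = sum(abs(s - mu) >= abs(obs - mu) - 1e-12 for s in sums)
    return extreme / len(sums)


def test_pairwise_wilcoxon_exact_enumeration():
    vals = np.array([1.0, 2, 3, 10, 11, 12])
    grp = np.array(["a"] * 3 + ["b"] * 3)
    mat = ms.pairwise_wilcoxon(vals, grp)
    oracle = _wilcoxon_exact_oracle(vals[:3], vals[3:])
    assert oracle == pytest.approx(0.1)
    assert mat.loc["a", "b"] == pytest.approx(oracle)


def test_pairwise_wilcoxon_symmetry_and_identity(rng):
    vals = rng.normal(0, 1, 30)
    grp = rng.choice(["x", "y", "z"], 30)
    # ensure non-empty groups
    grp[:3] = ["x", "y", "z"]
    mat = ms.pairwise_wilcoxon(vals, grp)
    for a in mat.index:
        for b in mat.columns:
            if a != b:
                assert mat.loc[a, b] == mat.loc[b, a]
    same = ms.pairwise_wilcoxon(np.tile([1.0, 2, 3, 4], 2),
                                np.repeat(["u", "v"], 4))
    assert same.loc["u", "v"] == pytest.approx(1.0, abs=0.15)


def test_kruskal_two_groups_monotone_with_ranksum(rng):
    """With two groups the KW p-value tracks the rank-sum p monotonically
    (the statistics are equivalent; only continuity handling differs)."""
    p_kw, p_w = [], []
    for shift in np.linspace(0.0, 2.0, 8):
        vals = np.concatenate([rng.normal(0, 1, 15),
                               rng.normal(shift, 1, 15)])
        grp = np.repeat(["a", "b"], 15)
        p_kw.append(ms.kruskal_wallis(vals, grp)[2])
        p_w.append(ms.pairwise_wilcoxon(vals, grp).loc["a", "b"])
    assert np.array_equal(np.argsort(p_kw), np.argsort(p_w))


# ---------------------------------------------------------------------------
# PCA

def test_pca_perfect_line():
    x = np.linspace(-1, 1, 50)
    X = np.column_stack([x, 2 * x])
    model = ms.pca_fit(X)
    assert model.explained[0] == pytest.approx(1.0)
    assert model.explained[1] == pytest.approx(0.0, abs=1e-12)
    direction = model.loadings[:, 0]
    expected = np.array([1.0, 2.0]) / np.sqrt(5.0)
    assert np.allclose(np.abs(direction @ expected), 1.0)


def test_pca_projecting_training_rows_reproduces_scores(rng):
    X = rng.normal(0, 1, (40, 6))
    model = ms.pca_fit(X)
    proj = ms.pca_project(model, X)
    assert np.allclose(proj, model.scores, atol=1e-10)


def test_pca_supplementary_rows_do_not_change_axes(rng):
    X = rng.normal(0, 1, (40, 5))
    model = ms.pca_fit(X)
    before = model.loadings.copy()
    ms.pca_project(model, rng.normal(10, 5, (200, 5)))
    assert np.array_equal(model.loadings, before)


def test_pca_isotropic_gaussian_splits_variance():
    rng = np.random.default_rng(55)
    X = rng.normal(0, 1, (100_000, 2))
    model = ms.pca_fit(X)
    assert model.explained[0] == pytest.approx(0.5, abs=0.01)
    assert model.explained[1] == pytest.approx(0.5, abs=0.01)


def test_pca_rejects_constant_matrix():
    with pytest.raises(ValueError):
        ms.pca_fit(np.ones((10, 3)))


# ---------------------------------------------------------------------------
# permutational MANOVA

def test_permanova_1d_equals_classical_anova_f(rng):
    vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 12),
                           rng.normal(2, 1, 9)])
    labels = np.array(["a"] * 10 + ["b"] * 12 + ["c"] * 9)
    res = ms.permutational_manova(vals, labels, n_perm=99, seed=0)
    f_ref, _ = sps.f_oneway(vals[:10], vals[10:22], vals[22:])
    assert res.F == pytest.approx(f_ref, rel=1e-10)
    assert res.df_between == 2
    assert res.r2 + (1 - res.r2) == pytest.approx(1.0)


def test_permanova_floor_p_for_separated_clusters(rng):
    X = np.vstack([rng.normal(0, 0.01, (10, 3)),
                   rng.normal(100, 0.01, (10, 3))])
    labels = np.repeat(["a", "b"], 10)
    res = ms.permutational_manova(X, labels, n_perm=999, seed=1)
    assert res.p == pytest.approx(1 / 1000)


def test_permanova_matches_skbio(rng):
    """Independent cross-check of the pseudo-F against scikit-bio."""
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    from scipy.spatial.distance import pdist, squareform
    X = rng.normal(0, 1, (30, 4))
    X[10:20] += 0.8
    labels = np.repeat(["a", "b", "c"], 10)
    res = ms.permutational_manova(X, labels, n_perm=99, seed=2)
    dm = skbio_stats.DistanceMatrix(squareform(pdist(X)))
    ref = skbio_stats.permanova(dm, grouping=list(labels), permutations=99)
    assert res.F == pytest.approx(ref["test statistic"], rel=1e-8)


def test_permanova_rejects_tiny_groups(rng):
    X = rng.normal(0, 1, (5, 2))
    with pytest.raises(ValueError):
        ms.permutational_manova(X, ["a", "a", "a", "a", "b"], n_perm=99)


def test_permanova_adj_r2_definition(rng):
    X = rng.normal(0, 1, (24, 3))
    labels = np.repeat(["a", "b", "c"], 8)
    res = ms.permutational_manova(X, labels, n_perm=99, seed=3)
    n, g = 24, 3
    assert res.adj_r2 == pytest.approx(
        1 - (1 - res.r2) * (n - 1) / (n - g), rel=1e-12)


# ---------------------------------------------------------------------------
# mean shapes

def test_mean_shapes_linearity():
    a = EFTCoefficients.from_flat(np.arange(20, dtype=float))
    b = EFTCoefficients.from_flat(np.arange(20, dtype=float) + 4.0)
    out = ms.mean_shapes({"t": [a, b]})
    mean, outline = out["t"]
    assert np.allclose(mean.flatten(), np.arange(20) + 2.0)
    single = ms.mean_shapes({"s": [a]})["s"][0]
    assert np.allclose(single.flatten(), a.flatten())


def test_mean_shape_recovery_from_simulated_taxon():
    """The per-taxon coefficient mean lands within 3 SE of the noiseless
    reference pushed through the same acquisition path."""
    from seedmorph import synthetic as syn
    from seedmorph.pipeline import RunConfig, stage_extract, stage_efa
    cfg = RunConfig(rng_seed=0)
    model = syn.default_taxon_models()[2]
    model.n_seeds = 30
    # fixed size: isolates shape recovery from the (nonlinear) interaction
    # of log-normal anisotropic rescaling with the normalization
    model.length_logsd = model.width_logsd = 0.0
    noisy = syn.simulate_population(
        [model], syn.NoiseSpec(rotation_sd=0.0, outline_jitter_sd=0.0005,
                               landmark_jitter_sd=0.0005, seed=21))
    ref_model = syn.TaxonModel(**{
        **model.__dict__, "n_seeds": 2,
        "coeff_sd": np.zeros_like(model.coeff_sd),
        "length_logsd": 0.0, "width_logsd": 0.0})
    clean = syn.simulate_population([ref_model], syn.NoiseSpec(seed=22))
    masks = {**noisy.masks, **{f"ref_{k}": v for k, v in clean.masks.items()}}
    lms = {**noisy.landmarks,
           **{f"ref_{k}": v for k, v in clean.landmarks.items()}}
    outlines, _ = stage_extract(masks, lms, scale=0.01)
    coeffs, _ = stage_efa(outlines, lms, cfg)
    is_ref = coeffs["id"].str.startswith("ref_")
    X = coeffs.loc[~is_ref].drop(columns="id").to_numpy()
    ref = coeffs.loc[is_ref].drop(columns="id").to_numpy().mean(axis=0)
    se = X.std(axis=0, ddof=1) / np.sqrt(len(X))
    dev = np.abs(X.mean(axis=0) - ref)
    # 3 SE statistical band plus a small systematic floor: sub-pixel
    # tracing and the nonlinear normalization bias coefficients by ~1e-3
    # at unit centroid size even for noiseless acquisition
    assert np.all(dev < 3 * se + 1.5e-3)


# ---------------------------------------------------------------------------
# UPGMA

def test_upgma_two_taxa_split_distance():
    tree = ms.upgma_tree({"A": np.array([0.0, 0.0]),
                          "B": np.array([4.0, 0.0])})
    assert tree.replace(" ", "") in ("(A:2,B:2);", "(B:2,A:2);")


def test_upgma_three_taxa_hand_computed():
    # d(A,B)=2, d(A,C)=d(B,C)=6 -> ((A,B):2,C:3); heights 1 and 3
    pts = {"A": np.array([-1.0, 0.0]), "B": np.array([1.0, 0.0]),
           "C": np.array([0.0, np.sqrt(35.0)])}
    nwk = ms.upgma_tree(pts)
    dendropy = pytest.importorskip("dendropy")
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(2.0)
    assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(6.0)
    assert pdm.distance(taxa["B"], taxa["C"]) == pytest.approx(6.0)


def test_upgma_cophenetic_recovers_ultrametric_input():
    h = np.sqrt(64.0 - 1.0 - 2.25)
    pts = {"A": np.array([-1.0, 0.0, 0.0]), "B": np.array([1.0, 0.0, 0.0]),
           "C": np.array([0.0, h, 1.5]), "D": np.array([0.0, h, -1.5])}
    # pairwise: AB=2, CD=3, cross=8 (ultrametric)
    nwk = ms.upgma_tree(pts)
    dendropy = pytest.importorskip("dendropy")
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    expected = {("A", "B"): 2.0, ("C", "D"): 3.0, ("A", "C"): 8.0,
                ("A", "D"): 8.0, ("B", "C"): 8.0, ("B", "D"): 8.0}
    for (a, b), d in expected.items():
        assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d)


def test_upgma_merge_heights_nondecreasing(rng):
    pts = {f"t{i}": rng.normal(0, 1, 6) for i in range(8)}
    nwk = ms.upgma_tree(pts)
    dendropy = pytest.importorskip("dendropy")
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.calc_node_ages(ultrametricity_precision=1e-6)   # raises if broken


def test_upgma_duplicate_names_rejected():
    with pytest.raises(ValueError):
        ms.upgma_tree(dict([("A", np.zeros(2))]))
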