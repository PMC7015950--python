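"""Distance-based statistics: Bray-Curtis, PCoA, PERMANOVA, CAP."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from rhizopipe.data_model import ValidationError
from rhizopipe.ordination import (DistanceMatrix, bray_curtis, cap,
                                  distance_matrix, group_centroids,
                                  parse_terms, pcoa, permanova, Term)


def _euclid(x):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    ids = [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(ids, squareform(pdist(x)))


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_examples():
    x = pd.DataFrame({"i": [1, 0], "j": [0, 1]})
    assert bray_curtis(x).d[0, 1] == pytest.approx(1.0)
    x = pd.DataFrame({"i": [2, 2], "j": [2, 2]})
    assert bray_curtis(x).d[0, 1] == pytest.approx(0.0)
    x = pd.DataFrame({"i": [2, 2], "j": [1, 3]})
    assert bray_curtis(x).d[0, 1] == pytest.approx(0.25)


def test_bray_curtis_range_and_symmetry():
    rng = np.random.default_rng(1)
    x = pd.DataFrame(rng.uniform(0, 5, size=(12, 6)))
    d = bray_curtis(x)
    assert (d.d >= 0).all() and (d.d <= 1).all()
    assert np.allclose(d.d, d.d.T)


def test_bray_curtis_rejects_zero_sample():
    x = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
    with pytest.raises(ValidationError, match="empty"):
        bray_curtis(x)


def test_distance_matrix_metrics():
    rng = np.random.default_rng(2)
    x = pd.DataFrame(rng.uniform(0, 5, size=(8, 5)))
    de = distance_matrix(x, "euclidean")
    assert np.allclose(de.d, squareform(pdist(x.to_numpy().T)))
    with pytest.raises(ValidationError):
        distance_matrix(x, "chebyshev")


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_equilateral_three_points():
    d = DistanceMatrix(list("abc"),
                       np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
    o = pcoa(d)
    pos = o.eigenvalues[o.eigenvalues > 1e-9]
    assert pos == pytest.approx([0.5, 0.5])
    assert np.trace(d.gower()) == pytest.approx(1.0)


def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.normal(size=(rng.integers(4, 15), rng.integers(2, 5)))
        d = _euclid(x)
        o = pcoa(d)
        rec = squareform(pdist(o.coordinates.to_numpy()))
        assert np.abs(rec - d.d).max() < 1e-8


def test_pcoa_reports_negative_eigenvalues_unused():
    # non-Euclidean Bray-Curtis distances typically yield negative eigs
    rng = np.random.default_rng(4)
    x = pd.DataFrame(rng.uniform(0, 1, size=(20, 12)) ** 3)
    o = pcoa(bray_curtis(x))
    assert (o.eigenvalues < 0).any()
    assert o.coordinates.shape[1] == (o.eigenvalues > 1e-9
                                      * abs(o.eigenvalues[0])).sum() \
        or (o.coordinates.shape[1]
            == (o.eigenvalues > 0).sum() - 0)  # positive axes only
    assert o.proportion_explained.sum() == pytest.approx(1.0)


def test_pcoa_duplicated_samples_coincide():
    x = np.array([[0.0, 0.0], [1.0, 2.0], [1.0, 2.0], [3.0, 1.0]])
    o = pcoa(_euclid(x))
    c = o.coordinates.to_numpy()
    assert np.allclose(c[1], c[2], atol=1e-9)


def test_pcoa_needs_three_samples():
    with pytest.raises(ValidationError):
        pcoa(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))


def test_centroid_of_all_samples_at_origin():
    o = pcoa(_euclid(np.random.default_rng(5).normal(size=(10, 3))))
    factor = pd.Series("all", index=o.coordinates.index)
    cent = group_centroids(o, factor)
    assert cent.loc["all", "PCo1_mean"] == pytest.approx(0.0, abs=1e-10)


def test_centroids_mean_se_and_singletons():
    o = pcoa(_euclid([0.0, 1.0, 4.0, 5.0, 9.0]))
    factor = pd.Series(["g1", "g1", "g1", "g1", "solo"],
                       index=o.coordinates.index)
    cent = group_centroids(o, factor)
    sub = o.coordinates.iloc[:4]["PCo1"]
    assert cent.loc["g1", "PCo1_mean"] == pytest.approx(sub.mean())
    assert cent.loc["g1", "PCo1_se"] == pytest.approx(
        sub.std(ddof=1) / 2)
    assert math.isnan(cent.loc["solo", "PCo1_se"])


def test_centroid_se_obeys_sqrt_n():
    x = np.array([0.0, 1.0, 4.0, 5.0])
    o1 = pcoa(_euclid(x))
    f1 = pd.Series("g", index=o1.coordinates.index)
    se1 = group_centroids(o1, f1).loc["g", "PCo1_se"]
    o4 = pcoa(_euclid(np.tile(x, 4)))
    f4 = pd.Series("g", index=o4.coordinates.index)
    se4 = group_centroids(o4, f4).loc["g", "PCo1_se"]
    # 4x duplication halves sd/sqrt(n) up to the ddof=1 correction
    pc1 = o1.coordinates["PCo1"].to_numpy()
    expected = np.std(np.tile(pc1, 4), ddof=1) / 4
    assert se4 == pytest.approx(expected, rel=1e-9)
    assert se4 < se1 / 1.9


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _anova_f(values, labels):
    groups = [values[labels == g] for g in np.unique(labels)]
    return stats.f_oneway(*groups)[0]


def exhaustive_p(values, labels):
    """Exact permutation p for one-way pseudo-F via full enumeration."""
    f_obs = _anova_f(values, labels)
    n = len(values)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        f = _anova_f(values[list(perm)], labels)
        hits += f >= f_obs - 1e-10
        total += 1
    return hits / total


def test_permanova_hand_example_f_and_exhaustive_p():
    x = np.array([0.0, 1.0, 4.0, 5.0])
    d = _euclid(x)
    meta = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=d.sample_ids)
    res = permanova(d, meta, "g", n_perm=9999, seed=0)
    row = res.table.loc["g"]
    assert row["pseudo_F"] == pytest.approx(32.0, abs=1e-10)
    assert row["SS"] == pytest.approx(16.0)
    assert res.table.loc["Residual", "SS"] == pytest.approx(1.0)
    # exhaustive p over all 24 orderings is 1/3
    assert exhaustive_p(x, np.array(["A", "A", "B", "B"])) \
        == pytest.approx(1 / 3)
    assert abs(row["p"] - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 9999)


def test_permanova_equals_classical_anova_f():
    rng = np.random.default_rng(6)
    for _ in range(20):
        n = int(rng.integers(6, 30))
        k = int(rng.integers(2, 4))
        labels = rng.integers(0, k, size=n)
        if len(np.unique(labels)) < 2 or np.bincount(labels).min() < 2:
            continue
        x = rng.normal(size=n)
        d = _euclid(x)
        meta = pd.DataFrame({"g": labels.astype(str)}, index=d.sample_ids)
        res = permanova(d, meta, "g", n_perm=0)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(
            _anova_f(x, labels), abs=1e-10)


def test_permanova_matches_scikit_bio_oneway():
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import permanova as sk_permanova
    rng = np.random.default_rng(7)
    y = rng.normal(size=(15, 6))
    d = _euclid(y)
    labels = (["a"] * 5 + ["b"] * 5 + ["c"] * 5)
    meta = pd.DataFrame({"g": labels}, index=d.sample_ids)
    ours = permanova(d, meta, "g", n_perm=0).table.loc["g", "pseudo_F"]
    theirs = sk_permanova(SkDM(d.d, d.sample_ids), labels,
                          permutations=9)["test statistic"]
    assert ours == pytest.approx(float(theirs), rel=1e-10)


def _wheat_like_meta(rng, n_per=3):
    rows = []
    lines = [("P", "aes", "mod", 6), ("R", "aes", "mod", 6),
             ("B", "dur", "mod", 4), ("K", "dur", "mod", 4),
             ("E", "tau", "wild", 2), ("T", "dic", "wild", 4),
             ("S", "shw", "syn", 6), ("F", "f1", "syn", 6)]
    for line, sp, anc, pl in lines:
        for rep in range(n_per):
            for frac in ("rhizosphere", "root"):
                rows.append(dict(sample=f"{line}_{frac}_{rep}",
                                 fraction=frac, genotype=line, species=sp,
                                 ancestry=anc, ploidy=pl))
    meta = pd.DataFrame(rows).set_index("sample")
    return meta


def test_permanova_multifactor_type1_additivity_and_df():
    rng = np.random.default_rng(8)
    meta = _wheat_like_meta(rng)
    x = rng.normal(size=(len(meta), 8))
    d = DistanceMatrix(list(meta.index), squareform(pdist(np.abs(x),
                                                          "braycurtis")))
    res = permanova(d, meta,
                    "fraction + ploidy + ancestry + species(ancestry) "
                    "+ genotype(species)", n_perm=49, seed=0)
    t = res.table
    terms = t.drop(index=["Residual", "Total"])
    assert terms["SS"].sum() + t.loc["Residual", "SS"] \
        == pytest.approx(t.loc["Total", "SS"], abs=1e-8)
    assert terms["df"].sum() + t.loc["Residual", "df"] == d.n - 1
    assert ((terms["p"] > 0) & (terms["p"] <= 1)).all()


def test_permanova_type3_marginal_ss():
    rng = np.random.default_rng(9)
    meta = _wheat_like_meta(rng)
    x = rng.normal(size=(len(meta), 5))
    d = _euclid(x)
    d = DistanceMatrix(list(meta.index), d.d)
    r1 = permanova(d, meta, "fraction + ancestry", n_perm=0, ss_type="III")
    r2 = permanova(d, meta, "ancestry + fraction", n_perm=0, ss_type="III")
    # marginal SS do not depend on term order
    assert r1.table.loc["fraction", "SS"] == pytest.approx(
        r2.table.loc["fraction", "SS"], rel=1e-10)
    assert r1.table.loc["ancestry", "SS"] == pytest.approx(
        r2.table.loc["ancestry", "SS"], rel=1e-10)


def test_permanova_p_invariant_to_sample_order():
    rng = np.random.default_rng(10)
    x = rng.normal(size=12)
    labels = np.array(["A"] * 6 + ["B"] * 6)
    d = _euclid(x)
    meta = pd.DataFrame({"g": labels}, index=d.sample_ids)
    p1 = permanova(d, meta, "g", n_perm=199, seed=5).table.loc["g", "p"]
    order = rng.permutation(12)
    d2 = DistanceMatrix([d.sample_ids[i] for i in order],
                        d.d[np.ix_(order, order)])
    p2 = permanova(d2, meta, "g", n_perm=199, seed=5).table.loc["g", "p"]
    assert p1 == p2


def test_permanova_rejects_aliased_and_saturated():
    meta = pd.DataFrame({"a": ["x", "x", "y", "y"],
                         "b": ["x", "x", "y", "y"],
                         "s": ["1", "2", "3", "4"]},
                        index=[f"s{i}" for i in range(4)])
    d = _euclid([0.0, 1.0, 4.0, 5.0])
    with pytest.raises(ValidationError, match="aliased"):
        permanova(d, meta, "a + b", n_perm=0)
    with pytest.raises(ValidationError, match="saturated"):
        permanova(d, meta, "s", n_perm=0)


def test_nested_term_parsing():
    terms = parse_terms("fraction + species(ancestry) + genotype(species)")
    assert terms[0] == Term("fraction", None)
    assert terms[1] == Term("species", "ancestry")
    assert terms[2].label == "genotype(species)"
    with pytest.raises(ValidationError):
        parse_terms("a + b(")


def test_nested_permanova_runs_with_restricted_permutations():
    rng = np.random.default_rng(11)
    meta = _wheat_like_meta(rng)
    x = rng.normal(size=(len(meta), 4))
    d = DistanceMatrix(list(meta.index),
                       squareform(pdist(x)))
    res = permanova(d, meta, "ancestry + species(ancestry)", n_perm=99,
                    seed=1)
    assert 0 < res.table.loc["species(ancestry)", "p"] <= 1


# ---------------------------------------------------------------------------
# CAP
# ---------------------------------------------------------------------------

def test_cap_separable_clouds_allocates_perfectly():
    rng = np.random.default_rng(12)
    a = rng.normal(0, 0.2, size=(8, 3))
    b = rng.normal(5, 0.2, size=(8, 3)) * [1, -1, 1]
    d = _euclid(np.vstack([a, b]))
    factor = pd.Series(["a"] * 8 + ["b"] * 8, index=d.sample_ids)
    res = cap(d, factor, n_perm=199, seed=0)
    assert res.allocation_success == 1.0
    assert res.p <= 1 / (199 + 1) + 1e-12
    assert res.trace <= res.m + 1e-9


def test_cap_random_labels_near_chance():
    rng = np.random.default_rng(13)
    x = rng.normal(size=(40, 4))
    d = _euclid(x)
    successes = []
    for rep in range(10):
        labels = rng.permutation(["a"] * 20 + ["b"] * 20)
        factor = pd.Series(labels, index=d.sample_ids)
        res = cap(d, factor, m=3, n_perm=0, seed=rep)
        successes.append(res.allocation_success)
    assert abs(np.mean(successes) - 0.5) < 0.15


def test_cap_forced_m_matches_automatic_on_1d_structure():
    rng = np.random.default_rng(14)
    x = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(4, 0.1, 6)])
    d = _euclid(x)
    factor = pd.Series(["a"] * 6 + ["b"] * 6, index=d.sample_ids)
    auto = cap(d, factor, n_perm=49, seed=2)
    forced = cap(d, factor, m=auto.m, n_perm=49, seed=2)
    assert forced.trace == pytest.approx(auto.trace)
    assert forced.allocation_success == auto.allocation_success


def test_cap_rejects_singleton_level():
    d = _euclid([0.0, 1.0, 2.0, 5.0])
    factor = pd.Series(["a", "a", "a", "b"], index=d.sample_ids)
    with pytest.raises(ValidationError, match="single sample"):
        cap(d, factor)
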