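"""Distance-based multivariate statistics: Bray-Curtis, PCoA, PERMANOVA, CAP.

PERMANOVA here supports ordered multifactorial models with sequential
(Type I) or marginal (Type III) sums of squares on an arbitrary
distance matrix, nested terms written ``child(parent)``, and p-values
by permutation of residuals under the reduced model (Freedman-Lane
realized on the Gower-centred matrix).  The pseudo-F for every term
uses the residual mean square as denominator by default.

For a single factor on Euclidean distances of univariate data the
pseudo-F coincides exactly with the classical one-way ANOVA F, which is
the primary correctness oracle for the implementation.
"""

from __future__ import annotations

import itertools
import math
import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import SampleFrame, ValidationError

__all__ = [
    "DistanceMatrix", "OrdinationResult", "PermanovaResult", "CapResult",
    "Term", "parse_terms", "bray_curtis", "distance_matrix", "pcoa", "pca",
    "group_centroids", "permanova", "cap",
]

_EIG_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample dissimilarities with zero diagonal."""

    sample_ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValidationError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def gower(self) -> np.ndarray:
        """Gower-centred matrix G = -1/2 J D^2 J with J = I - 11'/n."""
        a = -0.5 * self.d ** 2
        row = a.mean(axis=1, keepdims=True)
        col = a.mean(axis=0, keepdims=True)
        return a - row - col + a.mean()


def bray_curtis(x: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between sample columns.

    d(i,j) = sum_k |x_ki - x_kj| / sum_k (x_ki + x_kj); values in
    [0, 1].  All-zero sample columns make the denominator vanish and
    are rejected by name.
    """
    v = x.to_numpy(dtype=float).T  # samples x OTUs
    if (v < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    zero = v.sum(axis=1) == 0
    if zero.any():
        raise ValidationError(
            f"all-zero sample(s) make Bray-Curtis undefined: "
            f"{list(np.asarray(x.columns)[zero])}")
    d = squareform(pdist(v, metric="braycurtis"))
    return DistanceMatrix(list(x.columns), d)


def distance_matrix(x: pd.DataFrame, metric: str = "braycurtis",
                    ) -> DistanceMatrix:
    """Distance matrix between sample columns with a selectable metric.

    ``braycurtis`` (default), ``euclidean`` or ``jaccard`` (on
    presence/absence).
    """
    if metric == "braycurtis":
        return bray_curtis(x)
    v = x.to_numpy(dtype=float).T
    if metric == "jaccard":
        v = v > 0
    elif metric != "euclidean":
        raise ValidationError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(x.columns),
                          squareform(pdist(v, metric=metric)))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds sample scores on the axes of positive
    eigenvalue (columns PCo1, PCo2, ... ordered by decreasing
    eigenvalue); ``eigenvalues`` all eigenvalues in decreasing order
    (negative ones reported, their axes excluded);
    ``proportion_explained`` is relative to the sum of positive
    eigenvalues.  ``axes`` are the orthonormal eigenvectors of the
    positive axes (used by CAP).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    axes: np.ndarray

    @property
    def negative_eigenvalue_sum(self) -> float:
        return float(self.eigenvalues[self.eigenvalues < 0].sum())


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis via the Gower-centred matrix."""
    if d.n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    g = d.gower()
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > _EIG_TOL * scale
    vals = eigval[pos]
    vecs = eigvec[:, pos]
    # deterministic sign: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(vals)
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.sample_ids, columns=cols),
        eigenvalues=eigval,
        proportion_explained=vals / vals.sum(),
        axes=vecs)


def pca(x: pd.DataFrame) -> OrdinationResult:
    """Covariance-scale PCA of a taxa x sample table.

    Equivalent to PCoA of Euclidean distances between the sample
    columns (Gower's theorem), sharing the same eigen machinery.
    """
    return pcoa(distance_matrix(x, metric="euclidean"))


def group_centroids(ordination: OrdinationResult, factor: pd.Series,
                    n_axes: int | None = 2) -> pd.DataFrame:
    """Mean coordinate and per-axis SE for each factor level.

    ``factor`` must cover every embedded sample.  Singleton levels get
    SE = NaN.  ``n_axes=None`` returns all axes.
    """
    coords = ordination.coordinates
    missing = [s for s in coords.index if s not in factor.index]
    if missing:
        raise ValidationError(f"sample(s) without factor level: {missing}")
    axes = list(coords.columns[:n_axes]) if n_axes else list(coords.columns)
    lab = factor.loc[coords.index]
    rows = []
    for level, idx in coords.groupby(lab).groups.items():
        sub = coords.loc[idx, axes]
        n = len(sub)
        row = {"level": level, "n": n}
        for ax in axes:
            row[f"{ax}_mean"] = sub[ax].mean()
            row[f"{ax}_se"] = (sub[ax].std(ddof=1) / math.sqrt(n)
                               if n > 1 else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One model term: a factor, optionally nested in a parent factor."""

    factor: str
    parent: str | None = None

    @property
    def label(self) -> str:
        return f"{self.factor}({self.parent})" if self.parent else self.factor


_TERM_RE = re.compile(r"^\s*(\w+)\s*(?:\(\s*(\w+)\s*\))?\s*$")


def parse_terms(formula) -> list:
    """Parse "a + b + c(b)" (or a pre-built list) into Term objects."""
    if isinstance(formula, str):
        parts = [p for p in formula.split("+")]
        terms = []
        for p in parts:
            m = _TERM_RE.match(p)
            if not m:
                raise ValidationError(f"cannot parse model term {p!r}")
            terms.append(Term(m.group(1), m.group(2)))
        return terms
    return [t if isinstance(t, Term) else Term(t) for t in formula]


@dataclass
class PermanovaResult:
    """Term-wise df / SS / pseudo-F / permutation p plus residual and total.

    ``table`` has one row per term plus ``Residual`` and ``Total`` rows;
    Type I SS of all terms and the residual add to the total SS.
    """

    table: pd.DataFrame
    ss_type: str
    n_permutations: int

    def term(self, label: str) -> pd.Series:
        return self.table.loc[label]


def _dummies(labels: pd.Series) -> np.ndarray:
    levels = pd.unique(labels)
    return (labels.to_numpy()[:, None] == np.asarray(levels)[None, :]
            ).astype(float)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank.

    SVD-based so that rank-deficient dummy designs (overparameterized
    factors, nested terms) project correctly.
    """
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    u = u[:, :rank]
    return u @ u.T, rank


def _strata_permutation(rng: np.random.Generator,
                        strata: np.ndarray | None, n: int) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    idx = np.arange(n)
    out = np.empty(n, dtype=int)
    for level in pd.unique(strata):
        pos = idx[strata == level]
        out[pos] = rng.permutation(pos)
    return out


def _tr(h: np.ndarray, g: np.ndarray) -> float:
    # trace(H G) for symmetric G
    return float(np.sum(h * g))


def permanova(d: DistanceMatrix, meta, terms, n_perm: int = 9999,
              seed: int = 0, ss_type: str = "I") -> PermanovaResult:
    """Multifactorial (optionally nested) PERMANOVA on a distance matrix.

    Parameters
    ----------
    d:
        Distance matrix over the samples to test.
    meta:
        :class:`SampleFrame` or DataFrame (indexed by sample id) with a
        column per factor named in ``terms``.
    terms:
        Model formula string like
        ``"fraction + ploidy + ancestry + species(ancestry)"`` or a
        list of factor names / :class:`Term` objects, in testing order.
    n_perm:
        Number of residual permutations per term (0 = statistics only,
        p reported as NaN).
    ss_type:
        ``"I"`` (sequential) or ``"III"`` (marginal).

    Notes
    -----
    Sums of squares come from traces of projections of the Gower-centred
    matrix G: with cumulative-design hat matrices ``H_1..j``, the Type I
    SS of term j is tr(H_1..j G) - tr(H_1..j-1 G); Type III uses
    tr(H_full G) - tr(H_-j G).  Significance is assessed by
    Freedman-Lane permutation of residuals under the reduced model:
    R = (I - H_red) G (I - H_red) is row/column permuted (within parent
    strata for nested terms), H_red G H_red added back, and the
    pseudo-F recomputed; p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    table = meta.table if isinstance(meta, SampleFrame) else meta
    missing = [s for s in d.sample_ids if s not in table.index]
    if missing:
        raise ValidationError(f"sample(s) without metadata: {missing}")
    # canonicalize sample order so permutation p-values cannot depend on
    # the order samples arrive in
    order = np.argsort(np.asarray(d.sample_ids, dtype=object), kind="stable")
    ids = [d.sample_ids[i] for i in order]
    d = DistanceMatrix(ids, d.d[np.ix_(order, order)])
    table = table.loc[d.sample_ids]
    terms = parse_terms(terms)
    if ss_type not in ("I", "III"):
        raise ValidationError(f"ss_type must be 'I' or 'III', got {ss_type!r}")
    n = d.n
    g = d.gower()
    total_ss = float(np.trace(g))

    # cumulative designs and their hats
    ones = np.ones((n, 1))
    term_cols = []
    for t in terms:
        if t.factor not in table.columns:
            raise ValidationError(f"factor {t.factor!r} not in metadata")
        labels = table[t.factor].astype(str)
        if t.parent is not None:
            if t.parent not in table.columns:
                raise ValidationError(
                    f"nesting parent {t.parent!r} not in metadata")
            labels = table[t.parent].astype(str) + "/" + labels
        term_cols.append(_dummies(labels))

    hats, ranks = [], []
    x = ones
    h0, r0 = _hat(x)
    prev_rank = r0
    for i, cols in enumerate(term_cols):
        x = np.hstack([x, cols])
        h, r = _hat(x)
        df = r - prev_rank
        if df == 0:
            raise ValidationError(
                f"term {terms[i].label!r} is aliased with preceding terms "
                f"({' + '.join(t.label for t in terms[:i]) or 'intercept'})")
        hats.append(h)
        ranks.append(r)
        prev_rank = r
    h_full, rank_full = hats[-1], ranks[-1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValidationError("saturated model: no residual degrees of freedom")
    ss_res = total_ss - _tr(h_full, g)

    # marginal hats for type III
    h_minus = []
    if ss_type == "III":
        for j in range(len(terms)):
            x = np.hstack([ones] + [term_cols[i]
                                    for i in range(len(terms)) if i != j])
            h, _ = _hat(x)
            h_minus.append(h)

    rows = []
    dfs = []
    prev_hat, prev_tr = h0, _tr(h0, g)
    for j, t in enumerate(terms):
        df_t = ranks[j] - (ranks[j - 1] if j else r0)
        dfs.append(df_t)
        if ss_type == "I":
            h_red, h_top = hats[j - 1] if j else h0, hats[j]
            ss_t = _tr(h_top, g) - _tr(h_red, g)
        else:
            h_red, h_top = h_minus[j], h_full
            ss_t = _tr(h_full, g) - _tr(h_red, g)
        ms_t = ss_t / df_t
        f_obs = ms_t / (ss_res / df_res)

        p = float("nan")
        if n_perm > 0:
            strata = (table[t.parent].astype(str).to_numpy()
                      if t.parent else None)
            rng = np.random.default_rng(
                [int(seed) % (2**31), zlib.crc32(t.label.encode()), j])
            i_minus_h = np.eye(n) - h_red
            r_mat = i_minus_h @ g @ i_minus_h
            g_fix = h_red @ g @ h_red
            tr_top_fix = _tr(h_top, g_fix)
            tr_red_fix = _tr(h_red, g_fix)
            tr_full_fix = _tr(h_full, g_fix)
            tr_fix = float(np.trace(g_fix))
            tol = 1e-8 * max(1.0, abs(f_obs))
            hits = 0
            for _ in range(n_perm):
                perm = _strata_permutation(rng, strata, n)
                rp = r_mat[np.ix_(perm, perm)]
                ss_t_p = (tr_top_fix + _tr(h_top, rp)
                          - tr_red_fix - _tr(h_red, rp))
                ss_res_p = (tr_fix + float(np.trace(rp))
                            - tr_full_fix - _tr(h_full, rp))
                if ss_res_p <= 0:
                    f_star = math.inf
                else:
                    f_star = (ss_t_p / df_t) / (ss_res_p / df_res)
                if f_star >= f_obs - tol:
                    hits += 1
            p = (1.0 + hits) / (1.0 + n_perm)
        rows.append(dict(term=t.label, df=df_t, SS=ss_t, MS=ms_t,
                         pseudo_F=f_obs, p=p, n_perm=n_perm))

    rows.append(dict(term="Residual", df=df_res, SS=ss_res,
                     MS=ss_res / df_res, pseudo_F=float("nan"),
                     p=float("nan"), n_perm=0))
    rows.append(dict(term="Total", df=n - 1, SS=total_ss,
                     MS=float("nan"), pseudo_F=float("nan"),
                     p=float("nan"), n_perm=0))
    table_out = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table_out, ss_type, n_perm)


# ---------------------------------------------------------------------------
# CAP
# ---------------------------------------------------------------------------


@dataclass
class CapResult:
    """Canonical analysis of principal coordinates for one factor.

    ``m`` PCoA axes retained (chosen by leave-one-out allocation success
    of a nearest-centroid classifier when not forced), canonical axis
    scores, squared canonical correlations, the trace statistic
    tr(Q_m' H Q_m) and its label-permutation p-value.
    """

    m: int
    coordinates: pd.DataFrame
    canonical_eigenvalues: np.ndarray
    allocation_success: float
    trace: float
    p: float
    m_search: pd.DataFrame


def _loo_success(scores: np.ndarray, codes: np.ndarray) -> float:
    """Leave-one-out nearest-centroid allocation success rate."""
    n = len(codes)
    levels = np.unique(codes)
    sums = np.stack([scores[codes == lv].sum(axis=0) for lv in levels])
    counts = np.array([(codes == lv).sum() for lv in levels])
    hits = 0
    for i in range(n):
        cent = sums.copy()
        cnt = counts.astype(float).copy()
        k = np.where(levels == codes[i])[0][0]
        cent[k] -= scores[i]
        cnt[k] -= 1
        cent = cent / cnt[:, None]
        d2 = ((cent - scores[i]) ** 2).sum(axis=1)
        if levels[int(np.argmin(d2))] == codes[i]:
            hits += 1
    return hits / n


def cap(d: DistanceMatrix, factor: pd.Series, m: int | None = None,
        n_perm: int = 999, seed: int = 0) -> CapResult:
    """Constrained ordination maximizing separation of factor levels.

    PCoA axes are computed first; if ``m`` is not given, the number of
    retained axes is chosen to maximize leave-one-out allocation success
    of a nearest-centroid classifier (smallest m on ties).  Canonical
    axes come from the eigen-analysis of the group projection of the
    retained orthonormal axes; the trace statistic is tested by
    permutation of group labels.
    """
    lab = factor.loc[d.sample_ids]
    counts = lab.value_counts()
    if len(counts) < 2:
        raise ValidationError("CAP needs >= 2 factor levels")
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValidationError(f"CAP level(s) with a single sample: {bad}")
    ordn = pcoa(d)
    q = ordn.axes  # orthonormal columns
    scores = ordn.coordinates.to_numpy()
    codes = lab.to_numpy()
    rank = q.shape[1]
    m_max = min(d.n - 2, rank)
    if m is not None:
        if not 1 <= m <= m_max:
            raise ValidationError(f"m must lie in [1, {m_max}], got {m}")
        m_grid = [m]
    else:
        m_grid = list(range(1, m_max + 1))
    search = []
    for mm in m_grid:
        search.append((mm, _loo_success(scores[:, :mm], codes)))
    search_df = pd.DataFrame(search, columns=["m", "allocation_success"])
    best = search_df.loc[search_df["allocation_success"].idxmax()]
    # idxmax returns the first (smallest m) maximum
    m_sel = int(best["m"])
    success = float(best["allocation_success"])

    qm = q[:, :m_sel]
    h_grp, _ = _hat(np.hstack([np.ones((d.n, 1)), _dummies(lab)]))
    # remove the intercept direction: use centring of qm (already centred
    # since eigenvectors of the doubly centred G are orthogonal to 1)
    a = qm.T @ h_grp @ qm
    eigval, eigvec = np.linalg.eigh((a + a.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, 1.0), eigvec[:, order]
    n_axes = min(m_sel, len(counts) - 1)
    can = qm @ eigvec[:, :n_axes]
    trace = float(np.trace(a))

    rng = np.random.default_rng([int(seed) % (2**31), zlib.crc32(b"cap")])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(d.n)
        qp = qm[perm]
        trace_star = float(np.trace(qp.T @ h_grp @ qp))
        if trace_star >= trace - 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm) if n_perm > 0 else float("nan")
    cols = [f"CAP{i+1}" for i in range(can.shape[1])]
    return CapResult(
        m=m_sel,
        coordinates=pd.DataFrame(can, index=d.sample_ids, columns=cols),
        canonical_eigenvalues=eigval[:n_axes],
        allocation_success=success, trace=trace, p=p, m_search=search_df)
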