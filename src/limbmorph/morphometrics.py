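"""Geometric morphometrics: superimposition, ordination, and permutation tests.

Landmark configurations (n specimens x k landmarks x 3 coordinates, in mm,
column order x/y/z) are aligned by Generalized Procrustes Analysis; centroid
size is the size metric.  Hypothesis tests on the aligned coordinates use the
residual randomization permutation procedure (RRPP): the statistic of each
model term is referenced to a null distribution built by permuting the
residuals of that term's reduced model.  A phylogenetic variant premultiplies
response and design by the inverse symmetric square root of the (optionally
lambda-scaled) Brownian covariance.  Pillai's-trace MANOVA, pairwise
least-squares-mean tests, two-block partial least squares, and canonical
variate analysis with jackknife cross-validation round out the toolkit.

p-values follow the (1 + count) / (1 + n_perm) convention; effect sizes Z are
z-scores of the observed statistic within the raw permutation distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny, phylo_covariance

__all__ = [
    "LandmarkSample",
    "AlignedSample",
    "PermTestResult",
    "PLSResult",
    "CVAResult",
    "read_landmarks",
    "write_landmarks",
    "reflect_landmarks",
    "centroid_size",
    "gpa",
    "shape_pca",
    "procrustes_lm",
    "pairwise_groups",
    "two_block_pls",
    "cva_jackknife",
    "pillai_manova",
]


# ---------------------------------------------------------------------------
# Landmark containers and I/O
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSample:
    """Corresponding 3-D landmark configurations for a set of specimens."""

    coords: np.ndarray               # (n, k, 3) in mm, columns x/y/z
    specimen_ids: list[str]
    landmark_ids: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n, k, 3)")
        n, k, _ = self.coords.shape
        if len(self.specimen_ids) != n:
            raise ValueError("specimen id count mismatch")
        if len(set(self.specimen_ids)) != n:
            raise ValueError("specimen ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("missing/non-finite coordinates")
        if self.landmark_ids is None:
            self.landmark_ids = [f"lm{j + 1}" for j in range(k)]

    @classmethod
    def from_dict(cls, shapes: dict[str, np.ndarray]) -> "LandmarkSample":
        ids = list(shapes)
        return cls(np.stack([shapes[i] for i in ids]), ids)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def write_landmarks(sample: LandmarkSample, path) -> None:
    """Long-format CSV: specimen, landmark_id, x_mm, y_mm, z_mm."""
    n, k, _ = sample.coords.shape
    df = pd.DataFrame({
        "specimen": np.repeat(sample.specimen_ids, k),
        "landmark_id": np.tile(sample.landmark_ids, n),
        "x_mm": sample.coords[:, :, 0].ravel(),
        "y_mm": sample.coords[:, :, 1].ravel(),
        "z_mm": sample.coords[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False)


def read_landmarks(path) -> LandmarkSample:
    df = pd.read_csv(path)
    specimens = list(dict.fromkeys(df["specimen"]))
    lms = list(dict.fromkeys(df["landmark_id"]))
    k = len(lms)
    coords = np.empty((len(specimens), k, 3))
    for i, s in enumerate(specimens):
        sub = df[df["specimen"] == s].set_index("landmark_id").loc[lms]
        coords[i] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
    return LandmarkSample(coords, [str(s) for s in specimens],
                          [str(l) for l in lms])


def centroid_size(config: np.ndarray) -> float:
    """sqrt of summed squared landmark distances from the centroid."""
    c = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def reflect_landmarks(sample: LandmarkSample, sides: dict[str, str] | pd.Series,
                      mirror_axis: int = 0) -> LandmarkSample:
    """Mirror right-side configurations across a fixed plane.

    ``sides`` maps specimen id to ``"left"`` or ``"right"``; right-side
    configurations have coordinate ``mirror_axis`` negated (a fixed-plane
    reflection), left-side ones are untouched.  Mirroring preserves centroid
    size and all inter-landmark distances.
    """
    sides = pd.Series(sides)
    coords = sample.coords.copy()
    for i, sid in enumerate(sample.specimen_ids):
        side = sides.get(sid)
        if side == "right":
            coords[i, :, mirror_axis] *= -1.0
        elif side != "left":
            raise ValueError(f"unknown side label for {sid!r}: {side!r}")
    return LandmarkSample(coords, list(sample.specimen_ids),
                          list(sample.landmark_ids))


# ---------------------------------------------------------------------------
# Generalized Procrustes Analysis
# ---------------------------------------------------------------------------

@dataclass
class AlignedSample:
    """GPA-aligned configurations with centroid sizes and consensus."""

    coords: np.ndarray            # (n, k, 3), centered, unit centroid size
    centroid_sizes: np.ndarray    # (n,) in mm, measured before scaling
    consensus: np.ndarray         # (k, 3): mean of aligned configurations
    specimen_ids: list[str]
    landmark_ids: list[str]
    n_iterations: int = 0

    def flat(self) -> np.ndarray:
        """(n, 3k) matrix of aligned coordinates."""
        return self.coords.reshape(self.coords.shape[0], -1)


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||A R - B||_F."""
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def gpa(sample: LandmarkSample, tol: float = 1e-10,
        max_iter: int = 100) -> AlignedSample:
    """Generalized Procrustes Analysis.

    Each configuration is centered, scaled to unit centroid size, and
    iteratively rotated (proper rotations only — sides are mirrored upstream
    by :func:`reflect_landmarks`) to the running consensus until the
    consensus moves by less than ``tol``.  Specimens with coincident
    landmarks (zero centroid size) are rejected.
    """
    if sample.n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    if sample.k < 3:
        raise ValueError("GPA needs at least 3 landmarks")
    X = sample.coords.copy()
    cs = np.empty(sample.n)
    for i in range(sample.n):
        X[i] -= X[i].mean(axis=0)
        cs[i] = np.sqrt(np.sum(X[i] ** 2))
        if cs[i] < 1e-12:
            raise ValueError(
                f"specimen {sample.specimen_ids[i]!r} has coincident landmarks "
                "(zero centroid size)")
        X[i] /= cs[i]
    consensus = X[0].copy()
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(sample.n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        shift = np.sqrt(np.sum((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if shift < tol:
            break
    return AlignedSample(X, cs, consensus, list(sample.specimen_ids),
                         list(sample.landmark_ids), n_iterations=it)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared difference between two aligned configurations."""
    return float(np.sqrt(np.sum((a - b) ** 2)))


# ---------------------------------------------------------------------------
# Shape PCA / phylomorphospace
# ---------------------------------------------------------------------------

@dataclass
class ShapePCA:
    scores: np.ndarray           # (n, m)
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    components: np.ndarray       # (m, p) rows are axes
    mean: np.ndarray             # (p,)
    specimen_ids: list[str]
    node_scores: np.ndarray | None = None  # ancestral projections (phylomorphospace)


def shape_pca(aligned: AlignedSample | np.ndarray,
              tree: Phylogeny | None = None,
              specimen_ids: list[str] | None = None) -> ShapePCA:
    """PCA of aligned coordinates; optionally a phylomorphospace.

    With a tree, internal-node shapes are maximum-likelihood Brownian
    ancestral reconstructions (GLS best linear unbiased predictions given the
    tips) projected onto the tip-defined axes.
    """
    if isinstance(aligned, AlignedSample):
        Y = aligned.flat()
        ids = aligned.specimen_ids
    else:
        Y = np.asarray(aligned, dtype=float)
        ids = specimen_ids or [f"s{i}" for i in range(Y.shape[0])]
    n = Y.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eigval = s**2 / (n - 1)
    keep = s > s[0] * 1e-12 if s[0] > 0 else np.zeros_like(s, dtype=bool)
    U, s, Vt, eigval = U[:, keep], s[keep], Vt[keep], eigval[keep]
    scores = U * s
    pct = 100.0 * eigval / eigval.sum()

    node_scores = None
    if tree is not None:
        anc = brownian_ancestors(tree, Y, ids)
        node_scores = (anc - mean) @ Vt.T
    return ShapePCA(scores, eigval, pct, Vt, mean, list(ids), node_scores)


def brownian_ancestors(tree: Phylogeny, Y: np.ndarray,
                       ids: list[str]) -> np.ndarray:
    """ML (GLS/BLUP) Brownian reconstructions at internal nodes, (m, p)."""
    order = tree.reorder(ids)
    inv_order = np.argsort(order)
    Yt = Y[inv_order] if len(ids) == tree.n_tips else None
    if Yt is None:
        raise ValueError("ids must match the tree tips")
    C = tree.brownian_covariance()
    n = C.shape[0]
    Cinv_Y = np.linalg.solve(C, Yt)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    mu = (np.ones(n) @ Cinv_Y) / (np.ones(n) @ Cinv_1)  # (p,)
    resid = Yt - mu
    Cinv_resid = np.linalg.solve(C, resid)

    dtree = tree.tree
    dtree.calc_node_root_distances(return_leaf_distances_only=False)
    tip_pos = {l: i for i, l in enumerate(tree.tip_labels)}
    rows = []
    for node in dtree.preorder_internal_node_iter():
        depth = node.root_distance or 0.0
        below = [tip_pos[lf.taxon.label] for lf in node.leaf_iter()]
        cross = np.empty(n)
        s0 = below[0]
        cross[:] = np.minimum(C[s0], depth)  # MRCA depth with outside tips
        cross[below] = depth
        rows.append(mu + cross @ Cinv_resid)
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Linear models with RRPP
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    """Observed statistic with its RRPP permutation summary."""

    statistic_name: str
    observed: float
    z: float
    p: float
    n_perm: int
    seed: int | None = None
    perm_mean: float = np.nan
    perm_sd: float = np.nan


def _parse_formula(formula: str) -> list[str]:
    """Expand a '~ a * b'-style RHS into ordered terms (a, b, a:b)."""
    rhs = formula.split("~")[-1].strip()
    if rhs in ("1", ""):
        return []
    terms: list[str] = []
    for part in (p.strip() for p in rhs.split("+")):
        if "*" in part:
            facs = [f.strip() for f in part.split("*")]
            for f in facs:
                if f not in terms:
                    terms.append(f)
            inter = ":".join(facs)
            if inter not in terms:
                terms.append(inter)
        elif part and part not in terms:
            terms.append(part)
    return terms


def _term_block(data: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one term (treatment coding, no intercept column)."""
    def var_block(v: str) -> np.ndarray:
        col = data[v]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            return np.column_stack(
                [(col.astype(str) == lev).to_numpy(float) for lev in levels[1:]])
        return col.to_numpy(float).reshape(-1, 1)

    parts = [var_block(v) for v in term.split(":")]
    block = parts[0]
    for nxt in parts[1:]:
        block = np.concatenate(
            [block[:, i:i + 1] * nxt for i in range(block.shape[1])], axis=1)
    return block


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal-projection (hat) matrix onto col(X) and its rank."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    keep = diag > max(diag.max(), 1.0) * 1e-10 * X.shape[0] if diag.size else []
    Q = Q[:, keep]
    return Q @ Q.T, Q.shape[1]


def _phylo_transform(tree: Phylogeny, lam: float) -> np.ndarray:
    """Inverse symmetric square root of C(lambda) via eigendecomposition."""
    C = phylo_covariance(tree, lam)
    w, U = np.linalg.eigh(C)
    w = np.clip(w, 1e-12 * w.max(), None)
    return (U / np.sqrt(w)[None, :]) @ U.T


def _perm_indices(n: int, n_perm: int, rng, all_perms: bool) -> np.ndarray:
    if all_perms:
        perms = np.array(list(itertools.permutations(range(n))))
        return perms
    return np.array([rng.permutation(n) for _ in range(n_perm)])


@dataclass
class ProcrustesLMResult:
    """Fit of a multivariate linear model with RRPP term tests."""

    table: pd.DataFrame  # term, df, ss, r2, f, z, p
    n_perm: int
    seed: int | None
    formula: str
    terms: list[str] = field(repr=False, default_factory=list)
    _Y: np.ndarray = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)
    _hats: list[np.ndarray] = field(repr=False, default_factory=list)
    _ranks: list[int] = field(repr=False, default_factory=list)
    _transform: np.ndarray | None = field(repr=False, default=None)

    def term(self, name: str) -> PermTestResult:
        row = self.table.set_index("term").loc[name]
        return PermTestResult("F", float(row["f"]), float(row["z"]),
                              float(row["p"]), self.n_perm, self.seed)


def procrustes_lm(
    Y: np.ndarray,
    data: pd.DataFrame,
    formula: str,
    n_perm: int = 999,
    seed=0,
    phylo: str = "none",
    tree: Phylogeny | None = None,
    lam: float = 1.0,
    all_perms: bool = False,
) -> ProcrustesLMResult:
    """Multivariate (Procrustes) ANOVA/ANCOVA with RRPP term tests.

    Sums of squares are sequential (terms in formula order), measured as
    traces of residual cross-product differences between nested fits.  For
    each term, the residuals of its reduced model are permuted ``n_perm``
    times, added back to the reduced fitted values, and the term's F is
    recomputed; ``p = (1 + #{F* >= F_obs}) / (n_perm + 1)`` and Z is the
    z-score of F_obs in the permutation distribution.

    ``phylo="bm"`` premultiplies response and design by C(1)^(-1/2) of the
    supplied tree (Brownian motion); ``phylo="lambda"`` uses C(lam)^(-1/2).
    ``all_perms=True`` enumerates every residual permutation (small n only).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if len(data) != n:
        raise ValueError("predictors do not align with rows of Y")
    terms = _parse_formula(formula)
    if not terms:
        raise ValueError("formula has no terms to test")

    P = None
    if phylo != "none":
        if phylo not in ("bm", "lambda"):
            raise ValueError("phylo must be 'none', 'bm', or 'lambda'")
        if tree is None:
            raise ValueError("phylo transform requested but no tree given")
        order = tree.reorder(list(data.index.astype(str)))
        # reorder C into data row order, then invert its symmetric sqrt
        C = phylo_covariance(tree, 1.0 if phylo == "bm" else lam)
        C = C[np.ix_(order, order)]
        w, U = np.linalg.eigh(C)
        w = np.clip(w, 1e-12 * w.max(), None)
        P = (U / np.sqrt(w)[None, :]) @ U.T

    ones = np.ones((n, 1))
    blocks = [_term_block(data, t) for t in terms]
    designs = [ones]
    for b in blocks:
        designs.append(np.concatenate([designs[-1], b], axis=1))
    if P is not None:
        Yt = P @ Y
        designs = [P @ X for X in designs]
    else:
        Yt = Y

    hats, ranks = zip(*[_hat(X) for X in designs])
    hats, ranks = list(hats), list(ranks)
    if ranks[-1] >= n:
        raise ValueError("rank-deficient/saturated design: no residual df")
    for j, t in enumerate(terms):
        if ranks[j + 1] == ranks[j]:
            raise ValueError(f"term {t!r} adds no estimable columns "
                             "(rank-deficient design)")

    I = np.eye(n)
    ss_res = [float(np.sum(((I - H) @ Yt) ** 2)) for H in hats]
    df_res = n - ranks[-1]
    ss_tot = float(np.sum(((I - hats[0]) @ Yt) ** 2))
    mse_full = ss_res[-1] / df_res

    rng = np.random.default_rng(seed)
    rows = []
    for j, t in enumerate(terms):
        Hr, Hf = hats[j], hats[j + 1]
        df_t = ranks[j + 1] - ranks[j]
        ss_t = ss_res[j] - ss_res[j + 1]
        f_obs = (ss_t / df_t) / mse_full

        E = (I - Hr) @ Yt
        perms = _perm_indices(n, n_perm, rng, all_perms)
        B = perms.shape[0]
        f_perm = np.empty(B)
        Hk = hats[-1]
        chunk = max(1, int(5e7 // max(1, n * Yt.shape[1])))
        for c0 in range(0, B, chunk):
            pc = perms[c0:c0 + chunk]
            Ep = E[pc]                       # (b, n, p)
            Rr = Ep - np.einsum("ij,bjp->bip", Hr, Ep)
            Rf = Ep - np.einsum("ij,bjp->bip", Hf, Ep)
            Rk = Ep - np.einsum("ij,bjp->bip", Hk, Ep)
            ss_red = np.sum(Rr**2, axis=(1, 2))
            ss_full = np.sum(Rf**2, axis=(1, 2))
            ss_k = np.sum(Rk**2, axis=(1, 2))
            f_perm[c0:c0 + len(pc)] = (
                ((ss_red - ss_full) / df_t) / (ss_k / df_res))
        p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (B + 1.0)
        sd = f_perm.std()
        z = (f_obs - f_perm.mean()) / sd if sd > 0 else np.nan
        rows.append({"term": t, "df": df_t, "ss": ss_t,
                     "r2": ss_t / ss_tot if ss_tot > 0 else np.nan,
                     "f": f_obs, "z": z, "p": p})
    table = pd.DataFrame(rows)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None
    return ProcrustesLMResult(table, n_perm if not all_perms else B, seed_repr,
                              formula, terms, Yt, data, hats, ranks, P)


def pairwise_groups(
    fit: ProcrustesLMResult,
    group_col: str,
    n_perm: int = 999,
    seed=0,
    all_perms: bool = False,
) -> pd.DataFrame:
    """Pairwise distances between group least-squares means, RRPP p-values.

    The statistic is the Euclidean distance between group LS-means in
    response space (covariates held at their means).  The null permutes the
    residuals of the reduced model that drops every term involving the group
    factor.
    """
    if group_col not in fit._data.columns:
        raise ValueError(f"no {group_col!r} column in the model data")
    data = fit._data
    Y = fit._Y
    n = Y.shape[0]
    levels = sorted(pd.unique(data[group_col].astype(str)))
    sizes = data[group_col].astype(str).value_counts()
    for lev in levels:
        if sizes.get(lev, 0) < 2:
            warnings.warn(f"group {lev!r} has a single member: distances "
                          "reported without a permutation test")

    keep_terms = [t for t in fit.terms if group_col not in t.split(":")]
    ones = np.ones((n, 1))
    Xr_cols = [ones] + [_term_block(data, t) for t in keep_terms]
    X_red = np.concatenate(Xr_cols, axis=1)
    X_full_cols = [ones] + [_term_block(data, t) for t in fit.terms]
    X_full = np.concatenate(X_full_cols, axis=1)
    if fit._transform is not None:
        X_red = fit._transform @ X_red
        X_full = fit._transform @ X_full

    pinv_full = np.linalg.pinv(X_full)
    H_red, _ = _hat(X_red)

    # prediction rows: one per group level, covariates at their means
    # LS-means are linear in beta: prediction rows stay untransformed even
    # when the fit used a phylogenetic (GLS) transform
    pred = _lsmean_rows(data, fit.terms, group_col, levels)

    def lsmean_dists(Ym: np.ndarray) -> np.ndarray:
        beta = pinv_full @ Ym
        means = pred @ beta
        g = len(levels)
        d = np.empty((g, g))
        for i in range(g):
            for j in range(g):
                d[i, j] = np.linalg.norm(means[i] - means[j])
        return d

    d_obs = lsmean_dists(Y)
    E = Y - H_red @ Y
    F = H_red @ Y
    rng = np.random.default_rng(seed)
    perms = _perm_indices(n, n_perm, rng, all_perms)
    B = perms.shape[0]
    count = np.zeros_like(d_obs)
    for b in range(B):
        d_b = lsmean_dists(F + E[perms[b]])
        count += d_b >= d_obs - 1e-12
    pmat = (1.0 + count) / (B + 1.0)
    rows = []
    for i, a in enumerate(levels):
        for j in range(i + 1, len(levels)):
            rows.append({"group_a": a, "group_b": levels[j],
                         "distance": d_obs[i, j], "p": pmat[i, j]})
    return pd.DataFrame(rows)


def _lsmean_rows(data: pd.DataFrame, terms: list[str], group_col: str,
                 levels: list[str]) -> np.ndarray:
    """Design rows predicting each group's LS-mean (covariates at means)."""
    rows = []
    for lev in levels:
        d = {}
        for col in data.columns:
            if col == group_col:
                d[col] = lev
            elif data[col].dtype.kind in "OUSb":
                d[col] = data[col].mode().iloc[0]
            else:
                d[col] = data[col].mean()
        rows.append(d)
    pdata = pd.DataFrame(rows)
    # rebuild the same design (intercept + term blocks) on the pseudo-data,
    # using the original data's factor levels for consistent dummy coding
    combo = pd.concat([data, pdata], ignore_index=True)
    ones = np.ones((len(combo), 1))
    X = np.concatenate([ones] + [_term_block(combo, t) for t in terms], axis=1)
    return X[len(data):]


# ---------------------------------------------------------------------------
# Pillai's-trace MANOVA
# ---------------------------------------------------------------------------

def pillai_manova(
    Y: np.ndarray,
    data: pd.DataFrame,
    formula: str,
    n_perm: int = 999,
    seed=0,
    phylo: str = "none",
    tree: Phylogeny | None = None,
    lam: float = 1.0,
    all_perms: bool = False,
) -> pd.DataFrame:
    """MANOVA using Pillai's trace with RRPP permutation p-values.

    Per term (sequential): hypothesis cross-product H = Y'(H_full - H_red)Y,
    error E = Y'(I - H_model)Y, Pillai = tr(H (H + E)^{-1}).  Requires more
    residual degrees of freedom than response columns; reduce Y by PCA first
    when p >= n - rank(design).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    terms = _parse_formula(formula)
    base = procrustes_lm(Y, data, formula, n_perm=1, seed=0, phylo=phylo,
                         tree=tree, lam=lam)
    hats, ranks = base._hats, base._ranks
    Yt = base._Y
    if p >= n - ranks[-1]:
        raise ValueError(
            f"p = {p} response columns but only {n - ranks[-1]} residual df; "
            "project onto leading principal components first")
    I = np.eye(n)
    E_full = Yt.T @ (I - hats[-1]) @ Yt
    if np.linalg.matrix_rank(E_full) < p:
        raise ValueError("singular error matrix; reduce response dimension")

    rng = np.random.default_rng(seed)
    rows = []
    for j, t in enumerate(terms):
        Hr, Hf = hats[j], hats[j + 1]

        def pillai(Ym: np.ndarray) -> float:
            Hcp = Ym.T @ (Hf - Hr) @ Ym
            Ecp = Ym.T @ (I - hats[-1]) @ Ym
            return float(np.trace(np.linalg.solve((Hcp + Ecp).T, Hcp.T).T))

        stat_obs = pillai(Yt)
        E = (I - Hr) @ Yt
        Fr = Hr @ Yt
        perms = _perm_indices(n, n_perm, rng, all_perms)
        stat_perm = np.array([pillai(Fr + E[pi]) for pi in perms])
        B = len(stat_perm)
        pval = (1.0 + np.sum(stat_perm >= stat_obs - 1e-12)) / (B + 1.0)
        sd = stat_perm.std()
        z = (stat_obs - stat_perm.mean()) / sd if sd > 0 else np.nan
        rows.append({"term": t, "pillai": stat_obs, "z": z, "p": pval,
                     "n_perm": B})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-block partial least squares
# ---------------------------------------------------------------------------

@dataclass
class PLSResult:
    """First-axis covariation between two trait blocks."""

    r_pls: float
    z: float
    p: float
    x_axis: np.ndarray
    y_axis: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    n_perm: int
    seed: int | None = None


def two_block_pls(X: np.ndarray, Y: np.ndarray, n_perm: int = 999,
                  seed=0) -> PLSResult:
    """Two-block PLS: SVD of the cross-covariance between centered blocks.

    ``r_pls`` is the correlation of the first pair of singular-axis scores;
    the null permutes specimen order of the second block.  Z is the z-score
    of the observed r among the permuted values.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must share specimens")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if np.allclose(Xc, 0) or np.allclose(Yc, 0):
        raise ValueError("zero-variance block")

    def first_r(Ym: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        S = Xc.T @ Ym / (n - 1)
        U, _, Vt = np.linalg.svd(S, full_matrices=False)
        u, v = U[:, 0], Vt[0]
        xs, ys = Xc @ u, Ym @ v
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            return 0.0, u, v
        r = float(np.corrcoef(xs, ys)[0, 1])
        return abs(r), u, v

    r_obs, u, v = first_r(Yc)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for b in range(n_perm):
        r_perm[b], _, _ = first_r(Yc[rng.permutation(n)])
    p = (1.0 + np.sum(r_perm >= r_obs - 1e-12)) / (n_perm + 1.0)
    sd = r_perm.std()
    z = (r_obs - r_perm.mean()) / sd if sd > 0 else np.nan
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None
    return PLSResult(r_obs, z, p, u, v, Xc @ u, Yc @ v, n_perm, seed_repr)


# ---------------------------------------------------------------------------
# Canonical variate analysis with jackknife cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVAResult:
    """Canonical axes plus leave-one-out reclassification accuracies (%)."""

    axes: np.ndarray                 # (dims, n_axes) in the reduced space
    group_accuracy: pd.Series        # percent per group
    overall_accuracy: float          # specimen-weighted mean, percent
    assignments: pd.Series           # jackknife classification per specimen
    retained_dims: int


def cva_jackknife(
    data: np.ndarray,
    groups,
    retained_dims: int | None = None,
    var_threshold: float = 0.95,
) -> CVAResult:
    """CVA with jackknife (leave-one-out) reclassification.

    The data are first projected onto leading principal components capturing
    ``var_threshold`` of the variance (or exactly ``retained_dims``), capped
    below n - g so the pooled within-group covariance stays invertible.
    Canonical axes solve the generalized eigenproblem of between- vs pooled
    within-group covariance.  Each held-out specimen is classified to the
    group with the smallest Mahalanobis distance (pooled covariance
    recomputed without it); exact ties break toward the smallest group index.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    groups = pd.Series(np.asarray(groups).astype(str))
    n = X.shape[0]
    levels = sorted(groups.unique())
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if (groups.value_counts() < 2).any():
        raise ValueError("every group needs at least 2 members")

    # PCA reduction
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2
    nonzero = eig > (eig[0] if eig.size else 1) * 1e-12
    eig, Vt, s, U = eig[nonzero], Vt[nonzero], s[nonzero], U[:, nonzero]
    max_dims = n - g - 1
    if max_dims < 1:
        raise ValueError("too few specimens for the number of groups")
    if retained_dims is None:
        frac = np.cumsum(eig) / eig.sum()
        retained = int(np.searchsorted(frac, var_threshold) + 1)
    else:
        retained = retained_dims
    if retained > max_dims:
        warnings.warn(f"retained dims {retained} >= n - g: reduced to {max_dims}")
        retained = max_dims
    retained = min(retained, Vt.shape[0])
    Z = Xc @ Vt[:retained].T            # (n, dims)

    lab = groups.to_numpy()
    lab_idx = np.array([levels.index(l) for l in lab])

    def pooled_within(Zm, li, skip=None):
        W = np.zeros((Zm.shape[1], Zm.shape[1]))
        means = np.zeros((g, Zm.shape[1]))
        counts = np.zeros(g)
        for gi in range(g):
            sel = li == gi
            if skip is not None:
                sel = sel & (np.arange(len(li)) != skip)
            Zg = Zm[sel]
            means[gi] = Zg.mean(axis=0)
            counts[gi] = len(Zg)
            W += (Zg - means[gi]).T @ (Zg - means[gi])
        W /= (counts.sum() - g)
        return W, means, counts

    W, means, counts = pooled_within(Z, lab_idx)
    grand = Z.mean(axis=0)
    B = np.zeros_like(W)
    for gi in range(g):
        d = (means[gi] - grand)[:, None]
        B += counts[gi] * (d @ d.T)
    B /= (g - 1)
    from scipy.linalg import eigh as geigh

    evals, evecs = geigh(B, W)
    order = np.argsort(evals)[::-1][: g - 1]
    axes = evecs[:, order]

    # leave-one-out classification (Mahalanobis, pooled covariance)
    assigned = np.empty(n, dtype=int)
    for i in range(n):
        Wi, mi, ci = pooled_within(Z, lab_idx, skip=i)
        Winv = np.linalg.pinv(Wi)
        d2 = np.array([
            (Z[i] - mi[gi]) @ Winv @ (Z[i] - mi[gi]) for gi in range(g)])
        assigned[i] = int(np.argmin(d2))  # first min: smallest index wins ties
    correct = assigned == lab_idx
    per_group = pd.Series(
        {levels[gi]: 100.0 * correct[lab_idx == gi].mean() for gi in range(g)})
    overall = 100.0 * correct.mean()
    return CVAResult(axes, per_group, float(overall),
                     pd.Series([levels[a] for a in assigned]), retained)
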