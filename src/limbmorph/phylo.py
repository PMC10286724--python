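"""Phylogenetic comparative models for univariate bone traits.

Implements generalized least squares regression whose residual covariance is a
Pagel's-lambda-scaled Brownian-motion phylogenetic covariance matrix (PGLS),
with lambda estimated jointly with the regression coefficients by maximum
likelihood.  On top of the single fit sit the model-competition table (five
designs over ln size and ecotype, ranked by AICc weights), a parametric
bootstrap of the coefficients, percentile confidence intervals for pairwise
ecotype contrasts of means and scaling slopes, an isometry/allometry verdict
from the slope CI sign pattern, a phylogenetic ANOVA, and a phylogenetic
paired t-test for humerus-vs-femur trait contrasts.

Trees are handled through :class:`Phylogeny`, a thin wrapper over a dendropy
tree that caches the Brownian covariance matrix.  For ultrametric trees the
lambda transform shares the eigenvectors of the Brownian matrix, so profiling
the likelihood over lambda costs one eigendecomposition total instead of one
Cholesky factorization per candidate lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Phylogeny",
    "PglsFit",
    "ModelComparison",
    "BootstrapEnsemble",
    "AllometryCall",
    "phylo_covariance",
    "pgls_fit",
    "fit_model_set",
    "bootstrap_coefficients",
    "pairwise_ci",
    "classify_allometry",
    "phylo_anova",
    "phylo_paired_ttest",
    "design_matrix",
]

_ULTRAMETRIC_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Phylogeny wrapper
# ---------------------------------------------------------------------------

class Phylogeny:
    """Rooted tree with branch lengths and cached Brownian covariance.

    Parameters
    ----------
    tree
        A rooted :class:`dendropy.Tree` with branch lengths.  Tip labels must
        be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        self.tip_labels: list[str] = labels
        self._cov1: np.ndarray | None = None
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    # -- construction / serialization -----------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Read a Newick tree from a path or a literal Newick string."""
        if source.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    # -- covariance ------------------------------------------------------
    def brownian_covariance(self) -> np.ndarray:
        """C(1): C_ij = branch length shared from root to MRCA(i, j)."""
        if self._cov1 is None:
            self._cov1 = _brownian_covariance(self._tree, self.tip_labels)
        return self._cov1

    def covariance(self, lam: float = 1.0) -> np.ndarray:
        return phylo_covariance(self, lam)

    def tip_depths(self) -> np.ndarray:
        return np.diag(self.brownian_covariance()).copy()

    def is_ultrametric(self, rtol: float = _ULTRAMETRIC_RTOL) -> bool:
        d = self.tip_depths()
        return bool(np.max(d) - np.min(d) <= rtol * max(np.max(d), 1e-300))

    def patristic_distances(self) -> np.ndarray:
        C = self.brownian_covariance()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    def _eigen(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            w, U = np.linalg.eigh(self.brownian_covariance())
            self._eig = (w, U)
        return self._eig

    def reorder(self, labels) -> np.ndarray:
        """Index array mapping this tree's tip order onto ``labels``."""
        pos = {l: i for i, l in enumerate(self.tip_labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise ValueError(f"labels absent from tree: {missing[:5]}")
        return np.array([pos[l] for l in labels])


def _brownian_covariance(tree: dendropy.Tree, tip_labels: list[str]) -> np.ndarray:
    n = len(tip_labels)
    idx = {l: i for i, l in enumerate(tip_labels)}
    C = np.zeros((n, n))
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._lm_tips = [idx[node.taxon.label]]
            C[node._lm_tips[0], node._lm_tips[0]] = node.root_distance
        else:
            depth = node.root_distance or 0.0
            child_sets = [ch._lm_tips for ch in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.array(child_sets[a])
                    ib = np.array(child_sets[b])
                    C[np.ix_(ia, ib)] = depth
                    C[np.ix_(ib, ia)] = depth
            node._lm_tips = [t for s in child_sets for t in s]
    for node in tree.postorder_node_iter():
        del node._lm_tips
    return C


def phylo_covariance(tree: Phylogeny | np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform of the Brownian covariance.

    Off-diagonal entries of C(1) are multiplied by ``lam``; the diagonal is
    untouched, so ``C(lam) = lam*C(1) + (1-lam)*diag(C(1))``.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C1 = tree.brownian_covariance() if isinstance(tree, Phylogeny) else np.asarray(tree)
    out = lam * C1
    np.fill_diagonal(out, np.diag(C1))
    return out


# ---------------------------------------------------------------------------
# GLS workspace: fast profile likelihood over lambda
# ---------------------------------------------------------------------------

class _GLSWorkspace:
    """Pre-factorized quantities for repeated GLS solves on one tree.

    For an ultrametric tree, diag(C) = T*I, hence
    C(lam) = U diag(lam*w + (1-lam)*T) U^T for the eigenpairs (w, U) of C(1):
    every lambda evaluation reduces to weighted least squares in the rotated
    frame.  Non-ultrametric trees fall back to a Cholesky per lambda.
    """

    def __init__(self, tree: Phylogeny, order: np.ndarray | None = None):
        self.tree = tree
        C1 = tree.brownian_covariance()
        if order is not None:
            C1 = C1[np.ix_(order, order)]
        self.C1 = C1
        self.n = C1.shape[0]
        self.diag = np.diag(C1).copy()
        self.ultrametric = bool(
            np.max(self.diag) - np.min(self.diag)
            <= _ULTRAMETRIC_RTOL * max(np.max(self.diag), 1e-300)
        )
        if self.ultrametric:
            self.T = float(np.mean(self.diag))
            w, U = np.linalg.eigh(C1)
            self.evals = np.clip(w, 0.0, None)
            self.U = U
        else:
            self.T = float(np.mean(self.diag))

    def rotate(self, A: np.ndarray) -> np.ndarray:
        return self.U.T @ A

    def weights(self, lam: float) -> np.ndarray:
        """Eigenvalues of C(lam) (ultrametric path only)."""
        return lam * self.evals + (1.0 - lam) * self.T

    def solve_quadratics(self, lam, Xr, yr):
        """Return (beta, rss, logdet) for C(lam); inputs already rotated."""
        if self.ultrametric:
            w = self.weights(lam)
            if np.min(w) <= 0:
                w = np.clip(w, 1e-12 * np.max(w), None)
            sw = np.sqrt(w)
            Xw = Xr / sw[:, None]
            yw = yr / sw
            beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            if rank < Xr.shape[1]:
                raise np.linalg.LinAlgError("rank-deficient design")
            resid = yw - Xw @ beta
            return beta, float(resid @ resid), float(np.sum(np.log(w)))
        # generic path
        C = phylo_covariance(self.C1, lam)
        L = np.linalg.cholesky(C)
        Xw = _tri_solve(L, Xr)
        yw = _tri_solve(L, yr)
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < Xr.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design")
        resid = yw - Xw @ beta
        return beta, float(resid @ resid), float(2.0 * np.sum(np.log(np.diag(L))))

    def prepare(self, X: np.ndarray, y: np.ndarray):
        if self.ultrametric:
            return self.rotate(X), self.rotate(y)
        return X, y


def _tri_solve(L, B):
    from scipy.linalg import solve_triangular

    return solve_triangular(L, B, lower=True)


def _loglik(n: int, rss: float, logdet: float) -> float:
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    """A fitted phylogenetic generalized least squares model."""

    coef: pd.Series
    sigma2: float
    lam: float
    loglik: float
    aicc: float
    r2: float
    n: int
    k_params: int
    fitted: np.ndarray
    residuals: np.ndarray
    lambda_fixed: bool
    lambda_flat: bool = False  # likelihood flat in lambda (e.g. star tree)
    design: pd.DataFrame | None = field(default=None, repr=False)
    response: np.ndarray | None = field(default=None, repr=False)
    tree: Phylogeny | None = field(default=None, repr=False)

    @property
    def coef_names(self) -> list[str]:
        return list(self.coef.index)


def _profile_lambda(ws: _GLSWorkspace, Xr, yr, grid_points: int = 11):
    """Maximize the profile likelihood over lambda in [0, 1].

    An 11-point grid scan seeds a bounded 1-D search around the best grid
    point; profiles can be flat or bimodal.  Exact ties break toward the
    smaller lambda.
    """
    grid = np.linspace(0.0, 1.0, grid_points)
    lls = []
    for lam in grid:
        _, rss, logdet = ws.solve_quadratics(lam, Xr, yr)
        lls.append(_loglik(ws.n, rss, logdet))
    lls = np.array(lls)
    best = int(np.argmax(lls))  # argmax returns first index: ties -> smaller lam
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]

    def neg(lam):
        _, rss, logdet = ws.solve_quadratics(lam, Xr, yr)
        return -_loglik(ws.n, rss, logdet)

    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    if lls[best] >= ll_hat:  # grid point at least as good (flat profile edge)
        lam_hat, ll_hat = float(grid[best]), float(lls[best])
    flat = bool(np.max(lls) - np.min(lls) < 1e-8 * max(abs(np.max(lls)), 1.0))
    return lam_hat, ll_hat, flat


def _batch_loglik(ws: _GLSWorkspace, lam: float, Xr: np.ndarray,
                  Yr: np.ndarray):
    """Log-likelihoods and coefficients for many responses at one lambda."""
    w = ws.weights(lam)
    if np.min(w) <= 0:
        w = np.clip(w, 1e-12 * np.max(w), None)
    sw = np.sqrt(w)
    Xw = Xr / sw[:, None]
    Yw = Yr / sw[:, None]
    beta, _, rank, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    if rank < Xr.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = Yw - Xw @ beta
    rss = np.sum(resid**2, axis=0)
    logdet = float(np.sum(np.log(w)))
    n = ws.n
    sigma2 = np.clip(rss / n, np.finfo(float).tiny, None)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta


def _profile_lambda_batch(ws: _GLSWorkspace, Xr: np.ndarray, Yr: np.ndarray,
                          fine_step: float = 0.01):
    """Per-column grid ML of lambda for many responses at once.

    Coarse 11-point scan over [0, 1] followed by a +/-0.1 fine grid (step
    ``fine_step``) around each column's best coarse point; columns sharing a
    coarse optimum are refined together.  Ties break toward smaller lambda.
    Returns (lam_hat (B,), beta (k, B)).
    """
    B = Yr.shape[1]
    coarse = np.linspace(0.0, 1.0, 11)
    lls = np.stack([_batch_loglik(ws, lam, Xr, Yr)[0] for lam in coarse])
    best = np.argmax(lls, axis=0)
    lam_hat = coarse[best].astype(float)
    beta_out = np.empty((Xr.shape[1], B))
    for b0 in np.unique(best):
        cols = np.nonzero(best == b0)[0]
        lo = max(0.0, coarse[b0] - 0.1)
        hi = min(1.0, coarse[b0] + 0.1)
        fine = np.arange(lo, hi + fine_step / 2, fine_step)
        sub = Yr[:, cols]
        ll_f = np.stack([_batch_loglik(ws, lam, Xr, sub)[0] for lam in fine])
        bf = np.argmax(ll_f, axis=0)
        lam_hat[cols] = fine[bf]
        for lam_val in np.unique(bf):
            cc = cols[bf == lam_val]
            _, beta = _batch_loglik(ws, float(fine[lam_val]), Xr, Yr[:, cc])
            beta_out[:, cc] = beta
    return lam_hat, beta_out


def _reml_profile(ws: _GLSWorkspace, Xr: np.ndarray, yr: np.ndarray,
                  step: float = 0.05):
    """REML estimates (lambda, sigma2) for the bootstrap noise model.

    ML variance components are biased low (sigma2 by p/n; lambda collapses
    toward 0 when group factors align with clades), which shrinks every
    parametric-bootstrap CI.  The restricted likelihood removes the
    fixed-effect degrees of freedom, so simulated noise has the right scale.
    """
    n, p = Xr.shape

    def reml_ll(lam: float):
        w = np.clip(ws.weights(lam), 1e-12, None)
        sw = np.sqrt(w)
        Xw = Xr / sw[:, None]
        yw = yr / sw
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        rss = float(r @ r)
        s2 = rss / (n - p)
        _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * s2) + np.sum(np.log(w))
                     + logdet_xx + (n - p))
        return ll, s2

    grid = np.arange(0.0, 1.0 + step / 2, step)
    vals = [reml_ll(l) for l in grid]
    i = int(np.argmax([v[0] for v in vals]))
    fine = np.linspace(max(0.0, grid[i] - step), min(1.0, grid[i] + step), 21)
    valsf = [reml_ll(l) for l in fine]
    j = int(np.argmax([v[0] for v in valsf]))
    return float(fine[j]), float(valsf[j][1])


def pgls_fit(
    y,
    design: pd.DataFrame,
    tree: Phylogeny,
    lam: float | str = "ML",
    *,
    _ws: _GLSWorkspace | None = None,
) -> PglsFit:
    """Fit y = X beta + eps, eps ~ N(0, sigma^2 C(lambda)) by ML.

    Parameters
    ----------
    y
        Response vector indexed like ``design`` (tip order of ``design``).
    design
        Design matrix with named columns; rows ordered as ``tree.tip_labels``
        unless a ``_ws`` with its own ordering is supplied.
    lam
        ``"ML"`` to estimate Pagel's lambda by profile likelihood, or a fixed
        value in [0, 1].
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("response/design length mismatch")
    if n < p + 2:
        raise ValueError("need at least 2 more tips than design columns")
    ws = _ws if _ws is not None else _GLSWorkspace(tree)
    Xr, yr = ws.prepare(X, y)

    if isinstance(lam, str):
        if lam != "ML":
            raise ValueError("lam must be 'ML' or a float in [0,1]")
        lam_hat, ll, flat = _profile_lambda(ws, Xr, yr)
        fixed = False
    else:
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda outside [0, 1]")
        lam_hat, fixed, flat = float(lam), True, False
        ll = None

    beta, rss, logdet = ws.solve_quadratics(lam_hat, Xr, yr)
    sigma2 = rss / n
    if ll is None:
        ll = _loglik(n, rss, logdet)

    # GLS R^2 against the GLS intercept-only fit at the same lambda
    ones = np.ones((n, 1))
    onesr = ws.rotate(ones) if ws.ultrametric else ones
    _, rss0, _ = ws.solve_quadratics(lam_hat, onesr, yr)
    r2 = 0.0 if rss0 <= 0 else float(max(0.0, min(1.0, 1.0 - rss / rss0)))

    k = p + (1 if fixed else 2)  # sigma2, plus lambda when estimated
    denom = n - k - 1
    aicc = -2.0 * ll + 2.0 * k + (2.0 * k * (k + 1) / denom if denom > 0 else np.inf)

    fitted = X @ beta
    return PglsFit(
        coef=pd.Series(beta, index=list(design.columns)),
        sigma2=float(sigma2),
        lam=lam_hat,
        loglik=float(ll),
        aicc=float(aicc),
        r2=r2,
        n=n,
        k_params=k,
        fitted=fitted,
        residuals=y - fitted,
        lambda_fixed=fixed,
        lambda_flat=flat,
        design=design,
        response=y,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# Design construction and the five-model set
# ---------------------------------------------------------------------------

def design_matrix(
    lnsize: np.ndarray | None,
    ecotype: pd.Series | np.ndarray | None,
    interaction: bool = False,
    n: int | None = None,
) -> pd.DataFrame:
    """Treatment-coded design over {ln size, ecotype}.

    Columns: ``intercept``, optionally ``lnsize``, ``eco[<level>]`` dummies
    (reference = first sorted level), and ``lnsize:eco[<level>]`` products.
    """
    if lnsize is not None:
        lnsize = np.asarray(lnsize, dtype=float)
        n = lnsize.shape[0]
    if ecotype is not None:
        ecotype = pd.Series(np.asarray(ecotype), name="ecotype")
        n = len(ecotype)
    if n is None:
        raise ValueError("cannot infer number of rows")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if lnsize is not None:
        cols["lnsize"] = lnsize
    levels: list[str] = []
    if ecotype is not None:
        levels = sorted(ecotype.unique())
        for lev in levels[1:]:
            cols[f"eco[{lev}]"] = (ecotype == lev).to_numpy(dtype=float)
    if interaction:
        if lnsize is None or ecotype is None:
            raise ValueError("interaction needs both lnsize and ecotype")
        for lev in levels[1:]:
            cols[f"lnsize:eco[{lev}]"] = cols["lnsize"] * cols[f"eco[{lev}]"]
    X = pd.DataFrame(cols)
    X.attrs["eco_levels"] = levels
    return X


_MODEL_NAMES = ("size", "ecotype", "size+ecotype", "size*ecotype", "null")


@dataclass
class ModelComparison:
    """AICc ranking of the five PGLS designs for one trait."""

    table: pd.DataFrame          # model, r2, lambda, aicc, delta_aic, aicw, supported
    fits: dict[str, PglsFit]

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def fit_model_set(
    y,
    lnsize,
    ecotype,
    tree: Phylogeny,
    models: tuple[str, ...] = _MODEL_NAMES,
) -> ModelComparison:
    """Fit the five-design PGLS competition and rank by AICc weights.

    Designs: trait ~ lnsize; ~ ecotype; ~ lnsize + ecotype;
    ~ lnsize * ecotype; ~ 1.  Lambda is estimated jointly for each design.
    AICw = exp(-dAIC/2) normalized; dAIC < 2 flagged as supported.
    """
    ecotype = pd.Series(np.asarray(ecotype))
    counts = ecotype.value_counts()
    models = list(models)
    if (counts < 2).any() and "size*ecotype" in models:
        import warnings

        warnings.warn("ecotype with < 2 tips: skipping the interaction model")
        models.remove("size*ecotype")

    ws = _GLSWorkspace(tree)
    designs = {
        "size": design_matrix(lnsize, None),
        "ecotype": design_matrix(None, ecotype),
        "size+ecotype": design_matrix(lnsize, ecotype),
        "size*ecotype": design_matrix(lnsize, ecotype, interaction=True),
        "null": design_matrix(None, None, n=len(ecotype)),
    }
    fits = {m: pgls_fit(y, designs[m], tree, "ML", _ws=ws) for m in models}
    aicc = np.array([fits[m].aicc for m in models])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    table = pd.DataFrame(
        {
            "model": models,
            "r2": [fits[m].r2 for m in models],
            "lambda": [fits[m].lam for m in models],
            "aicc": aicc,
            "delta_aic": delta,
            "aicw": w,
            "supported": delta < 2.0,
        }
    ).sort_values("delta_aic", kind="stable").reset_index(drop=True)
    return ModelComparison(table=table, fits=fits)


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapEnsemble:
    """Coefficient replicates from a parametric bootstrap of one PGLS fit."""

    coefs: pd.DataFrame  # n_boot x coefficient columns
    seed: int
    fit: PglsFit
    n_failed: int = 0


def bootstrap_coefficients(
    fit: PglsFit,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    *,
    reestimate_lambda: bool = True,
) -> BootstrapEnsemble:
    """Parametric bootstrap: simulate y* = X beta_hat + eps*, refit, collect.

    eps* is drawn from N(0, sigma2_hat C(lambda_hat)) through a factor of C;
    lambda is re-estimated for every replicate.  Tips are not exchangeable
    under phylogenetic covariance, so case resampling is deliberately avoided.
    """
    if fit.design is None or fit.tree is None:
        raise ValueError("fit does not carry its design/tree")
    rng = np.random.default_rng(seed)
    ws = _GLSWorkspace(fit.tree)
    X = fit.design.to_numpy(dtype=float)
    n, p = X.shape
    mean = X @ fit.coef.to_numpy()
    # noise parameters for the simulation are REML-estimated: ML sigma2 and
    # lambda are biased low in small samples, which would shrink every CI.
    # Replicate refits stay ML, mirroring the original estimator.
    if ws.ultrametric and not fit.lambda_fixed:
        Xr0, yr0 = ws.prepare(X, np.asarray(fit.response, dtype=float))
        lam_sim, sigma2_sim = _reml_profile(ws, Xr0, yr0)
    else:
        lam_sim = fit.lam
        sigma2_sim = fit.sigma2 * n / max(n - p, 1)
    if ws.ultrametric:
        scale = np.sqrt(np.clip(ws.weights(lam_sim), 0.0, None) * sigma2_sim)
        factor = ws.U * scale[None, :]
    else:
        C = phylo_covariance(ws.C1, lam_sim) * sigma2_sim
        factor = np.linalg.cholesky(C + 1e-12 * np.eye(n))

    Xr = ws.prepare(X, np.zeros(n))[0]
    n_failed = 0
    if ws.ultrametric and reestimate_lambda:
        # batched grid-ML over lambda: all replicates solved per grid point
        Ystar = mean[:, None] + factor @ rng.standard_normal((n, n_boot))
        Yr = ws.rotate(Ystar)
        _, beta_mat = _profile_lambda_batch(ws, Xr, Yr)
        rows = beta_mat.T
    else:
        rows = np.empty((n_boot, X.shape[1]))
        max_tries = n_boot + max(50, n_boot // 10)
        i = tries = 0
        while i < n_boot and tries < max_tries:
            tries += 1
            ystar = mean + factor @ rng.standard_normal(n)
            yr = ws.rotate(ystar) if ws.ultrametric else ystar
            try:
                if reestimate_lambda:
                    lam_b, _, _ = _profile_lambda(ws, Xr, yr)
                else:
                    lam_b = fit.lam
                beta, _, _ = ws.solve_quadratics(lam_b, Xr, yr)
            except np.linalg.LinAlgError:
                n_failed += 1
                continue
            rows[i] = beta
            i += 1
        if i < n_boot:
            raise RuntimeError(
                f"bootstrap failed to converge: {n_failed} failures")
    coefs = pd.DataFrame(rows, columns=fit.coef_names)
    seed_repr = seed if isinstance(seed, int) else -1
    return BootstrapEnsemble(coefs=coefs, seed=seed_repr, fit=fit, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Pairwise contrasts and allometry calls
# ---------------------------------------------------------------------------

def _eco_levels(design: pd.DataFrame) -> list[str]:
    levels = design.attrs.get("eco_levels") or []
    if not levels:
        # reconstruct from column names
        levels = [c[4:-1] for c in design.columns if c.startswith("eco[")]
    return levels


def group_quantities(coefs: pd.DataFrame, design: pd.DataFrame,
                     quantity: str, at_lnsize: float | None = None) -> pd.DataFrame:
    """Per-ecotype means (LS-means at ``at_lnsize``) or slopes per replicate.

    For treatment coding the reference level's slope is ``lnsize`` and level
    g's slope is ``lnsize + lnsize:eco[g]``; means analogously add the dummy
    main effect, evaluated at the grand-mean ln size when size is in the model.
    """
    levels = _eco_levels(design)
    if not levels:
        raise ValueError("model has no ecotype term")
    ref = levels[0]
    has_size = "lnsize" in coefs.columns
    out = {}
    for lev in levels:
        dummy = f"eco[{lev}]"
        inter = f"lnsize:eco[{lev}]"
        if quantity == "slopes":
            if not has_size:
                raise ValueError("model has no size term: slopes undefined")
            s = coefs["lnsize"].copy()
            if inter in coefs.columns:  # else common-slope model
                s = s + coefs[inter]
            out[lev] = s
        elif quantity == "means":
            m = coefs["intercept"].copy()
            if lev != ref and dummy in coefs.columns:
                m = m + coefs[dummy]
            if has_size:
                x0 = at_lnsize if at_lnsize is not None else 0.0
                s = coefs["lnsize"].copy()
                if inter in coefs.columns:
                    s = s + coefs[inter]
                m = m + s * x0
            out[lev] = m
        else:
            raise ValueError("quantity must be 'means' or 'slopes'")
    return pd.DataFrame(out)


def pairwise_ci(
    ensemble: BootstrapEnsemble,
    quantity: str = "means",
    level: float = 0.95,
) -> pd.DataFrame:
    """Pairwise ecotype differences with bootstrap percentile CIs.

    For each unordered pair (a, b): observed difference from the point fit,
    percentile bounds of the replicate differences, and a significance flag
    when the CI excludes zero.  Group means are least-squares means at the
    grand-mean ln size when size is in the model.
    """
    fit = ensemble.fit
    design = fit.design
    at_x = None
    if "lnsize" in design.columns:
        at_x = float(design["lnsize"].mean())
    boot_q = group_quantities(ensemble.coefs, design, quantity, at_x)
    obs_q = group_quantities(fit.coef.to_frame().T, design, quantity, at_x).iloc[0]
    alpha = (1.0 - level) / 2.0
    rows = []
    levels = list(boot_q.columns)
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            diffs = boot_q[a] - boot_q[b]
            lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "observed": float(obs_q[a] - obs_q[b]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AllometryCall:
    """Isometry/allometry verdict from a scaling-slope confidence interval."""

    slope: float
    ci_low: float
    ci_high: float
    verdict: str  # positive | negative | isometric


def classify_allometry(slope: float, ci_low: float, ci_high: float) -> AllometryCall:
    """Classify a dimensionless-trait scaling slope by its CI sign pattern.

    CI entirely above zero -> positive allometry; entirely below -> negative;
    straddling zero -> isometric (the traits are dimensionless, so the
    isometric expectation is a zero slope).
    """
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        raise ValueError("CI bounds must be finite")
    if ci_low > ci_high:
        raise ValueError("reversed CI bounds")
    if ci_low > 0:
        verdict = "positive"
    elif ci_high < 0:
        verdict = "negative"
    else:
        verdict = "isometric"
    return AllometryCall(float(slope), float(ci_low), float(ci_high), verdict)


def slope_ci(ensemble: BootstrapEnsemble, group: str | None = None,
             level: float = 0.95) -> AllometryCall:
    """Bootstrap percentile CI and allometry call for a scaling slope.

    ``group=None`` returns the across-ecotypes slope: the unweighted mean of
    the per-ecotype slopes when the model has an interaction, else the common
    slope.
    """
    design = ensemble.fit.design
    if "lnsize" not in design.columns:
        raise ValueError("model has no size term")
    has_eco = any(c.startswith("eco[") for c in design.columns)
    if group is None:
        if has_eco and any(c.startswith("lnsize:eco[") for c in ensemble.coefs.columns):
            boot = group_quantities(ensemble.coefs, design, "slopes").mean(axis=1)
            obs = group_quantities(ensemble.fit.coef.to_frame().T, design,
                                   "slopes").iloc[0].mean()
        else:
            boot = ensemble.coefs["lnsize"]
            obs = float(ensemble.fit.coef["lnsize"])
    else:
        boot = group_quantities(ensemble.coefs, design, "slopes")[group]
        obs = float(group_quantities(ensemble.fit.coef.to_frame().T, design,
                                     "slopes").iloc[0][group])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return classify_allometry(float(obs), float(lo), float(hi))


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA and paired t-test
# ---------------------------------------------------------------------------

def phylo_anova(y, ecotype, tree: Phylogeny) -> PglsFit:
    """One-way phylogenetic ANOVA with jointly estimated Pagel's lambda.

    A PGLS fit with group-indicator design; the fit's ``r2`` is the GLS R^2 of
    the group term against the intercept-only model.
    """
    ecotype = pd.Series(np.asarray(ecotype))
    if ecotype.nunique() < 2:
        raise ValueError("need at least two groups")
    X = design_matrix(None, ecotype)
    return pgls_fit(y, X, tree, "ML")


@dataclass
class PairedTTestResult:
    mean_difference: float
    se: float
    t: float
    p: float
    lam: float
    df: int
    degenerate: bool = False


def phylo_paired_ttest(trait_a, trait_b, tree: Phylogeny) -> PairedTTestResult:
    """Phylogenetic paired t-test on per-tip trait differences.

    Fits an intercept-only PGLS to d = a - b with lambda estimated for the
    difference vector (a single lambda, not a joint two-trait model); the
    intercept is the phylogenetic mean difference, tested against a t
    distribution with n - 1 degrees of freedom.  SE uses the n/(n-1)
    bias-corrected GLS variance.
    """
    a = np.asarray(trait_a, dtype=float)
    b = np.asarray(trait_b, dtype=float)
    d = a - b
    n = d.shape[0]
    if np.allclose(d, d[0]):
        if abs(d[0]) < 1e-300:
            return PairedTTestResult(0.0, np.nan, np.nan, np.nan, np.nan,
                                     n - 1, degenerate=True)
    X = pd.DataFrame({"intercept": np.ones(n)})
    fit = pgls_fit(d, X, tree, "ML")
    ws = _GLSWorkspace(tree)
    Xr, _ = ws.prepare(X.to_numpy(), d)
    if ws.ultrametric:
        w = ws.weights(fit.lam)
        xtcx = float(np.sum(Xr[:, 0] ** 2 / w))
    else:
        C = phylo_covariance(ws.C1, fit.lam)
        xtcx = float(np.ones(n) @ np.linalg.solve(C, np.ones(n)))
    s2_unbiased = fit.sigma2 * n / (n - 1)
    se = np.sqrt(s2_unbiased / xtcx)
    mu = float(fit.coef["intercept"])
    if se == 0:
        return PairedTTestResult(mu, 0.0, np.nan, np.nan, fit.lam, n - 1,
                                 degenerate=True)
    t = mu / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTTestResult(mu, float(se), float(t), float(p), fit.lam, n - 1)
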