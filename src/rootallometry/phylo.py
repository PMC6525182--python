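"""Phylogenetic comparative statistics on trait data.

Tree plumbing (Newick I/O, polytomy resolution, Yule simulation) is
delegated to :mod:`dendropy`; the comparative statistics themselves —
Felsenstein's independent contrasts, Blomberg's K, maximum-likelihood
Pagel's lambda, and phylogenetic generalized least squares — are
implemented here directly on the Brownian-motion covariance matrix
``C[i, j] =`` shared root-to-MRCA path length between tips i and j.

Conventions
-----------
* Traits are mappings (or pandas Series) keyed by tip label; every tip must
  have a value.
* ``lambda`` scales only the off-diagonal of C (the standard Pagel
  transform): lambda = 0 is a star phylogeny, lambda = 1 plain Brownian
  motion.
* Zero-length branches (e.g. from polytomy resolution) are floored at
  ``BRANCH_FLOOR`` = 1e-8 when C is built, keeping it invertible without
  measurably distorting path lengths.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, asdict
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import linalg, optimize, stats

__all__ = [
    "BRANCH_FLOOR",
    "PhyloError",
    "SignalResult",
    "PICSet",
    "PICRegression",
    "PGLSResult",
    "read_newick",
    "write_newick",
    "resolve_polytomies",
    "simulate_tree",
    "tip_labels",
    "vcv_matrix",
    "lambda_transform",
    "simulate_bm_trait",
    "pic",
    "pic_regression",
    "blomberg_k",
    "pagel_lambda_ml",
    "pgls",
    "reconcile_species",
]

BRANCH_FLOOR = 1e-8


class PhyloError(ValueError):
    """Tree or trait input violates a structural requirement."""


# --------------------------------------------------------------------------
# result records


@dataclass(frozen=True)
class SignalResult:
    """A phylogenetic signal estimate (Blomberg's K or Pagel's lambda)."""

    statistic: str
    estimate: float
    p_value: float
    n_tips: int
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PICSet:
    """Standardized independent contrasts, one per internal node."""

    contrasts: NDArray[np.float64]
    expected_sd: NDArray[np.float64]
    node_order: list[str]

    @property
    def n(self) -> int:
        return self.contrasts.size


@dataclass(frozen=True)
class PICRegression:
    slope: float
    r: float
    p_value: float
    n_contrasts: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PGLSResult:
    params: pd.Series
    se: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    sigma2: float
    n: int
    correlation: str
    lambda_: float | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se": self.se.to_dict(),
            "t_values": self.t_values.to_dict(),
            "p_values": self.p_values.to_dict(),
            "sigma2": self.sigma2,
            "n": self.n,
            "correlation": self.correlation,
            "lambda": self.lambda_,
        }


# --------------------------------------------------------------------------
# tree I/O and simulation


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree; every non-root edge needs a length."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"malformed Newick: {exc}") from exc
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        raise PhyloError("duplicate tip labels in tree")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            if node.edge.length is None:
                node.edge.length = 0.0
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.is_leaf() and node.taxon else "internal"
            raise PhyloError(f"edge above {name!r} node has no branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to Newick with branch lengths at full precision."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip()


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Arbitrarily (but reproducibly) binarize polytomies.

    Inserted edges receive length 0, so every tip-to-root path length and
    the total tree length are unchanged.
    """
    out = tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    for node in out.preorder_node_iter():
        if node.edge.length is None:
            node.edge.length = 0.0
    return out


def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, labelled s0001..."""
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the simulator stops at the n-th birth, leaving the two newest tips
    # with zero-length pendant edges; extend every tip by the waiting time
    # to the next (unrealized) event so all branch lengths are positive
    extra = rng.expovariate(birth_rate * n_tips)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"s{i:04d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            node.edge.length = 0.0
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in stable (leaf-iteration) order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# --------------------------------------------------------------------------
# Brownian-motion covariance


def vcv_matrix(
    tree: dendropy.Tree, branch_floor: float = BRANCH_FLOOR
) -> tuple[NDArray[np.float64], list[str]]:
    """Shared-path-length covariance matrix C and its tip-label order.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
    diagonal holds tip depths.  Edge lengths of exactly zero are floored
    at ``branch_floor`` so C stays positive definite.
    """
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    def elen(node) -> float:
        length = node.edge.length or 0.0
        if node.parent_node is None:
            return length  # root edge: keep as-is (usually 0)
        return max(length, branch_floor)

    depth: dict[int, float] = {}
    tips_below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth[id(node.parent_node)] if node.parent_node else 0.0
        depth[id(node)] = parent_depth + elen(node)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tips_below[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        groups = [tips_below[id(ch)] for ch in node.child_nodes()]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                ix = np.ix_(groups[gi], groups[gj])
                C[ix] = d
                C[np.ix_(groups[gj], groups[gi])] = d
        tips_below[id(node)] = [t for g in groups for t in g]
    return C, labels


def lambda_transform(C: NDArray[np.float64], lam: float) -> NDArray[np.float64]:
    """Multiply off-diagonal entries of C by lambda; diagonal untouched."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _trait_vector(
    trait: Mapping[str, float] | pd.Series, labels: list[str]
) -> NDArray[np.float64]:
    series = pd.Series(dict(trait)) if not isinstance(trait, pd.Series) else trait
    missing = [lab for lab in labels if lab not in series.index]
    if missing:
        raise PhyloError(f"missing trait values for tips: {missing[:10]}")
    vec = series.reindex(labels).to_numpy(dtype=float)
    if np.any(~np.isfinite(vec)):
        raise PhyloError("non-finite trait values")
    return vec


# --------------------------------------------------------------------------
# trait simulation


def simulate_bm_trait(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    lam: float = 1.0,
    seed: int | None = None,
) -> pd.Series:
    """One draw of a (lambda-transformed) Brownian trait at the tips.

    The sample has exactly the multivariate normal law
    ``N(root_value, sigma2 * C(lambda))``: a plain edge-wise Brownian walk
    supplies the shared-path component, then the identity
    ``C(lambda) = lambda*(C - diag C) + diag C`` lets the lambda transform
    be drawn as ``sqrt(lambda) * BM + sqrt(1-lambda) * independent`` tip
    noise with variance equal to each tip's depth.  This is O(n), with no
    dense covariance factorization.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    value: dict[int, float] = {}
    depth: dict[int, float] = {}
    sd = np.sqrt(sigma2)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[id(node)] = 0.0
            depth[id(node)] = node.edge.length or 0.0
            continue
        blen = node.edge.length or 0.0
        value[id(node)] = value[id(node.parent_node)] + sd * np.sqrt(
            blen
        ) * rng.standard_normal()
        depth[id(node)] = depth[id(node.parent_node)] + blen
    labels = tip_labels(tree)
    leaves = list(tree.leaf_node_iter())
    bm = np.array([value[id(leaf)] for leaf in leaves])
    if lam < 1.0:
        depths = np.array([depth[id(leaf)] for leaf in leaves])
        indep = sd * np.sqrt(depths) * rng.standard_normal(len(leaves))
        bm = np.sqrt(lam) * bm + np.sqrt(1.0 - lam) * indep
    return pd.Series(root_value + bm, index=labels)


# --------------------------------------------------------------------------
# independent contrasts


def pic(tree: dendropy.Tree, trait: Mapping[str, float] | pd.Series) -> PICSet:
    """Felsenstein's phylogenetic independent contrasts.

    Standard pruning pass: at each internal node of a binary tree the
    contrast between daughter values is standardized by the square root of
    the summed (corrected) branch lengths, the ancestral value is their
    branch-length-weighted average, and the node's own branch is extended
    by ``b1*b2 / (b1 + b2)``.
    """
    labels = tip_labels(tree)
    series = pd.Series(dict(trait)) if not isinstance(trait, pd.Series) else trait
    missing = [lab for lab in labels if lab not in series.index]
    if missing:
        raise PhyloError(f"missing trait values for species: {missing[:10]}")

    value: dict[int, float] = {}
    blen: dict[int, float] = {}
    min_label: dict[int, str] = {}
    contrasts: list[float] = []
    expected_sd: list[float] = []
    node_order: list[str] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            value[id(node)] = float(series[node.taxon.label])
            blen[id(node)] = float(node.edge.length or 0.0)
            min_label[id(node)] = node.taxon.label
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise PhyloError(
                "tree is not binary; resolve polytomies before computing PICs"
            )
        c1, c2 = children
        v1, v2 = value[id(c1)], value[id(c2)]
        b1 = max(blen[id(c1)], BRANCH_FLOOR)
        b2 = max(blen[id(c2)], BRANCH_FLOOR)
        var = b1 + b2
        contrasts.append((v1 - v2) / np.sqrt(var))
        expected_sd.append(np.sqrt(var))
        min_label[id(node)] = min(min_label[id(c1)], min_label[id(c2)])
        node_order.append(min_label[id(node)])
        value[id(node)] = (v1 / b1 + v2 / b2) / (1.0 / b1 + 1.0 / b2)
        blen[id(node)] = float(node.edge.length or 0.0) + b1 * b2 / var
    return PICSet(
        contrasts=np.asarray(contrasts),
        expected_sd=np.asarray(expected_sd),
        node_order=node_order,
    )


def pic_regression(
    tree: dendropy.Tree,
    x_trait: Mapping[str, float] | pd.Series,
    y_trait: Mapping[str, float] | pd.Series,
) -> PICRegression:
    """Through-origin OLS of y-contrasts on x-contrasts.

    Each contrast pair is oriented so its x-contrast is positive (the
    usual positivization; slope and correlation are unaffected, the sign
    convention just fixes the arbitrary daughter order).
    """
    cx = pic(tree, x_trait).contrasts
    cy = pic(tree, y_trait).contrasts
    flip = np.where(cx < 0, -1.0, 1.0)
    ux, uy = cx * flip, cy * flip
    sxx = float((ux**2).sum())
    syy = float((uy**2).sum())
    if sxx == 0.0:
        raise PhyloError("all x-contrasts are zero")
    sxy = float((ux * uy).sum())
    slope = sxy / sxx
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    n = ux.size
    df = n - 1  # through-origin regression
    if abs(r) >= 1.0:
        p = 0.0
    elif df <= 0:
        p = float("nan")
    else:
        t_stat = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return PICRegression(slope=float(slope), r=float(r), p_value=p, n_contrasts=n)


# --------------------------------------------------------------------------
# phylogenetic signal


def _phylo_mean_and_mse(
    z: NDArray[np.float64], cho: tuple
) -> tuple[float, float, NDArray[np.float64]]:
    """GLS mean under covariance C and the C-weighted mean squared error."""
    n = z.size
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    a_hat = float(ones @ linalg.cho_solve(cho, z)) / float(ones @ Ci1)
    resid = z - a_hat
    mse = float(resid @ linalg.cho_solve(cho, resid)) / (n - 1)
    return a_hat, mse, resid


def _k_statistic(
    z: NDArray[np.float64], cho: tuple, expected_ratio: float
) -> float:
    a_hat, mse, resid = _phylo_mean_and_mse(z, cho)
    mse0 = float(resid @ resid) / (z.size - 1)
    if mse <= 0:
        raise PhyloError("degenerate trait: zero phylogenetic mean squared error")
    return (mse0 / mse) / expected_ratio


def blomberg_k(
    tree: dendropy.Tree,
    trait: Mapping[str, float] | pd.Series,
    n_permutations: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K compares the observed ratio of raw to phylogenetically corrected
    mean squared error with its Brownian-motion expectation
    ``(tr C - n / (1' C^-1 1)) / (n - 1)``; K is calibrated to 1 under
    Brownian evolution.  Significance: the proportion of trait-shuffled
    trees with K at least as large as observed.
    """
    C, labels = vcv_matrix(tree)
    n = len(labels)
    if n < 4:
        raise PhyloError("need at least 4 tips")
    z = _trait_vector(trait, labels)
    if np.allclose(z, z[0]):
        raise PhyloError("constant trait: K undefined")
    try:
        cho = linalg.cho_factor(C)
    except linalg.LinAlgError as exc:
        raise PhyloError(f"singular phylogenetic covariance: {exc}") from exc
    ones = np.ones(n)
    denom = float(ones @ linalg.cho_solve(cho, ones))
    expected_ratio = (float(np.trace(C)) - n / denom) / (n - 1)
    k_obs = _k_statistic(z, cho, expected_ratio)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        k_perm = _k_statistic(rng.permutation(z), cho, expected_ratio)
        if k_perm >= k_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return SignalResult(
        statistic="K",
        estimate=float(k_obs),
        p_value=p,
        n_tips=n,
        detail={"n_permutations": n_permutations},
    )


def _profile_loglik(
    z: NDArray[np.float64], C: NDArray[np.float64], lam: float
) -> float:
    """Gaussian log-likelihood at lambda with mean and sigma2 profiled out."""
    n = z.size
    V = lambda_transform(C, lam)
    cho = linalg.cho_factor(V)
    _, mse, resid = _phylo_mean_and_mse(z, cho)
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / n
    logdet = 2.0 * float(np.log(np.diag(cho[0])).sum())
    return -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n


def _check_not_star(C: NDArray[np.float64]) -> None:
    off = C - np.diag(np.diag(C))
    if np.max(np.abs(off)) <= 1e2 * BRANCH_FLOOR:
        raise PhyloError("star phylogeny: lambda is unidentifiable")


def pagel_lambda_ml(
    tree: dendropy.Tree, trait: Mapping[str, float] | pd.Series
) -> SignalResult:
    """Maximum-likelihood Pagel's lambda on [0, 1] with an LR test vs 0.

    The lambda transform scales only the off-diagonal of the Brownian
    covariance; mean and rate are profiled analytically, leaving a bounded
    one-dimensional likelihood maximized to 1e-6.  The p-value is the
    chi-squared (1 df) likelihood-ratio test against lambda = 0 (no
    phylogenetic covariance).
    """
    C, labels = vcv_matrix(tree)
    n = len(labels)
    if n < 4:
        raise PhyloError("need at least 4 tips")
    _check_not_star(C)
    z = _trait_vector(trait, labels)
    if np.allclose(z, z[0]):
        raise PhyloError("constant trait: lambda undefined")

    neg = lambda lam: -_profile_loglik(z, C, lam)
    res = optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(float(res.x), -float(res.fun))]
    for lam in (0.0, 1.0):
        candidates.append((lam, _profile_loglik(z, C, lam)))
    lam_hat, loglik_hat = max(candidates, key=lambda t: t[1])
    loglik0 = _profile_loglik(z, C, 0.0)
    lr = max(2.0 * (loglik_hat - loglik0), 0.0)
    p = float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
    return SignalResult(
        statistic="lambda",
        estimate=lam_hat,
        p_value=p,
        n_tips=n,
        detail={"log_likelihood": loglik_hat, "lr": lr, "df": 1},
    )


# --------------------------------------------------------------------------
# PGLS


def _design_matrix(
    X: pd.DataFrame | ArrayLike, n: int, add_intercept: bool
) -> tuple[NDArray[np.float64], list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{j}" for j in range(mat.shape[1])]
    if mat.shape[0] != n:
        raise ValueError("design matrix rows must match the number of tips")
    if add_intercept:
        mat = np.column_stack([np.ones(n), mat])
        names = ["intercept"] + names
    return mat, names


def _collinear_columns(mat: NDArray[np.float64], names: list[str]) -> list[str]:
    bad = []
    rank = 0
    for j in range(mat.shape[1]):
        new_rank = np.linalg.matrix_rank(mat[:, : j + 1])
        if new_rank == rank:
            bad.append(names[j])
        rank = new_rank
    return bad


def pgls(
    tree: dendropy.Tree,
    y: Mapping[str, float] | pd.Series,
    X: pd.DataFrame | ArrayLike,
    correlation: str = "bm",
    add_intercept: bool = True,
) -> PGLSResult:
    """Phylogenetic generalized least squares.

    ``beta = (X' C^-1 X)^-1 X' C^-1 y`` with residual covariance C from
    plain Brownian motion (``correlation="bm"``) or with lambda estimated
    by maximum likelihood jointly with the coefficients
    (``correlation="lambda"``).  ``X`` may be a DataFrame (rows in tree
    tip order, or indexed by tip label) and may contain interaction
    columns; an intercept is prepended unless ``add_intercept=False``.
    """
    C, labels = vcv_matrix(tree)
    n = len(labels)
    y_vec = _trait_vector(y, labels)
    if isinstance(X, pd.DataFrame) and not X.index.equals(pd.RangeIndex(len(X))):
        missing = [lab for lab in labels if lab not in X.index]
        if missing:
            raise PhyloError(f"design matrix missing tips: {missing[:10]}")
        X = X.loc[labels]
    mat, names = _design_matrix(X, n, add_intercept)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        bad = _collinear_columns(mat, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    lam_hat: float | None = None
    if correlation == "bm":
        V = C
    elif correlation == "lambda":
        _check_not_star(C)

        def negloglik(lam: float) -> float:
            Vl = lambda_transform(C, lam)
            cho = linalg.cho_factor(Vl)
            Xt_Vi = linalg.cho_solve(cho, mat).T
            beta = np.linalg.solve(Xt_Vi @ mat, Xt_Vi @ y_vec)
            resid = y_vec - mat @ beta
            sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / n
            logdet = 2.0 * float(np.log(np.diag(cho[0])).sum())
            return 0.5 * n * np.log(2.0 * np.pi * sigma2) + 0.5 * logdet + 0.5 * n

        res = optimize.minimize_scalar(
            negloglik, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
        )
        lam_hat = float(res.x)
        for lam in (0.0, 1.0):
            if negloglik(lam) < negloglik(lam_hat):
                lam_hat = lam
        V = lambda_transform(C, lam_hat)
    else:
        raise ValueError(f"unknown correlation {correlation!r}")

    cho = linalg.cho_factor(V)
    Vi_X = linalg.cho_solve(cho, mat)
    XtViX = mat.T @ Vi_X
    beta = np.linalg.solve(XtViX, Vi_X.T @ y_vec)
    resid = y_vec - mat @ beta
    p_dim = mat.shape[1]
    df = n - p_dim
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / df
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df)
    idx = pd.Index(names)
    return PGLSResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        t_values=pd.Series(t_vals, index=idx),
        p_values=pd.Series(p_vals, index=idx),
        sigma2=sigma2,
        n=n,
        correlation=correlation,
        lambda_=lam_hat,
    )


# --------------------------------------------------------------------------
# species-name reconciliation

_WS = re.compile(r"\s+")


def normalize_species(name: str) -> str:
    """Trim, replace underscores with spaces, collapse whitespace."""
    return _WS.sub(" ", name.strip().replace("_", " "))


def reconcile_species(
    names: list[str] | pd.Index, tree: dendropy.Tree
) -> tuple[dict[str, str], list[str]]:
    """Exact-match species names to tree tips after normalization.

    Returns (mapping from input name to tip label, list of unmatched
    input names).  Unmatched species are the caller's to drop — with a
    logged count, never silently.
    """
    tip_norm = {normalize_species(lab): lab for lab in tip_labels(tree)}
    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for name in names:
        key = normalize_species(str(name))
        if key in tip_norm:
            mapping[str(name)] = tip_norm[key]
        else:
            unmatched.append(str(name))
    return mapping, unmatched
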