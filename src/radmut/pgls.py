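"""Phylogenetic generalized least squares with likelihood-ratio tests.

The error covariance of the regression encodes shared phylogenetic history:
under Brownian motion the covariance of two tips equals the root-to-MRCA
path length (the depth of their most recent common ancestor on an ultrametric
chronogram).  Alternative correlation structures (Pagel's lambda, Martins'
exponential decay, Blomberg's ACDC) are obtained by transforming the
Brownian matrix.  Models are fitted by maximum likelihood — never REML —
so that nested models can be compared with a likelihood-ratio test, and
goodness of fit is summarised by the Cox–Snell pseudo-R²,
R² = 1 − exp(−Λ/n).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


class TreeError(ValueError):
    """Malformed or inconsistent tree input."""


class EstimationError(ValueError):
    """GLS estimation cannot proceed (singular design, non-PSD covariance...)."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def parse_tree(newick: str, check_ultrametric: bool = True,
               rel_tol: float = 1e-6) -> dendropy.Tree:
    """Parse a rooted newick chronogram and validate it.

    Checks: parseable newick, branch lengths present on non-root edges,
    unique tip labels, and (optionally) ultrametricity within ``rel_tol``
    relative spread of root-to-tip depths.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeError("missing branch length on an edge")
        if edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    if check_ultrametric:
        spread = ultrametricity_spread(tree)
        depth = tree_depth(tree)
        if depth > 0 and spread > rel_tol * depth:
            raise TreeError(
                f"tree is not ultrametric: root-to-tip depth spread {spread:g} "
                f"exceeds tolerance ({rel_tol:g} relative to depth {depth:g})"
            )
    return tree


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def ultrametricity_spread(tree: dendropy.Tree) -> float:
    """Max minus min root-to-tip depth (0 for a perfect chronogram)."""
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    return max(depths) - min(depths)


def prune_tips(tree: dendropy.Tree, drop: list[str]) -> dendropy.Tree:
    """Return a copy of the tree with the named tips removed.

    The pendant branch of each removed tip disappears and any resulting
    degree-2 node is merged, summing branch lengths; the root is retained.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(drop) - labels
    if missing:
        raise TreeError(f"cannot prune unknown tips: {sorted(missing)}")
    if len(labels) - len(set(drop)) < 2:
        raise TreeError("pruning would leave fewer than 2 tips")
    pruned = tree.clone(depth=1)
    taxa = [t for t in pruned.taxon_namespace if t.label in set(drop)]
    pruned.prune_taxa(taxa, suppress_unifurcations=False)
    # merge degree-2 nodes, summing branch lengths; keep the root (and hence
    # the basal path) even if it is left with a single child
    changed = True
    while changed:
        changed = False
        for node in list(pruned.preorder_node_iter()):
            if node is pruned.seed_node or node.is_leaf():
                continue
            children = node.child_nodes()
            if len(children) == 1:
                child = children[0]
                child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
                parent = node.parent_node
                parent.remove_child(node)
                parent.add_child(child)
                changed = True
    return pruned


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


# ---------------------------------------------------------------------------
# Covariance structures
# ---------------------------------------------------------------------------

@dataclass
class PhyloCovariance:
    """Tip-indexed phylogenetic covariance matrix and its generating model."""

    matrix: np.ndarray
    labels: list[str]
    model: str = "brownian"
    parameter: float | None = None

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(
            matrix=self.matrix[np.ix_(idx, idx)],
            labels=list(labels),
            model=self.model,
            parameter=self.parameter,
        )


def brownian_vcv(tree: dendropy.Tree, labels: list[str] | None = None) -> PhyloCovariance:
    """Brownian-motion variance/covariance matrix of the tips.

    V[i, j] is the root-to-MRCA path length of tips i and j; V[i, i] is the
    tip depth (equal to the tree depth on a chronogram).
    """
    leaves = list(tree.leaf_node_iter())
    if labels is None:
        labels = [l.taxon.label for l in leaves]
    by_label = {l.taxon.label: l for l in leaves}
    unknown = set(labels) - set(by_label)
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)}")
    n = len(labels)
    depth_from_root = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth_from_root[node] = (depth_from_root[parent] + edge) if parent else 0.0
    V = np.zeros((n, n))
    # V[i, j] = depth of MRCA(i, j): accumulate over internal nodes, whose
    # descendant-tip bipartitions identify every pair they are the MRCA of.
    pdm = None
    for i in range(n):
        V[i, i] = depth_from_root[by_label[labels[i]]]
    for i in range(n):
        for j in range(i + 1, n):
            if pdm is None:
                pdm = dendropy.PhylogeneticDistanceMatrix.from_tree(tree)
            d = pdm.patristic_distance(by_label[labels[i]].taxon, by_label[labels[j]].taxon)
            V[i, j] = V[j, i] = 0.5 * (V[i, i] + V[j, j] - d)
    return PhyloCovariance(matrix=V, labels=list(labels), model="brownian")


def correlation_transform(
    vcv: PhyloCovariance, model: str, parameter: float | None = None
) -> PhyloCovariance:
    """Transform a Brownian VCV into an alternative correlation structure.

    - ``pagel``: off-diagonal entries multiplied by lambda in [0, 1];
    - ``martins``: correlation exp(-alpha * d_ij) with d_ij the patristic
      distance (recovered as V_ii + V_jj - 2 V_ij), alpha >= 0; variances
      are preserved;
    - ``blomberg``: ACDC model with the Brownian rate changing as exp(g*t)
      along time, i.e. shared-path covariances become (exp(g*V) - 1)/g
      elementwise; the g -> 0 limit is Brownian motion;
    - ``brownian``: returned unchanged.
    """
    V = vcv.matrix
    if model == "brownian":
        return PhyloCovariance(V.copy(), list(vcv.labels), "brownian")
    if parameter is None:
        raise ValueError(f"model {model!r} requires a parameter")
    if model == "pagel":
        lam = float(parameter)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("pagel lambda must lie in [0, 1]")
        out = V * lam
        np.fill_diagonal(out, np.diag(V))
    elif model == "martins":
        alpha = float(parameter)
        if alpha < 0:
            raise ValueError("martins alpha must be >= 0")
        diag = np.diag(V)
        d = diag[:, None] + diag[None, :] - 2.0 * V
        out = np.sqrt(np.outer(diag, diag)) * np.exp(-alpha * d)
    elif model == "blomberg":
        g = float(parameter)
        if g == 0.0:
            raise ValueError("blomberg g must be nonzero (g -> 0 is brownian)")
        out = (np.exp(g * V) - 1.0) / g
    else:
        raise ValueError(f"unknown correlation model {model!r}")
    return PhyloCovariance(out, list(vcv.labels), model, float(parameter))


# ---------------------------------------------------------------------------
# GLS fitting
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """A GLS fit by maximum likelihood under a phylogenetic covariance."""

    beta: np.ndarray
    sigma2: float
    loglik: float
    n: int
    terms: list[str]
    response: str
    model: str
    parameter: float | None
    method: str
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def slope(self) -> float:
        """Coefficient of the first non-intercept term (NaN for intercept-only)."""
        return float(self.beta[1]) if len(self.beta) > 1 else float("nan")


@dataclass
class LRTResult:
    """Likelihood-ratio test between nested ML fits."""

    statistic: float
    df: int
    p_value: float
    cox_snell_r2: float
    n: int


def cox_snell_r2(statistic: float, n: int) -> float:
    """Cox–Snell pseudo-R², 1 - exp(-Lambda/n)."""
    return 1.0 - float(np.exp(-statistic / n))


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("covariance matrix is not positive definite") from exc


def fit_gls(
    table: pd.DataFrame,
    response: str,
    terms: list[str] | tuple[str, ...],
    vcv: PhyloCovariance | np.ndarray,
    method: str = "ML",
) -> PGLSFit:
    """Fit response ~ intercept + terms by GLS with covariance V.

    Solves the whitened least-squares problem L^-1 y = L^-1 X beta with L
    the Cholesky factor of V (no explicit inverses).  The ML variance is
    sigma2 = RSS_whitened / n and the log-likelihood is

        l = -(n/2) log(2 pi sigma2) - (1/2) log|V| - n/2.
    """
    if method != "ML":
        raise EstimationError("only ML fitting is supported (REML would invalidate LRTs)")
    if isinstance(vcv, PhyloCovariance):
        V = vcv.reorder([str(t) for t in table.index]).matrix
        model, parameter = vcv.model, vcv.parameter
    else:
        V = np.asarray(vcv, dtype=float)
        model, parameter = "custom", None
    n = len(table)
    if V.shape != (n, n):
        raise EstimationError(f"covariance is {V.shape}, expected ({n}, {n})")
    cols = [response, *terms]
    sub = table[cols]
    if sub.isna().any().any():
        raise EstimationError("missing values in fitted columns")
    y = sub[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] + [sub[t].to_numpy(dtype=float) for t in terms])
    L = _chol(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError("singular design matrix (collinear terms?)")
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = rss / n
    logdet_v = 2.0 * float(np.log(np.diag(L)).sum())
    if sigma2 <= 0:
        # perfect fit: the Gaussian ML likelihood diverges; report +inf
        loglik = float("inf")
    else:
        loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet_v - 0.5 * n
    fitted = X @ beta
    return PGLSFit(
        beta=beta,
        sigma2=sigma2,
        loglik=float(loglik),
        n=n,
        terms=list(terms),
        response=response,
        model=model,
        parameter=parameter,
        method="ML",
        fitted=fitted,
        residuals=y - fitted,
    )


def lrt(fit_full: PGLSFit, fit_null: PGLSFit, n_for_r2: int | None = None) -> LRTResult:
    """Likelihood-ratio test of a null model nested in a full model.

    ``n_for_r2`` sets the sample size in the Cox–Snell formula; it defaults
    to the number of fitted rows but can be overridden when a reporting
    convention requires a different n.
    """
    if fit_full.method != "ML" or fit_null.method != "ML":
        raise EstimationError("LRT requires ML fits")
    if fit_full.response != fit_null.response or fit_full.n != fit_null.n:
        raise EstimationError("LRT requires the same response and observations")
    if not set(fit_null.terms) <= set(fit_full.terms):
        raise EstimationError("null model terms are not nested in the full model")
    df = len(fit_full.terms) - len(fit_null.terms)
    if df <= 0:
        raise EstimationError("full model must have more parameters than the null")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    stat = max(stat, 0.0)  # optimizer-free closed form; clamp tiny negatives
    p = float(stats.chi2.sf(stat, df))
    n = int(n_for_r2) if n_for_r2 is not None else fit_full.n
    return LRTResult(
        statistic=float(stat), df=df, p_value=p, cox_snell_r2=cox_snell_r2(stat, n), n=n
    )


def pgls_lrt(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    response: str,
    predictor: str,
    model: str = "brownian",
    parameter: float | None = None,
    n_for_r2: int | None = None,
) -> dict:
    """One-predictor pGLS with an LRT against the intercept-only model.

    The tree is pruned to the table's rows (index = tip labels) before the
    covariance is built.  Returns a flat record mirroring one line of a
    regression report: slope, Lambda, df, p, Cox–Snell R², n.
    """
    labels = [str(t) for t in table.index]
    extra = set(tip_labels(tree)) - set(labels)
    work_tree = prune_tips(tree, sorted(extra)) if extra else tree
    vcv = brownian_vcv(work_tree, labels=labels)
    if model != "brownian":
        vcv = correlation_transform(vcv, model, parameter)
    full = fit_gls(table, response, [predictor], vcv)
    null = fit_gls(table, response, [], vcv)
    res = lrt(full, null, n_for_r2=n_for_r2)
    return {
        "response": response,
        "predictor": predictor,
        "model": model,
        "parameter": parameter,
        "slope": full.slope,
        "l_ratio": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "cox_snell_r2": res.cox_snell_r2,
        "n": res.n,
    }


def model_robustness(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    response: str,
    predictor: str,
    models: dict[str, float | None] | None = None,
) -> pd.DataFrame:
    """The same regression under several correlation structures.

    ``models`` maps model name to its fixed parameter; the default sweeps
    Brownian, Pagel (lambda=0.5), Martins (alpha=1) and Blomberg (g=0.5).
    """
    if models is None:
        models = {"brownian": None, "pagel": 0.5, "martins": 1.0, "blomberg": 0.5}
    rows = [
        pgls_lrt(table, tree, response, predictor, model=m, parameter=par)
        for m, par in models.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def jackknife_fits(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    response: str,
    predictor: str,
    model: str = "brownian",
    parameter: float | None = None,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Leave-one-tip-out influence analysis of a one-predictor pGLS.

    Each species is removed in turn, the tree re-pruned, the covariance
    rebuilt, and the regression refitted.  Flags mark a change of slope sign
    or of significance at ``alpha_level`` relative to the full fit.
    """
    if len(table) < 4:
        raise EstimationError("jackknife requires at least 4 tips")
    full = pgls_lrt(table, tree, response, predictor, model=model, parameter=parameter)
    rows = []
    for tip in table.index:
        sub = table.drop(index=tip)
        rec = pgls_lrt(sub, tree, response, predictor, model=model, parameter=parameter)
        rows.append(
            {
                "left_out": tip,
                "slope": rec["slope"],
                "p_value": rec["p_value"],
                "sign_change": np.sign(rec["slope"]) != np.sign(full["slope"]),
                "significance_change": (rec["p_value"] < alpha_level)
                != (full["p_value"] < alpha_level),
            }
        )
    return pd.DataFrame(rows)


def residual_diagnostics(fit: PGLSFit, vcv: PhyloCovariance | np.ndarray) -> dict:
    """Whitened residuals, Shapiro–Wilk normality p, fitted-vs-residual table."""
    V = vcv.matrix if isinstance(vcv, PhyloCovariance) else np.asarray(vcv, dtype=float)
    L = _chol(V)
    white = np.linalg.solve(L, fit.residuals)
    if np.allclose(white, 0.0):
        shapiro_p = float("nan")  # degenerate: no variation to test
    else:
        shapiro_p = float(stats.shapiro(white).pvalue)
    return {
        "whitened_residuals": white,
        "shapiro_p": shapiro_p,
        "table": pd.DataFrame({"fitted": fit.fitted, "residual": fit.residuals,
                               "whitened_residual": white}),
    }
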