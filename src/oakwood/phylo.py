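"""Phylogenetic comparative statistics on rooted, branch-lengthed trees.

Implements Felsenstein's phylogenetically independent contrasts (PIC),
through-origin contrast correlations, PCA on species means or contrasts,
Blomberg's K with a tip-shuffling randomization test, Brownian-motion PGLS
with AIC model selection (plus the ordinary least squares counterpart), a
simulation-based phylogenetic ANOVA with Holm-adjusted post hoc tests, and
a Brownian trait simulator used as the null engine.

Trees are dendropy objects throughout; tip labels are reconciled with
trait tables case-insensitively with spaces and underscores unified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_newick",
    "write_newick",
    "prune",
    "normalize_name",
    "reconcile_names",
    "brownian_covariance",
    "ContrastSet",
    "pic",
    "correlation_matrix",
    "combined_correlation_table",
    "PCAResult",
    "pca",
    "SignalResult",
    "blomberg_k",
    "PGLSFit",
    "pgls",
    "ols",
    "model_select",
    "PhylANOVAResult",
    "phyl_anova",
    "simulate_bm",
]


# ---------------------------------------------------------------------------
# Tree I/O and manipulation


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, requiring branch lengths on all non-root edges."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune(tree: dendropy.Tree, keep_tips) -> dendropy.Tree:
    """Return a copy restricted to ``keep_tips``; unifurcations created by
    pruning are suppressed with branch lengths summed."""
    keep = list(keep_tips)
    have = set(tip_labels(tree))
    missing = sorted(set(keep) - have)
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    out = tree.clone(depth=1)
    out.retain_taxa_with_labels(keep)
    return out


def normalize_name(name: str) -> str:
    return name.strip().lower().replace(" ", "_")


def reconcile_names(tree: dendropy.Tree, table_names) -> dict[str, str]:
    """Map table names onto tree tip labels, case-insensitively with
    space/underscore unification; raises listing every unmatched name."""
    tips = {normalize_name(t): t for t in tip_labels(tree)}
    mapping, unmatched = {}, []
    for name in table_names:
        key = normalize_name(name)
        if key in tips:
            mapping[name] = tips[key]
        else:
            unmatched.append(name)
    if unmatched:
        raise ValueError(f"names not matched to tree tips: {sorted(unmatched)}")
    return mapping


def _check_positive_lengths(tree: dendropy.Tree, allow_zero: bool = False):
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length
        if bl is None or bl < 0 or (bl == 0 and not allow_zero):
            raise ValueError("tree requires strictly positive branch lengths")


def brownian_covariance(tree: dendropy.Tree, order: list[str] | None = None):
    """Brownian-motion covariance of tip values: C[i, j] is the root-to-MRCA
    shared branch length of tips i and j. Returns ``(labels, C)``."""
    labels = sorted(tip_labels(tree)) if order is None else list(order)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        parent_depth = getattr(node.parent_node, "_root_dist", 0.0) if node.parent_node else 0.0
        node._root_dist = parent_depth + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            node._tips = [i]
            C[i, i] = node._root_dist
        else:
            groups = [child._tips for child in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = node._root_dist
            node._tips = [i for g in groups for i in g]
    return labels, C


# ---------------------------------------------------------------------------
# Independent contrasts


@dataclass
class ContrastSet:
    """Standardized contrasts from a post-order Felsenstein pass.

    ``contrasts[k]`` is ``(x_L - x_R)/sqrt(v_L + v_R)`` at the k-th internal
    node (postorder); ``raw_variances`` stores the ``v_L + v_R`` divisors.
    """

    labels: list[str]
    contrasts: np.ndarray
    raw_variances: np.ndarray

    @property
    def variance(self) -> float:
        """Mean squared contrast, the randomization statistic for signal."""
        return float(np.sum(self.contrasts**2) / len(self.contrasts))


class _PICEngine:
    """Branch-length bookkeeping for contrasts, data-independent so shuffled
    tip values can be re-contrasted cheaply."""

    def __init__(self, tree: dendropy.Tree, resolve_polytomies: bool = True):
        work = tree
        if any(len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter()):
            if not resolve_polytomies:
                raise ValueError("tree contains polytomies; enable resolve_polytomies")
            work = tree.clone(depth=1)
            work.resolve_polytomies(limit=2)
        _check_positive_lengths(work, allow_zero=True)
        self.labels: list[str] = []
        self.ops: list[tuple[int, int, float, float, int]] = []
        slot = {}
        adj_var = {}
        n_leaves = sum(1 for _ in work.leaf_node_iter())
        leaf_counter, counter = 0, n_leaves  # leaves occupy slots [0, n_tips)
        for node in work.postorder_node_iter():
            if node.is_leaf():
                slot[node] = leaf_counter
                self.labels.append(node.taxon.label)
                adj_var[node] = node.edge.length or 0.0
                leaf_counter += 1
            else:
                children = node.child_nodes()
                if len(children) != 2:
                    raise ValueError("internal node is not binary after resolution")
                left, right = children
                vl, vr = adj_var[left], adj_var[right]
                slot[node] = counter
                self.ops.append((slot[left], slot[right], vl, vr, counter))
                counter += 1
                extra = vl * vr / (vl + vr) if (vl + vr) > 0 else 0.0
                adj_var[node] = (node.edge.length or 0.0) + extra
        self.n_tips = len(self.labels)
        self.n_slots = counter

    def contrasts(self, x: np.ndarray):
        vals = np.empty(self.n_slots)
        vals[: self.n_tips] = x
        out = np.empty(len(self.ops))
        var = np.empty(len(self.ops))
        for k, (li, ri, vl, vr, pi) in enumerate(self.ops):
            xl, xr = vals[li], vals[ri]
            vsum = vl + vr
            if vsum > 0:
                out[k] = (xl - xr) / np.sqrt(vsum)
                vals[pi] = (vr * xl + vl * xr) / vsum
            else:  # zero-length cherry from polytomy resolution
                out[k] = 0.0
                vals[pi] = 0.5 * (xl + xr)
            var[k] = vsum
        return out, var


def _as_tip_values(values, labels: list[str]) -> np.ndarray:
    if isinstance(values, pd.Series):
        values = values.to_dict()
    if isinstance(values, dict):
        lookup = {normalize_name(k): v for k, v in values.items()}
        missing = [lab for lab in labels if normalize_name(lab) not in lookup]
        if missing:
            raise ValueError(f"missing trait values for tips: {missing}")
        return np.array([float(lookup[normalize_name(lab)]) for lab in labels])
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(labels),):
        raise ValueError("trait vector length does not match tip count")
    return arr


def pic(tree: dendropy.Tree, trait, *, resolve_polytomies: bool = True) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    ``trait`` maps tip label -> value (dict/Series) or is a vector in the
    engine's postorder tip order. Polytomies are resolved to zero-length
    binary branches unless disabled, in which case they raise.
    """
    engine = _PICEngine(tree, resolve_polytomies=resolve_polytomies)
    x = _as_tip_values(trait, engine.labels)
    contrasts, variances = engine.contrasts(x)
    return ContrastSet(labels=engine.labels, contrasts=contrasts, raw_variances=variances)


# ---------------------------------------------------------------------------
# Correlations and PCA


def _through_origin_r(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    return float(np.sum(x * y) / denom) if denom > 0 else np.nan


def correlation_matrix(
    traits: pd.DataFrame,
    mode: str = "raw",
    tree: dendropy.Tree | None = None,
):
    """Pairwise Pearson correlations among trait columns.

    mode="raw": ordinary Pearson on species means, P from the usual t test.
    mode="pic": through-origin correlation of independent contrasts,
    ``r = sum(xy)/sqrt(sum(x^2) sum(y^2))``, with significance from the
    through-origin regression on ``n_tips - 2`` degrees of freedom.

    Returns ``(r, p)`` DataFrames. Zero-variance traits give missing
    entries with a warning.
    """
    cols = list(traits.columns)
    if mode == "pic":
        if tree is None:
            raise ValueError("mode='pic' requires a tree")
        engine = _PICEngine(tree)
        data = {
            c: engine.contrasts(_as_tip_values(traits[c], engine.labels))[0] for c in cols
        }
        df_resid = len(engine.labels) - 2
    elif mode == "raw":
        data = {c: traits[c].to_numpy(dtype=float) for c in cols}
        df_resid = len(traits) - 2
    else:
        raise ValueError("mode must be 'raw' or 'pic'")
    if len(traits) < 3:
        raise ValueError("need at least 3 species")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            xa, xb = data[a], data[b]
            if np.std(xa) == 0 or np.std(xb) == 0:
                if mode == "raw":
                    warnings.warn(f"zero-variance trait in pair ({a}, {b})", stacklevel=2)
                    rij, pij = np.nan, np.nan
                else:
                    rij, pij = _to_r_p(xa, xb, df_resid)
            elif mode == "raw":
                rij, pij = stats.pearsonr(xa, xb)
            else:
                rij, pij = _to_r_p(xa, xb, df_resid)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


def _to_r_p(x: np.ndarray, y: np.ndarray, df_resid: int):
    rij = _through_origin_r(x, y)
    if np.isnan(rij) or abs(rij) >= 1.0:
        return rij, 0.0 if abs(rij) >= 1.0 else np.nan
    t = rij * np.sqrt(df_resid / (1.0 - rij**2))
    return rij, float(2.0 * stats.t.sf(abs(t), df_resid))


def combined_correlation_table(
    traits: pd.DataFrame, tree: dendropy.Tree
) -> pd.DataFrame:
    """Single matrix with raw Pearson correlations below the diagonal and
    PIC through-origin correlations above it."""
    r_raw, _ = correlation_matrix(traits, mode="raw")
    r_pic, _ = correlation_matrix(traits, mode="pic", tree=tree)
    out = r_raw.copy()
    cols = list(traits.columns)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            out.loc[a, cols[j]] = r_pic.loc[a, cols[j]]
    return out


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # rows x components
    percent_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.percent_variance)


def pca(data: pd.DataFrame, standardize: bool = True, exclude: list[str] | None = None) -> PCAResult:
    """PCA by eigendecomposition of the correlation (standardize=True) or
    covariance matrix. Components are sorted by explained variance, signs
    fixed so each component's largest-magnitude loading is positive, and
    percent variances sum to 100."""
    if exclude:
        data = data.drop(columns=list(exclude))
    cols = list(data.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 variables")
    X = data.to_numpy(dtype=float)
    if X.shape[0] <= 1:
        raise ValueError("need more rows than components")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"constant column(s) under standardization: {bad}")
        Xc = Xc / sd
    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    pct = 100.0 * eigval / eigval.sum()
    comp = [f"PC{k + 1}" for k in range(len(cols))]
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=cols, columns=comp),
        scores=pd.DataFrame(Xc @ eigvec, index=data.index, columns=comp),
        percent_variance=pct,
    )


# ---------------------------------------------------------------------------
# Phylogenetic signal


@dataclass
class SignalResult:
    K: float
    p_value: float
    p_two_sided: float
    n_randomizations: int
    seed: int | None


def _k_statistic(x: np.ndarray, Cinv: np.ndarray, trC: float, sum_cinv: float) -> float:
    n = len(x)
    ones = np.ones(n)
    ahat = (ones @ Cinv @ x) / sum_cinv
    resid = x - ahat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ Cinv @ resid / (n - 1)
    expected = (trC - n / sum_cinv) / (n - 1)
    return float((mse0 / mse) / expected)


def blomberg_k(
    tree: dendropy.Tree,
    trait,
    n_randomizations: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-shuffling randomization test.

    K is the ratio of observed to Brownian-expected ``MSE0/MSE``, where
    MSE0 is the mean squared tip deviation from the phylogenetic (GLS)
    mean and MSE the GLS mean squared error under the Brownian covariance.
    The one-sided P is the +1-corrected proportion of tip-label shuffles
    whose contrast variance is <= the observed (low contrast variance =
    signal); a two-sided version is reported alongside.
    """
    engine = _PICEngine(tree)
    if engine.n_tips < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    x = _as_tip_values(trait, engine.labels)
    labels, C = brownian_covariance(tree, order=engine.labels)
    Cinv = np.linalg.inv(C)
    trC = float(np.trace(C))
    sum_cinv = float(Cinv.sum())
    K = _k_statistic(x, Cinv, trC, sum_cinv)

    if n_randomizations > 0:
        if seed is None:
            raise ValueError("seed is mandatory for the randomization test")
        rng = np.random.default_rng(seed)
        obs_var = ContrastSet(engine.labels, *engine.contrasts(x)).variance
        le = ge = 0
        for _ in range(n_randomizations):
            perm_var = ContrastSet(
                engine.labels, *engine.contrasts(rng.permutation(x))
            ).variance
            le += perm_var <= obs_var
            ge += perm_var >= obs_var
        p_one = (le + 1) / (n_randomizations + 1)
        p_hi = (ge + 1) / (n_randomizations + 1)
        p_two = min(1.0, 2.0 * min(p_one, p_hi))
    else:
        p_one = p_two = np.nan
    return SignalResult(
        K=K, p_value=float(p_one), p_two_sided=float(p_two),
        n_randomizations=n_randomizations, seed=seed,
    )


# ---------------------------------------------------------------------------
# PGLS / OLS


@dataclass
class PGLSFit:
    predictor: str
    coefficients: np.ndarray  # intercept, slope(s)
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    aic: float
    sigma2_ml: float
    n: int
    covariance_model: str = "brownian"
    zero_residual: bool = False
    aic_table: pd.DataFrame | None = field(default=None, repr=False)


def _gls_fit(X: np.ndarray, y: np.ndarray, C: np.ndarray | None, name: str, model: str) -> PGLSFit:
    n, p = X.shape
    if C is None:
        L = np.eye(n)
        logdet = 0.0
    else:
        L = np.linalg.cholesky(C)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("singular design matrix")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    zero_resid = rss <= 1e-12 * max(1.0, float(yw @ yw))
    sigma2_unbiased = rss / (n - p) if n > p else np.nan
    cov_beta = sigma2_unbiased * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)
    if zero_resid:
        ll = np.inf
        aic = -np.inf
    else:
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
        aic = 2.0 * (p + 1) - 2.0 * ll  # k = coefficients + 1 variance
    return PGLSFit(
        predictor=name,
        coefficients=beta,
        std_errors=se,
        t_values=tvals,
        p_values=pvals,
        log_likelihood=float(ll),
        aic=float(aic),
        sigma2_ml=sigma2_ml,
        n=n,
        covariance_model=model,
        zero_residual=zero_resid,
    )


def _align_tree_values(tree, response, predictor):
    labels = sorted(tip_labels(tree))
    y = _as_tip_values(response, labels)
    x = _as_tip_values(predictor, labels)
    return labels, y, x


def pgls(tree: dendropy.Tree, response, predictor, *, name: str = "predictor") -> PGLSFit:
    """Generalized least squares regression with Brownian-motion residual
    covariance (shared branch length), no lambda estimation. On a star
    phylogeny the estimates coincide exactly with OLS."""
    labels, y, x = _align_tree_values(tree, response, predictor)
    _, C = brownian_covariance(tree, order=labels)
    X = np.column_stack([np.ones(len(y)), x])
    return _gls_fit(X, y, C, name, "brownian")


def ols(response, predictor, *, name: str = "predictor") -> PGLSFit:
    """Ordinary least squares counterpart ignoring phylogeny."""
    y = np.asarray(
        response.to_numpy() if isinstance(response, pd.Series) else response, dtype=float
    )
    x = np.asarray(
        predictor.to_numpy() if isinstance(predictor, pd.Series) else predictor, dtype=float
    )
    X = np.column_stack([np.ones(len(y)), x])
    return _gls_fit(X, y, None, name, "ols")


def model_select(tree: dendropy.Tree, response, predictors: pd.DataFrame) -> PGLSFit:
    """Fit one single-predictor Brownian PGLS per column of ``predictors``
    and return the minimum-AIC fit, carrying the full AIC table."""
    fits = {c: pgls(tree, response, predictors[c], name=c) for c in predictors.columns}
    table = pd.DataFrame(
        {
            "predictor": list(fits),
            "aic": [f.aic for f in fits.values()],
            "slope": [f.coefficients[1] for f in fits.values()],
            "p_slope": [f.p_values[1] for f in fits.values()],
        }
    ).sort_values("aic", ignore_index=True)
    best = fits[table.loc[0, "predictor"]]
    best.aic_table = table
    return best


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA


@dataclass
class PhylANOVAResult:
    F: float
    p_value: float
    n_simulations: int
    seed: int | None
    pairwise: pd.DataFrame  # group_a, group_b, t, p_sim, p_holm


def _anova_f(X: np.ndarray, G: np.ndarray, sizes: np.ndarray):
    """F statistics (and pairwise machinery inputs) for columns of X.

    X is tips x datasets; G is the tips x groups indicator matrix.
    Returns (F, group_means, msw) each per dataset.
    """
    n, k = G.shape[0], G.shape[1]
    means = (G.T @ X) / sizes[:, None]
    grand = X.mean(axis=0)
    ssb = np.sum(sizes[:, None] * (means - grand) ** 2, axis=0)
    sst = np.sum((X - grand) ** 2, axis=0)
    ssw = sst - ssb
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    return F, means, msw


def phyl_anova(
    tree: dendropy.Tree,
    trait,
    groups,
    n_simulations: int = 1000,
    seed: int | None = None,
) -> PhylANOVAResult:
    """Phylogenetic ANOVA with a Brownian-simulation null distribution.

    The observed F is the standard one-way ANOVA statistic; the null
    distribution re-computes F on traits simulated under Brownian motion on
    the tree with the rate estimated from the data (GLS ML). P is the
    +1-corrected proportion of simulated F >= observed. Post hoc pairwise t
    statistics (pooled ANOVA error) get simulation-based P-values,
    Holm-adjusted across pairs.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the simulation test")
    labels = sorted(tip_labels(tree))
    x = _as_tip_values(trait, labels)
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    glookup = {normalize_name(k): v for k, v in groups.items()}
    try:
        glabels = np.array([str(glookup[normalize_name(lab)]) for lab in labels])
    except KeyError as exc:
        raise ValueError(f"missing group for tip {exc}") from exc
    group_names, ginv = np.unique(glabels, return_inverse=True)
    k = len(group_names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(ginv)
    if np.any(sizes < 2):
        small = group_names[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 tips: {small}")
    G = np.zeros((len(labels), k))
    G[np.arange(len(labels)), ginv] = 1.0

    _, C = brownian_covariance(tree, order=labels)
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(labels))
    ahat = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    resid = x - ahat
    sigma2 = float(resid @ Cinv @ resid) / len(labels)

    F_obs, means_obs, msw_obs = _anova_f(x[:, None], G, sizes)
    F_obs = float(F_obs[0])

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma2 * C)
    sims = L @ rng.standard_normal((len(labels), n_simulations))
    F_sim, means_sim, msw_sim = _anova_f(sims, G, sizes)
    p_global = (np.sum(F_sim >= F_obs) + 1) / (n_simulations + 1)

    rows = []
    tstats = []
    for a in range(k):
        for b in range(a + 1, k):
            scale = np.sqrt(1.0 / sizes[a] + 1.0 / sizes[b])
            t_obs = (means_obs[a, 0] - means_obs[b, 0]) / (np.sqrt(msw_obs[0]) * scale)
            t_sim = (means_sim[a] - means_sim[b]) / (np.sqrt(msw_sim) * scale)
            p_sim = (np.sum(np.abs(t_sim) >= abs(t_obs)) + 1) / (n_simulations + 1)
            rows.append((group_names[a], group_names[b], float(t_obs), float(p_sim)))
            tstats.append(t_obs)
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_sim"])
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p_sim"], method="holm")[1]
    return PhylANOVAResult(
        F=F_obs, p_value=float(p_global), n_simulations=n_simulations,
        seed=seed, pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Brownian simulation


def simulate_bm(
    tree: dendropy.Tree,
    rate: float = 1.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    n_traits: int = 1,
    root_value: float = 0.0,
) -> pd.DataFrame:
    """Simulate Brownian-motion trait values at the tips.

    Gaussian increments along each branch with variance ``rate * length``.
    Returns a DataFrame (tips x traits) indexed by tip label; reproducible
    given the seed.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if rng is None:
        if seed is None:
            raise ValueError("seed (or rng) is mandatory for simulation")
        rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.full(n_traits, float(root_value))
        else:
            bl = node.edge.length or 0.0
            step = rng.standard_normal(n_traits) * np.sqrt(rate * bl)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    frame = pd.DataFrame(out).T
    frame.columns = [f"trait_{i + 1}" for i in range(n_traits)]
    return frame.sort_index()
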