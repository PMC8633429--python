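"""Relative distance plasticity index (RDPI) and multiple regression on
distance matrices (MRM).

RDPI for one species and trait is the mean, over all pairs of individuals
growing in different plots, of the relative distance
``|x_i'j' - x_ij| / (x_i'j' + x_ij)``; it lies in [0, 1] for nonnegative
traits, 0 meaning no plasticity and 1 maximal plasticity. Plot-pair RDPI
matrices averaged per phylogenetic section are regressed on geographic and
environmental Euclidean distance matrices with MRM, whose significance
comes from joint row/column permutations of the response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RDPIResult",
    "DistanceMatrix",
    "MRMFit",
    "rdpi",
    "rdpi_table",
    "rdpi_plot_pair_matrix",
    "section_mean",
    "geographic_distance",
    "environmental_distance",
    "mrm",
    "rdpi_transform",
    "welch_ttest",
]


@dataclass
class RDPIResult:
    species: str
    trait: str
    rdpi: float
    n_pairs: int


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over labelled plots.

    ``kind`` is one of {"rdpi", "geographic", "environmental"}; NaN entries
    (species absent from a plot) are permitted only for kind="rdpi".
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "rdpi"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        diag = np.diag(self.values)
        if np.any(diag[~np.isnan(diag)] != 0):
            raise ValueError("distance matrix must have zero diagonal")
        finite = self.values[~np.isnan(self.values)]
        if np.any(finite < 0):
            raise ValueError("distances must be nonnegative")
        if self.kind != "rdpi" and np.isnan(self.values).any():
            raise ValueError(f"missing entries not allowed for kind={self.kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class MRMFit:
    predictors: list[str]
    coefficients: np.ndarray  # intercept first
    r_squared: float
    p_coefficients: np.ndarray  # permutation P per slope (intercept excluded)
    p_r_squared: float
    n_permutations: int
    seed: int | None
    n_pairs_used: int
    n_pairs_dropped: int = 0

    def summary(self) -> pd.DataFrame:
        rows = [("intercept", self.coefficients[0], np.nan)]
        for name, b, p in zip(self.predictors, self.coefficients[1:], self.p_coefficients):
            rows.append((name, b, p))
        return pd.DataFrame(rows, columns=["term", "coefficient", "p_perm"])


def _relative_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|a-b|/(a+b) over a cross product of two plots' values; 0/0 := 0."""
    diff = np.abs(a[:, None] - b[None, :])
    total = a[:, None] + b[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(total > 0, diff / total, 0.0)
    return rel


def rdpi(values_by_plot: dict, species: str = "", trait: str = "") -> RDPIResult:
    """RDPI over all cross-plot individual pairs.

    ``values_by_plot`` maps plot id -> sequence of nonnegative trait values.
    Within-plot pairs are excluded (the index compares distinct growing
    conditions); pairs with both values zero contribute 0.
    """
    plots = {p: np.asarray(v, dtype=float) for p, v in values_by_plot.items() if len(v) > 0}
    if len(plots) < 2:
        raise ValueError("no cross-environment pairs: need individuals in >= 2 plots")
    for p, v in plots.items():
        if np.any(v < 0):
            raise ValueError(f"negative trait value in plot {p!r}")
    keys = list(plots)
    total, n_pairs = 0.0, 0
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            rel = _relative_distance(plots[keys[i]], plots[keys[j]])
            total += rel.sum()
            n_pairs += rel.size
    return RDPIResult(species=species, trait=trait, rdpi=total / n_pairs, n_pairs=n_pairs)


def rdpi_table(
    records: pd.DataFrame,
    traits: list[str],
    *,
    species_col: str = "species",
    plot_col: str = "plot",
    species_list: list[str] | None = None,
) -> pd.DataFrame:
    """One RDPI per species x trait; single-plot species excluded.

    Returns a tidy frame (species, trait, rdpi, n_pairs) plus an
    ``excluded`` attribute in ``DataFrame.attrs`` listing species dropped
    because they occur in fewer than two plots.
    """
    if species_list is None:
        species_list = sorted(records[species_col].unique())
    present = [s for s in species_list if (records[species_col] == s).any()]
    if not present:
        raise ValueError("no overlap between species_list and records")
    rows, excluded = [], []
    for sp in present:
        sub = records[records[species_col] == sp]
        if sub[plot_col].nunique() < 2:
            excluded.append(sp)
            continue
        for trait in traits:
            groups = {
                p: g[trait].dropna().to_numpy()
                for p, g in sub.groupby(plot_col)
            }
            groups = {p: v for p, v in groups.items() if len(v)}
            if len(groups) < 2:
                continue
            res = rdpi(groups, species=sp, trait=trait)
            rows.append((sp, trait, res.rdpi, res.n_pairs))
    out = pd.DataFrame(rows, columns=["species", "trait", "rdpi", "n_pairs"])
    out.attrs["excluded"] = excluded
    return out


def rdpi_plot_pair_matrix(
    records: pd.DataFrame,
    species: str,
    trait: str,
    *,
    plots: list[str] | None = None,
    species_col: str = "species",
    plot_col: str = "plot",
) -> DistanceMatrix:
    """Plot-pair RDPI matrix: entry (p, q) is the RDPI restricted to
    individual pairs between plots p and q; NaN where the species is absent
    from either plot."""
    sub = records[records[species_col] == species]
    if sub[plot_col].nunique() < 2:
        raise ValueError(f"species {species!r} occurs in fewer than 2 plots")
    groups = {p: g[trait].dropna().to_numpy() for p, g in sub.groupby(plot_col)}
    groups = {p: v for p, v in groups.items() if len(v)}
    if plots is None:
        plots = sorted(groups)
    n = len(plots)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = groups.get(plots[i]), groups.get(plots[j])
            if a is None or b is None:
                continue
            values[i, j] = values[j, i] = _relative_distance(a, b).mean()
    return DistanceMatrix(labels=list(plots), values=values, kind="rdpi")


def section_mean(matrices: list[DistanceMatrix]) -> DistanceMatrix:
    """Entrywise mean over a section's species matrices, ignoring missing
    entries; an entry missing in every matrix stays missing."""
    if not matrices:
        raise ValueError("no matrices to average")
    labels = matrices[0].labels
    for m in matrices:
        if m.labels != labels:
            raise ValueError("all matrices must share the same plot labels")
    stack = np.stack([m.values for m in matrices])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries stay NaN
        mean = np.nanmean(stack, axis=0)
    return DistanceMatrix(labels=list(labels), values=mean, kind="rdpi")


def geographic_distance(
    plots: pd.DataFrame, *, x_col: str = "x", y_col: str = "y", plot_col: str = "plot"
) -> DistanceMatrix:
    """Euclidean distance between plots from planar coordinates."""
    labels = plots[plot_col].astype(str).tolist()
    coords = plots[[x_col, y_col]].to_numpy(dtype=float)
    return DistanceMatrix(labels=labels, values=squareform(pdist(coords)), kind="geographic")


def environmental_distance(
    plots: pd.DataFrame, variables: list[str], *, plot_col: str = "plot"
) -> DistanceMatrix:
    """Euclidean distance on climate variables standardised to zero mean,
    unit (sample) standard deviation."""
    labels = plots[plot_col].astype(str).tolist()
    X = plots[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant environmental variable(s) under scaling: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    return DistanceMatrix(labels=labels, values=squareform(pdist(Z)), kind="environmental")


def _lower_triangle(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def mrm(
    response: DistanceMatrix,
    predictors: list[DistanceMatrix],
    *,
    n_permutations: int = 5000,
    seed: int | None = None,
    predictor_names: list[str] | None = None,
) -> MRMFit:
    """Multiple regression on distance matrices with permutation inference.

    OLS on the unfolded strict lower triangles. Each permutation applies one
    random label permutation simultaneously to rows and columns of the
    response only, refits, and P-values use the +1-corrected proportion of
    permuted statistics >= the observed (|coefficient| per slope, R^2 for
    the model). Triangle elements with any missing value across response or
    predictors are dropped pairwise; the permuted response carries its own
    missingness pattern.
    """
    if seed is None and n_permutations > 0:
        raise ValueError("seed is mandatory for the MRM permutation test")
    labels = response.labels
    for p in predictors:
        if p.labels != labels:
            raise ValueError("all matrices must share the same plot labels")
    n = len(labels)
    if n < 4:
        raise ValueError("MRM needs at least 4 plots")
    if predictor_names is None:
        predictor_names = [p.kind for p in predictors]

    Xtri = np.column_stack([_lower_triangle(p.values) for p in predictors])
    if np.isnan(Xtri).any():
        raise ValueError("predictor matrices may not contain missing entries")

    def fit(y_matrix: np.ndarray):
        y = _lower_triangle(y_matrix)
        mask = ~np.isnan(y)
        yv = y[mask]
        Xv = np.column_stack([np.ones(mask.sum()), Xtri[mask]])
        if mask.sum() < Xv.shape[1] + 1:
            raise ValueError(
                f"only {int(mask.sum())} usable plot pairs for {Xv.shape[1]} parameters"
            )
        beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        resid = yv - Xv @ beta
        tss = np.sum((yv - yv.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
        return beta, r2, int(mask.sum())

    beta_obs, r2_obs, n_used = fit(response.values)
    n_dropped = n * (n - 1) // 2 - n_used

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed_beta = np.zeros(len(predictors), dtype=int)
        exceed_r2 = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            y_perm = response.values[np.ix_(perm, perm)]
            beta_p, r2_p, _ = fit(y_perm)
            exceed_beta += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:])
            exceed_r2 += r2_p >= r2_obs
        p_beta = (exceed_beta + 1) / (n_permutations + 1)
        p_r2 = (exceed_r2 + 1) / (n_permutations + 1)
    else:
        p_beta = np.full(len(predictors), np.nan)
        p_r2 = np.nan

    return MRMFit(
        predictors=list(predictor_names),
        coefficients=beta_obs,
        r_squared=r2_obs,
        p_coefficients=p_beta,
        p_r_squared=float(p_r2),
        n_permutations=n_permutations,
        seed=seed,
        n_pairs_used=n_used,
        n_pairs_dropped=n_dropped,
    )


def rdpi_transform(values):
    """Arcsine-square-root transform for RDPI values in [0, 1]."""
    arr = np.asarray(values, dtype=float)
    if np.any((arr[~np.isnan(arr)] < 0) | (arr[~np.isnan(arr)] > 1)):
        raise ValueError("values must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if out.ndim == 0 else out


def welch_ttest(group_a, group_b):
    """Welch two-sample t-test with Satterthwaite fractional df.

    Returns ``(t, df, p)`` two-sided. When both groups have zero variance
    and equal means, t = 0 and P = 1 by convention.
    """
    from scipy import stats

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return np.inf, float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
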