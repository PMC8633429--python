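"""Probabilistic pairwise species co-occurrence.

For two species occupying n1 and n2 of N sites, the number of jointly
occupied sites under independent random placement follows the
hypergeometric distribution
``P(j) = C(n1, j) C(N-n1, n2-j) / C(N, n2)`` on
``max(0, n1+n2-N) <= j <= min(n1, n2)``. Exact lower/upper tail
probabilities at the observed co-occurrence (both tails include the
observed value) classify each pair as a significant positive, negative or
random association at a chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["PairResult", "pair_pmf", "classify_pair", "cooccurrence_table"]


@dataclass
class PairResult:
    species_1: str
    species_2: str
    n1: int
    n2: int
    observed: int
    expected: float
    p_lt: float
    p_gt: float
    label: str


def pair_pmf(N: int, n1: int, n2: int):
    """Hypergeometric pmf of the co-occurrence count.

    Returns ``(support, probabilities)`` where support runs from
    ``max(0, n1+n2-N)`` to ``min(n1, n2)``.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("site counts must satisfy 0 <= n1, n2 <= N")
    lo = max(0, n1 + n2 - N)
    hi = min(n1, n2)
    support = np.arange(lo, hi + 1)
    return support, hypergeom.pmf(support, N, n1, n2)


def classify_pair(
    N: int,
    n1: int,
    n2: int,
    observed: int,
    *,
    alpha: float = 0.05,
    species_1: str = "sp1",
    species_2: str = "sp2",
) -> PairResult:
    """Classify one species pair from its exact tail probabilities.

    ``p_lt`` is the probability of at most the observed co-occurrence,
    ``p_gt`` of at least it; positive when p_gt < alpha, negative when
    p_lt < alpha, random otherwise. ``expected = n1*n2/N``.
    """
    support, _ = pair_pmf(N, n1, n2)
    if not (support[0] <= observed <= support[-1]):
        raise ValueError(
            f"observed={observed} outside hypergeometric support [{support[0]}, {support[-1]}]"
        )
    p_lt = float(hypergeom.cdf(observed, N, n1, n2))
    p_gt = float(hypergeom.sf(observed - 1, N, n1, n2))
    p_lt, p_gt = min(p_lt, 1.0), min(p_gt, 1.0)
    if p_gt < alpha:
        label = "positive"
    elif p_lt < alpha:
        label = "negative"
    else:
        label = "random"
    return PairResult(
        species_1=species_1,
        species_2=species_2,
        n1=n1,
        n2=n2,
        observed=observed,
        expected=n1 * n2 / N,
        p_lt=p_lt,
        p_gt=p_gt,
        label=label,
    )


def cooccurrence_table(
    presence: pd.DataFrame, *, alpha: float = 0.05, min_expected: float | None = None
):
    """Evaluate every unordered species pair of a presence-absence matrix.

    ``presence`` has species as rows, plots as columns, 0/1 entries.
    Species with zero occurrences are excluded with a warning before
    pairing. By default no expected-frequency filter is applied (all
    C(S, 2) pairs are evaluated); pass ``min_expected`` to drop pairs with
    expected co-occurrence below it.

    Returns ``(pairs, summary)``: a per-pair DataFrame and a dict with
    counts and full-precision percentages per label.
    """
    occ = presence.astype(bool)
    empty = occ.index[~occ.any(axis=1)].tolist()
    if empty:
        warnings.warn(f"excluding species with zero occurrences: {empty}", stacklevel=2)
        occ = occ.drop(index=empty)
    if occ.shape[0] < 2:
        raise ValueError("need at least 2 species with occurrences")
    N = occ.shape[1]
    species = list(occ.index)
    counts = occ.sum(axis=1).to_dict()
    M = occ.to_numpy()
    rows = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            s1, s2 = species[i], species[j]
            observed = int(np.sum(M[i] & M[j]))
            res = classify_pair(
                N, int(counts[s1]), int(counts[s2]), observed,
                alpha=alpha, species_1=s1, species_2=s2,
            )
            if min_expected is not None and res.expected < min_expected:
                continue
            rows.append(res)
    pairs = pd.DataFrame([r.__dict__ for r in rows])
    total = len(pairs)
    summary = {"total": total, "alpha": alpha}
    for label in ("positive", "negative", "random"):
        k = int((pairs["label"] == label).sum())
        summary[label] = k
        summary[f"{label}_pct"] = 100.0 * k / total if total else np.nan
    return pairs, summary
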