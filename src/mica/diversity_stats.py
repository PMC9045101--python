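"""Alpha/beta diversity, ordination, group tests, and variance partitioning.

Conventions: Shannon entropy in nats on relative abundances; Pielou evenness
H / ln(richness) (0 when richness <= 1); Bray-Curtis on relative abundances
by default; PERMANOVA reports both pseudo-F and R^2 = SS_between/SS_total;
permutation tests take an explicit seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
import skbio
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

from mica.io_formats import (
    DistanceMatrix,
    OTUTable,
    ValidationError,
    relative_abundance,
)

__all__ = [
    "AlphaRecord",
    "OrdinationResult",
    "PermanovaResult",
    "alpha_diversity",
    "compare_groups",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
    "mantel",
    "upgma_dendrogram",
    "rda_variance",
    "shared_otu_counts",
]


@dataclass
class AlphaRecord:
    sample_id: str
    richness: int
    shannon: float
    pielou: float


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def alpha_diversity(table: OTUTable) -> list[AlphaRecord]:
    """Richness, Shannon (nats) and Pielou evenness per sample."""
    rel = relative_abundance(table)
    records = []
    for sid, row in zip(table.sample_ids, rel):
        present = row[row > 0]
        richness = int(present.size)
        shannon = float(-(present * np.log(present)).sum()) if richness else 0.0
        pielou = shannon / np.log(richness) if richness > 1 else 0.0
        records.append(AlphaRecord(sid, richness, shannon, float(pielou)))
    return records


def compare_groups(values, groups, test: str = "kruskal_wallis"):
    """Rank-based group comparison of per-sample values.

    ``kruskal_wallis`` for any number of groups; ``mann_whitney`` (two-sided)
    for exactly two. Ties are handled by midranks.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    split = [values[groups == g] for g in labels]
    if test == "kruskal_wallis":
        res = scipy.stats.kruskal(*split)
    elif test == "mann_whitney":
        if len(labels) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        res = scipy.stats.mannwhitneyu(split[0], split[1], alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def bray_curtis_matrix(table: OTUTable, use_relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(a, b) = 1 - 2 * sum_i min(a_i, b_i) / (sum a + sum b), computed on
    relative abundances by default so library size does not masquerade as
    community difference.
    """
    data = relative_abundance(table) if use_relative else table.counts.astype(float)
    condensed = ssd.pdist(data, metric="braycurtis")
    return DistanceMatrix(list(table.sample_ids), ssd.squareform(condensed))


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (metric eigen-embedding).

    Eigendecomposition of the Gower-centered -D^2/2 matrix. Negative
    eigenvalues (non-Euclidean distances) are reported but excluded from the
    proportion-explained denominator.
    """
    res = _skbio_pcoa(d.to_skbio(), warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    pos_sum = eig[eig > 0].sum()
    prop = np.where(eig > 0, eig, 0.0) / pos_sum if pos_sum > 0 else np.zeros_like(eig)
    return OrdinationResult(
        sample_ids=list(d.ids),
        coordinates=res.samples.to_numpy(),
        eigenvalues=eig,
        proportion_explained=prop,
    )


def permanova(
    d: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations). R^2 is
    SS_between / SS_total from the distance-based partition.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.max() == len(groups):
        raise ValueError("one group contains every sample")
    res = _skbio_permanova(
        d.to_skbio(), list(groups), permutations=n_permutations, seed=seed
    )
    f_obs = float(res["test statistic"])
    # R^2 from the same sums-of-squares partition the pseudo-F uses:
    # F = (SS_b/(a-1)) / (SS_w/(n-a))  =>  R^2 = SS_b/SS_t
    a, n = len(labels), len(groups)
    ratio = f_obs * (a - 1) / (n - a)  # SS_b / SS_w
    r2 = ratio / (1.0 + ratio)
    return PermanovaResult(
        pseudo_f=f_obs,
        r_squared=float(r2),
        p_value=float(res["p-value"]),
        n_permutations=n_permutations,
    )


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 999,
    seed: int = 0,
):
    """Mantel correlation between two distance matrices (permutation p)."""
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices have mismatched ids")
    r, p, _n = _skbio_mantel(
        d1.to_skbio(),
        d2.to_skbio(),
        method=method,
        permutations=n_permutations,
        strict=True,
        seed=seed,
    )
    return float(r), float(p)


def upgma_dendrogram(d: DistanceMatrix) -> skbio.TreeNode:
    """Average-linkage (UPGMA) dendrogram as an ultrametric tree.

    Tip-to-tip distance in the returned tree equals the cophenetic
    (merge-height) distance; each tip sits at merge_height / 2 from the
    joining node.
    """
    if len(d.ids) < 2:
        raise ValueError("need at least 2 ids")
    linkage = sch.linkage(d.condensed(), method="average")
    # skbio places each tip at merge_height / 2, so tip-to-tip patristic
    # distance equals the cophenetic distance
    tree = skbio.TreeNode.from_linkage_matrix(linkage, d.ids)
    if tree.length is None:
        tree.length = 0.0
    return tree


def rda_variance(table: OTUTable, predictors, hellinger: bool = True):
    """Redundancy analysis: fraction of community variance explained.

    The community matrix (Hellinger-transformed relative abundances by
    default) is column-centered and regressed on the centered predictor
    matrix; the explained fraction is ||fitted||^2 / ||Y||^2 and per-axis
    fractions come from the singular values of the fitted matrix.
    Rank-deficient predictors fall back to the pseudo-inverse with a warning.
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = table.n_samples
    if X.shape[0] != n:
        raise ValueError("predictor rows must match samples")
    if n <= X.shape[1] + 1:
        raise ValueError("need n_samples > n_predictors + 1")
    rel = relative_abundance(table)
    Y = np.sqrt(rel) if hellinger else rel
    Y = Y - Y.mean(axis=0)
    total = float((Y**2).sum())
    if total <= 1e-300:
        return 0.0, np.zeros(0)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        import warnings

        warnings.warn("rank-deficient predictors; using pseudo-inverse", stacklevel=2)
    beta = np.linalg.pinv(Xc) @ Y
    fitted = Xc @ beta
    explained = float((fitted**2).sum()) / total
    sv = np.linalg.svd(fitted, compute_uv=False)
    axis_fractions = (sv**2) / total
    axis_fractions = axis_fractions[axis_fractions > 1e-12]
    return explained, axis_fractions


def shared_otu_counts(tables_by_group: dict) -> dict:
    """Exact set algebra on OTU presence across named groups.

    An OTU is "present" in a group if it has count > 0 in at least one
    sample. Values may be OTUTable instances or plain sets of OTU ids.
    Returns {frozenset(group names): count} for every non-empty membership
    region of the presence diagram.
    """
    if len(tables_by_group) < 2:
        raise ValueError("need at least 2 groups")
    presence = {}
    for name, value in tables_by_group.items():
        if isinstance(value, OTUTable):
            mask = value.counts.sum(axis=0) > 0
            presence[name] = {o for o, m in zip(value.otu_ids, mask) if m}
        else:
            presence[name] = set(value)
    names = list(presence)
    regions = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(presence[m] for m in members))
            outside = set.union(set(), *(presence[m] for m in names if m not in members))
            regions[frozenset(members)] = len(inside - outside)
    return regions
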