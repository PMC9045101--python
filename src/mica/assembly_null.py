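"""Phylogenetic and taxonomic null models for community assembly.

The inference logic: for every pair of communities, compare the observed
phylogenetic turnover (betaMNTD, the mean nearest-taxon distance between
communities) against a null distribution obtained by shuffling taxa across
the tips of the phylogeny. The z-score is betaNTI. |betaNTI| >= 2 flags
deterministic assembly — selection pushed the pair further apart
(betaNTI > 2, variable selection) or held it closer together
(betaNTI < -2, homogeneous selection) than chance. For pairs with
|betaNTI| < 2, the Bray-Curtis Raup-Crick index (RCI) splits the stochastic
processes: RCI > 0.95 dispersal limitation, RCI < -0.95 homogenizing
dispersal, |RCI| <= 0.95 drift.

Null sizes default to 999; each randomization consumes an independent
logged sub-seed so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from mica.io_formats import (
    DistanceMatrix,
    MetadataTable,
    OTUTable,
    ValidationError,
    relative_abundance,
    tip_distance_matrix,
)

__all__ = [
    "AssemblyResult",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "partition_processes",
    "bnti_environment_distances",
    "PROCESSES",
]

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)


@dataclass
class AssemblyResult:
    sample_ids: list[str]
    bnti: np.ndarray  # signed symmetric matrix, nan diagonal
    rc: np.ndarray  # signed symmetric matrix in [-1, 1], nan diagonal
    partition: dict  # process -> fraction, sums to 1
    n_null: int
    seed: int


def _aligned_tip_distances(table: OTUTable, tree: skbio.TreeNode) -> np.ndarray:
    """Patristic distance matrix in table OTU order; errors on missing tips."""
    dm = tip_distance_matrix(tree)
    tip_index = {t: i for i, t in enumerate(dm.ids)}
    missing = [o for o in table.otu_ids if o not in tip_index]
    if missing:
        raise ValidationError(
            f"OTUs missing from the phylogeny: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    order = [tip_index[o] for o in table.otu_ids]
    return dm.values[np.ix_(order, order)]


def _beta_mntd_from_distances(
    rel: np.ndarray, tipdist: np.ndarray, weighted: bool
) -> np.ndarray:
    """betaMNTD for all sample pairs given aligned tip distances.

    For samples s, t: mean over taxa in s of the distance to the nearest
    taxon in t, plus the reverse direction, averaged. Weighted mode weights
    each taxon's nearest-taxon distance by its relative abundance.
    """
    n_samples, n_otus = rel.shape
    present = rel > 0
    # dmin[s, j] = distance from taxon j to its nearest taxon in sample s
    dmin = np.empty((n_samples, n_otus))
    for s in range(n_samples):
        idx = np.flatnonzero(present[s])
        dmin[s] = tipdist[idx].min(axis=0)
    if weighted:
        w = rel / rel.sum(axis=1, keepdims=True)
    else:
        w = present / present.sum(axis=1, keepdims=True)
    # side[s, t] = sum_j w[t, j] * dmin[s, j]: mean distance from t's taxa
    # to their nearest neighbours in s
    side = w @ dmin.T  # (t, s) orientation
    out = (side + side.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(table: OTUTable, tree: skbio.TreeNode, weighted: bool = True) -> DistanceMatrix:
    """Between-community mean nearest taxon distance (betaMNTD).

    Abundance-weighted by default; with equal abundances the weighted and
    unweighted versions coincide.
    """
    tipdist = _aligned_tip_distances(table, tree)
    rel = relative_abundance(table)
    values = _beta_mntd_from_distances(rel, tipdist, weighted)
    return DistanceMatrix(list(table.sample_ids), values)


def beta_nti(
    table: OTUTable,
    tree: skbio.TreeNode,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """beta Nearest Taxon Index: z-score of betaMNTD against a taxa-shuffle null.

    The null shuffles taxon identities across the phylogeny tips (a
    permutation of rows/columns of the patristic distance matrix) and
    recomputes betaMNTD; betaNTI = (obs - mean_null) / sd_null per pair.
    Pairs whose null distribution has zero spread get NaN with a warning.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    tipdist = _aligned_tip_distances(table, tree)
    rel = relative_abundance(table)
    obs = _beta_mntd_from_distances(rel, tipdist, weighted)
    n_otus = rel.shape[1]
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_null)
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for k in range(n_null):
        perm = np.random.default_rng(sub_seeds[k]).permutation(n_otus)
        null = _beta_mntd_from_distances(rel, tipdist[np.ix_(perm, perm)], weighted)
        null_sum += null
        null_sq += null**2
    mean = null_sum / n_null
    var = null_sq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = (sd == 0) & ~np.eye(len(obs), dtype=bool)
    if degenerate.any():
        import warnings

        warnings.warn(
            f"{degenerate.sum() // 2} sample pairs have a degenerate null "
            "(sd = 0); betaNTI reported as NaN",
            stacklevel=2,
        )
        z[degenerate] = np.nan
    np.fill_diagonal(z, np.nan)
    return z


def _bray_curtis_counts(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    return 1.0 - 2.0 * np.minimum(a, b).sum() / s


def raup_crick_bray(table: OTUTable, n_null: int = 999, seed: int = 0) -> np.ndarray:
    """Bray-Curtis Raup-Crick index (RCI) in [-1, 1] for all sample pairs.

    Null communities preserve each sample's observed richness and total
    abundance: taxa are first drawn without replacement with probability
    proportional to their metacommunity occurrence frequency, then the
    remaining individuals are assigned multinomially in proportion to
    metacommunity relative abundance (restricted to the drawn taxa).

    RCI = 2 * (#{null BC < obs BC} + 0.5 * #{null BC = obs BC}) / n_null - 1:
    +1 means the pair is more dissimilar than every null draw (dispersal
    limitation), -1 more similar than every null draw (homogenizing
    dispersal).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts
    n_samples, n_otus = counts.shape
    occ_freq = (counts > 0).mean(axis=0)
    metacomm = counts.sum(axis=0).astype(float)
    metacomm_rel = metacomm / metacomm.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_null)
    # one independent null metacommunity realization per draw: null versions
    # of every sample, paired within a draw
    null_tables = np.empty((n_null, n_samples, n_otus))
    occ_p = occ_freq / occ_freq.sum()
    for k in range(n_null):
        krng = np.random.default_rng(sub_seeds[k])
        for s in range(n_samples):
            chosen = krng.choice(n_otus, size=richness[s], replace=False, p=occ_p)
            null = np.zeros(n_otus)
            null[chosen] = 1.0  # each drawn taxon gets one individual
            remaining = int(totals[s] - richness[s])
            if remaining > 0:
                probs = metacomm_rel[chosen]
                probs = probs / probs.sum()
                extra = krng.multinomial(remaining, probs)
                null[chosen] += extra
            assert (null > 0).sum() == richness[s] and null.sum() == totals[s]
            null_tables[k, s] = null

    rci = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            obs_bc = _bray_curtis_counts(counts[i].astype(float), counts[j].astype(float))
            null_bc = np.array(
                [_bray_curtis_counts(null_tables[k, i], null_tables[k, j]) for k in range(n_null)]
            )
            less = (null_bc < obs_bc - 1e-12).sum()
            equal = (np.abs(null_bc - obs_bc) <= 1e-12).sum()
            val = 2.0 * (less + 0.5 * equal) / n_null - 1.0
            rci[i, j] = rci[j, i] = val
    np.fill_diagonal(rci, np.nan)
    return rci


def partition_processes(bnti: np.ndarray, rc: np.ndarray) -> dict:
    """Assign every sample pair to one of five assembly processes.

    Thresholds: variable selection betaNTI > 2; homogeneous selection
    betaNTI < -2; otherwise (|betaNTI| <= 2) dispersal limitation RCI > 0.95,
    homogenizing dispersal RCI < -0.95, drift |RCI| <= 0.95. Pairs with
    missing betaNTI are excluded (their count is reported via logging).
    """
    bnti = np.asarray(bnti, dtype=float)
    rc = np.asarray(rc, dtype=float)
    if bnti.shape != rc.shape:
        raise ValueError("betaNTI and RCI matrices must be aligned")
    iu = np.triu_indices(bnti.shape[0], k=1)
    b = bnti[iu]
    r = rc[iu]
    valid = ~np.isnan(b)
    n_missing = int((~valid).sum())
    if n_missing:
        import logging

        logging.getLogger(__name__).info(
            "partition_processes: excluding %d pairs with missing betaNTI", n_missing
        )
    b, r = b[valid], r[valid]
    n = len(b)
    if n == 0:
        raise ValueError("no valid pairs to partition")
    counts = {
        "homogeneous_selection": int((b < -2).sum()),
        "variable_selection": int((b > 2).sum()),
    }
    stochastic = np.abs(b) <= 2
    counts["dispersal_limitation"] = int((stochastic & (r > 0.95)).sum())
    counts["homogenizing_dispersal"] = int((stochastic & (r < -0.95)).sum())
    counts["drift"] = int((stochastic & (np.abs(r) <= 0.95)).sum())
    assert sum(counts.values()) == n
    return {k: counts[k] / n for k in PROCESSES}


def assembly_analysis(
    table: OTUTable,
    tree: skbio.TreeNode,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> AssemblyResult:
    """Full null-model analysis: betaNTI, RCI and the process partition."""
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    bnti = beta_nti(table, tree, n_null=n_null, weighted=weighted, seed=int(s1))
    rc = raup_crick_bray(table, n_null=n_null, seed=int(s2))
    partition = partition_processes(bnti, rc)
    return AssemblyResult(
        sample_ids=list(table.sample_ids),
        bnti=bnti,
        rc=rc,
        partition=partition,
        n_null=n_null,
        seed=seed,
    )


def bnti_environment_distances(metadata: MetadataTable, variable: str) -> DistanceMatrix:
    """Pairwise absolute differences of an environmental variable.

    Feeds a Mantel test of betaNTI against e.g. latitude, longitude, annual
    mean temperature or precipitation.
    """
    col = metadata.column(variable)
    vals = pd.to_numeric(col, errors="coerce")
    missing = list(vals.index[vals.isna()])
    if missing:
        raise ValidationError(f"missing {variable!r} for samples: {missing}")
    v = vals.to_numpy(dtype=float)
    return DistanceMatrix(list(vals.index), np.abs(v[:, None] - v[None, :]))
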