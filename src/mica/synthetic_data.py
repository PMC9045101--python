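"""Synthetic communities with known ground truth.

Each generator emulates one assembly regime so the downstream estimators can
be tested against the truth that produced the data:

* :func:`simulate_neutral` — source–sink sampling under the Sloan neutral
  model with migration rate ``m``;
* :func:`simulate_selection` — habitat filtering on a phylogenetically
  conserved trait (deterministic, selection-driven assembly);
* :func:`simulate_sources_sink` — a sink community that is a known convex
  mixture of source communities plus an unknown component;
* :func:`simulate_correlated_composition` — compositional counts whose
  latent (basis) abundances have a prescribed correlation structure.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import skbio

from mica.io_formats import MetadataTable, OTUTable, validate_tree

__all__ = [
    "NeutralSimTruth",
    "SelectionSimTruth",
    "MixtureTruth",
    "simulate_tree",
    "brownian_trait",
    "simulate_neutral",
    "simulate_selection",
    "simulate_sources_sink",
    "simulate_correlated_composition",
    "simulate_drift",
    "standardize_trait",
    "lognormal_pool",
]

import pandas as pd


def _simplex_check(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a probability vector summing to 1")
    return np.clip(v, 0.0, None)


@dataclass
class NeutralSimTruth:
    """Ground truth for a neutral source–sink simulation."""

    source_rel_abund: np.ndarray
    m: float
    depth: int
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        self.source_rel_abund = _simplex_check(self.source_rel_abund, "source_rel_abund")
        if not (0 < self.m <= 1):
            raise ValueError("m must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SelectionSimTruth:
    """Ground truth for habitat-filtered (selection-driven) assembly."""

    tree: skbio.TreeNode
    trait: dict
    habitat_optima: dict
    filter_strength: float
    base_rel_abund: np.ndarray | None = None

    def __post_init__(self) -> None:
        validate_tree(self.tree)
        tips = [t.name for t in self.tree.tips()]
        missing = [t for t in tips if t not in self.trait]
        if missing:
            raise ValueError(f"trait undefined for tips: {missing[:5]}")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")
        if len(self.habitat_optima) < 2:
            raise ValueError("need at least 2 distinct habitat optima")


@dataclass
class MixtureTruth:
    """Ground truth for a source-tracking mixture.

    ``alpha`` has one entry per source plus a final "unknown" entry.
    """

    alpha: np.ndarray
    source_profiles: np.ndarray
    sink_depth: int
    source_depth: int
    seed: int
    unknown_concentration: float = 0.5

    def __post_init__(self) -> None:
        self.alpha = _simplex_check(self.alpha, "alpha")
        profiles = np.asarray(self.source_profiles, dtype=float)
        if profiles.ndim != 2:
            raise ValueError("source_profiles must be 2-D (sources x OTUs)")
        if len(self.alpha) != profiles.shape[0] + 1:
            raise ValueError("alpha must have one entry per source plus unknown")
        for j in range(profiles.shape[0]):
            profiles[j] = _simplex_check(profiles[j], f"source profile {j}")
        self.source_profiles = profiles
        if self.sink_depth <= 0 or self.source_depth <= 0:
            raise ValueError("depths must be positive")


def simulate_tree(n_tips: int, seed: int) -> skbio.TreeNode:
    """Pure-birth (Yule) ultrametric tree with tips ``OTU1..OTUn``.

    Lineages split at unit rate; waiting times are exponential in the number
    of extant lineages, so the returned tree is ultrametric with all branch
    lengths positive.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    # active lineages: (parent newick subtree placeholder, birth time)
    root_time = 0.0
    nodes = {0: root_time, 1: root_time}  # lineage id -> birth time
    children: dict[int, list[int]] = {}
    next_id = 2
    t = 0.0
    while True:
        active = [i for i in nodes if i not in children]
        t += rng.exponential(1.0 / len(active))
        if len(active) == n_tips:
            break
        split = active[rng.integers(len(active))]
        children[split] = [next_id, next_id + 1]
        nodes[next_id] = t
        nodes[next_id + 1] = t
        next_id += 2
    # t has advanced one waiting time past the last split, so every terminal
    # branch has positive length
    tips = [i for i in nodes if i not in children]
    labels = {tip: f"OTU{k + 1}" for k, tip in enumerate(sorted(tips))}

    def with_length(node_id: int, parent_time: float) -> str:
        if node_id not in children:
            return f"{labels[node_id]}:{t - parent_time:.10f}"
        split_time = nodes[children[node_id][0]]
        inner = ",".join(with_length(k, split_time) for k in children[node_id])
        return f"({inner}):{split_time - parent_time:.10f}"

    nwk = f"({with_length(0, 0.0)},{with_length(1, 0.0)});"
    tree = skbio.TreeNode.read([nwk], format="newick")
    tree.length = 0.0
    return validate_tree(tree)


def brownian_trait(tree: skbio.TreeNode, seed: int, rate: float = 1.0) -> dict:
    """Brownian-motion trait on a tree; returns {tip_name: value}.

    Each branch adds a Normal(0, rate * length) increment, so related tips
    have correlated trait values (phylogenetic conservatism).
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        val = parent_val + rng.normal(0.0, np.sqrt(rate * max(node.length, 0.0)))
        values[id(node)] = val
        if node.is_tip():
            out[node.name] = val
    return out


def lognormal_pool(n_otus: int, seed: int, sigma: float = 1.5) -> np.ndarray:
    """Log-normal species-abundance pool on the simplex.

    A standard abundance distribution for microbial metacommunities: a few
    dominant taxa, a long tail of rare ones.
    """
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus)
    return raw / raw.sum()


def simulate_neutral(truth: NeutralSimTruth) -> OTUTable:
    """Neutral source–sink sampling under the Sloan model.

    Each local community's composition is a Dirichlet draw around the source
    pool with concentration ``depth * m * p`` — the stationary local
    composition of the Sloan model, whose per-OTU marginals are
    Beta(N*m*p, N*m*(1-p)) — closed to counts by a multinomial draw of size
    ``depth``. With m = 1 the concentration is large and samples are
    effectively iid multinomials from the pool.
    """
    rng = np.random.default_rng(truth.seed)
    p = truth.source_rel_abund
    n_otus = len(p)
    conc = truth.depth * truth.m * p
    # Dirichlet with exact-zero concentration entries: those OTUs never occur.
    pos = conc > 0
    counts = np.zeros((truth.n_samples, n_otus), dtype=np.int64)
    for s in range(truth.n_samples):
        local = np.zeros(n_otus)
        local[pos] = rng.dirichlet(conc[pos])
        counts[s] = rng.multinomial(truth.depth, local)
        if counts[s].sum() == 0:  # pragma: no cover - depth > 0 guarantees reads
            counts[s, rng.integers(n_otus)] = 1
    sample_ids = [f"S{i + 1}" for i in range(truth.n_samples)]
    otu_ids = [f"OTU{i + 1}" for i in range(n_otus)]
    return OTUTable(sample_ids, otu_ids, counts)


def simulate_selection(
    truth: SelectionSimTruth,
    n_samples_per_habitat: int,
    depth: int,
    seed: int,
) -> tuple[OTUTable, MetadataTable]:
    """Habitat-filtered assembly on a phylogeny with a conserved trait.

    The sampling weight of OTU i in a sample from habitat h is

        w_i ∝ base_i * exp(-filter_strength * (trait_i - optimum_h)^2),

    a Gaussian fitness filter around the habitat optimum. With
    ``filter_strength = 0`` this reduces to neutral sampling from the base
    pool. Counts are multinomial draws of size ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_samples_per_habitat < 1:
        raise ValueError("n_samples_per_habitat must be >= 1")
    rng = np.random.default_rng(seed)
    tips = [t.name for t in truth.tree.tips()]
    trait = np.array([truth.trait[t] for t in tips])
    base = (
        np.full(len(tips), 1.0 / len(tips))
        if truth.base_rel_abund is None
        else _simplex_check(truth.base_rel_abund, "base_rel_abund")
    )
    rows, sample_ids, groups, optima = [], [], [], []
    for habitat, optimum in truth.habitat_optima.items():
        w = base * np.exp(-truth.filter_strength * (trait - optimum) ** 2)
        if w.sum() <= 0:
            raise ValueError(f"habitat {habitat!r}: filter removes every OTU")
        w = w / w.sum()
        for k in range(n_samples_per_habitat):
            row = rng.multinomial(depth, w)
            if row.sum() == 0:  # pragma: no cover
                row[rng.integers(len(tips))] = 1
            rows.append(row)
            sample_ids.append(f"{habitat}_{k + 1}")
            groups.append(habitat)
            optima.append(optimum)
    table = OTUTable(sample_ids, tips, np.vstack(rows))
    meta = MetadataTable(
        pd.DataFrame(
            {"group": groups, "habitat_optimum": optima},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return table, meta


def simulate_sources_sink(truth: MixtureTruth) -> tuple[OTUTable, OTUTable]:
    """Sink community as a known convex mixture of sources plus unknown.

    The unknown component's profile is drawn from a symmetric
    Dirichlet(``unknown_concentration``) over all OTUs. Returns
    ``(sink, sources)``: a one-sample sink table and a table of observed
    source communities (multinomial draws from their profiles).
    """
    rng = np.random.default_rng(truth.seed)
    n_sources, n_otus = truth.source_profiles.shape
    unknown_profile = rng.dirichlet(
        np.full(n_otus, truth.unknown_concentration)
    )
    profiles = np.vstack([truth.source_profiles, unknown_profile])
    mixture = truth.alpha @ profiles
    mixture = mixture / mixture.sum()
    sink_counts = rng.multinomial(truth.sink_depth, mixture)[None, :]
    source_counts = np.vstack(
        [rng.multinomial(truth.source_depth, truth.source_profiles[j]) for j in range(n_sources)]
    )
    otu_ids = [f"OTU{i + 1}" for i in range(n_otus)]
    sink = OTUTable(["sink"], otu_ids, sink_counts)
    sources = OTUTable([f"source{j + 1}" for j in range(n_sources)], otu_ids, source_counts)
    return sink, sources


def simulate_correlated_composition(
    n_samples: int,
    basis_corr: np.ndarray,
    seed: int,
    depth: int = 50_000,
    log_sd: float = 1.0,
    mean_log: float = 0.0,
) -> OTUTable:
    """Compositional counts whose latent abundances have a set correlation.

    Latent absolute abundances are log-normal with log-scale correlation
    ``basis_corr`` (unit diagonal, positive semi-definite); each sample is
    closed to counts by a multinomial draw of size ``depth``.
    """
    C = np.asarray(basis_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("basis_corr must be square")
    if np.abs(C - C.T).max() > 1e-10 or not np.allclose(np.diag(C), 1.0):
        raise ValueError("basis_corr must be symmetric with unit diagonal")
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-8:
        raise ValueError("basis_corr must be positive semi-definite")
    rng = np.random.default_rng(seed)
    n_otus = C.shape[0]
    cov = (log_sd**2) * C
    logs = rng.multivariate_normal(
        np.full(n_otus, mean_log), cov, size=n_samples, method="eigh"
    )
    abund = np.exp(logs)
    comp = abund / abund.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, comp[s]) for s in range(n_samples)])
    return OTUTable(
        [f"S{i + 1}" for i in range(n_samples)],
        [f"OTU{i + 1}" for i in range(n_otus)],
        counts,
    )


def simulate_drift(
    pool: np.ndarray,
    occurrence_prob: np.ndarray,
    richness: int,
    depth: int,
    n_samples: int,
    seed: int,
) -> OTUTable:
    """Drift-only (stochastic) assembly with fixed richness and depth.

    Each sample gets exactly ``richness`` taxa, drawn without replacement
    with probability proportional to ``occurrence_prob``; the remaining
    ``depth - richness`` individuals are assigned multinomially in
    proportion to the metacommunity ``pool`` restricted to the drawn taxa.
    This is exactly the randomization used by the Raup-Crick null, so
    communities built this way carry no assembly signal beyond chance.
    """
    pool = _simplex_check(pool, "pool")
    occ = np.asarray(occurrence_prob, dtype=float)
    if occ.shape != pool.shape or np.any(occ < 0) or occ.sum() <= 0:
        raise ValueError("occurrence_prob must be non-negative, same length as pool")
    n_otus = len(pool)
    if not (0 < richness <= n_otus):
        raise ValueError("richness must be in (0, n_otus]")
    if depth < richness:
        raise ValueError("depth must be >= richness")
    occ_p = occ / occ.sum()
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    for s in range(n_samples):
        chosen = rng.choice(n_otus, size=richness, replace=False, p=occ_p)
        row = np.zeros(n_otus)
        row[chosen] = 1.0
        if depth > richness:
            probs = pool[chosen] / pool[chosen].sum()
            row[chosen] += rng.multinomial(depth - richness, probs)
        counts[s] = row
    return OTUTable(
        [f"S{i + 1}" for i in range(n_samples)],
        [f"OTU{i + 1}" for i in range(n_otus)],
        counts,
    )


def standardize_trait(trait: dict) -> dict:
    """Z-score a tip trait across taxa.

    Habitat optima and filter strengths are naturally expressed in trait
    standard deviations; standardizing makes a given filter configuration
    mean the same thing for every tree/trait realization.
    """
    vals = np.array(list(trait.values()), dtype=float)
    sd = vals.std()
    if sd == 0:
        raise ValueError("trait has zero variance")
    mean = vals.mean()
    return {k: (v - mean) / sd for k, v in trait.items()}
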