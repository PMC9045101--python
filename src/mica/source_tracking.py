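"""Expectation-maximization microbial source tracking.

A sink community is modeled as a convex mixture of source communities plus
an optional unknown source: sink counts x ~ Multinomial(sum_j alpha_j *
gamma_j), where gamma_j is source j's composition. Observed source tables
are themselves noisy multinomial draws from gamma_j, so the gammas are
re-estimated jointly with the mixing proportions alpha (the unknown
source's profile is estimated from sink reads alone).

The EM: the E-step computes the responsibility of each source for each
sink read; the M-step updates alpha (responsibility-weighted read shares)
and, when source re-estimation is on, gamma_j proportional to observed
source counts plus the sink reads attributed to j. The tracked objective
is the joint log-likelihood of sink and source counts, which EM never
decreases. Multiple restarts guard against local optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mica.io_formats import OTUTable

__all__ = [
    "MixtureEstimate",
    "feast_em",
    "feast_em_table",
    "mixture_loglik",
    "summarize_sources",
]


@dataclass
class MixtureEstimate:
    source_names: list[str]  # includes "unknown" last when modeled
    alpha: np.ndarray
    source_profiles_hat: np.ndarray  # len(source_names) x n_otus
    loglik_trace: list[float]
    converged: bool
    n_iterations: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.alpha, index=self.source_names)


def mixture_loglik(sink, alpha, profiles) -> float:
    """Multinomial log-likelihood of sink counts under a mixture.

    The multinomial coefficient is omitted (constant in the parameters).
    A mixture probability of zero at an observed OTU yields -inf.
    """
    sink = np.asarray(sink, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    mix = alpha @ profiles
    observed = sink > 0
    if np.any(mix[observed] <= 0):
        return float("-inf")
    return float((sink[observed] * np.log(mix[observed])).sum())


def _source_loglik(sources: np.ndarray, profiles: np.ndarray) -> float:
    """Multinomial log-likelihood of the observed source tables."""
    total = 0.0
    for j in range(sources.shape[0]):
        obs = sources[j] > 0
        if np.any(profiles[j][obs] <= 0):
            return float("-inf")
        total += float((sources[j][obs] * np.log(profiles[j][obs])).sum())
    return total


def feast_em(
    sink,
    sources,
    include_unknown: bool = True,
    reestimate_sources: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
    source_names: list[str] | None = None,
) -> MixtureEstimate:
    """Estimate mixing proportions of sources (plus unknown) for one sink.

    ``sink`` is a count vector; ``sources`` a count matrix (sources x OTUs)
    over the same OTU universe. Convergence: relative change of the tracked
    log-likelihood below ``tol``. The best of ``n_restarts`` randomized
    initializations (by final log-likelihood) is returned.

    The unknown source's support is restricted to OTUs with zero counts in
    every observed source, initialized proportional to the sink counts
    there. Zero entries of a component profile are absorbing under
    multinomial EM, so the unknown can only ever explain reads no known
    source could have produced. Without this restriction the unknown is
    unidentifiable: a free extra component converges to the sink's own
    empirical composition and absorbs arbitrary amounts of real source
    mass. When the sources jointly cover every OTU, the unknown is kept as
    a frozen uniform background component (it cannot mimic the sink, so it
    draws only reads the sources explain poorly).
    """
    sink = np.asarray(sink, dtype=float).ravel()
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 2 or sources.shape[1] != sink.size:
        raise ValueError("sources must be a (n_sources, n_otus) matrix matching sink")
    if sink.sum() <= 0:
        raise ValueError("sink has no reads")
    n_sources, n_otus = sources.shape
    if source_names is None:
        source_names = [f"source{j + 1}" for j in range(n_sources)]
    names = list(source_names) + (["unknown"] if include_unknown else [])
    k = len(names)

    # unknown component: support limited to OTUs absent from every source
    unknown_frozen = False
    if include_unknown:
        support = sources.sum(axis=0) == 0
        if support.any():
            unknown0 = np.where(support, sink + 1e-6, 0.0)
            unknown0 = unknown0 / unknown0.sum()
        else:
            unknown0 = np.full(n_otus, 1.0 / n_otus)
            unknown_frozen = True

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=max(1, n_restarts))

    best: MixtureEstimate | None = None
    for r, sub_seed in enumerate(restart_seeds):
        rrng = np.random.default_rng(sub_seed)
        if r == 0:
            alpha = np.full(k, 1.0 / k)
        else:
            alpha = rrng.dirichlet(np.ones(k))
        gamma = np.empty((k, n_otus))
        gamma[:n_sources] = (sources + 1e-10) / (sources + 1e-10).sum(
            axis=1, keepdims=True
        )
        if include_unknown:
            if r == 0 or unknown_frozen:
                gamma[-1] = unknown0
            else:
                # jitter within the restricted support only
                noisy = unknown0 * rrng.dirichlet(np.ones(n_otus)) ** 0.1
                gamma[-1] = noisy / noisy.sum()

        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            mix = alpha @ gamma
            # E-step: responsibility of component j for reads at OTU i
            with np.errstate(divide="ignore", invalid="ignore"):
                resp = (alpha[:, None] * gamma) / mix[None, :]
            resp[:, mix <= 0] = 0.0
            weighted = resp * sink[None, :]  # expected reads per (component, OTU)
            # M-step
            comp_reads = weighted.sum(axis=1)
            alpha = comp_reads / comp_reads.sum()
            if reestimate_sources:
                new_gamma = sources + weighted[:n_sources]
                gamma[:n_sources] = new_gamma / np.clip(
                    new_gamma.sum(axis=1, keepdims=True), 1e-300, None
                )
            if include_unknown and not unknown_frozen:
                unk = weighted[-1]
                if unk.sum() > 0:
                    gamma[-1] = unk / unk.sum()
            ll = mixture_loglik(sink, alpha, gamma)
            if reestimate_sources:
                ll += _source_loglik(sources, gamma[:n_sources])
            trace.append(ll)
            if len(trace) > 1:
                prev = trace[-2]
                if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                    converged = True
                    break
        est = MixtureEstimate(
            source_names=names,
            alpha=alpha,
            source_profiles_hat=gamma.copy(),
            loglik_trace=trace,
            converged=converged,
            n_iterations=it,
        )
        if best is None or (trace and trace[-1] > best.loglik_trace[-1]):
            best = est
    assert best is not None
    return best


def feast_em_table(
    sinks: OTUTable,
    sources: OTUTable,
    include_unknown: bool = True,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Run :func:`feast_em` for every sink sample in a table.

    Sources are shared across sinks; OTU universes must match. Returns
    {sink sample id: MixtureEstimate}. Each sink consumes an independent
    sub-seed so results are order-independent.
    """
    if sinks.otu_ids != sources.otu_ids:
        raise ValueError("sink and source tables must share the same OTU universe")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=sinks.n_samples)
    out = {}
    for i, sid in enumerate(sinks.sample_ids):
        out[sid] = feast_em(
            sinks.counts[i],
            sources.counts,
            include_unknown=include_unknown,
            seed=int(sub_seeds[i]),
            source_names=list(sources.sample_ids),
            **kwargs,
        )
    return out


def summarize_sources(estimates: dict, grouping: dict | None = None) -> pd.DataFrame:
    """Mean mixing proportions per source, overall or per sink group.

    ``estimates`` maps sink ids to MixtureEstimate; ``grouping`` maps sink
    ids to group labels (one overall group when omitted). Rows sum to 1.
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    rows = {sid: est.as_series() for sid, est in estimates.items()}
    df = pd.DataFrame(rows).T
    if grouping is None:
        labels = pd.Series("all", index=df.index)
    else:
        labels = pd.Series({sid: grouping[sid] for sid in df.index})
    return df.groupby(labels).mean()
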