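"""Bayesian microbial source tracking by collapsed Gibbs sampling.

Each *sink* community (a concrete sample) is modelled as a mixture of
known *source* communities (the precursor materials) plus an Unknown
source absorbing taxa no source explains. Per sink read i with taxon
t_i and current source assignment z_i, the collapsed sampler draws

    P(z_i = v | ...) propto phi_v(t_i) * (n_v^{-i} + tau)

where for a known source v the taxon distribution is fixed by the
rarefied source table, phi_v(t) = (m_vt + alpha1) / (m_v. + alpha1 T),
while the Unknown source's distribution is estimated from its current
read assignments, phi_u(t) = (c_ut^{-i} + alpha2) / (c_u.^{-i} +
alpha2 T). Small alpha1 keeps known sources faithful to their observed
profiles; alpha2 = 1 gives the Unknown a broad prior. Mixing
proportions are posterior means of n_v / N over retained draws across
independent restarts.

Sources are pooled (summed) per source type and rarefied to
``source_depth``; sinks are rarefied to ``sink_depth``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import AsvTable

UNKNOWN = "Unknown"


def _gibbs_py(taxa, phi_known, alpha2, tau, n_taxa, burn_in, draws, thinning,
              seed):
    """One chain; returns (draws x V) source-proportion samples.

    ``taxa``: per-read taxon index of the sink. ``phi_known``:
    (V_known x T) fixed source taxon distributions.
    """
    np.random.seed(seed)
    n_reads = taxa.shape[0]
    v_known = phi_known.shape[0]
    v_total = v_known + 1
    z = np.empty(n_reads, dtype=np.int64)
    n_v = np.zeros(v_total, dtype=np.float64)
    c_ut = np.zeros(n_taxa, dtype=np.float64)
    c_u = 0.0
    for i in range(n_reads):
        z[i] = np.random.randint(0, v_total)
        n_v[z[i]] += 1.0
        if z[i] == v_known:
            c_ut[taxa[i]] += 1.0
            c_u += 1.0
    out = np.zeros((draws, v_total), dtype=np.float64)
    probs = np.empty(v_total, dtype=np.float64)
    total_sweeps = burn_in + draws * thinning
    kept = 0
    for sweep in range(total_sweeps):
        for i in range(n_reads):
            t = taxa[i]
            old = z[i]
            n_v[old] -= 1.0
            if old == v_known:
                c_ut[t] -= 1.0
                c_u -= 1.0
            s = 0.0
            for v in range(v_known):
                p = phi_known[v, t] * (n_v[v] + tau)
                probs[v] = p
                s += p
            pu = ((c_ut[t] + alpha2) / (c_u + alpha2 * n_taxa)) \
                * (n_v[v_known] + tau)
            probs[v_known] = pu
            s += pu
            r = np.random.random() * s
            acc = 0.0
            new = v_total - 1
            for v in range(v_total):
                acc += probs[v]
                if r < acc:
                    new = v
                    break
            z[i] = new
            n_v[new] += 1.0
            if new == v_known:
                c_ut[t] += 1.0
                c_u += 1.0
        if sweep >= burn_in and (sweep - burn_in + 1) % thinning == 0:
            if kept < draws:
                for v in range(v_total):
                    out[kept, v] = n_v[v] / n_reads
                kept += 1
    return out


try:  # hot loop; the jitted and pure-Python paths run the same algorithm
    from numba import njit

    _gibbs = njit(cache=False)(_gibbs_py)
except Exception:  # pragma: no cover
    _gibbs = _gibbs_py


@dataclass
class SourceTrackParams:
    """Sampler configuration; smoothing and depths follow the study setup."""

    alpha1: float = 0.01    # pseudo-count of known-source taxon distributions
    alpha2: float = 1.0     # pseudo-count of the Unknown's distribution
    tau: float = 1.0        # mixing-proportion prior pseudo-count
    restarts: int = 10
    burn_in: int = 100
    draws: int = 25
    thinning: int = 10
    source_depth: int = 8000
    sink_depth: int = 635
    seed: int | None = None

    def validate(self):
        for name in ("alpha1", "alpha2", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("restarts", "burn_in", "draws", "thinning",
                     "source_depth", "sink_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SourceEstimate:
    """Posterior mean mixing proportions (+ sd over draws) for one sink."""

    sink_id: str
    proportions: pd.Series   # over known sources + Unknown; sums to 1
    sd: pd.Series


def pool_sources(table: AsvTable, by: str = "sample_type",
                 source_types=None) -> pd.DataFrame:
    """Sum replicate samples per source type -> source x ASV counts."""
    md = table.metadata[by]
    if source_types is not None:
        keep = md.isin(source_types)
        tbl = table.select_samples(list(table.metadata.index[keep]))
        md = tbl.metadata[by]
    else:
        tbl = table
    pooled = tbl.counts.groupby(md.values).sum()
    pooled.index.name = None
    return pooled


def _rarefy_vector(counts: np.ndarray, depth: int, rng) -> np.ndarray:
    total = int(counts.sum())
    if total <= depth:
        return counts.astype(np.int64)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def sourcetrack(sources: pd.DataFrame, sinks: AsvTable | pd.DataFrame,
                params: SourceTrackParams | None = None) -> list[SourceEstimate]:
    """Estimate mixing proportions of each sink over the sources + Unknown.

    ``sources``: pooled source x ASV counts (see :func:`pool_sources`).
    ``sinks``: samples x ASV counts sharing the same ASV universe.
    """
    params = params or SourceTrackParams()
    params.validate()
    if params.seed is None:
        raise ValueError("seed is required")
    if sources.shape[0] == 0:
        raise ValueError("zero sources")
    sink_counts = sinks.counts if isinstance(sinks, AsvTable) else sinks
    if list(sink_counts.columns) != list(sources.columns):
        common = [a for a in sources.columns if a in set(sink_counts.columns)]
        if not common:
            raise ValueError("sources and sinks share no ASVs")
        sources = sources[common]
        sink_counts = sink_counts[common]
    ss = np.random.SeedSequence(params.seed)
    rar_rng = np.random.default_rng(ss.spawn(1)[0])
    src = np.vstack([
        _rarefy_vector(sources.iloc[v].to_numpy(), params.source_depth, rar_rng)
        for v in range(sources.shape[0])
    ]).astype(np.float64)
    t_dim = src.shape[1]
    phi = (src + params.alpha1) / (
        src.sum(axis=1, keepdims=True) + params.alpha1 * t_dim)

    names = list(sources.index) + [UNKNOWN]
    estimates = []
    for s_i, sink_id in enumerate(sink_counts.index):
        vec = sink_counts.iloc[s_i].to_numpy()
        if vec.sum() < params.sink_depth:
            warnings.warn(f"sink {sink_id!r} below sink_depth "
                          f"({int(vec.sum())} < {params.sink_depth}); skipped")
            continue
        vec = _rarefy_vector(vec, params.sink_depth, rar_rng)
        taxa = np.repeat(np.arange(t_dim), vec).astype(np.int64)
        chains = []
        child_seeds = ss.spawn(params.restarts)
        for r in range(params.restarts):
            chain_seed = int(np.random.default_rng(child_seeds[r]).integers(
                0, 2 ** 31 - 1))
            chains.append(_gibbs(taxa, phi, params.alpha2, params.tau, t_dim,
                                 params.burn_in, params.draws, params.thinning,
                                 chain_seed))
        alldraws = np.vstack(chains)
        props = pd.Series(alldraws.mean(axis=0), index=names)
        props = props / props.sum()
        sd = pd.Series(alldraws.std(axis=0, ddof=0), index=names)
        estimates.append(SourceEstimate(str(sink_id), props, sd))
    return estimates


def leave_one_out(sources: pd.DataFrame,
                  params: SourceTrackParams | None = None) -> pd.DataFrame:
    """Source-vs-source attribution: each source as the sink in turn.

    Rows are held-out sources (as sinks), columns the remaining sources
    plus Unknown; each row sums to 1. Exposes the potential for
    misattribution between similar sources.
    """
    params = params or SourceTrackParams()
    if sources.shape[0] < 2:
        raise ValueError("leave-one-out needs >= 2 source types")
    names = list(sources.index)
    out = pd.DataFrame(0.0, index=names, columns=names + [UNKNOWN])
    for held in names:
        rest = sources.drop(index=held)
        sink = sources.loc[[held]]
        est = sourcetrack(rest, sink, params)
        if not est:
            continue
        for col, val in est[0].proportions.items():
            out.loc[held, col] = val
    return out


def recover_mixtures_benchmark(sources: pd.DataFrame, sinks,
                               true_weights: pd.DataFrame,
                               params: SourceTrackParams | None = None):
    """Absolute error of estimated vs known mixing proportions per sink.

    ``true_weights``: sinks x (sources + Unknown) known weights. Returns
    (errors DataFrame, mean absolute error per source Series).
    """
    params = params or SourceTrackParams()
    estimates = sourcetrack(sources, sinks, params)
    rows = {}
    for est in estimates:
        truth = true_weights.loc[est.sink_id]
        aligned = est.proportions.reindex(truth.index).fillna(0.0)
        rows[est.sink_id] = (aligned - truth).abs()
    errors = pd.DataFrame(rows).T
    return errors, errors.mean(axis=0)
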