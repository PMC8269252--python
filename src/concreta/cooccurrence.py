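"""Pairwise ASV association inference on compositional counts.

Amplicon counts are compositional: only relative information survives
sequencing, so naive correlations between proportions are spurious. The
two association metrics here are designed for compositions:

* **SparCC** — estimates correlations of latent *basis* (absolute)
  abundances from the variances of pairwise log-ratios under a sparsity
  assumption, with iterative exclusion of strongly correlated pairs and
  permutation p-values.
* **proportionality rho** — ``1 - var(a_i - a_j)/(var a_i + var a_j)``
  on centred-log-ratio transformed counts, thresholded at fixed cutoffs
  (> 0.65 or < -0.5) in lieu of permutation FDR control.

Both produce a :class:`CorrelationNetwork`: a symmetric score matrix
with a per-metric significance mask — the evidence base of the
contaminant classifier. Pairwise chi-square tests (Monte-Carlo p with
fixed margins) and Levenshtein edit distances round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats

SPARCC_SCORE_CUTOFF = 0.35
SPARCC_P_CUTOFF = 0.05
RHO_POS_CUTOFF = 0.65
RHO_NEG_CUTOFF = -0.5


@dataclass
class CorrelationNetwork:
    """Symmetric pairwise association scores with a significance mask."""

    metric: str                       # "sparcc" or "rho"
    asv_ids: list
    scores: np.ndarray                # symmetric, unit diagonal
    pvalues: np.ndarray | None = None  # sparcc only
    mask: np.ndarray = None            # per-metric significance rule
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mask is None:
            self.mask = self._default_mask()

    def _default_mask(self) -> np.ndarray:
        s = self.scores
        if self.metric == "sparcc":
            m = np.abs(s) > SPARCC_SCORE_CUTOFF
            if self.pvalues is not None:
                m &= self.pvalues < SPARCC_P_CUTOFF
        elif self.metric == "rho":
            m = (s > RHO_POS_CUTOFF) | (s < RHO_NEG_CUTOFF)
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        np.fill_diagonal(m, False)
        if "undefined" in self.notes:
            idx = [self.asv_ids.index(a) for a in self.notes["undefined"]]
            m[idx, :] = False
            m[:, idx] = False
        return m

    def index_of(self, asv_id) -> int:
        return self.asv_ids.index(asv_id)

    def to_edge_frame(self) -> pd.DataFrame:
        """Long-form edge list (upper triangle)."""
        i, j = np.triu_indices(len(self.asv_ids), k=1)
        frame = pd.DataFrame({
            "asv_i": np.asarray(self.asv_ids)[i],
            "asv_j": np.asarray(self.asv_ids)[j],
            "score": self.scores[i, j],
            "significant": self.mask[i, j],
        })
        if self.pvalues is not None:
            frame.insert(3, "p", self.pvalues[i, j])
        return frame

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.asv_ids, columns=self.asv_ids)


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------


def _fractions(counts: np.ndarray, iterations: int, rng) -> np.ndarray:
    """Per-sample fraction estimates (N x D).

    ``iterations > 0``: mean of Dirichlet(counts + 1) posterior draws.
    ``iterations == 0``: plug-in counts/total (requires positive counts).
    """
    counts = np.asarray(counts, dtype=float)
    if iterations == 0:
        if (counts <= 0).any():
            raise ValueError("plug-in fractions (iterations=0) require "
                             "strictly positive counts")
        return counts / counts.sum(axis=1, keepdims=True)
    alpha = counts + 1.0
    acc = np.zeros_like(alpha)
    for _ in range(iterations):
        g = rng.standard_gamma(alpha)
        acc += g / g.sum(axis=1, keepdims=True)
    return acc / iterations


def _pseudo_fractions(counts: np.ndarray) -> np.ndarray:
    """Posterior-mean fractions (counts+1)/(total+D); used for null runs."""
    a = np.asarray(counts, dtype=float) + 1.0
    return a / a.sum(axis=1, keepdims=True)


def _variation_matrix(frac: np.ndarray):
    """t_ij = var over samples of log(f_i / f_j), via the log covariance."""
    log_f = np.log(frac)
    cov = np.cov(log_f, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0), cov


def _solve_basis_variances(t: np.ndarray, excluded: set) -> np.ndarray:
    """Solve the sparse-correlation linear system for basis variances.

    Row i of the system: sum_j t_ij = (D-1) w_i + sum_{j!=i} w_j, with
    each excluded pair's term removed from both of its rows.
    """
    d = t.shape[0]
    m = np.ones((d, d))
    np.fill_diagonal(m, d - 1.0)
    b = t.sum(axis=1)
    for (i, j) in excluded:
        b[i] -= t[i, j]
        b[j] -= t[i, j]
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
    omega = np.linalg.solve(m, b)
    return np.maximum(omega, 1e-12)


def _basis_correlations(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_rho(frac, exclusion_threshold, exclusion_rounds):
    t, _ = _variation_matrix(frac)
    d = t.shape[0]
    excluded: set = set()
    try:
        omega = _solve_basis_variances(t, excluded)
        rho = _basis_correlations(t, omega)
        for _ in range(exclusion_rounds):
            cand = np.abs(rho).copy()
            np.fill_diagonal(cand, 0.0)
            for (i, j) in excluded:
                cand[i, j] = cand[j, i] = 0.0
            i, j = np.unravel_index(np.argmax(cand), cand.shape)
            if cand[i, j] <= exclusion_threshold:
                break
            excluded.add((min(i, j), max(i, j)))
            omega = _solve_basis_variances(t, excluded)
            rho = _basis_correlations(t, omega)
    except np.linalg.LinAlgError:
        warnings.warn("singular basis-variance system after exclusions; "
                      "falling back to the no-exclusion solve")
        omega = _solve_basis_variances(t, set())
        rho = _basis_correlations(t, omega)
        excluded = set()
    return rho, omega, excluded


def sparcc(table, iterations: int = 50, exclusion_threshold: float = 0.1,
           exclusion_rounds: int = 10, permutations: int = 1000,
           seed: int | None = None) -> CorrelationNetwork:
    """SparCC basis correlations with permutation p-values.

    ``table`` may be an :class:`~concreta.tables_io.AsvTable` or a
    samples x ASVs count DataFrame. Fractions are estimated by averaging
    ``iterations`` Dirichlet(counts+1) draws (``iterations=0`` uses the
    plug-in estimate); permutation null datasets shuffle each ASV's
    counts across samples independently and are scored with the
    posterior-mean fraction estimate and no pair exclusion.
    """
    counts = _counts_frame(table)
    ids = list(counts.columns)
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 4:
        raise ValueError("SparCC needs >= 4 ASVs (system underdetermined)")
    if x.shape[0] < 3:
        raise ValueError("SparCC needs >= 3 samples")
    if (x < 0).any():
        raise ValueError("negative counts")
    rng = np.random.default_rng(seed)
    frac = _fractions(x, iterations, rng)
    rho, omega, excluded = _sparcc_rho(frac, exclusion_threshold, exclusion_rounds)
    # ASVs never observed carry no co-occurrence information; their
    # pseudocount fractions would correlate spuriously with library size
    undefined = [ids[k] for k in np.where(x.sum(axis=0) == 0)[0]]
    if undefined:
        idx = [ids.index(u) for u in undefined]
        rho[idx, :] = 0.0
        rho[:, idx] = 0.0
        np.fill_diagonal(rho, 1.0)

    pvals = None
    if permutations > 0:
        n, d = x.shape
        obs = np.abs(rho)
        exceed = np.zeros((d, d))
        for _ in range(permutations):
            order = np.argsort(rng.random((n, d)), axis=0)
            perm = x[order, np.arange(d)]
            pf = _pseudo_fractions(perm)
            t, _ = _variation_matrix(pf)
            w = _solve_basis_variances(t, set())
            r = _basis_correlations(t, w)
            exceed += np.abs(r) >= obs
        pvals = (1.0 + exceed) / (1.0 + permutations)
        np.fill_diagonal(pvals, 1.0 / (1.0 + permutations))
    notes = {"basis_variances": omega, "excluded_pairs": sorted(excluded)}
    if undefined:
        notes["undefined"] = undefined
    return CorrelationNetwork("sparcc", ids, rho, pvals, notes=notes)


# ---------------------------------------------------------------------------
# proportionality rho
# ---------------------------------------------------------------------------


def clr(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio transform per sample (rows)."""
    x = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return x - x.mean(axis=1, keepdims=True)


def proportionality_rho(table, pseudocount: float = 1.0) -> CorrelationNetwork:
    """Proportionality rho = 1 - var(a_i - a_j) / (var a_i + var a_j)."""
    counts = _counts_frame(table)
    ids = list(counts.columns)
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("rho needs >= 2 ASVs")
    if x.shape[0] < 3:
        raise ValueError("rho needs >= 3 samples")
    a = clr(x, pseudocount)
    cov = np.cov(a, rowvar=False)
    v = np.diag(cov).copy()
    # zero post-clr variance or never observed: rho undefined
    dead = (v <= 1e-15) | (x.sum(axis=0) == 0)
    undefined = [ids[i] for i in np.where(dead)[0]]
    denom = v[:, None] + v[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, 2.0 * cov / denom, 0.0)
    if undefined:
        idx = [ids.index(u) for u in undefined]
        rho[idx, :] = 0.0
        rho[:, idx] = 0.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationNetwork("rho", ids, rho, None,
                              notes={"undefined": undefined} if undefined else {})


# ---------------------------------------------------------------------------
# pairwise chi-square with simulated p-values
# ---------------------------------------------------------------------------


def _chisq_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    ok = expected > 0
    return float((((obs - expected) ** 2)[ok] / expected[ok]).sum())


def pairwise_chisq(table, permutations: int = 100000,
                   seed: int | None = None) -> pd.DataFrame:
    """Chi-square independence test on each ASV pair's 2 x S contingency.

    p-values by Monte-Carlo simulation of tables with both margins fixed
    (Patefield sampling), Laplace-corrected. Pairs with an all-zero
    margin get p = 1 and are flagged in the ``degenerate`` column.
    """
    counts = _counts_frame(table)
    ids = list(counts.columns)
    if len(ids) < 2:
        raise ValueError("need >= 2 ASVs")
    x = counts.to_numpy(dtype=np.int64).T  # D x S
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            obs = np.vstack([x[i], x[j]])
            row_m = obs.sum(axis=1)
            col_m = obs.sum(axis=0)
            degenerate = row_m.min() == 0 or col_m.max() == 0
            if degenerate:
                rows.append((ids[i], ids[j], 0.0, 1.0, True))
                continue
            keep = col_m > 0  # all-zero sample columns carry no information
            obs_k, col_k = obs[:, keep], col_m[keep]
            total = row_m.sum()
            expected = np.outer(row_m, col_k) / total
            stat = _chisq_stat(obs_k, expected)
            sim = stats.random_table(row_m, col_k).rvs(
                permutations, random_state=rng)
            sim_stats = ((sim - expected) ** 2 / expected).sum(axis=(1, 2))
            k = int((sim_stats >= stat - 1e-9).sum())
            p = (1.0 + k) / (1.0 + permutations)
            rows.append((ids[i], ids[j], stat, p, False))
    return pd.DataFrame(rows, columns=["asv_i", "asv_j", "statistic", "p",
                                       "degenerate"])


# ---------------------------------------------------------------------------
# edit distances
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Unit-cost global edit distance."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def edit_distances(records) -> pd.DataFrame:
    """Symmetric Levenshtein distance matrix over ASV records."""
    records = list(records)
    if any(len(r.sequence) == 0 for r in records):
        raise ValueError("empty sequence")
    ids = [r.id for r in records]
    n = len(ids)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(records[i].sequence,
                                            records[j].sequence)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# neighbourhood statistics
# ---------------------------------------------------------------------------


def neighborhood_stats(network: CorrelationNetwork, focus, candidate):
    """Edge counts and mean raw score from ``candidate`` to a focus set.

    Returns ``(n_pos, n_neg, mean_score)``: counts of significant
    (masked) positive / negative edges between the candidate and focus
    members, and the mean of *raw* scores to all focus members
    (self-pairs excluded).
    """
    focus_idx = [network.index_of(a) for a in focus]
    c = network.index_of(candidate)
    focus_idx = [i for i in focus_idx if i != c]
    if not focus_idx:
        return 0, 0, float("nan")
    scores = network.scores[c, focus_idx]
    masked = network.mask[c, focus_idx]
    n_pos = int((masked & (scores > 0)).sum())
    n_neg = int((masked & (scores < 0)).sum())
    return n_pos, n_neg, float(scores.mean())


def _counts_frame(table) -> pd.DataFrame:
    if hasattr(table, "counts"):
        return table.counts
    return table
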