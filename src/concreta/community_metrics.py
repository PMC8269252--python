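"""Alpha/beta diversity, ordination, and permutation tests.

Alpha diversity: Shannon entropy (base 2 by default) and Faith's
phylogenetic diversity (total branch length spanning a sample's observed
taxa), with rarefaction to a fixed depth beforehand so samples are
comparable.

Beta diversity: Bray-Curtis, Jaccard, and the UniFrac family including
the *generalized* UniFrac of exponent alpha in [0, 1],

    d = sum_i b_i (p_iA + p_iB)^alpha |p_iA - p_iB| / (p_iA + p_iB)
        ---------------------------------------------------------
        sum_i b_i (p_iA + p_iB)^alpha

over branches i with length b_i and descending proportion p in each
sample (alpha = 1 recovers weighted-normalized UniFrac; alpha = 0 moves
toward the unweighted extreme).

Inference on distance matrices: principal-coordinate analysis (negative
eigenvalues reported, not corrected), multi-term PERMANOVA (sequential
and marginal pseudo-F via the McArdle-Anderson partition, p by free
permutation of sample rows), dispersion homogeneity (betadisper-style),
Mantel correlation, a one-sided Welch test of replicate similarity, and
per-ASV occurrence-frequency entropies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import mantel as _skbio_mantel

from .tables_io import AsvTable

UNIFRAC_METRICS = ("unweighted_unifrac", "weighted_unifrac_raw",
                   "weighted_unifrac_normalized", "generalized_unifrac")
NONPHYLO_METRICS = ("bray_curtis", "jaccard")


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity
# ---------------------------------------------------------------------------


def rarefy(table: AsvTable, depth: int = 1000, seed: int | None = None):
    """Subsample each library to exactly ``depth`` reads (no replacement).

    Samples below ``depth`` are dropped and listed rather than erroring.
    Returns ``(rarefied_table, dropped_sample_ids)``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    depths = table.depths()
    keep = [s for s in table.sample_ids if depths[s] >= depth]
    dropped = [s for s in table.sample_ids if depths[s] < depth]
    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts.to_numpy())
    for i, s in enumerate(keep):
        row = sub.counts.iloc[i].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=keep, columns=sub.asv_ids)
    return AsvTable(counts, sub.metadata.copy()), dropped


def shannon(sample_counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p log_base p over nonzero proportions."""
    x = np.asarray(sample_counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero sample")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def faith_pd(sample_counts, tree: TreeNode, asv_ids) -> float:
    """Faith's PD: branch length of the union of root-to-leaf paths."""
    x = np.asarray(sample_counts, dtype=float)
    if (x > 0).sum() == 0:
        raise ValueError("all-zero sample")
    observed = {a for a, c in zip(asv_ids, x) if c > 0}
    leaves = {t.name for t in tree.tips()}
    missing = observed - leaves
    if missing:
        raise ValueError(f"leaf {sorted(missing)[0]!r} not in tree")
    total = 0.0
    for node in tree.postorder(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if tips & observed and node.length:
            total += node.length
    return float(total)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Named symmetric distance matrix over sample ids."""

    metric: str
    ids: list
    data: np.ndarray
    alpha: float | None = None  # generalized-UniFrac exponent

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def to_skbio(self) -> SkbioDM:
        return SkbioDM(self.data, ids=[str(i) for i in self.ids])

    def condensed(self) -> np.ndarray:
        i, j = np.triu_indices(len(self.ids), k=1)
        return self.data[i, j]


def _branch_table(table: AsvTable, tree: TreeNode):
    """Per-sample branch proportions: for each branch, the fraction of a
    sample's reads descending through it."""
    leaves = {t.name for t in tree.tips()}
    present = [a for a in table.asv_ids
               if table.counts[a].sum() > 0 or a in leaves]
    missing = set(a for a in table.asv_ids
                  if table.counts[a].sum() > 0) - leaves
    if missing:
        raise ValueError(f"leaf {sorted(missing)[0]!r} not in tree")
    asv_idx = {a: k for k, a in enumerate(table.asv_ids)}
    props = table.counts.to_numpy(dtype=float)
    props = props / props.sum(axis=1, keepdims=True)
    branch_len = []
    branch_prop = []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        cols = [asv_idx[t] for t in tips if t in asv_idx]
        if not cols:
            continue
        branch_len.append(node.length)
        branch_prop.append(props[:, cols].sum(axis=1))
    return np.asarray(branch_len), np.vstack(branch_prop).T  # (B,), (N, B)


def generalized_unifrac(table: AsvTable, tree: TreeNode,
                        alpha: float = 0.5) -> DistanceMatrix:
    """Generalized UniFrac distance with exponent ``alpha`` in [0, 1]."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    b, p = _branch_table(table, tree)
    n = p.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = p[i] + p[j]
            nz = tot > 0
            w = b[nz] * tot[nz] ** alpha
            num = (w * np.abs(p[i, nz] - p[j, nz]) / tot[nz]).sum()
            den = w.sum()
            d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(f"generalized_unifrac", list(table.sample_ids), d,
                          alpha=alpha)


def distance_matrix(table: AsvTable, metric: str, tree: TreeNode | None = None,
                    alpha: float = 0.5) -> DistanceMatrix:
    """Dispatch to the named beta-diversity metric.

    UniFrac-family metrics require a rooted tree covering the observed
    ASVs; Jaccard works on presence/absence; proportions are computed per
    sample for the abundance-weighted metrics.
    """
    ids = [str(s) for s in table.sample_ids]
    counts = table.counts.to_numpy(dtype=float)
    if metric in ("bray_curtis", "braycurtis"):
        dm = beta_diversity("braycurtis", counts, ids=ids)
        data = dm.data
    elif metric == "jaccard":
        dm = beta_diversity("jaccard", (counts > 0).astype(int), ids=ids)
        data = dm.data
    elif metric in UNIFRAC_METRICS:
        if tree is None:
            raise ValueError(f"metric {metric!r} requires a phylogeny")
        if metric == "generalized_unifrac":
            return generalized_unifrac(table, tree, alpha)
        skbio_metric = {"unweighted_unifrac": "unweighted_unifrac",
                        "weighted_unifrac_raw": "weighted_unifrac",
                        "weighted_unifrac_normalized": "weighted_unifrac"}[metric]
        kwargs = {}
        if metric.startswith("weighted"):
            kwargs["normalized"] = metric == "weighted_unifrac_normalized"
        dm = beta_diversity(
            skbio_metric, counts.astype(int), ids=ids, tree=tree,
            taxa=table.asv_ids, **kwargs,
        )
        data = dm.data
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(metric, list(table.sample_ids), np.asarray(data))


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(d: DistanceMatrix):
    """Principal-coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower-centred matrix; axes ordered by
    eigenvalue; negative eigenvalues are reported as-is (their axes get
    zero coordinates). Returns (coordinates DataFrame, eigenvalues,
    proportion_explained).
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("PCoA needs >= 3 samples")
    g = _gower_center(d.data)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = np.zeros_like(evecs)
    pos = evals > 1e-12
    coords[:, pos] = evecs[:, pos] * np.sqrt(evals[pos])
    prop = np.where(evals > 0, evals, 0.0)
    prop = prop / prop.sum() if prop.sum() > 0 else prop
    cols = [f"PC{k + 1}" for k in range(n)]
    return (pd.DataFrame(coords, index=d.ids, columns=cols), evals, prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    mode: str                  # "sequential" | "marginal"
    permutations: int
    table: pd.DataFrame        # per term: df, R2, F, p
    total_ss: float
    residual_df: int


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    col = metadata[term]
    if col.isna().any():
        raise ValueError(f"term {term!r} has missing values")
    if col.dtype == object or str(col.dtype) == "category":
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"constant term column {term!r}")
        return pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
    x = col.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"constant term column {term!r}")
    return x[:, None]


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10).sum())
    return q[:, :rank] @ q[:, :rank].T


def _permanova_stats(g: np.ndarray, term_cols: list, mode: str):
    """Sum-of-squares partition and pseudo-F per term on a centred G."""
    n = g.shape[0]
    intercept = np.ones((n, 1))
    total_ss = float(np.trace(g))
    x_full = np.hstack([intercept] + term_cols)
    h_full = _hat(x_full)
    rank_full = int(round(np.trace(h_full)))
    resid_df = n - rank_full
    resid_ss = float(np.trace((np.eye(n) - h_full) @ g))
    ss, dfs = [], []
    for k in range(len(term_cols)):
        if mode == "sequential":
            x_prev = np.hstack([intercept] + term_cols[:k])
            x_with = np.hstack([intercept] + term_cols[: k + 1])
        elif mode == "marginal":
            others = [c for i, c in enumerate(term_cols) if i != k]
            x_prev = np.hstack([intercept] + others)
            x_with = x_full
        else:
            raise ValueError(f"unknown mode {mode!r}")
        h_prev, h_with = _hat(x_prev), _hat(x_with)
        ss_k = float(np.trace((h_with - h_prev) @ g))
        df_k = int(round(np.trace(h_with) - np.trace(h_prev)))
        if df_k == 0:
            raise ValueError("rank-deficient design: aliased term "
                             f"(index {k})")
        ss.append(ss_k)
        dfs.append(df_k)
    fstats = [(s / d) / (resid_ss / resid_df) for s, d in zip(ss, dfs)]
    return np.array(ss), np.array(dfs), np.array(fstats), resid_ss, resid_df, \
        total_ss


def permanova(d: DistanceMatrix, metadata: pd.DataFrame, terms,
              mode: str = "sequential", permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """Multi-term PERMANOVA (McArdle-Anderson) on a distance matrix.

    ``terms`` are metadata column names entered in order (Type-I when
    sequential; each term last when marginal). p-values by free
    permutation of sample rows of the Gower-centred matrix,
    Laplace-corrected.
    """
    md = metadata.loc[d.ids]
    term_cols = [_design_columns(md, t) for t in terms]
    g = _gower_center(d.data)
    ss, dfs, f_obs, resid_ss, resid_df, total_ss = _permanova_stats(
        g, term_cols, mode)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(permutations):
        perm = rng.permutation(len(d.ids))
        gp = g[np.ix_(perm, perm)]
        _, _, f_p, _, _, _ = _permanova_stats(gp, term_cols, mode)
        exceed += f_p >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + permutations)
    out = pd.DataFrame({
        "term": list(terms), "df": dfs, "SumOfSqs": ss,
        "R2": ss / total_ss, "F": f_obs, "p": pvals,
    }).set_index("term")
    return PermanovaResult(mode, permutations, out, total_ss, resid_df)


def betadisper(d: DistanceMatrix, groups, permutations: int = 999,
               seed: int | None = None):
    """Homogeneity of multivariate dispersion around group centroids.

    Distances to centroids are computed in the full PCoA space; axes
    with negative eigenvalues contribute *negatively* to the squared
    distance. Returns (per-sample distances Series, F statistic,
    permutation p).
    """
    groups = pd.Series(groups, index=d.ids) if not isinstance(groups, pd.Series) \
        else groups.loc[d.ids]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError(f"singleton group {counts.idxmin()!r}")
    n = len(d.ids)
    g = _gower_center(d.data)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.abs(evals) > 1e-10
    axes = evecs[:, keep] * np.sqrt(np.abs(evals[keep]))
    sign = np.sign(evals[keep])
    dist = np.zeros(n)
    for grp, members in groups.groupby(groups).groups.items():
        idx = [list(d.ids).index(m) for m in members]
        centroid = axes[idx].mean(axis=0)
        diff = axes[idx] - centroid
        z2 = (sign * diff ** 2).sum(axis=1)
        dist[idx] = np.sqrt(np.maximum(z2, 0.0))
    dist = pd.Series(dist, index=d.ids, name="dist_to_centroid")

    def _fstat(values):
        grand = values.mean()
        ssb = sum(len(ix) * (values[list(ix)].mean() - grand) ** 2
                  for ix in _group_indices(groups, d.ids))
        ssw = sum(((values[list(ix)] - values[list(ix)].mean()) ** 2).sum()
                  for ix in _group_indices(groups, d.ids))
        k = len(counts)
        if ssw == 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (k - 1)) / (ssw / (n - k))

    vals = dist.to_numpy()
    f_obs = _fstat(vals)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        f_p = _fstat(vals[rng.permutation(n)])
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + permutations)
    return dist, float(f_obs), float(p)


def _group_indices(groups: pd.Series, ids):
    pos = {s: i for i, s in enumerate(ids)}
    for _, members in groups.groupby(groups).groups.items():
        yield [pos[m] for m in members]


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "pearson",
           permutations: int = 999, seed: int | None = None):
    """Mantel correlation between two distance matrices."""
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must cover the same samples")
    rng_seed = int(np.random.default_rng(seed).integers(0, 2 ** 31 - 1))
    np.random.seed(rng_seed)  # skbio's permutation draws use global state
    r, p, _ = _skbio_mantel(d1.to_skbio(), d2.to_skbio(), method=method,
                            permutations=permutations)
    return float(r), float(p)


def replicate_similarity_test(d: DistanceMatrix, replicate_groups):
    """Are replicate extractions more similar than unrelated samples?

    Similarities 1 - d are split into within-replicate-group and
    between-group pairs; one-sided Welch's t (within > between).
    Returns (mean_within, mean_between, p).
    """
    groups = pd.Series(replicate_groups, index=d.ids) \
        if not isinstance(replicate_groups, pd.Series) \
        else replicate_groups.loc[d.ids]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 replicate groups")
    sim = 1.0 - d.data
    ids = list(d.ids)
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            (within if groups.iloc[i] == groups.iloc[j] else between).append(
                sim[i, j])
    if not within or not between:
        raise ValueError("degenerate replicate structure")
    res = stats.ttest_ind(within, between, equal_var=False,
                          alternative="greater")
    return float(np.mean(within)), float(np.mean(between)), float(res.pvalue)


def occurrence_entropy(table: AsvTable, groups, base: float = 2.0):
    """Per-ASV occurrence-frequency distribution over groups + entropy.

    The occurrence frequency of an ASV in each group (fraction of that
    group's samples where it is present) is normalized to sum 1; its
    Shannon entropy measures how evenly the ASV spreads across groups.
    ASVs absent everywhere get NaN entropy.
    """
    groups = pd.Series(groups, index=table.sample_ids) \
        if not isinstance(groups, pd.Series) else groups.loc[table.sample_ids]
    present = table.counts > 0
    freq = present.groupby(groups.values).mean()  # groups x ASVs
    freq = freq.T  # ASVs x groups
    totals = freq.sum(axis=1)
    rel = freq.div(totals.replace(0, np.nan), axis=0)
    ent = rel.apply(
        lambda row: np.nan if row.isna().all() else
        float(-(row[row > 0] * np.log(row[row > 0])).sum() / np.log(base)),
        axis=1)
    return rel, ent
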