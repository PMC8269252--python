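"""Multi-stage contaminant classification for low-biomass 16S tables.

In low-biomass samples (nanogram-scale DNA), reagent and laboratory
contaminant DNA can rival the genuine signal. The classifier combines,
in order,

1. a prevalence test — is an ASV statistically more likely to be seen in
   negative-control extractions than in real samples? (2x2 one-sided
   test at a deliberately permissive probability threshold);
2. reagent-contaminant rules — a core cluster of mutually positively
   correlated ASVs observed in negative controls, expanded by screening
   every other ASV's co-occurrence neighbourhood against the core;
   plus the strict negatives-only rule;
3. laboratory-contaminant rules — ASVs nearly identical (> 99% global
   identity) to known laboratory strains, expanded by correlation;
4. a secondary screen of every remaining ASV against the master list of
   contaminants identified so far; and
5. edit-distance propagation — single-substitution sequence variants of
   identified contaminants inherit their parent's classification
   (residual sequencing error produces such satellites).

An ASV's *category* is its first flagging stage; the set of methods that
flagged it (``flagged_by``) accumulates across stages, supporting
Euler-plot-style overlap accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cooccurrence import CorrelationNetwork, edit_distances, levenshtein, \
    neighborhood_stats
from .tables_io import AsvTable

CATEGORIES = ("prevalence", "reagent_core", "reagent_expanded", "negative_only",
              "lab_seed", "lab_expanded", "secondary", "edit_neighbor")

STAGE_OF = {"prevalence": 1, "reagent_core": 2, "negative_only": 2,
            "reagent_expanded": 2, "lab_seed": 3, "lab_expanded": 3,
            "secondary": 4, "edit_neighbor": 5}


@dataclass
class ContaminantCall:
    """Per-ASV verdict of the decontamination pipeline."""

    asv_id: str
    verdict: str = "retained"          # "retained" | "contaminant"
    category: str | None = None        # first flagging stage
    flagged_by: set = field(default_factory=set)
    stage: int | None = None
    parent: str | None = None          # edit-neighbour match
    inherited_category: str | None = None
    p_prevalence: float | None = None

    def flag(self, category: str, methods) -> None:
        if self.verdict == "retained":
            self.verdict = "contaminant"
            self.category = category
            self.stage = STAGE_OF[category]
        self.flagged_by |= set(methods)


@dataclass
class MetricRule:
    """Strict-inequality thresholds on a candidate's neighbourhood stats.

    Any of the three components may be None (not required); all present
    components must hold (printed rules read as conjunctions).
    """

    min_net_pos: int | float | None = None   # n_pos - n_neg > this
    min_pos: int | float | None = None       # n_pos > this
    min_mean: float | None = None            # mean raw score > this

    def satisfied(self, n_pos: int, n_neg: int, mean: float) -> bool:
        if self.min_net_pos is not None and not (n_pos - n_neg > self.min_net_pos):
            return False
        if self.min_pos is not None and not (n_pos > self.min_pos):
            return False
        if self.min_mean is not None:
            if math.isnan(mean) or not (mean > self.min_mean):
                return False
        return True


def _default_rules():
    return {
        "reagent_core": {"sparcc": MetricRule(min_net_pos=0, min_mean=0.3),
                         "rho": MetricRule(min_net_pos=0)},
        "reagent": {"sparcc": MetricRule(min_pos=10, min_mean=0.25),
                    "rho": MetricRule(min_net_pos=0)},
        "lab": {"sparcc": MetricRule(min_pos=1, min_mean=0.3),
                "rho": MetricRule(min_pos=0)},
        "secondary": {"sparcc": MetricRule(min_pos=5, min_mean=0.3),
                      "rho": MetricRule(min_pos=1, min_mean=0.3)},
    }


@dataclass
class DecontamRules:
    """All cutoffs of the classifier (printed ">" symbols are strict)."""

    prevalence_threshold: float = 0.33
    lab_min_identity: float = 0.99
    edit_distance_max: int = 1
    transitive_edit_propagation: bool = False
    rules: dict = field(default_factory=_default_rules)

    def rule_for(self, rule_set: str, metric: str) -> MetricRule | None:
        if rule_set not in self.rules:
            raise ValueError(f"unknown rule_set {rule_set!r}")
        return self.rules[rule_set].get(metric)


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------


def prevalence_test(table: AsvTable, is_negative=None,
                    threshold: float = 0.33) -> pd.DataFrame:
    """One-sided 2x2 test for enrichment of presence in negative controls.

    Per ASV a presence/absence x negative/sample table is built; the
    one-sided p (Fisher's exact when any expected cell < 5, chi-square
    without continuity correction otherwise) is compared to the
    permissive decision threshold. Returns a DataFrame indexed by ASV
    with columns ``p`` and ``flagged``.
    """
    neg = table.is_negative() if is_negative is None else \
        table.metadata.index.to_series().apply(is_negative).astype(bool)
    n_neg = int(neg.sum())
    n_smp = int((~neg).sum())
    if n_neg == 0:
        raise ValueError("prevalence test undefined without negative controls")
    if n_smp == 0:
        raise ValueError("prevalence test undefined without non-negative samples")
    present = table.counts.to_numpy() > 0
    neg_mask = neg.to_numpy()
    a = present[neg_mask].sum(axis=0)       # present in negatives
    c = present[~neg_mask].sum(axis=0)      # present in samples
    pvals = np.ones(table.n_asvs)
    total = n_neg + n_smp
    for k in range(table.n_asvs):
        tab = np.array([[a[k], c[k]], [n_neg - a[k], n_smp - c[k]]], dtype=float)
        row = tab.sum(axis=1)
        col = tab.sum(axis=0)
        if row.min() == 0:  # present everywhere or nowhere: no direction
            pvals[k] = 1.0
            continue
        expected = np.outer(row, col) / total
        if (expected < 5).any():
            # exact hypergeometric upper tail on presence in negatives
            pvals[k] = stats.hypergeom.sf(a[k] - 1, total, a[k] + c[k], n_neg)
        else:
            stat = ((tab - expected) ** 2 / expected).sum()
            p_two = stats.chi2.sf(stat, df=1)
            if a[k] / n_neg > c[k] / n_smp:
                pvals[k] = p_two / 2.0
            else:
                pvals[k] = 1.0 - p_two / 2.0
    return pd.DataFrame({"p": pvals, "flagged": pvals <= threshold},
                        index=table.asv_ids)


def negative_only(table: AsvTable) -> set:
    """ASVs seen in >= 1 negative control and in no other sample."""
    neg = table.is_negative().to_numpy()
    counts = table.counts.to_numpy()
    in_neg = counts[neg].sum(axis=0) > 0
    in_smp = counts[~neg].sum(axis=0) > 0
    return {a for a, x, y in zip(table.asv_ids, in_neg, in_smp) if x and not y}


def core_reagent_cluster(networks: dict, neg_asvs, rules: DecontamRules) -> dict:
    """Per-metric core of mutually correlated negative-control ASVs.

    For each metric independently, a member of ``neg_asvs`` joins the
    core when its neighbourhood statistics against the *other* members
    satisfy that metric's core rule.
    """
    neg_asvs = [a for a in neg_asvs]
    out = {}
    for metric, net in networks.items():
        rule = rules.rule_for("reagent_core", metric)
        if rule is None:
            continue
        core = set()
        if len(neg_asvs) < 2:
            import warnings
            warnings.warn("fewer than 2 negative-control ASVs; empty core")
            out[metric] = core
            continue
        for a in neg_asvs:
            others = [b for b in neg_asvs if b != a]
            n_pos, n_neg, mean = neighborhood_stats(net, others, a)
            if rule.satisfied(n_pos, n_neg, mean):
                core.add(a)
        out[metric] = core
    return out


def expand_from_seeds(networks: dict, seeds, rule_set: str,
                      rules: DecontamRules) -> dict:
    """Candidates whose neighbourhood against ``seeds`` fires a rule.

    Every non-seed ASV of each network is evaluated under that metric's
    rule for ``rule_set``; returns ``{asv_id: {metrics that fired}}``,
    whose key set is the union of hits over metrics.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("expand_from_seeds requires non-empty seeds")
    hits: dict[str, set] = {}
    for metric, net in networks.items():
        rule = rules.rule_for(rule_set, metric)
        if rule is None:
            continue
        seed_list = [a for a in seeds if a in net.asv_ids]
        if not seed_list:
            continue
        for a in net.asv_ids:
            if a in seeds:
                continue
            n_pos, n_neg, mean = neighborhood_stats(net, seed_list, a)
            if rule.satisfied(n_pos, n_neg, mean):
                hits.setdefault(a, set()).add(metric)
    return hits


def lab_seeds(records, lab_reference, min_identity: float = 0.99) -> set:
    """ASVs whose best global identity to a lab strain exceeds the cutoff.

    Identity is 1 - Levenshtein / max(length); the comparison is strict.
    """
    if not lab_reference:
        import warnings
        warnings.warn("empty lab reference; no lab seeds")
        return set()
    hits = set()
    for rec in records:
        for ref in lab_reference:
            dist = levenshtein(rec.sequence, ref.sequence)
            ident = 1.0 - dist / max(len(rec.sequence), len(ref.sequence))
            if ident > min_identity:
                hits.add(rec.id)
                break
    return hits


def propagate_edit_neighbors(calls: dict, edit_matrix: pd.DataFrame,
                             max_dist: int = 1, transitive: bool = False) -> set:
    """Flag retained ASVs within ``max_dist`` edits of a contaminant.

    Single pass by default (neighbours of the *pre-propagation* set);
    ties broken by smallest distance then lexicographically smallest
    parent id. Mutates ``calls`` in place and returns the newly flagged
    ids.
    """
    newly = set()
    while True:
        contaminants = sorted(a for a, c in calls.items()
                              if c.verdict == "contaminant")
        batch = []
        for a, call in calls.items():
            if call.verdict != "retained" or a not in edit_matrix.index:
                continue
            dists = edit_matrix.loc[a, contaminants]
            near = dists[dists <= max_dist]
            if near.empty:
                continue
            dmin = near.min()
            parent = sorted(near[near == dmin].index)[0]
            batch.append((a, parent))
        for a, parent in batch:
            call = calls[a]
            call.flag("edit_neighbor", calls[parent].flagged_by | {"edit_distance"})
            call.parent = parent
            call.inherited_category = calls[parent].category
            newly.add(a)
        if not transitive or not batch:
            break
    return newly


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def run_decontamination(table: AsvTable, records, networks: dict,
                        lab_reference, rules: DecontamRules | None = None,
                        tree=None, edit_matrix: pd.DataFrame | None = None):
    """Apply every stage in order and assemble calls, clean table, report.

    ``networks`` maps metric name ("sparcc", "rho") to its
    :class:`~concreta.cooccurrence.CorrelationNetwork`. ``tree`` is
    accepted for interface symmetry but unused by the rules.
    """
    rules = rules or DecontamRules()
    for metric, net in networks.items():
        missing = set(table.asv_ids) - set(net.asv_ids)
        if missing:
            raise ValueError(f"{metric} network missing ASVs, e.g. "
                             f"{sorted(missing)[0]!r}")
    calls = {a: ContaminantCall(a) for a in table.asv_ids}

    # stage 1: prevalence
    prev = prevalence_test(table, threshold=rules.prevalence_threshold)
    for a in table.asv_ids:
        calls[a].p_prevalence = float(prev.loc[a, "p"])
        if prev.loc[a, "flagged"]:
            calls[a].flag("prevalence", {"decontam_prevalence"})

    # stage 2: reagent contamination
    neg = table.is_negative().to_numpy()
    observed_in_neg = [a for a, x in zip(table.asv_ids,
                                         table.counts.to_numpy()[neg].sum(axis=0))
                       if x > 0]
    cores = core_reagent_cluster(networks, observed_in_neg, rules)
    for metric in sorted(cores):
        for a in cores[metric]:
            calls[a].flag("reagent_core", {metric})
    for a in negative_only(table):
        calls[a].flag("negative_only", {"negative_only"})
    reagent_seed_set = set().union(*cores.values()) if cores else set()
    if reagent_seed_set:
        for a, metrics in expand_from_seeds(networks, reagent_seed_set,
                                            "reagent", rules).items():
            calls[a].flag("reagent_expanded", metrics)

    # stage 3: laboratory contamination
    seeds = lab_seeds(records, lab_reference, rules.lab_min_identity)
    for a in seeds:
        if a in calls:
            calls[a].flag("lab_seed", {"blast_identity"})
    lab_seed_in_table = seeds & set(table.asv_ids)
    if lab_seed_in_table:
        for a, metrics in expand_from_seeds(networks, lab_seed_in_table,
                                            "lab", rules).items():
            calls[a].flag("lab_expanded", metrics)

    # stage 4: secondary screen of the remaining ASVs vs the master list
    master = {a for a, c in calls.items() if c.verdict == "contaminant"}
    if master:
        for a, metrics in expand_from_seeds(networks, master, "secondary",
                                            rules).items():
            if calls[a].verdict == "retained":
                calls[a].flag("secondary", metrics)

    # stage 5: edit-distance propagation
    if edit_matrix is None:
        edit_matrix = edit_distances([r for r in records
                                      if r.id in set(table.asv_ids)])
    propagate_edit_neighbors(calls, edit_matrix, rules.edit_distance_max,
                             rules.transitive_edit_propagation)

    contaminants = [a for a in table.asv_ids
                    if calls[a].verdict == "contaminant"]
    clean_table = table.drop_asvs(contaminants)
    report = _summarize(calls, table)
    return list(calls.values()), clean_table, report


def _summarize(calls: dict, table: AsvTable) -> dict:
    by_category: dict[str, int] = {}
    by_method: dict[str, int] = {}
    overlap: dict[str, int] = {}
    for c in calls.values():
        if c.verdict != "contaminant":
            continue
        by_category[c.category] = by_category.get(c.category, 0) + 1
        for m in c.flagged_by:
            by_method[m] = by_method.get(m, 0) + 1
        key = "+".join(sorted(c.flagged_by))
        overlap[key] = overlap.get(key, 0) + 1
    n_contam = sum(1 for c in calls.values() if c.verdict == "contaminant")
    return {
        "n_asvs": table.n_asvs,
        "n_contaminants": n_contam,
        "n_retained": table.n_asvs - n_contam,
        "by_category": by_category,
        "by_method": by_method,
        "method_overlap": overlap,
    }


def calls_frame(calls) -> pd.DataFrame:
    """Serializable view of the calls (one row per ASV)."""
    rows = []
    for c in calls:
        rows.append((c.asv_id, c.verdict, c.category or "",
                     ",".join(sorted(c.flagged_by)), c.parent or "",
                     c.inherited_category or "", c.p_prevalence))
    return pd.DataFrame(rows, columns=["asv_id", "verdict", "category",
                                       "flagged_by", "parent",
                                       "inherited_category", "p_prevalence"])
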