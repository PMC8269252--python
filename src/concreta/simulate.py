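"""Synthetic longitudinal low-biomass 16S studies with full ground truth.

Emulates the design of a two-series concrete weathering experiment: 15
time points x 2 series (ASR-reactive vs ASR-mitigated) x 3 replicates of
concrete, triplicate precursor materials (gravel, sand, cement powder,
fly ash, water), and triplicate negative-control extractions — 105
samples. The generator plants, with known labels,

* a *true* community mixed per-series from partially disjoint precursor
  source profiles plus an "unknown" environmental profile,
* reagent contaminants present in every negative-control library and,
  diluted by a per-sample contaminant load, in real samples,
* lab contaminants sharing a latent log-normal batch factor (hence
  strongly mutually correlated), a subset copied at >=99% identity from
  a reference FASTA of laboratory strains,
* single-substitution edit variants of contaminants, and
* reactive-series indicator taxa whose presence probability rises with
  months through a logistic link.

Expected richness of the true community declines linearly with months
and is modulated upward in warm (summer) months; counts are drawn
Dirichlet-multinomial at log-normally distributed library sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import METADATA_COLUMNS, AsvRecord, AsvTable

PRECURSORS = ("gravel", "sand", "cement", "fly_ash", "water")
#: water feeds the mixture but is not sampled (no amplicon data for it in
#: the emulated design), so emitted precursor samples cover four materials
SAMPLED_PRECURSORS = ("gravel", "sand", "cement", "fly_ash")
SOURCES = PRECURSORS + ("unknown",)

#: study start (day-of-year of the first pour, early May) and series span
START_DOY = 122.0
SPAN_MONTHS = 21.0
DAYS_PER_MONTH = 365.25 / 12.0


def _check_weights(w: dict) -> None:
    if set(w) != set(SOURCES):
        raise ValueError(f"source_weights keys must be {SOURCES}, got {sorted(w)}")
    vals = np.array([w[s] for s in SOURCES], dtype=float)
    if (vals < 0).any():
        raise ValueError("source_weights must be non-negative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"source_weights must sum to 1 (got {vals.sum():.12f})")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_timepoints: int = 15
    n_series: int = 2
    n_replicates: int = 3
    n_negatives: int = 3
    n_precursor_replicates: int = 3
    n_true_asvs: int = 120
    n_reagent_contaminants: int = 25
    n_lab_contaminants: int = 15
    n_edit_variants: int = 10
    n_lab_strains: int = 5
    n_negative_only: int = 5  # reagent contaminants never seen outside negatives
    n_indicators: int = 8
    source_weights: dict = field(default_factory=lambda: {
        "reactive": {"gravel": 0.32, "sand": 0.02, "cement": 0.14,
                     "fly_ash": 0.07, "water": 0.06, "unknown": 0.39},
        "mitigated": {"gravel": 0.25, "sand": 0.02, "cement": 0.18,
                      "fly_ash": 0.12, "water": 0.06, "unknown": 0.37},
    })
    diversity_decay_rate: float = 0.03   # fraction of expected richness lost / month
    seasonal_amplitude: float = 0.15     # richness modulation per sd of temperature
    library_size_log_mean: float = 10.8  # exp(10.8) ~ 49k reads
    library_size_log_sd: float = 0.4
    contaminant_load_fraction: float = 0.85
    load_logit_sd: float = 1.0           # sample-to-sample spread of the load
    lab_batch_log_sd: float = 0.8        # shared log-normal factor of lab ASVs
    dirichlet_concentration: float = 500.0
    sequence_length: int = 420
    indicator_slope: float = 0.35        # per-month logit increase in reactive series
    seed: int | None = None

    def validate(self) -> None:
        counts = {
            "n_timepoints": self.n_timepoints, "n_series": self.n_series,
            "n_replicates": self.n_replicates, "n_negatives": self.n_negatives,
            "n_precursor_replicates": self.n_precursor_replicates,
            "n_true_asvs": self.n_true_asvs,
            "n_reagent_contaminants": self.n_reagent_contaminants,
            "n_lab_contaminants": self.n_lab_contaminants,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        if self.n_edit_variants < 0:
            raise ValueError("n_edit_variants must be >= 0")
        if self.seed is None:
            raise ValueError("seed is required (reproducibility contract)")
        if not (0 <= self.contaminant_load_fraction < 1):
            raise ValueError("contaminant_load_fraction must be in [0, 1)")
        if self.n_reagent_contaminants + self.n_lab_contaminants > self.n_true_asvs:
            raise ValueError(
                "contaminant counts exceed n_true_asvs; truth labels ill-posed"
            )
        if self.n_series > 2:
            raise ValueError("at most two series (reactive, mitigated) supported")
        for series in list(self.source_weights)[: self.n_series]:
            _check_weights(self.source_weights[series])


@dataclass
class GroundTruth:
    """Planted labels and parameters accompanying a synthetic study."""

    labels: dict            # asv_id -> "true_community" | "reagent_contaminant"
                            #           | "lab_contaminant" | "edit_variant"
    variant_parents: dict   # edit-variant asv_id -> parent contaminant id
    negative_only: list     # reagent ASVs with zero counts outside negatives
    lab_seed_asvs: list     # lab ASVs copied (>=99% id) from the reference FASTA
    source_mixtures: dict   # concrete sample id -> {source: true weight}
    indicator_asvs: list    # taxa with rising reactive-series prevalence
    temporal_params: dict   # decay rate, seasonal amplitude, indicator slope,
                            # temperature peak day-of-year

    def contaminants(self) -> set:
        return {a for a, lab in self.labels.items() if lab != "true_community"}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _substitute(rng, seq: str, n_subs: int) -> str:
    """Exactly n_subs substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def temperature_at(months: np.ndarray, rng=None, noise_sd: float = 1.5):
    """30-day mean temperature (deg C): annual sinusoid peaking ~day 200."""
    doy = (START_DOY + np.asarray(months, dtype=float) * DAYS_PER_MONTH) % 365.25
    temp = 13.0 + 11.0 * np.sin(2 * np.pi * (doy - 110.0) / 365.25)
    if rng is not None and noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, size=np.shape(temp))
    return temp, doy


def generate_tree(n_leaves: int, seed: int, leaf_names=None) -> TreeNode:
    """Random rooted binary tree with exponential branch lengths.

    Leaves are named ``ASV0001``.. unless ``leaf_names`` is given.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    if leaf_names is None:
        leaf_names = [f"ASV{i + 1:04d}" for i in range(n_leaves)]
    if len(leaf_names) != n_leaves:
        raise ValueError("leaf_names length must equal n_leaves")
    nodes = []
    for name in leaf_names:
        leaf = TreeNode(name=name)
        leaf.length = float(rng.exponential(0.1)) + 1e-9
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.1)) + 1e-9
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _build_profiles(rng, cfg: SimulationConfig, asv_ids):
    """Dirichlet base profiles over partially disjoint true-taxon subsets."""
    n = cfg.n_true_asvs
    n_sources = len(SOURCES)
    n_excl = max(1, int(0.6 * n / n_sources))
    profiles = {}
    support = {}
    shared = list(range(n_excl * n_sources, n))
    for k, src in enumerate(SOURCES):
        idx = list(range(k * n_excl, (k + 1) * n_excl)) + shared
        support[src] = idx
        base = np.zeros(n)
        base[idx] = rng.dirichlet(np.full(len(idx), 0.8))
        profiles[src] = base
    return profiles, support


def generate_study(config: SimulationConfig):
    """Generate one synthetic study.

    Returns ``(table, records, tree, lab_reference, truth)`` where
    ``records`` are the ASV representative sequences and
    ``lab_reference`` the known-laboratory-strain FASTA records.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_true = cfg.n_true_asvs
    n_reag = cfg.n_reagent_contaminants
    n_lab = cfg.n_lab_contaminants
    n_var = cfg.n_edit_variants

    true_ids = [f"ASV{i + 1:04d}" for i in range(n_true)]
    reagent_ids = [f"REAG{i + 1:03d}" for i in range(n_reag)]
    lab_ids = [f"LAB{i + 1:03d}" for i in range(n_lab)]
    variant_ids = [f"VAR{i + 1:03d}" for i in range(n_var)]
    asv_ids = true_ids + reagent_ids + lab_ids + variant_ids

    # ---- sequences -------------------------------------------------------
    lab_reference = [
        AsvRecord(f"LABSTRAIN{i + 1:02d}", _random_dna(rng, cfg.sequence_length))
        for i in range(cfg.n_lab_strains)
    ]
    seqs: dict[str, str] = {}
    for a in true_ids + reagent_ids:
        seqs[a] = _random_dna(rng, cfg.sequence_length)
    n_seed = min(cfg.n_lab_strains, n_lab)
    lab_seed_asvs = lab_ids[:n_seed]
    for i, a in enumerate(lab_ids):
        if i < n_seed:  # copy from reference at >=99% identity (<=3 edits)
            seqs[a] = _substitute(rng, lab_reference[i].sequence,
                                  int(rng.integers(0, 4)))
        else:
            seqs[a] = _random_dna(rng, cfg.sequence_length)
    contaminant_pool = reagent_ids + lab_ids
    variant_parents = {}
    for i, a in enumerate(variant_ids):
        parent = contaminant_pool[int(rng.integers(0, len(contaminant_pool)))]
        variant_parents[a] = parent
        seqs[a] = _substitute(rng, seqs[parent], 1)
    records = [AsvRecord(a, seqs[a]) for a in asv_ids]

    # ---- contaminant profiles -------------------------------------------
    neg_only = set(reagent_ids[:min(cfg.n_negative_only, n_reag)])
    reagent_w = rng.dirichlet(np.full(n_reag, 1.0))
    lab_w = rng.dirichlet(np.full(n_lab, 1.0))
    # edit variants ride inside their parent's profile at 3% of its weight
    reag_var = [v for v in variant_ids if variant_parents[v] in set(reagent_ids)]
    lab_var = [v for v in variant_ids if variant_parents[v] in set(lab_ids)]

    def _contam_profile(ids, weights, variants, exclude=()):
        w = {a: float(x) for a, x in zip(ids, weights)}
        for v in variants:
            w[v] = 0.03 * w[variant_parents[v]]
        for a in exclude:
            w[a] = 0.0
            # their variants vanish with them
        for v in variants:
            if variant_parents[v] in exclude:
                w[v] = 0.0
        vec = np.array([w.get(a, 0.0) for a in asv_ids])
        return vec / vec.sum()

    reagent_profile_neg = _contam_profile(reagent_ids, reagent_w, reag_var)
    reagent_profile_smp = _contam_profile(reagent_ids, reagent_w, reag_var,
                                          exclude=neg_only)
    lab_profile = _contam_profile(lab_ids, lab_w, lab_var)

    # ---- true-community profiles ----------------------------------------
    profiles, _ = _build_profiles(rng, cfg, true_ids)
    series_names = ["reactive", "mitigated"][: cfg.n_series]
    mix = {}
    for s in series_names:
        w = cfg.source_weights[s]
        mix[s] = sum(w[src] * profiles[src] for src in SOURCES)
    indicator_asvs = list(rng.choice(true_ids, size=min(cfg.n_indicators, n_true),
                                     replace=False))
    robustness = rng.uniform(0.0, 1.0, size=n_true)  # nested extinction order

    months = np.linspace(0.0, SPAN_MONTHS, cfg.n_timepoints)
    temps, _doy = temperature_at(months, rng)
    temp_z = (temps - temps.mean()) / (temps.std() + 1e-12)

    # ---- assemble samples -----------------------------------------------
    idx_of = {a: i for i, a in enumerate(asv_ids)}
    true_idx = np.array([idx_of[a] for a in true_ids])
    ind_idx = np.array([idx_of[a] for a in indicator_asvs], dtype=int)

    rows, sample_ids, meta_rows = [], [], []
    source_mixtures = {}

    def _dirichlet_theta(profile):
        """One realized composition around a base profile (overdispersion
        applied per community component, not to the blended library)."""
        alpha = cfg.dirichlet_concentration * profile
        pos = alpha > 0
        theta = np.zeros_like(profile)
        theta[pos] = rng.dirichlet(alpha[pos])
        return theta

    def _library_size(shift=0.0):
        return max(1000, int(rng.lognormal(cfg.library_size_log_mean + shift,
                                           cfg.library_size_log_sd)))

    def _contaminated(true_profile):
        """Realized sample composition: true community blended with
        reagent + lab contaminant mass at a drawn per-sample load."""
        theta_true = _dirichlet_theta(true_profile)
        if cfg.contaminant_load_fraction == 0.0:
            return theta_true, 0.0
        logit = math.log(cfg.contaminant_load_fraction /
                         (1 - cfg.contaminant_load_fraction))
        c = 1.0 / (1.0 + math.exp(-(logit + rng.normal(0.0, cfg.load_logit_sd))))
        b = rng.lognormal(0.0, cfg.lab_batch_log_sd)  # shared lab batch factor
        contam = 0.7 * _dirichlet_theta(reagent_profile_smp) \
            + 0.3 * b * _dirichlet_theta(lab_profile)
        contam = contam / contam.sum()
        return (1.0 - c) * theta_true + c * contam, c

    # concrete series
    for s_i, series in enumerate(series_names):
        for t_i in range(cfg.n_timepoints):
            mo, temp = months[t_i], temps[t_i]
            alive_frac = np.clip(
                1.0 - cfg.diversity_decay_rate * mo
                + cfg.seasonal_amplitude * temp_z[t_i], 0.05, 1.0)
            alive = robustness < alive_frac
            for r in range(cfg.n_replicates):
                profile = np.zeros(len(asv_ids))
                base = mix[series].copy()
                base[~alive] = 0.0
                # indicator taxa: presence prob rises with months (reactive)
                for k, a in enumerate(indicator_asvs):
                    j = true_ids.index(a)
                    if series == "reactive":
                        p = 1.0 / (1.0 + math.exp(
                            -(-1.5 + cfg.indicator_slope * mo)))
                    else:
                        p = 0.15  # non-degenerate baseline prevalence
                    present = rng.uniform() < p
                    base[j] = 0.004 if present else 0.0
                if base.sum() == 0:
                    base[true_ids.index(indicator_asvs[0])] = 1.0
                base = base / base.sum()
                profile[true_idx] = base
                theta, load = _contaminated(profile)
                lib = _library_size()
                counts = rng.multinomial(lib, theta)
                sid = f"C{series[0].upper()}T{t_i + 1:02d}R{r + 1}"
                rows.append(counts)
                sample_ids.append(sid)
                meta_rows.append(("concrete", series, mo, temp, f"R{r + 1}"))
                source_mixtures[sid] = dict(cfg.source_weights[series])

    # precursor materials (water is not sampled)
    for src in SAMPLED_PRECURSORS:
        for r in range(cfg.n_precursor_replicates):
            profile = np.zeros(len(asv_ids))
            profile[true_idx] = profiles[src]
            theta, _ = _contaminated(profile)
            lib = _library_size(-0.3)
            counts = rng.multinomial(lib, theta)
            sid = f"{src.upper()}R{r + 1}"
            rows.append(counts)
            sample_ids.append(sid)
            meta_rows.append((src, "none", 0.0, temps[0], f"R{r + 1}"))

    # negative controls: reagent mass only; every reagent ASV present
    reag_idx = np.array([idx_of[a] for a in reagent_ids])
    for r in range(cfg.n_negatives):
        lib = _library_size(-1.2)
        lib = max(lib, n_reag + 1)
        counts = np.zeros(len(asv_ids), dtype=np.int64)
        counts[reag_idx] += 1  # guarantee prevalence 1.0 in negatives
        counts += rng.multinomial(lib - n_reag,
                                  _dirichlet_theta(reagent_profile_neg))
        sid = f"NEG{r + 1}"
        rows.append(counts)
        sample_ids.append(sid)
        meta_rows.append(("negative_control", "none", 0.0, temps[0], f"R{r + 1}"))

    counts = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=asv_ids)
    metadata = pd.DataFrame(meta_rows, index=sample_ids,
                            columns=list(METADATA_COLUMNS))
    table = AsvTable(counts, metadata)

    tree = generate_tree(len(asv_ids), int(rng.integers(0, 2 ** 31 - 1)),
                         leaf_names=asv_ids)

    non_neg = ~table.is_negative()
    observed_outside = counts.loc[non_neg.values].sum(axis=0) > 0
    observed_in_neg = counts.loc[~non_neg.values].sum(axis=0) > 0
    realized_neg_only = [a for a in asv_ids
                         if observed_in_neg[a] and not observed_outside[a]]

    labels = {a: "true_community" for a in true_ids}
    labels.update({a: "reagent_contaminant" for a in reagent_ids})
    labels.update({a: "lab_contaminant" for a in lab_ids})
    labels.update({a: "edit_variant" for a in variant_ids})
    truth = GroundTruth(
        labels=labels,
        variant_parents=variant_parents,
        negative_only=realized_neg_only,
        lab_seed_asvs=lab_seed_asvs,
        source_mixtures=source_mixtures,
        indicator_asvs=indicator_asvs,
        temporal_params={
            "diversity_decay_rate": cfg.diversity_decay_rate,
            "seasonal_amplitude": cfg.seasonal_amplitude,
            "indicator_slope": cfg.indicator_slope,
            "temperature_peak_doy": 201.0,
        },
    )
    return table, records, tree, lab_reference, truth
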