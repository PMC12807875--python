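"""Seeded generator of allelic-count datasets with the structure the
analysis assumes.

The generator emulates one clonal NPC-like Dox time course: 379 informative
X-linked genes of which 133 escape (12 constitutive, 84 facultative, 37
clone-specific), Dox induction days {0, 3, 7, 14, 21} with 3/3/3/2/2
biological replicates, and 7-day washout arms after 7, 14 and 21 days of
induction (2 replicates each). Each escapee follows a true trajectory

    r(t) = (r0 - b) * exp(-k * t) + b

and every sample's inactive-X read count is Binomial(total, r(t)) with
per-gene totals drawn around a negative-binomially distributed depth.
Escapees are laid out on one chromosome so that configured clusters satisfy
the 100-kb chaining rule, cluster members share similar decay constants, and
a 19-study literature matrix is generated consistently with each gene's
category. Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError
from .io import condition_label, validate_allelic_counts, validate_sample_sheet

CATEGORY_RANGES = {
    #               r0 range      k range      b range     P(b > 0)
    "constitutive":  ((0.20, 0.60), (0.05, 0.20), (0.10, 0.30), 0.7),
    "facultative":   ((0.12, 0.50), (0.08, 0.80), (0.05, 0.20), 0.2),
    "clone_specific": ((0.12, 0.40), (0.20, 1.00), (0.00, 0.00), 0.0),
}

# fraction (reversible, partially irreversible, irreversible) per induction
# duration; constitutive escapees stay mostly reversible at every duration
REVERSIBILITY_PROBS = {
    7.0: (0.72, 0.12, 0.16),
    14.0: (0.45, 0.12, 0.43),
    21.0: (0.42, 0.12, 0.46),
}
RECOVERY_RANGES = {
    "reversible": (0.60, 1.00),
    "partially_irreversible": (0.15, 0.45),
    "irreversible": (0.00, 0.08),
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic Dox time course."""
    n_genes: int = 379
    category_counts: Mapping[str, int] = field(default_factory=lambda: {
        "constitutive": 12, "facultative": 84, "clone_specific": 37,
    })
    time_grid: tuple = (0.0, 3.0, 7.0, 14.0, 21.0)
    replicates_per_timepoint: Mapping[float, int] = field(
        default_factory=lambda: {0.0: 3, 3.0: 3, 7.0: 3, 14.0: 2, 21.0: 2}
    )
    washout_durations: tuple = (7.0, 14.0, 21.0)
    washout_days: float = 7.0
    washout_replicates: int = 2
    depth_mean: float = 300.0
    depth_dispersion: float = 2.0   # negative-binomial shape across genes
    n_studies: int = 19
    n_clusters: int = 11
    cluster_size_range: tuple = (3, 14)
    cluster_k_sigma: float = 0.15   # log-scale spread of k within a cluster
    within_cluster_gap: tuple = (20_000, 80_000)
    between_entity_gap: tuple = (150_000, 1_200_000)
    n_high_ratio_artifacts: int = 3
    include_xist: bool = True
    xi_haplotype: str = "hap1"
    seed: int = 0

    def n_escapees(self) -> int:
        return sum(self.category_counts.values())

    def validate(self) -> None:
        if self.n_escapees() + self.n_high_ratio_artifacts + int(
            self.include_xist
        ) > self.n_genes:
            raise ConfigurationError(
                "category counts, artifacts and Xist exceed n_genes"
            )
        if any(v < 0 for v in self.category_counts.values()):
            raise ConfigurationError("category counts must be non-negative")
        if not set(self.replicates_per_timepoint) >= set(self.time_grid):
            raise ConfigurationError("every timepoint needs a replicate count")


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    study_matrix: pd.DataFrame
    truth: pd.DataFrame
    truth_reversibility: pd.DataFrame
    truth_ratios: pd.DataFrame
    config: SimulationConfig


def _draw_gene_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for category, count in cfg.category_counts.items():
        (r0_lo, r0_hi), (k_lo, k_hi), (b_lo, b_hi), p_b = CATEGORY_RANGES[category]
        for _ in range(count):
            r0 = rng.uniform(r0_lo, r0_hi)
            k = rng.uniform(k_lo, k_hi)
            b = min(rng.uniform(b_lo, b_hi), 0.8 * r0) if rng.random() < p_b else 0.0
            rows.append((f"gene{idx:04d}", category, r0, k, b))
            idx += 1
    n_silenced = (cfg.n_genes - cfg.n_escapees()
                  - cfg.n_high_ratio_artifacts - int(cfg.include_xist))
    for _ in range(n_silenced):
        r0 = rng.uniform(0.0, 0.05)
        rows.append((f"gene{idx:04d}", "silenced", r0, np.nan, r0))
        idx += 1
    for _ in range(cfg.n_high_ratio_artifacts):
        r0 = rng.uniform(0.85, 0.98)
        rows.append((f"gene{idx:04d}", "artifact_high_ratio", r0, np.nan, r0))
        idx += 1
    if cfg.include_xist:
        rows.append(("Xist", "xist", 0.95, np.nan, 0.95))
    return pd.DataFrame(rows, columns=["gene_id", "category", "r0", "k", "b"])


def _assign_clusters(truth: pd.DataFrame, cfg: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Pick cluster members among escapees and homogenise their k values."""
    truth = truth.copy()
    truth["cluster_id"] = np.nan
    escapees = truth.index[truth["category"].isin(CATEGORY_RANGES)].to_numpy()
    order = rng.permutation(escapees)
    lo, hi = cfg.cluster_size_range
    cursor = 0
    for cluster in range(cfg.n_clusters):
        size = int(rng.integers(lo, hi + 1))
        remaining = len(order) - cursor
        # keep enough escapees outside clusters for singles and pairs
        size = min(size, max(0, remaining - 3 * (cfg.n_clusters - cluster - 1)))
        if size < lo:
            break
        members = order[cursor:cursor + size]
        cursor += size
        cluster_k = rng.uniform(0.08, 0.8)
        ks = cluster_k * np.exp(rng.normal(0.0, cfg.cluster_k_sigma, size))
        truth.loc[members, "k"] = np.clip(ks, 1e-3, 5.0)
        truth.loc[members, "cluster_id"] = cluster + 1
    return truth


def _layout_positions(truth: pd.DataFrame, cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Lay genes on one chromosome: cluster members adjacent and within the
    window; everything else separated by more than the window."""
    entities: list[list[str]] = []
    for cluster, sub in truth[truth["cluster_id"].notna()].groupby("cluster_id"):
        entities.append(sub["gene_id"].tolist())
    loose = truth.loc[truth["cluster_id"].isna(), "gene_id"].tolist()
    loose_escapees = [g for g in loose
                      if truth.set_index("gene_id").loc[g, "category"]
                      in CATEGORY_RANGES]
    others = [g for g in loose if g not in set(loose_escapees)]
    # pair up some loose escapees (escapee pairs are still "singles or pairs")
    i = 0
    while i < len(loose_escapees):
        if i + 1 < len(loose_escapees) and rng.random() < 0.3:
            entities.append(loose_escapees[i:i + 2])
            i += 2
        else:
            entities.append([loose_escapees[i]])
            i += 1
    entities.extend([g] for g in others)
    order = rng.permutation(len(entities))

    rows = []
    position = int(rng.integers(100_000, 500_000))
    for ent_idx in order:
        for j, gene in enumerate(entities[ent_idx]):
            if j > 0:
                position += int(rng.integers(*cfg.within_cluster_gap))
            rows.append((gene, "X", position, position + 1000, "+"))
        position += int(rng.integers(*cfg.between_entity_gap))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )


def _study_matrix(truth: pd.DataFrame, cfg: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Literature calls consistent with each gene's category."""
    studies = [f"study{j + 1:02d}" for j in range(cfg.n_studies)]
    rows = []
    for rec in truth.itertuples(index=False):
        category = rec.category
        if category in ("xist", "artifact_high_ratio"):
            continue
        for _ in range(200):  # resample until the category constraint holds
            if category == "constitutive":
                detected = rng.random(cfg.n_studies) < 0.85
                escaping = detected & (rng.random(cfg.n_studies) < 0.8)
                ok = detected.sum() >= 3 and escaping.sum() > 0.5 * detected.sum()
            elif category == "facultative":
                detected = rng.random(cfg.n_studies) < 0.8
                escaping = detected & (rng.random(cfg.n_studies) < 0.25)
                ok = escaping.sum() >= 1 and (
                    detected.sum() < 3
                    or escaping.sum() <= 0.5 * detected.sum()
                )
            elif category == "clone_specific":
                detected = rng.random(cfg.n_studies) < 0.6
                escaping = np.zeros(cfg.n_studies, dtype=bool)
                ok = True
            else:  # silenced
                detected = rng.random(cfg.n_studies) < 0.7
                escaping = np.zeros(cfg.n_studies, dtype=bool)
                ok = detected.sum() >= 1
            if ok:
                break
        for j, study in enumerate(studies):
            if not detected[j]:
                call = "not_detected"
            elif escaping[j]:
                call = "escaping"
            else:
                call = "silenced"
            rows.append((rec.gene_id, study, call))
    return pd.DataFrame(rows, columns=["gene_id", "study_id", "call"])


def _true_ratio(rec, t: float) -> float:
    if rec.category in CATEGORY_RANGES:
        return (rec.r0 - rec.b) * np.exp(-rec.k * t) + rec.b
    return rec.r0  # silenced / artifact / Xist: constant


def _washout_truth(truth: pd.DataFrame, cfg: SimulationConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    classes = list(RECOVERY_RANGES)
    for rec in truth.itertuples(index=False):
        escapee = rec.category in CATEGORY_RANGES
        for duration in cfg.washout_durations:
            if not escapee:
                rows.append((rec.gene_id, duration, np.nan, rec.r0, "undefined"))
                continue
            probs = REVERSIBILITY_PROBS.get(
                7.0 if rec.category == "constitutive" else duration,
                REVERSIBILITY_PROBS[7.0],
            )
            intended = classes[rng.choice(3, p=np.asarray(probs) / sum(probs))]
            f = rng.uniform(*RECOVERY_RANGES[intended])
            washout_ratio = f * rec.r0
            # record the class the rule actually assigns to these true values
            if f >= 0.5 and washout_ratio > 0.1:
                actual = "reversible"
            elif f >= 0.1 and washout_ratio > 0.1:
                actual = "partially_irreversible"
            else:
                actual = "irreversible"
            rows.append((rec.gene_id, duration, f, washout_ratio, actual))
    return pd.DataFrame(rows, columns=[
        "gene_id", "induction_days", "recovery_fraction", "washout_ratio",
        "class",
    ])


def _sample_sheet(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in cfg.time_grid:
        for rep in range(1, cfg.replicates_per_timepoint[t] + 1):
            rows.append((f"d{int(t)}_r{rep}", t, 0.0, False, rep,
                         cfg.xi_haplotype))
    for duration in cfg.washout_durations:
        for rep in range(1, cfg.washout_replicates + 1):
            rows.append((f"d{int(duration)}wo_r{rep}", duration,
                         cfg.washout_days, False, rep, cfg.xi_haplotype))
    sheet = pd.DataFrame(rows, columns=[
        "sample_id", "dox_days", "washout_days", "auxin", "replicate",
        "xi_haplotype",
    ])
    return validate_sample_sheet(sheet.astype(str))


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate one clone's full dataset plus the generating truth.

    ``seed`` overrides ``config.seed``; the same seed reproduces the dataset
    byte for byte.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    truth = _draw_gene_truth(cfg, rng)
    truth = _assign_clusters(truth, cfg, rng)
    annotation = _layout_positions(truth, cfg, rng)
    study_matrix = _study_matrix(truth, cfg, rng)
    washout_truth = _washout_truth(truth, cfg, rng)
    sheet = _sample_sheet(cfg)

    # per-condition true ratios
    washout_lookup = washout_truth.set_index(["gene_id", "induction_days"])[
        "washout_ratio"
    ]
    ratio_rows = []
    for rec in truth.itertuples(index=False):
        for cond in sheet[["dox_days", "washout_days", "condition_label"]].drop_duplicates().itertuples(index=False):
            if cond.washout_days > 0:
                r = float(washout_lookup.get((rec.gene_id, cond.dox_days), rec.r0))
            else:
                r = float(_true_ratio(rec, cond.dox_days))
            ratio_rows.append((rec.gene_id, cond.condition_label, r))
    truth_ratios = pd.DataFrame(
        ratio_rows, columns=["gene_id", "condition_label", "true_ratio"]
    )

    # counts: NB depth per gene, Poisson per sample, binomial Xi split
    n_genes = len(truth)
    shape = cfg.depth_dispersion
    base_depth = rng.gamma(shape, cfg.depth_mean / shape, n_genes)
    ratio_lookup = truth_ratios.set_index(["gene_id", "condition_label"])[
        "true_ratio"
    ]
    count_rows = []
    for g, rec in enumerate(truth.itertuples(index=False)):
        for sample in sheet.itertuples(index=False):
            total = int(rng.poisson(base_depth[g]))
            r = float(np.clip(
                ratio_lookup.loc[(rec.gene_id, sample.condition_label)], 0.0, 1.0
            ))
            xi = int(rng.binomial(total, r)) if total > 0 else 0
            xa = total - xi
            hap1, hap2 = (xi, xa) if cfg.xi_haplotype == "hap1" else (xa, xi)
            count_rows.append((rec.gene_id, sample.sample_id, hap1, hap2, "X"))
    counts = validate_allelic_counts(pd.DataFrame(count_rows, columns=[
        "gene_id", "sample_id", "count_hap1", "count_hap2", "chromosome",
    ]))

    return SimulatedDataset(
        counts=counts, sheet=sheet, annotation=annotation,
        study_matrix=study_matrix, truth=truth,
        truth_reversibility=washout_truth, truth_ratios=truth_ratios,
        config=cfg,
    )


def simulate_mixture(pure_a: pd.DataFrame, pure_b: pd.DataFrame,
                     fraction_b: float, seed: int | None = None) -> pd.DataFrame:
    """Mix two count tables: expected counts (1 - f) * a + f * b per gene.

    Emulates contaminating one cell population with a defined fraction of
    another. Samples are aligned by order within each table (both tables must
    have the same genes and the same number of samples); fractional expected
    counts are rounded stochastically so that the expectation is exact.
    """
    if not 0.0 <= fraction_b <= 1.0:
        raise ValueError("fraction_b must lie in [0, 1]")
    genes_a = set(pure_a["gene_id"])
    genes_b = set(pure_b["gene_id"])
    if genes_a != genes_b:
        raise IntegrityError("mixture inputs must cover identical gene sets")
    samples_a = pure_a["sample_id"].drop_duplicates().tolist()
    samples_b = pure_b["sample_id"].drop_duplicates().tolist()
    if len(samples_a) != len(samples_b):
        raise IntegrityError("mixture inputs must have matching sample counts")
    rng = np.random.default_rng(seed)

    a = pure_a.set_index(["gene_id", "sample_id"])
    b = pure_b.set_index(["gene_id", "sample_id"])
    rows = []
    genes = pure_a["gene_id"].drop_duplicates().tolist()
    for i, (sa, sb) in enumerate(zip(samples_a, samples_b), start=1):
        mix_id = f"mix{i}"
        for gene in genes:
            row_a = a.loc[(gene, sa)]
            row_b = b.loc[(gene, sb)]
            new = {"gene_id": gene, "sample_id": mix_id,
                   "chromosome": row_a["chromosome"]}
            for col in ("count_hap1", "count_hap2"):
                expected = ((1.0 - fraction_b) * float(row_a[col])
                            + fraction_b * float(row_b[col]))
                floor = int(np.floor(expected))
                new[col] = floor + int(rng.random() < expected - floor)
            rows.append(new)
    return validate_allelic_counts(pd.DataFrame(rows))
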