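"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates log2-scale microarray data: baseline gene means are
Normal(8, 1), each histology class carries planted up/down gene programs
shifted by a stated log2 effect, genotype/batch offsets hit a disjoint set
of genes in a random subset of samples independently of histology, and
i.i.d. Gaussian noise is added on top.  Mixed-histology samples are convex
combinations of the component class mean profiles plus noise.  Survival
times are exponential with a hazard that scales with a standardized
per-sample score.

Default dimensions (2000 genes, six histology classes of 12 samples with
60-gene up and 30-gene down programs at 2.0 log2 effect, one batch offset,
unit noise) mirror a compact mouse-mammary-tumor study and keep full
pipeline runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "HistologySpec",
    "BatchSpec",
    "MixtureSpec",
    "CohortConfig",
    "CohortTruth",
    "simulate_cohort",
    "simulate_survival",
    "default_config",
]

DEFAULT_HISTOLOGIES = (
    "squamous",
    "emt",
    "microacinar",
    "papillary",
    "solid",
    "adenomyoepithelial",
)


@dataclass
class HistologySpec:
    name: str
    n_samples: int = 12
    n_up_planted: int = 60
    n_down_planted: int = 30
    effect_log2: float = 2.0


@dataclass
class BatchSpec:
    name: str
    affected_sample_fraction: float = 0.5
    n_affected_genes: int = 100
    offset_log2: float = 1.5


@dataclass
class MixtureSpec:
    components: tuple[tuple[str, float], ...]  # (histology, weight) pairs
    n_samples: int = 1

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1 (got {total})")


@dataclass
class CohortConfig:
    n_genes: int = 2000
    histologies: list[HistologySpec] = field(default_factory=list)
    genotype_batches: list[BatchSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    mixtures: list[MixtureSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        n_planted = sum(h.n_up_planted + h.n_down_planted for h in self.histologies)
        n_batch = sum(b.n_affected_genes for b in self.genotype_batches)
        if n_planted + n_batch > self.n_genes:
            raise ValueError(
                f"planted ({n_planted}) + batch ({n_batch}) genes exceed n_genes ({self.n_genes})"
            )


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    cfg = CohortConfig(
        histologies=[HistologySpec(name) for name in DEFAULT_HISTOLOGIES],
        genotype_batches=[BatchSpec("genotypeA")],
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@dataclass
class CohortTruth:
    planted_up: dict[str, list[str]]
    planted_down: dict[str, list[str]]
    labels: pd.Series  # sample -> histology ("mixture" samples get the dominant one)
    mixture_composition: dict[str, dict[str, float]]  # sample -> {histology: weight}
    batch_genes: dict[str, list[str]]
    batch_samples: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "planted_up": self.planted_up,
            "planted_down": self.planted_down,
            "labels": self.labels.to_dict(),
            "mixture_composition": self.mixture_composition,
            "batch_genes": self.batch_genes,
            "batch_samples": self.batch_samples,
        }


def simulate_cohort(cfg: CohortConfig) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw one cohort; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)

    # planted programs claim disjoint gene blocks in declaration order
    cursor = 0
    planted_up: dict[str, list[str]] = {}
    planted_down: dict[str, list[str]] = {}
    effect: dict[str, np.ndarray] = {}
    for h in cfg.histologies:
        up = list(range(cursor, cursor + h.n_up_planted))
        cursor += h.n_up_planted
        down = list(range(cursor, cursor + h.n_down_planted))
        cursor += h.n_down_planted
        planted_up[h.name] = [genes[i] for i in up]
        planted_down[h.name] = [genes[i] for i in down]
        e = np.zeros(cfg.n_genes)
        e[up] = h.effect_log2
        e[down] = -h.effect_log2
        effect[h.name] = e
    batch_gene_idx: dict[str, list[int]] = {}
    for b in cfg.genotype_batches:
        idx = list(range(cursor, cursor + b.n_affected_genes))
        cursor += b.n_affected_genes
        batch_gene_idx[b.name] = idx

    class_mean = {name: baseline + effect[name] for name in effect}

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    mixture_composition: dict[str, dict[str, float]] = {}
    for h in cfg.histologies:
        for i in range(h.n_samples):
            sid = f"{h.name}_{i:02d}"
            sample_ids.append(sid)
            labels[sid] = h.name
            columns.append(class_mean[h.name].copy())
    for mi, mix in enumerate(cfg.mixtures):
        profile = np.zeros(cfg.n_genes)
        for name, w in mix.components:
            profile += w * class_mean[name]
        dominant = max(mix.components, key=lambda cw: cw[1])[0]
        for i in range(mix.n_samples):
            sid = f"mix{mi:02d}_{i:02d}"
            sample_ids.append(sid)
            labels[sid] = dominant
            mixture_composition[sid] = dict(mix.components)
            columns.append(profile.copy())

    x = np.column_stack(columns)

    # batch offsets: random sample subset, independent of histology
    batch_samples: dict[str, list[str]] = {}
    batch_genes: dict[str, list[str]] = {}
    n_samples = len(sample_ids)
    for b in cfg.genotype_batches:
        n_aff = int(round(b.affected_sample_fraction * n_samples))
        aff = sorted(rng.choice(n_samples, size=n_aff, replace=False))
        batch_samples[b.name] = [sample_ids[j] for j in aff]
        batch_genes[b.name] = [genes[i] for i in batch_gene_idx[b.name]]
        for j in aff:
            x[batch_gene_idx[b.name], j] += b.offset_log2

    x += rng.normal(0.0, cfg.noise_sd, size=x.shape)

    annotations = pd.DataFrame(
        {
            "model": ["synthetic"] * n_samples,
            "genotype": [
                ";".join(b for b in batch_samples if sid in set(batch_samples[b])) or "wt"
                for sid in sample_ids
            ],
            "histology_label": [labels[sid] for sid in sample_ids],
            "batch": [
                ";".join(b for b in batch_samples if sid in set(batch_samples[b]))
                for sid in sample_ids
            ],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=sample_ids), annotations
    )
    truth = CohortTruth(
        planted_up=planted_up,
        planted_down=planted_down,
        labels=pd.Series(labels, name="histology"),
        mixture_composition=mixture_composition,
        batch_genes=batch_genes,
        batch_samples=batch_samples,
    )
    return matrix, truth


def _calibrate_censor_rate(rates: np.ndarray, censor_rate: float) -> float:
    """Censoring rate c with mean_i c/(c + rate_i) = censor_rate (bisection)."""
    lo, hi = 1e-12, rates.max() * 1e6

    def frac(c: float) -> float:
        return float(np.mean(c / (c + rates)))

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < censor_rate:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def simulate_survival(
    scores: pd.Series,
    beta: float,
    baseline_rate: float = 0.02,
    censor_rate: float = 0.3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential event times with hazard baseline_rate * exp(beta * z).

    ``z`` is the standardized score.  Independent exponential censoring is
    calibrated so the expected censored fraction equals ``censor_rate``
    (0 disables censoring).  Returns records (time, event, score) indexed
    by sample.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    s = scores.to_numpy(dtype=float)
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    rates = baseline_rate * np.exp(beta * z)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        return pd.DataFrame(
            {"time": event_times, "event": 1, "score": s}, index=scores.index
        )
    c = _calibrate_censor_rate(rates, censor_rate)
    censor_times = rng.exponential(1.0 / c, size=len(s))
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return pd.DataFrame({"time": time, "event": event, "score": s}, index=scores.index)
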