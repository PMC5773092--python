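"""Two-class gene set enrichment analysis (weighted-KS running sum).

Genes are ranked by a signal-to-noise metric, the running sum increments at
set members by |metric|^p normalized over the set and decrements by
1/(N - N_H) elsewhere, and the enrichment score (ES) is the signed maximum
deviation.  Significance comes from phenotype (label) permutations when the
class sizes allow, otherwise random gene-set permutations: NES normalizes
ES by the mean same-signed permuted ES, the nominal p is the same-signed
permutation tail fraction, FDR q follows the sign-stratified ratio of tail
fractions over normalized scores, and FWER uses the per-permutation maximum
NES distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection
from .sam import TwoClassContrast, _permutation_indicator_matrix

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "GseaConfig",
    "rank_by_signal2noise",
    "enrichment_score",
    "gsea_significance",
]


@dataclass
class RankedList:
    genes: list[str]  # descending by metric
    metric: np.ndarray
    metric_name: str = "signal2noise"

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric must have the same length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    fwer_p: float
    leading_edge_genes: list[str]
    n_permutations: int
    permutation_type: str
    n_extreme: int = 0  # same-signed permuted ES at least as extreme (basis of p)


@dataclass
class GseaConfig:
    n_permutations: int = 1000
    permutation_type: str = "phenotype"  # or "gene_set"
    weight: float = 1.0
    seed: int | None = None
    min_phenotype_group: int = 7  # below this, fall back to gene_set permutation


def _signal2noise(x: np.ndarray, na: int) -> np.ndarray:
    """Floored signal-to-noise for genes x samples data, group a first."""
    xa, xb = x[:, :na], x[:, na:]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a, sd_b = xa.std(axis=1, ddof=1), xb.std(axis=1, ddof=1)
    sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mu_b), 0.2))
    return (mu_a - mu_b) / (sd_a + sd_b)


def rank_by_signal2noise(m: ExpressionMatrix, c: TwoClassContrast) -> RankedList:
    """Rank genes by (mu_a - mu_b)/(sd_a + sd_b) with the canonical sd floor.

    Falls back to difference of class means (with a warning) when either
    group has fewer than 3 samples.  Ties are broken by gene ID.
    """
    c.validate_against(m)
    x = m.values[list(c.group_a) + list(c.group_b)].to_numpy(dtype=float)
    na = len(c.group_a)
    if na < 3 or x.shape[1] - na < 3:
        warnings.warn(
            "fewer than 3 samples in a class: ranking by difference of means",
            stacklevel=2,
        )
        metric = x[:, :na].mean(axis=1) - x[:, na:].mean(axis=1)
        name = "diff_of_means"
    else:
        metric = _signal2noise(x, na)
        name = "signal2noise"
    order = sorted(range(len(metric)), key=lambda i: (-metric[i], m.gene_ids[i]))
    return RankedList(
        genes=[m.gene_ids[i] for i in order], metric=metric[order], metric_name=name
    )


def enrichment_score(
    r: RankedList, genes, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS ES, full running sum, and the leading-edge genes.

    Set genes absent from the ranked list are dropped with a warning.  When
    the set covers the whole list the miss decrement is undefined; by
    convention it is 0 so the sum climbs to 1 (degenerate but documented).
    """
    gene_pos = {g: i for i, g in enumerate(r.genes)}
    present = [g for g in genes if g in gene_pos]
    dropped = [g for g in genes if g not in gene_pos]
    if dropped:
        warnings.warn(f"{len(dropped)} set genes absent from ranked list", stacklevel=2)
    if not present:
        raise ValueError("no overlap between gene set and ranked list")
    n = len(r.genes)
    hit = np.zeros(n, dtype=bool)
    hit[[gene_pos[g] for g in present]] = True
    running = _running_sum(r.metric, hit, weight)
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    if es >= 0:
        leading = [g for g in r.genes[: idx + 1] if hit[gene_pos[g]]]
    else:
        leading = [g for g in r.genes[idx:] if hit[gene_pos[g]]]
    return es, running, leading


def _running_sum(metric: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    n = len(metric)
    n_hit = int(hit.sum())
    w = np.abs(metric) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics zero: fall back to equal steps
        hit_w = hit.astype(float)
        total = float(n_hit)
    steps = hit_w / total
    n_miss = n - n_hit
    if n_miss > 0:
        steps = steps - np.where(hit, 0.0, 1.0 / n_miss)
    return np.cumsum(steps)


def _es_for_hits(metric: np.ndarray, hit: np.ndarray, weight: float) -> float:
    running = _running_sum(metric, hit, weight)
    return float(running[int(np.argmax(np.abs(running)))])


def gsea_significance(
    m: ExpressionMatrix,
    c: TwoClassContrast,
    sets: GeneSetCollection,
    cfg: GseaConfig | None = None,
) -> list[EnrichmentResult]:
    """Permutation significance for every set against one two-class contrast."""
    cfg = cfg or GseaConfig()
    if len(sets) == 0:
        raise ValueError("empty gene set collection")
    c.validate_against(m)
    perm_type = cfg.permutation_type
    na, nb = len(c.group_a), len(c.group_b)
    if perm_type == "phenotype" and min(na, nb) < cfg.min_phenotype_group:
        total = comb(na + nb, na)
        if total < 50:
            warnings.warn(
                f"small classes ({na}v{nb}): switching to gene_set permutation",
                stacklevel=2,
            )
            perm_type = "gene_set"
    rng = np.random.default_rng(cfg.seed)

    ranked = rank_by_signal2noise(m, c)
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    n = len(ranked.genes)
    set_names = sets.names()
    hits_obs: dict[str, np.ndarray] = {}
    es_obs: dict[str, float] = {}
    leading: dict[str, list[str]] = {}
    for name in set_names:
        es, _, le = enrichment_score(ranked, sets[name].genes, cfg.weight)
        es_obs[name] = es
        leading[name] = le
        hit = np.zeros(n, dtype=bool)
        hit[[gene_pos[g] for g in sets[name].genes if g in gene_pos]] = True
        hits_obs[name] = hit

    if perm_type == "phenotype":
        es_perm, n_perm = _phenotype_permutation_es(
            m, c, hits_obs, set_names, cfg, rng
        )
    elif perm_type == "gene_set":
        es_perm, n_perm = _gene_set_permutation_es(
            ranked.metric, hits_obs, set_names, cfg, rng
        )
    else:
        raise ValueError(f"unknown permutation_type {cfg.permutation_type!r}")

    return _summarize(
        set_names, es_obs, es_perm, leading, hits_obs, n_perm, perm_type
    )


def _phenotype_permutation_es(m, c, hits_obs, set_names, cfg, rng):
    """ES* per set under label permutations (re-ranking each time)."""
    x = m.values[list(c.group_a) + list(c.group_b)].to_numpy(dtype=float)
    na = len(c.group_a)
    n_samples = x.shape[1]
    small = min(na, n_samples - na) < 3
    perms, _ = _permutation_indicator_matrix(n_samples, na, cfg.n_permutations, rng)
    gene_idx = {name: np.flatnonzero(h) for name, h in hits_obs.items()}
    es_perm = {name: np.empty(perms.shape[0]) for name in set_names}
    n_genes = x.shape[0]
    for b in range(perms.shape[0]):
        xa_idx = np.flatnonzero(perms[b])
        xb_idx = np.flatnonzero(~perms[b])
        xp = x[:, np.concatenate([xa_idx, xb_idx])]
        if small:
            metric = xp[:, :na].mean(axis=1) - xp[:, na:].mean(axis=1)
        else:
            metric = _signal2noise(xp, na)
        order = np.argsort(-metric, kind="stable")
        pos_of_gene = np.empty(n_genes, dtype=int)
        pos_of_gene[order] = np.arange(n_genes)
        metric_sorted = metric[order]
        for name in set_names:
            hit = np.zeros(n_genes, dtype=bool)
            hit[pos_of_gene[gene_idx[name]]] = True
            es_perm[name][b] = _es_for_hits(metric_sorted, hit, cfg.weight)
    return es_perm, perms.shape[0]


def _gene_set_permutation_es(metric, hits_obs, set_names, cfg, rng):
    """ES* per set from random same-size gene sets on the fixed ranking."""
    n = len(metric)
    es_perm = {}
    for name in set_names:
        k = int(hits_obs[name].sum())
        vals = np.empty(cfg.n_permutations)
        for b in range(cfg.n_permutations):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=k, replace=False)] = True
            vals[b] = _es_for_hits(metric, hit, cfg.weight)
        es_perm[name] = vals
    return es_perm, cfg.n_permutations


def _normalize(es: float, perm: np.ndarray) -> float:
    """ES / mean |same-signed permuted ES| (0 if no same-signed permutations)."""
    if es >= 0:
        same = perm[perm >= 0]
    else:
        same = perm[perm < 0]
    if len(same) == 0 or np.mean(np.abs(same)) == 0:
        return 0.0
    return float(es / np.mean(np.abs(same)))


def _summarize(set_names, es_obs, es_perm, leading, hits_obs, n_perm, perm_type):
    # normalized observed and permuted scores
    nes_obs = {name: _normalize(es_obs[name], es_perm[name]) for name in set_names}
    nes_perm: dict[str, np.ndarray] = {}
    for name in set_names:
        perm = es_perm[name]
        out = np.empty_like(perm)
        for sign, mask in ((1, perm >= 0), (-1, perm < 0)):
            same = perm[mask]
            denom = np.mean(np.abs(same)) if len(same) else 0.0
            out[mask] = 0.0 if denom == 0 else same / denom
        nes_perm[name] = out

    all_nes_perm = np.concatenate([nes_perm[name] for name in set_names])
    all_nes_obs = np.array([nes_obs[name] for name in set_names])
    results = []
    for name in set_names:
        es = es_obs[name]
        nes = nes_obs[name]
        perm = es_perm[name]
        if es >= 0:
            same = perm[perm >= 0]
            n_extreme = int(np.sum(same >= es))
        else:
            same = perm[perm < 0]
            n_extreme = int(np.sum(same <= es))
        p_nom = n_extreme / len(same) if len(same) else 1.0
        fdr_q = _fdr_q(nes, all_nes_perm, all_nes_obs)
        fwer = _fwer(nes, nes_perm, set_names)
        results.append(
            EnrichmentResult(
                set_name=name,
                set_size=int(hits_obs[name].sum()),
                es=float(es),
                nes=float(nes),
                p_nominal=float(p_nom),
                fdr_q=float(fdr_q),
                fwer_p=float(fwer),
                leading_edge_genes=leading[name],
                n_permutations=n_perm,
                permutation_type=perm_type,
                n_extreme=n_extreme,
            )
        )
    return _monotonize_fdr(results)


def _fdr_q(nes, all_nes_perm, all_nes_obs) -> float:
    """Sign-stratified ratio of permuted to observed tail fractions."""
    if nes >= 0:
        perm_side = all_nes_perm[all_nes_perm >= 0]
        obs_side = all_nes_obs[all_nes_obs >= 0]
        num = np.mean(perm_side >= nes) if len(perm_side) else 0.0
        den = np.mean(obs_side >= nes) if len(obs_side) else 1.0
    else:
        perm_side = all_nes_perm[all_nes_perm < 0]
        obs_side = all_nes_obs[all_nes_obs < 0]
        num = np.mean(perm_side <= nes) if len(perm_side) else 0.0
        den = np.mean(obs_side <= nes) if len(obs_side) else 1.0
    if den == 0:
        return 0.0
    return min(1.0, num / den)


def _fwer(nes, nes_perm, set_names) -> float:
    mat = np.stack([nes_perm[name] for name in set_names])
    if nes >= 0:
        maxima = mat.max(axis=0)
        return float(np.mean(maxima >= nes))
    minima = mat.min(axis=0)
    return float(np.mean(minima <= nes))


def _monotonize_fdr(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """FDR q nonincreasing in |NES| within each sign stratum.

    Each set takes the minimum raw q over itself and all less extreme sets
    of the same sign (running min along ascending |NES|)."""
    for positive in (True, False):
        side = [r for r in results if (r.nes >= 0) == positive]
        side.sort(key=lambda r: abs(r.nes))  # least extreme first
        running = np.inf
        for r in side:
            running = min(running, r.fdr_q)
            r.fdr_q = running
    return results


def results_to_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "set": r.set_name,
            "size": r.set_size,
            "es": r.es,
            "nes": r.nes,
            "p_nominal": r.p_nominal,
            "fdr_q": r.fdr_q,
            "fwer_p": r.fwer_p,
            "leading_edge_size": len(r.leading_edge_genes),
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("set")
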