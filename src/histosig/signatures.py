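"""Histology signature derivation.

A signature is the set of genes consistently significant in the same
direction across every contrast of the target histology against the other
histologies in the training set: up genes need q <= threshold and d > 0 in
all contrasts, down genes q <= threshold and d < 0 in all contrasts.  An
optional fold-change filter then keeps up genes whose worst-case (minimum)
fold across contrasts clears a floor, and down genes whose best-case
(maximum) fold stays under a ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneSet, GeneSetCollection
from .sam import SamResult

__all__ = ["GeneSignature", "derive_signature", "apply_fold_filter"]


@dataclass
class GeneSignature:
    name: str
    up_genes: list[str]
    down_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"signature {self.name!r}: genes both up and down: {sorted(overlap)[:5]}")

    def to_collection(self) -> GeneSetCollection:
        """Paired NAME_UP / NAME_DOWN sets (empty directions omitted)."""
        sets = {}
        if self.up_genes:
            up = f"{self.name}_UP"
            sets[up] = GeneSet(up, f"genes up in {self.name}", list(self.up_genes))
        if self.down_genes:
            down = f"{self.name}_DOWN"
            sets[down] = GeneSet(down, f"genes down in {self.name}", list(self.down_genes))
        return GeneSetCollection(sets)


def derive_signature(
    results: list[SamResult], q_threshold: float = 0.05, name: str | None = None
) -> GeneSignature:
    """Intersect per-contrast significant gene lists, separately by direction.

    All results must target the same histology (same group_a semantics);
    the contrast names are expected to be 'TARGET_vs_X' or a shared prefix —
    mismatched targets raise.
    """
    if not results:
        raise ValueError("need at least one SamResult")
    targets = {r.contrast_name.split("_vs_")[0] for r in results}
    if len(targets) > 1:
        raise ValueError(f"results target different histologies: {sorted(targets)}")
    target = targets.pop()
    up_sets = [set(r.significant(q_threshold, "up")) for r in results]
    down_sets = [set(r.significant(q_threshold, "down")) for r in results]
    up = set.intersection(*up_sets)
    down = set.intersection(*down_sets)
    # stable order: by the first result's gene order
    gene_order = {g: i for i, g in enumerate(results[0].table.index)}
    provenance = {
        "target": target,
        "contrasts": [r.contrast_name for r in results],
        "q_threshold": q_threshold,
        "per_contrast_up_counts": [len(s) for s in up_sets],
        "per_contrast_down_counts": [len(s) for s in down_sets],
        "fold_filters": None,
    }
    return GeneSignature(
        name=name or target.upper(),
        up_genes=sorted(up, key=gene_order.get),
        down_genes=sorted(down, key=gene_order.get),
        provenance=provenance,
    )


def apply_fold_filter(
    sig: GeneSignature,
    results: list[SamResult],
    up_min_fold: float = 1.0,
    down_max_fold: float = np.inf,
) -> GeneSignature:
    """Keep up genes with min fold across contrasts >= up_min_fold and down
    genes with max fold <= down_max_fold (folds on the linear scale, so a
    2-fold down gene has fold_change 0.5).  Thresholds of 1 (up) and inf
    (down) disable the respective filter."""
    if up_min_fold <= 0 or down_max_fold <= 0:
        raise ValueError("fold thresholds must be positive")
    for r in results:
        missing = [g for g in sig.up_genes + sig.down_genes if g not in r.table.index]
        if missing:
            raise ValueError(
                f"signature genes missing from contrast {r.contrast_name!r}: {missing[:5]}"
            )
    folds = {r.contrast_name: r.table["fold_change"] for r in results}

    def min_fold(g: str) -> float:
        return min(f.loc[g] for f in folds.values())

    def max_fold(g: str) -> float:
        return max(f.loc[g] for f in folds.values())

    up = [g for g in sig.up_genes if min_fold(g) >= up_min_fold]
    down = [g for g in sig.down_genes if max_fold(g) <= down_max_fold]
    provenance = dict(sig.provenance)
    provenance["fold_filters"] = {
        "up_min_fold": up_min_fold,
        "down_max_fold": None if np.isinf(down_max_fold) else down_max_fold,
        "up_before": len(sig.up_genes),
        "down_before": len(sig.down_genes),
    }
    return GeneSignature(sig.name, up, down, provenance)
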