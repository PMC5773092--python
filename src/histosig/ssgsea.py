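"""Single-sample GSEA scoring and maximum-score histology calling.

Each sample is scored independently for each gene set: genes are ranked by
expression within the sample, in-set genes contribute a weighted ECDF step
proportional to rank^alpha, out-of-set genes a uniform step, and the score
is the sum over the whole ranking of the difference between the two ECDFs
(Barbie-style).  A tumor's histology call is the "up" signature with the
highest score; ties go to the lexicographically first signature name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SampleScoreMatrix",
    "HistologyCall",
    "ssgsea_score",
    "classify_by_max",
    "figure_order",
]


@dataclass
class SampleScoreMatrix:
    scores: pd.DataFrame  # samples x signatures
    alpha: float
    normalized: bool
    degenerate_sets: list[str] = field(default_factory=list)  # empty-complement sets
    failed_sets: dict[str, str] = field(default_factory=dict)  # set -> error message


@dataclass
class HistologyCall:
    sample_id: str
    predicted_histology: str
    winning_score: float
    margin: float  # over the runner-up (equals winning_score with one candidate)
    tie: bool
    scores: dict[str, float]
    low_confidence: bool = False


def ssgsea_score(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> SampleScoreMatrix:
    """Score every sample for every set.

    Per sample, genes are ordered by expression descending (ties by gene
    ID) and assigned ranks N..1.  The score is

        sum_j [ P_in(j) - P_out(j) ]

    where P_in is the cumulative rank^alpha weight over in-set genes and
    P_out the cumulative uniform ECDF over out-of-set genes.  When
    ``normalize`` all scores are divided by the range of scores across the
    whole matrix (the canonical module's normalization).  Sets overlapping
    the gene universe by < 2 genes are reported in ``failed_sets`` and
    skipped; a set covering the entire universe is scored with a zero miss
    term and flagged in ``degenerate_sets``.
    """
    genes = list(m.gene_ids)
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    x = m.values.to_numpy(dtype=float)

    set_masks: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    failed: dict[str, str] = {}
    for name in sets.names():
        members = sets[name].genes
        present = [g for g in members if g in gene_index]
        if len(present) < len(members):
            warnings.warn(
                f"set {name!r}: {len(members) - len(present)} genes absent from matrix",
                stacklevel=2,
            )
        if len(present) < 2:
            failed[name] = f"only {len(present)} genes overlap the matrix"
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[gene_index[g] for g in present]] = True
        if mask.all():
            degenerate.append(name)
        set_masks[name] = mask
    if not set_masks:
        raise ValueError("no scoreable gene sets (all failed the overlap check)")

    # per-sample descending order, ties broken by gene id
    id_rank = np.argsort(np.argsort(np.array(genes, dtype=object), kind="stable"))
    cols = {}
    order_per_sample = []
    for j in range(x.shape[1]):
        order = np.lexsort((id_rank, -x[:, j]))  # primary: expr desc, tie: gene id
        order_per_sample.append(order)
    ranks = np.arange(n, 0, -1, dtype=float)  # rank N at top position
    rank_w = ranks**alpha
    for name, mask in set_masks.items():
        col = np.empty(x.shape[1])
        n_hit = int(mask.sum())
        n_miss = n - n_hit
        for j, order in enumerate(order_per_sample):
            hit_sorted = mask[order]
            w = np.where(hit_sorted, rank_w, 0.0)
            p_in = np.cumsum(w) / w.sum()
            if n_miss == 0:
                p_out = np.zeros(n)
            else:
                p_out = np.cumsum(~hit_sorted) / n_miss
            col[j] = float(np.sum(p_in - p_out))
        cols[name] = col
    scores = pd.DataFrame(cols, index=m.sample_ids)
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return SampleScoreMatrix(
        scores=scores,
        alpha=alpha,
        normalized=normalize,
        degenerate_sets=degenerate,
        failed_sets=failed,
    )


def classify_by_max(
    scores: SampleScoreMatrix,
    up_signatures: list[str],
    margin_floor: float = 0.0,
) -> list[HistologyCall]:
    """Assign each sample the 'up' signature it scores highest for.

    Ties are broken lexicographically by signature name and recorded.  A
    call whose margin over the runner-up is below ``margin_floor`` is
    flagged low-confidence (the stored argmax never changes).
    """
    if not up_signatures:
        raise ValueError("empty signature list")
    missing = [s for s in up_signatures if s not in scores.scores.columns]
    if missing:
        raise ValueError(f"signatures not in score matrix: {missing}")
    sub = scores.scores[sorted(up_signatures)]
    calls = []
    for sample_id, row in sub.iterrows():
        vals = row.to_numpy()
        best = int(np.argmax(vals))  # argmax returns first max -> lexicographic tie
        winner = sub.columns[best]
        win_score = float(vals[best])
        tie = bool(np.sum(vals == win_score) > 1)
        if len(vals) > 1:
            margin = float(win_score - np.partition(vals, -2)[-2])
        else:
            margin = win_score
        calls.append(
            HistologyCall(
                sample_id=str(sample_id),
                predicted_histology=str(winner),
                winning_score=win_score,
                margin=margin,
                tie=tie,
                scores={c: float(v) for c, v in row.items()},
                low_confidence=margin < margin_floor,
            )
        )
    return calls


def figure_order(calls: list[HistologyCall]) -> list[str]:
    """Sample ordering for the classification heatmap: samples grouped by
    call (groups in signature-name order), sorted by winning score
    descending within each group."""
    return [
        c.sample_id
        for c in sorted(calls, key=lambda c: (c.predicted_histology, -c.winning_score))
    ]


def calls_to_table(calls: list[HistologyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "call": c.predicted_histology,
                "score": c.winning_score,
                "margin": c.margin,
            }
            for c in calls
        ]
    ).set_index("sample")
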