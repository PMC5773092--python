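"""Two-class permutation differential expression (SAM-style).

Implements the Tusher-style relative difference statistic

    d_i = (mean_a_i - mean_b_i) / (s_i + s0)

with the pooled standard error

    s_i = sqrt( (1/n_a + 1/n_b) * (SS_a_i + SS_b_i) / (n_a + n_b - 2) )

a fudge factor s0 chosen on a percentile grid of the s distribution to
minimize the coefficient of variation of windowed MADs of d, and per-gene
false discovery rates (q-values) from label permutations: for a gene at
threshold t = |d|, the q-value is

    q = pi0 * median_over_permutations #{ |d*| >= t } / #{ observed |d| >= t }

capped at 1 and made monotone nonincreasing in t.  pi0 is estimated as the
fraction of observed d falling in the central 50% of the pooled permuted d
distribution, capped at 1.  Ties count as exceeding (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "TwoClassContrast",
    "SamConfig",
    "SamResult",
    "compute_d_statistics",
    "select_s0",
    "permutation_qvalues",
    "contrasts_for_target",
]

S0_PERCENTILE_GRID = np.arange(0, 101, 5)


@dataclass(frozen=True)
class TwoClassContrast:
    """One comparison: target samples (group_a) vs a reference (group_b)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __init__(self, name, group_a, group_b):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "group_a", tuple(group_a))
        object.__setattr__(self, "group_b", tuple(group_b))
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"contrast {name!r}: each group needs >= 2 samples")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {name!r}: groups overlap")

    def validate_against(self, m: ExpressionMatrix) -> None:
        missing = [s for s in self.group_a + self.group_b if s not in m.sample_ids]
        if missing:
            raise ValueError(f"contrast {self.name!r}: samples not in matrix: {missing}")


@dataclass
class SamConfig:
    n_permutations: int = 1000
    seed: int | None = None
    s0_mode: str | float = "tusher"  # "tusher" or a fixed percentile (0..100)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class SamResult:
    """Per-gene d, s, fold change and q-value for one contrast."""

    contrast_name: str
    table: pd.DataFrame  # index gene_id; columns d, s, mean_a, mean_b, fold_change, q_value
    s0: float
    s0_percentile: float | None
    pi0: float
    n_permutations: int
    exhaustive: bool
    seed: int | None

    def significant(self, q_threshold: float, direction: str | None = None) -> pd.Index:
        """Genes at q <= q_threshold; direction 'up' needs d > 0, 'down' d < 0."""
        t = self.table
        mask = t["q_value"] <= q_threshold
        if direction == "up":
            mask &= t["d"] > 0
        elif direction == "down":
            mask &= t["d"] < 0
        elif direction is not None:
            raise ValueError("direction must be 'up', 'down' or None")
        return t.index[mask]

    def to_table(self) -> pd.DataFrame:
        out = self.table.copy()
        out["direction"] = np.where(out["d"] > 0, "up", np.where(out["d"] < 0, "down", "flat"))
        return out


def contrasts_for_target(labels: pd.Series, target: str) -> list[TwoClassContrast]:
    """One contrast per non-target class: target samples vs that class.

    ``labels`` maps sample ID to histology.  Contrast names follow the
    'TARGET_vs_OTHER' convention the derivation step expects.
    """
    group_a = list(labels.index[labels == target])
    if not group_a:
        raise ValueError(f"no samples labeled {target!r}")
    others = sorted(set(labels) - {target})
    if not others:
        raise ValueError("need at least one non-target class")
    return [
        TwoClassContrast(
            f"{target}_vs_{other}", group_a, list(labels.index[labels == other])
        )
        for other in others
    ]


def _group_stats(x: np.ndarray, na: int, nb: int):
    """Means and pooled SE components for genes x (n_a + n_b) data (a first)."""
    xa, xb = x[:, :na], x[:, na:]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    ss_a = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ss_a + ss_b) / (na + nb - 2))
    return mean_a, mean_b, s


def compute_d_statistics(
    m: ExpressionMatrix, c: TwoClassContrast, s0: float
) -> pd.DataFrame:
    """Per-gene d, s, group means and fold change (anti-logged log2 means)."""
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    c.validate_against(m)
    x = m.values[list(c.group_a) + list(c.group_b)].to_numpy(dtype=float)
    na, nb = len(c.group_a), len(c.group_b)
    mean_a, mean_b, s = _group_stats(x, na, nb)
    numer = mean_a - mean_b
    denom = s + s0
    if np.any((denom == 0) & (numer != 0)):
        raise ValueError(
            "s + s0 is zero for a gene with nonzero mean difference; use a positive s0"
        )
    d = np.zeros_like(numer)
    nz = denom > 0
    d[nz] = numer[nz] / denom[nz]
    return pd.DataFrame(
        {
            "d": d,
            "s": s,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": 2.0 ** numer,
        },
        index=m.gene_ids,
    )


def select_s0(s: np.ndarray, d_numerators: np.ndarray) -> tuple[float, float]:
    """Fudge factor: the percentile of s minimizing CV of windowed MADs of d.

    Candidates are the percentiles 0, 5, ..., 100 of the s distribution.  For
    each candidate, genes are ordered by s and split into contiguous windows;
    the spread (MAD) of d = r/(s + s0) is computed per window, and the
    candidate with the smallest coefficient of variation of those spreads
    wins.  With fewer than 20 genes the 5th percentile is returned directly.

    Returns (s0, percentile).
    """
    s = np.asarray(s, dtype=float)
    r = np.asarray(d_numerators, dtype=float)
    if s.shape != r.shape:
        raise ValueError("s and d_numerators must have the same length")
    if np.ptp(s) == 0:
        return float(s[0]), 50.0
    if len(s) < 20:
        return float(np.percentile(s, 5)), 5.0
    order = np.argsort(s, kind="stable")
    s_sorted, r_sorted = s[order], r[order]
    n = len(s)
    n_windows = max(2, min(100, n // 10))
    bounds = np.linspace(0, n, n_windows + 1).astype(int)
    best = (np.inf, 0.0, 0.0)
    for pct in S0_PERCENTILE_GRID:
        cand = float(np.percentile(s, pct))
        d = r_sorted / (s_sorted + cand)
        mads = np.array(
            [
                np.median(np.abs(d[lo:hi] - np.median(d[lo:hi])))
                for lo, hi in zip(bounds[:-1], bounds[1:])
                if hi > lo
            ]
        )
        mean = mads.mean()
        cv = np.inf if mean == 0 else mads.std(ddof=0) / mean
        if cv < best[0]:
            best = (cv, cand, float(pct))
    return best[1], best[2]


def _permutation_indicator_matrix(
    n: int, na: int, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Rows select which of n samples form group a; exhaustive if feasible."""
    total = comb(n, na)
    if total <= n_permutations:
        perms = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), na)):
            perms[i, list(idx)] = True
        return perms, True
    perms = np.zeros((n_permutations, n), dtype=bool)
    for i in range(n_permutations):
        perms[i, rng.choice(n, size=na, replace=False)] = True
    return perms, False


def _permuted_d(x: np.ndarray, perms: np.ndarray, s0: float) -> np.ndarray:
    """d* for every permutation: genes x B matrix, fully vectorized."""
    n = x.shape[1]
    na = int(perms[0].sum())
    nb = n - na
    p = perms.astype(float).T  # n x B
    q = 1.0 - p
    sum_a = x @ p
    sum_b = x @ q
    sumsq = x**2
    ss_a = sumsq @ p - sum_a**2 / na
    ss_b = sumsq @ q - sum_b**2 / nb
    # numeric floor: within-group SS cannot be negative
    np.maximum(ss_a, 0.0, out=ss_a)
    np.maximum(ss_b, 0.0, out=ss_b)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ss_a + ss_b) / (na + nb - 2))
    numer = sum_a / na - sum_b / nb
    denom = s + s0
    d = np.zeros_like(numer)
    nz = denom > 0
    d[nz] = numer[nz] / denom[nz]
    return d


def permutation_qvalues(
    m: ExpressionMatrix, c: TwoClassContrast, cfg: SamConfig | None = None
) -> SamResult:
    """Full SAM run for one contrast: d statistics plus permutation q-values."""
    cfg = cfg or SamConfig()
    c.validate_against(m)
    x = m.values[list(c.group_a) + list(c.group_b)].to_numpy(dtype=float)
    na = len(c.group_a)
    mean_a, mean_b, s = _group_stats(x, na, x.shape[1] - na)
    numer = mean_a - mean_b
    if cfg.s0_mode == "tusher":
        s0, s0_pct = select_s0(s, numer)
    else:
        s0_pct = float(cfg.s0_mode)
        s0 = float(np.percentile(s, s0_pct))
    table = compute_d_statistics(m, c, s0)

    rng = np.random.default_rng(cfg.seed)
    perms, exhaustive = _permutation_indicator_matrix(
        x.shape[1], na, cfg.n_permutations, rng
    )
    d_perm = _permuted_d(x, perms, s0)  # genes x B
    abs_perm = np.abs(d_perm)
    abs_obs = np.abs(table["d"].to_numpy())

    # counts #{ |d*| >= t } per permutation, t = each observed |d|
    B = abs_perm.shape[1]
    counts = np.empty((len(abs_obs), B), dtype=float)
    for b in range(B):
        col = np.sort(abs_perm[:, b])
        counts[:, b] = len(col) - np.searchsorted(col, abs_obs, side="left")
    median_false = np.median(counts, axis=1)
    obs_sorted = np.sort(abs_obs)
    n_called = len(abs_obs) - np.searchsorted(obs_sorted, abs_obs, side="left")

    pi0 = estimate_pi0(table["d"].to_numpy(), d_perm)
    q_raw = np.minimum(1.0, pi0 * median_false / n_called)
    q = _monotonize(abs_obs, q_raw)
    table = table.assign(q_value=q)
    return SamResult(
        contrast_name=c.name,
        table=table,
        s0=float(s0),
        s0_percentile=s0_pct,
        pi0=float(pi0),
        n_permutations=perms.shape[0],
        exhaustive=exhaustive,
        seed=cfg.seed,
    )


def estimate_pi0(d_obs: np.ndarray, d_perm: np.ndarray) -> float:
    """Fraction of observed d inside the central 50% of permuted d, capped at 1."""
    lo, hi = np.percentile(d_perm, [25, 75])
    inside = np.mean((d_obs >= lo) & (d_obs <= hi))
    return float(min(1.0, inside / 0.5))


def _monotonize(t: np.ndarray, q_raw: np.ndarray) -> np.ndarray:
    """Enforce q nonincreasing in t = |d| (running min from least significant)."""
    order = np.argsort(t, kind="stable")  # ascending |d|
    q = q_raw.copy()
    running = np.minimum.accumulate(q[order])
    q[order] = running
    return q
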