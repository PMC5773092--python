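"""Signature scoring of clinical cohorts and median-split survival analysis.

Tumors are scored for a signature (mean of median-centered expression of
the signature's up genes, or an ssGSEA score), split at the median of the
analyzed population (the stratum, when stratified) into high and low
groups — strictly above the median is "high" — and compared by
Kaplan-Meier curves, the log-rank test, and a high-vs-low hazard ratio
from a univariate proportional-hazards fit (Mantel-Haenszel O/E ratio as a
fallback when the fit does not converge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .io import ExpressionMatrix
from .signatures import GeneSignature
from .ssgsea import ssgsea_score

__all__ = [
    "SurvivalComparison",
    "assign_groups",
    "signature_scores",
    "compare_survival",
]

RECORD_COLUMNS = ("time", "event")


@dataclass
class SurvivalComparison:
    logrank_chi2: float
    p_value: float
    hazard_ratio: float  # high vs low
    hr_ci95: tuple[float, float]
    hr_method: str  # "cox" or "mantel_haenszel"
    hr_mantel_haenszel: float
    n: int
    n_events: int
    km_curves: dict[str, pd.DataFrame]  # group -> (time, at_risk, survival, censored)
    undefined: bool = False  # no events: curves returned, test undefined


def signature_scores(
    m: ExpressionMatrix, sig: GeneSignature, method: str = "mean_centered"
) -> pd.Series:
    """Per-sample signature score.

    ``mean_centered``: mean of median-centered expression of the up genes.
    ``ssgsea``: single-sample enrichment score of the up genes.
    """
    genes = [g for g in sig.up_genes if g in m.gene_ids]
    if not genes:
        raise ValueError(f"signature {sig.name!r}: no up genes overlap the matrix")
    if method == "mean_centered":
        sub = m.values.loc[genes]
        centered = sub.sub(sub.median(axis=1), axis=0)
        return centered.mean(axis=0)
    if method == "ssgsea":
        ssm = ssgsea_score(m, sig.to_collection(), normalize=False)
        return ssm.scores[f"{sig.name}_UP"]
    raise ValueError("method must be 'mean_centered' or 'ssgsea'")


def assign_groups(
    m: ExpressionMatrix,
    sig: GeneSignature,
    records: pd.DataFrame,
    stratum: str | None = None,
    method: str = "mean_centered",
) -> pd.DataFrame:
    """Attach score and high/low group to survival records.

    ``records`` is indexed by sample ID with at least ``time`` and ``event``
    columns (an optional ``stratum`` column).  The median is computed over
    the analyzed population: the named stratum when given, else — when a
    stratum column exists — within each stratum independently, else the
    whole cohort.  Scores strictly above the median are "high"; ties go to
    "low" (recorded in the output attrs).
    """
    for col in RECORD_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    records = records.copy()
    if stratum is not None:
        if "stratum" not in records.columns:
            raise ValueError("stratum requested but records have no 'stratum' column")
        records = records[records["stratum"] == stratum]
        if records.empty:
            raise ValueError(f"no records in stratum {stratum!r}")
    common = [s for s in records.index if s in m.sample_ids]
    if not common:
        raise ValueError("no survival records match matrix samples")
    records = records.loc[common]
    scores = signature_scores(m.subset_samples(common), sig, method)
    records["score"] = scores.loc[common].to_numpy()

    def split(df: pd.DataFrame) -> pd.DataFrame:
        med = df["score"].median()
        if df["score"].nunique() == 1:
            raise ValueError("all scores identical: degenerate median split")
        df = df.copy()
        df["group"] = np.where(df["score"] > med, "high", "low")
        return df

    if stratum is None and "stratum" in records.columns and records["stratum"].nunique() > 1:
        records = pd.concat(
            [split(g) for _, g in records.groupby("stratum", sort=True)]
        ).loc[[s for s in common]]
    else:
        records = split(records)
    records.attrs["tie_rule"] = "ties_to_low"
    records.attrs["signature"] = sig.name
    return records


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
            "censored": table["censored"].to_numpy(dtype=float),
        }
    )


def _mantel_haenszel_hr(time, event, high) -> float:
    """(O_high/E_high)/(O_low/E_low) from the log-rank expectations."""
    o = np.array([event[high].sum(), event[~high].sum()], dtype=float)
    e = np.zeros(2)
    for t in np.unique(time[event.astype(bool)]):
        at_risk = time >= t
        d = float(((time == t) & event.astype(bool)).sum())
        n = float(at_risk.sum())
        e[0] += d * at_risk[high].sum() / n
        e[1] += d * at_risk[~high].sum() / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = o / e
    if rates[1] == 0 or not np.isfinite(rates).all():
        return float("nan")
    return float(rates[0] / rates[1])


def compare_survival(records: pd.DataFrame) -> SurvivalComparison:
    """Compare high vs low groups within one analyzed population."""
    for col in ("time", "event", "group"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if np.any(time < 0) or not set(np.unique(event)) <= {0, 1}:
        raise ValueError("time must be >= 0 and event in {0, 1}")
    high = (records["group"] == "high").to_numpy()
    if high.all() or (~high).all():
        raise ValueError("one of the groups is empty")
    curves = {
        "high": _km_curve(time[high], event[high]),
        "low": _km_curve(time[~high], event[~high]),
    }
    n_events = int(event.sum())
    if n_events == 0:
        return SurvivalComparison(
            logrank_chi2=float("nan"),
            p_value=float("nan"),
            hazard_ratio=float("nan"),
            hr_ci95=(float("nan"), float("nan")),
            hr_method="undefined",
            hr_mantel_haenszel=float("nan"),
            n=len(records),
            n_events=0,
            km_curves=curves,
            undefined=True,
        )
    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    hr_mh = _mantel_haenszel_hr(time, event, high)
    df = pd.DataFrame({"time": time, "event": event, "high": high.astype(int)})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        ci = cph.confidence_intervals_
        with np.errstate(over="ignore"):  # tiny cohorts give unbounded CIs
            hr_ci = (
                float(np.exp(ci.loc["high"].iloc[0])),
                float(np.exp(ci.loc["high"].iloc[1])),
            )
        hr_method = "cox"
    except (ConvergenceError, ValueError):
        hr = hr_mh
        hr_ci = (float("nan"), float("nan"))
        hr_method = "mantel_haenszel"
    return SurvivalComparison(
        logrank_chi2=float(lr.test_statistic),
        p_value=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci95=hr_ci,
        hr_method=hr_method,
        hr_mantel_haenszel=hr_mh,
        n=len(records),
        n_events=n_events,
        km_curves=curves,
    )
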