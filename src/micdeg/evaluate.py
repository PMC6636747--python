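"""ROC/AUC scoring, per-group summaries, and noise-immunity slope analysis.

A per-gene score vector is judged against the ground-truth DE mask by the
rank-based ROC AUC (Mann-Whitney with midrank tie handling): the
probability that a random DE gene outranks a random non-DE gene, 0.5 being
chance.  Noise immunity is assessed by fitting an ordinary least-squares
line of AUC against the noise level l = 10 - SNR_dB (larger l = more
noise); a line is "horizontal" when |slope| <= 1e-4, "positive" (anomalous)
when the slope exceeds +1e-4, and "negative" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import mic_core
from .noise import DEFAULT_SNR_LEVELS, noise_series
from .simulate import DatasetSpec, dataset_seed, generate_dataset

__all__ = [
    "AUCRecord",
    "SlopeFit",
    "SLOPE_TOLERANCE",
    "roc_auc",
    "auc_summary",
    "fit_noise_auc_line",
    "count_positive_slopes",
    "experiment_noise_free",
    "experiment_noisy",
]

#: lines with |slope| at or below this are treated as horizontal
SLOPE_TOLERANCE = 1.0e-4


@dataclass(frozen=True)
class AUCRecord:
    group_id: str
    replicate: int
    auc: float
    snr_db: float | None = None
    method: str = "mic"


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    category: str
    tolerance: float = SLOPE_TOLERANCE
    group_id: str | None = None
    replicate: int | None = None


def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC with midrank tie handling.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_summary(aucs) -> dict:
    """Summary statistics of a set of AUCs, including the count at or below
    chance level (inclusive <= 0.5)."""
    a = np.asarray(list(aucs), dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AUC record")
    return {
        "n": int(a.size),
        "mean": float(a.mean()),
        "median": float(np.median(a)),
        "variance": float(a.var(ddof=1)) if a.size > 1 else 0.0,
        "q1": float(np.percentile(a, 25)),
        "q3": float(np.percentile(a, 75)),
        "n_le_half": int((a <= 0.5).sum()),
    }


def fit_noise_auc_line(levels, aucs, tolerance: float = SLOPE_TOLERANCE,
                       **meta) -> SlopeFit:
    """OLS line of AUC on noise level; classify its slope.

    ``levels`` are noise intensities (larger = noisier; callers working in
    SNR dB should pass 10 - snr_db).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(aucs, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (level, auc) points")
    if np.unique(x).size < 2:
        raise ValueError("levels must not all be identical")
    slope, intercept = np.polyfit(x, y, 1)
    if abs(slope) <= tolerance:
        cat = "horizontal"
    elif slope > 0:
        cat = "positive"
    else:
        cat = "negative"
    return SlopeFit(slope=float(slope), intercept=float(intercept),
                    category=cat, tolerance=tolerance, **meta)


def count_positive_slopes(fits) -> int:
    """Count fitted lines classified positive (horizontal lines excluded by
    the tolerance rule)."""
    return sum(1 for f in fits if f.category == "positive")


def _score_fn(mic_kwargs):
    kw = mic_kwargs or {}

    def score(ds):
        return mic_core.mic_scores(ds.matrix, ds.phenotype, **kw)

    return score


def experiment_noise_free(groups, reps_per_group: int,
                          spec: DatasetSpec | None = None, base_seed: int = 0,
                          mic_kwargs: dict | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate -> score -> AUC for every (group, replicate).

    Returns tidy records (group, family, replicate, method, auc) and
    per-group summaries including the AUC <= 0.5 count.
    """
    spec = spec or DatasetSpec()
    score = _score_fn(mic_kwargs)
    rows = []
    for g in groups:
        for r in range(reps_per_group):
            ds = generate_dataset(g, spec, rng=dataset_seed(base_seed, g.group_id, r),
                                  replicate=r)
            auc = roc_auc(score(ds), ds.de_mask)
            rows.append({"group_id": g.group_id, "family": g.family,
                         "replicate": r, "snr_db": None, "method": "mic",
                         "auc": auc})
    records = pd.DataFrame(rows, columns=["group_id", "family", "replicate",
                                          "snr_db", "method", "auc"])
    if records.empty:
        return records, pd.DataFrame()
    summaries = (
        records.groupby(["family", "group_id"])["auc"]
        .apply(lambda s: pd.Series(auc_summary(s)))
        .unstack()
        .reset_index()
    )
    return records, summaries


def experiment_noisy(groups, reps_per_group: int, levels=DEFAULT_SNR_LEVELS,
                     spec: DatasetSpec | None = None, base_seed: int = 0,
                     mic_kwargs: dict | None = None,
                     ) -> tuple[pd.DataFrame, list[SlopeFit], dict]:
    """Noise-immunity experiment: per (dataset, SNR level) AUC, one slope
    fit per dataset, and positive-slope counts per family."""
    spec = spec or DatasetSpec()
    levels = list(levels)
    score = _score_fn(mic_kwargs)
    rows = []
    fits: list[SlopeFit] = []
    for g in groups:
        for r in range(reps_per_group):
            seed = dataset_seed(base_seed, g.group_id, r)
            ds = generate_dataset(g, spec, rng=seed, replicate=r)
            aucs = []
            for lvl, noisy in noise_series(ds, levels, base_seed=seed + 1):
                auc = roc_auc(score(noisy), noisy.de_mask)
                aucs.append(auc)
                rows.append({"group_id": g.group_id, "family": g.family,
                             "replicate": r, "snr_db": lvl, "method": "mic",
                             "auc": auc})
            fits.append(fit_noise_auc_line([10.0 - l for l in levels], aucs,
                                           group_id=g.group_id, replicate=r))
    records = pd.DataFrame(rows, columns=["group_id", "family", "replicate",
                                          "snr_db", "method", "auc"])
    fam_of = {g.group_id: g.family for g in groups}
    counts: dict[str, int] = {}
    for f in fits:
        fam = fam_of[f.group_id]
        counts[fam] = counts.get(fam, 0) + (1 if f.category == "positive" else 0)
    return records, fits, counts
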