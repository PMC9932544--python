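"""Behavioral scoring: QuickSiN SNR-loss, target detection, performance levels.

QuickSiN presents one six-sentence list per run, one sentence per SNR step
from 25 dB down to 0 dB in 5 dB steps, five keywords per sentence.  The
SNR-50 (SNR for 50% keyword recall) follows the Spearman-Karber rule
SNR-50 = 27.5 - (total keywords correct); SNR-loss subtracts the 2 dB
normal-hearing reference, and a listener's score is the mean over four
lists.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

QUICKSIN_SNRS = (25, 20, 15, 10, 5, 0)
NH_REFERENCE_DB = 2.0
KEYWORDS_PER_SENTENCE = 5


def quicksin_score_list(tallies) -> float:
    """SNR-loss for a single six-sentence list of keyword tallies."""
    tallies = np.asarray(tallies)
    if tallies.shape != (len(QUICKSIN_SNRS),):
        raise ValueError(f"expected {len(QUICKSIN_SNRS)} sentence tallies, got {tallies.shape}")
    if np.any((tallies < 0) | (tallies > KEYWORDS_PER_SENTENCE)):
        raise ValueError("keyword tallies must be within 0..5")
    snr50 = 27.5 - float(tallies.sum())
    return snr50 - NH_REFERENCE_DB


def quicksin_score(tallies) -> float:
    """Listener SNR-loss: mean over four lists (lists x 6 sentences)."""
    tallies = np.asarray(tallies)
    if tallies.ndim != 2 or tallies.shape[1] != len(QUICKSIN_SNRS):
        raise ValueError("expected lists x 6 sentence tallies")
    return float(np.mean([quicksin_score_list(row) for row in tallies]))


def detection_summary(hits, rts, n_targets: int = 210) -> tuple[float, float]:
    """Percent correct over rare-target trials and mean RT over hits.

    With zero hits the RT is undefined and reported as NaN (missing), not
    zero.
    """
    if n_targets <= 0:
        raise ValueError("no target trials")
    hits = np.asarray(hits, dtype=bool)
    percent = 100.0 * hits.sum() / n_targets
    rts = np.asarray(rts, dtype=float)
    mean_rt = float(rts.mean()) if rts.size else float("nan")
    return float(percent), mean_rt


def performance_levels(
    percent_correct: np.ndarray, low_pct: float = 30.0, high_pct: float = 70.0
) -> np.ndarray:
    """Label each participant 'poor' / 'average' / 'good' by cohort percentiles.

    Poor: score <= 30th percentile; good: score >= 70th percentile
    (linear-interpolation quantiles, boundary-equal scores included, then
    trimmed to the distinct-value class size by rank for the classifier's
    balance bookkeeping).  Invariant to monotone rescaling of the scores.
    """
    scores = np.asarray(percent_correct, dtype=float)
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 participants to form performance levels")
    q_low, q_high = np.quantile(scores, [low_pct / 100.0, high_pct / 100.0])
    if q_low == q_high:
        # fully degenerate cohort: everyone straddles both cutoffs
        return np.full(n, "average", dtype=object).astype(str)
    low_cap = int(math.floor((n - 1) * low_pct / 100.0)) + 1
    high_cap = n - int(math.ceil((n - 1) * high_pct / 100.0))
    labels = np.full(n, "average", dtype=object)
    order = np.argsort(scores, kind="stable")
    poor = [i for i in order if scores[i] <= q_low][:low_cap]
    good = [i for i in order[::-1] if scores[i] >= q_high][:high_cap]
    labels[np.asarray(poor, dtype=int)] = "poor"
    labels[np.asarray(good, dtype=int)] = "good"
    return labels.astype(str)


def score_cohort(cohort) -> pd.DataFrame:
    """Scored behavior summary for a synthetic cohort.

    One row per participant: group, PTA, age, SNR-loss, percent correct
    and mean RT per condition, and the cohort performance level (clear
    condition).
    """
    rows = []
    for p in cohort:
        beh = p.behavior
        row = {
            "participant": p.params.participant,
            "group": p.params.group,
            "age": p.params.age,
            "pta": p.params.pta,
            "snr_loss": quicksin_score(beh["quicksin_tallies"]),
        }
        for condition, rec in beh["conditions"].items():
            pc, rt = detection_summary(rec["hits"], rec["rts"], n_targets=rec["hits"].size)
            row[f"percent_correct_{condition}"] = pc
            row[f"mean_rt_{condition}"] = rt
        rows.append(row)
    df = pd.DataFrame(rows)
    df["performance_level"] = performance_levels(df["percent_correct_clear"].to_numpy())
    return df
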