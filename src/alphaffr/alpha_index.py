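"""Trial-wise cortical state indexing from posterior alpha power.

Single-trial alpha RMS at the POz proxy is normalized to each run's
median, then trials are pooled per participant x condition and split at
the 35th / 65th percentiles into "low alpha" and "high alpha" states (the
middle 30% is set aside).  The same machinery runs unchanged on the
POz-beta (18-22 Hz) and Fz-alpha control streams.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .preprocess import Epochs

CATEGORIES = ("low", "middle", "high")


def trial_rms(alpha_epochs: Epochs) -> np.ndarray:
    """Root-mean-square amplitude per trial over the full epoch window."""
    data = alpha_epochs.data
    if data.size == 0:
        raise ValueError("empty epochs")
    return np.sqrt(np.mean(data.astype(np.float64) ** 2, axis=(1, 2)))


def normalize_by_run(raw_rms: np.ndarray, run_ids: np.ndarray) -> np.ndarray:
    """Divide each trial's RMS by the median RMS of its run (block).

    The per-run median of the output is exactly 1; scaling any run by a
    positive constant leaves its normalized values unchanged.
    """
    raw_rms = np.asarray(raw_rms, dtype=float)
    run_ids = np.asarray(run_ids)
    if raw_rms.shape != run_ids.shape:
        raise ValueError("raw_rms and run_ids must align")
    out = np.empty_like(raw_rms)
    for run in np.unique(run_ids):
        mask = run_ids == run
        med = np.median(raw_rms[mask])
        if med <= 0:
            raise ValueError(f"run {run!r} has non-positive median RMS")
        out[mask] = raw_rms[mask] / med
    return out


def _cap_counts(n: int, low_pct: float, high_pct: float) -> tuple[int, int]:
    # counts a linearly interpolated quantile admits when values are distinct
    low_cap = int(math.floor((n - 1) * low_pct / 100.0)) + 1
    high_cap = n - int(math.ceil((n - 1) * high_pct / 100.0))
    return low_cap, high_cap


def categorize(
    norm_rms: np.ndarray, low_pct: float = 35.0, high_pct: float = 65.0
) -> np.ndarray:
    """Label trials 'low' / 'middle' / 'high' by pooled percentile cutoffs.

    Quantiles use linear interpolation.  Values equal to a cutoff go to the
    extreme category; if ties push a category past the count a distinct-
    valued sample would have, the earliest trials (by index) are kept and
    the excess returns to 'middle'.  Low is assigned before high, so in
    fully degenerate input the two never overlap.
    """
    norm_rms = np.asarray(norm_rms, dtype=float)
    n = norm_rms.size
    if n < 3:
        raise ValueError("need at least 3 trials to categorize")
    q_low, q_high = np.quantile(norm_rms, [low_pct / 100.0, high_pct / 100.0])
    low_cap, high_cap = _cap_counts(n, low_pct, high_pct)
    cats = np.full(n, "middle", dtype=object)

    def _assign(candidates: np.ndarray, boundary: np.ndarray, cap: int, label: str):
        strict = candidates & ~boundary
        chosen = list(np.flatnonzero(strict))
        for i in np.flatnonzero(boundary & candidates):
            if len(chosen) >= cap:
                break
            chosen.append(i)
        cats[np.asarray(chosen, dtype=int)[:cap]] = label

    unassigned = np.full(n, True)
    _assign(norm_rms <= q_low, norm_rms == q_low, low_cap, "low")
    unassigned = cats == "middle"
    _assign((norm_rms >= q_high) & unassigned, (norm_rms == q_high) & unassigned,
            high_cap, "high")
    return cats.astype(str)


def span_lengths(categories: np.ndarray) -> dict:
    """Mean length of maximal consecutive runs of 'low' and 'high' labels.

    'middle' trials break runs.  Returns per-category means (NaN if a
    category never occurs).
    """
    categories = np.asarray(categories)
    out = {}
    for label in ("low", "high"):
        runs = []
        count = 0
        for c in categories:
            if c == label:
                count += 1
            elif count:
                runs.append(count)
                count = 0
        if count:
            runs.append(count)
        out[label] = float(np.mean(runs)) if runs else float("nan")
    return out


def build_trial_table(
    alpha_epochs: Epochs, low_pct: float = 35.0, high_pct: float = 65.0
) -> pd.DataFrame:
    """Full per-trial table: raw RMS, run-normalized RMS, state category.

    Percentiles are pooled over all runs of the participant-condition
    (normalization is per run, categorization is pooled).
    """
    raw = trial_rms(alpha_epochs)
    md = alpha_epochs.metadata
    norm = normalize_by_run(raw, md["block"].to_numpy())
    cats = categorize(norm, low_pct, high_pct)
    table = md.copy()
    table["raw_rms"] = raw
    table["norm_rms"] = norm
    table["category"] = cats
    return table
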