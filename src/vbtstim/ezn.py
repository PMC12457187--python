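"""Epileptogenicity values (EVs): onset detection and per-region summaries.

A region's onset t_i is the first sample of its (estimated or simulated)
source time series with x strictly above 0; regions that never cross
receive the sentinel value 200.  With t_0 = min_i t_i, the raw EV is

    EV_i = -log(((t_i - t_0) + 1) / 20)

(natural log), strictly decreasing in onset delay, and each sample's EV
vector is min-max normalized to [0, 1].  An all-equal vector (for
instance no seizure anywhere) maps to all zeros: no epileptogenic
evidence.  Onset times, the sentinel and the /20 scale are expressed in
time-grid units and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SourceActivity

__all__ = [
    "OnsetVector",
    "EVResult",
    "detect_onsets",
    "compute_evs",
    "ev_samples_from_trajectories",
    "summarize_ev_posterior",
]

ONSET_SENTINEL = 200.0
EV_TIME_SCALE = 20.0


@dataclass
class OnsetVector:
    """Per-region onset times on the source grid; sentinel for non-seizing."""

    t: np.ndarray
    sentinel: float = ONSET_SENTINEL

    @property
    def t0(self) -> float:
        return float(self.t.min())


@dataclass
class EVResult:
    """Raw and [0, 1]-normalized EVs of one posterior sample."""

    raw: np.ndarray
    normalized: np.ndarray


def _first_crossings(values: np.ndarray, threshold: float,
                     sentinel: float) -> np.ndarray:
    above = values > threshold  # strictly "above": x = threshold excluded
    any_above = above.any(axis=1)
    first = above.argmax(axis=1).astype(float)
    first[~any_above] = sentinel
    return first


def detect_onsets(activity: SourceActivity, threshold: float = 0.0,
                  sentinel: float = ONSET_SENTINEL) -> OnsetVector:
    """First sample index with x strictly above ``threshold`` per region."""
    if activity.node_kind != "region":
        raise ValueError("onset detection expects region-level activity")
    if activity.values.shape[1] == 0:
        raise ValueError("empty source series")
    return OnsetVector(t=_first_crossings(activity.values, threshold, sentinel),
                       sentinel=sentinel)


def compute_evs(onsets: OnsetVector, time_scale: float = EV_TIME_SCALE) -> EVResult:
    """EV_i = -log(((t_i - t_0) + 1) / time_scale), min-max normalized."""
    delay = onsets.t - onsets.t0
    raw = -np.log((delay + 1.0) / time_scale)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        normalized = np.zeros_like(raw)
    else:
        normalized = (raw - lo) / (hi - lo)
    return EVResult(raw=raw, normalized=normalized)


def ev_samples_from_trajectories(x_draws: np.ndarray, threshold: float = 0.0,
                                 sentinel: float = ONSET_SENTINEL,
                                 time_scale: float = EV_TIME_SCALE) -> np.ndarray:
    """Normalized EVs for a stack of source trajectories.

    ``x_draws`` has shape (n_samples, L, n_times); returns (n_samples, L).
    """
    out = np.empty(x_draws.shape[:2])
    for s in range(x_draws.shape[0]):
        onsets = OnsetVector(_first_crossings(x_draws[s], threshold, sentinel),
                             sentinel=sentinel)
        out[s] = compute_evs(onsets, time_scale).normalized
    return out


def summarize_ev_posterior(ev_samples: np.ndarray,
                           region_names: list[str]) -> pd.DataFrame:
    """Percentile table (25/50/75) per region, ranked by median EV."""
    ev_samples = np.atleast_2d(ev_samples)
    if ev_samples.shape[0] < 1:
        raise ValueError("need at least one EV sample")
    p25, med, p75 = np.percentile(ev_samples, [25, 50, 75], axis=0)
    df = pd.DataFrame({"region": region_names, "p25": p25,
                       "median": med, "p75": p75})
    df["rank"] = df["median"].rank(ascending=False, method="min").astype(int)
    return df.sort_values("rank", kind="stable").reset_index(drop=True)
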