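"""Contamination-dependent score thresholding and the read-budget formula.

The filtering policy keeps reads whose maternal-origin score falls below a
threshold chosen from the estimated contamination fraction r:

* r <= 0.10 (low contamination): retain all reads;
* 0.10 < r < 0.60 (moderate): threshold 0.2;
* r >= 0.60 (high): stringent threshold 0.15.

The read budget needed for reliable CNV reconstruction at contamination r
is ``ceil(120 / (1 - r) * 10_000)`` input reads — the empirical baseline of
1.2M reads at r = 0 scaled by the expected retention loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .readio import ReadSet
from .scores import ScoreSet

__all__ = [
    "ThresholdPolicy",
    "RETAIN_ALL",
    "choose_threshold",
    "filter_reads",
    "required_reads",
    "sufficiency_check",
]

RETAIN_ALL = None  # sentinel: no score filtering applied


@dataclass(frozen=True)
class ThresholdPolicy:
    low_band: float = 0.10
    high_band: float = 0.60
    moderate_threshold: float = 0.20
    high_threshold: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.high_threshold <= self.moderate_threshold < 0.5):
            raise ValueError("need 0 < high_threshold <= moderate_threshold < 0.5")
        if not (0 < self.low_band < self.high_band <= 1):
            raise ValueError("need 0 < low_band < high_band <= 1")


def choose_threshold(r: float, policy: ThresholdPolicy = ThresholdPolicy()):
    """Score threshold for a sample at contamination fraction ``r``.

    Returns ``RETAIN_ALL`` (None) in the low-contamination band.
    """
    if not 0 <= r <= 1:
        raise ValueError("contamination fraction must lie in [0, 1]")
    if r <= policy.low_band:
        return RETAIN_ALL
    if r < policy.high_band:
        return policy.moderate_threshold
    return policy.high_threshold


def filter_reads(readset: ReadSet, scores, threshold) -> ReadSet:
    """Retain reads with score strictly below ``threshold``.

    ``threshold=RETAIN_ALL`` keeps everything.  Retained counts are logged
    in the output provenance.
    """
    s = scores.scores if isinstance(scores, ScoreSet) else np.asarray(scores, dtype=float)
    if s.size != len(readset):
        raise ValueError(f"scores ({s.size}) and reads ({len(readset)}) length mismatch")
    if threshold is RETAIN_ALL:
        keep = np.ones(s.size, dtype=bool)
    else:
        keep = s < threshold
    out = readset[keep]
    out.provenance["filter_threshold"] = None if threshold is RETAIN_ALL else float(threshold)
    out.provenance["n_input"] = int(s.size)
    out.provenance["n_retained"] = int(keep.sum())
    out.provenance["retained_fraction"] = float(keep.mean()) if s.size else 0.0
    return out


def required_reads(r: float) -> int:
    """Input reads needed for reliable CNV reconstruction at contamination
    ``r``: 120 / (1 - r) in units of 10,000 reads, rounded up."""
    if not 0 <= r < 1:
        raise ValueError("contamination fraction must lie in [0, 1)")
    value = 1_200_000.0 / (1.0 - r)
    nearest = round(value)
    if abs(value - nearest) < 1e-6 * max(nearest, 1):  # absorb float round-off
        return int(nearest)
    return math.ceil(value)


def sufficiency_check(n_available: int, r: float) -> dict:
    """Advisory comparison of available reads against the budget formula."""
    needed = required_reads(r)
    shortfall = max(0, needed - n_available)
    out = {
        "sufficient": n_available >= needed,
        "needed": needed,
        "available": int(n_available),
        "shortfall": shortfall,
    }
    if shortfall:
        out["advisory"] = (
            f"deeper sequencing recommended: {needed:,} reads needed at "
            f"contamination {r:.2f}, {n_available:,} available"
        )
    return out
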