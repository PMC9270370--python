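"""Conditional predicates that convert image features into triggers.

All predicates are pure functions of their inputs; edge-triggering
(fire-once semantics) belongs to the scenario engine.  Three trigger kinds
cover the built-in protocols: a cell-count threshold (population-density
triggered perfusion switching), detection of a fluorescent cell (pick one
RFP-positive region at random to track), and bud-growth mitosis prediction
(a bud that has reached a threshold size and grown over each of the last
three frames is about to undergo nuclear separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CONDITION_KINDS = ("count_threshold", "rfp_positive", "bud_mitosis")


@dataclass
class ConditionSpec:
    kind: str
    params: dict = field(default_factory=dict)
    position_id: int = 0
    repeating: bool = False

    def __post_init__(self):
        if self.kind not in CONDITION_KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}")
        required = {
            "count_threshold": {"n"},
            "rfp_positive": {"intensity_threshold"},
            "bud_mitosis": {"a_min_px", "k_frames"},
        }[self.kind]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"condition {self.kind} missing params {sorted(missing)}")


@dataclass
class TriggerRecord:
    t_sim: float
    position_id: int
    kind: str
    payload: dict = field(default_factory=dict)


def eval_count_threshold(features, n: int) -> bool:
    """True iff the number of (non-bud) regions reaches ``n``."""
    if n < 1:
        raise ValueError("threshold must be >= 1")
    count = sum(1 for f in features if not f.is_bud_candidate)
    return count >= n


def find_rfp_cell(features, intensity_threshold: float,
                  rng: np.random.Generator) -> Optional[int]:
    """Uniform random choice among regions whose RFP mean reaches threshold."""
    qualifiers = [f.label for f in features
                  if f.mean_intensity.get("RFP", 0.0) >= intensity_threshold]
    if not qualifiers:
        return None
    return int(qualifiers[int(rng.integers(len(qualifiers)))])


def bud_mitosis_imminent(area_history, a_min_px: float, k_frames: int = 3) -> bool:
    """Mitosis is imminent when the bud has reached ``a_min_px`` and has
    grown strictly over each of the last ``k_frames`` frames.

    ``area_history`` is time-ordered; fewer than ``k_frames + 1`` samples is
    insufficient evidence and returns False.  Strict growth over every recent
    frame is what rejects segmentation jitter.
    """
    hist = list(area_history)
    if len(hist) < k_frames + 1:
        return False
    if hist[-1] < a_min_px:
        return False
    recent = hist[-(k_frames + 1):]
    return all(b > a for a, b in zip(recent, recent[1:]))


def default_rfp_threshold(background_mean: float, background_sd: float) -> float:
    """RFP positivity: background mean + 5 standard deviations."""
    return background_mean + 5.0 * background_sd


def auto_bud_a_min(features, frac: float = 0.35) -> float:
    """Median-based bud-size threshold: ``frac`` x the median non-bud region
    area, in px^2 (size filtering against a population reference)."""
    mothers = [f.area_px for f in features if not f.is_bud_candidate]
    if not mothers:
        return float("inf")
    return frac * float(np.median(mothers))


def bud_a_min_for_mother(mother_area_px: float, frac: float = 0.38) -> float:
    """Size-relative bud threshold: ``frac`` x the linked mother's own area.

    Scaling the threshold to each mother removes the mother-size bias a
    population-median threshold has (small mothers divide at absolutely
    smaller bud sizes), so the trigger leads nuclear separation by a
    mother-size-independent margin.
    """
    return frac * float(mother_area_px)


def bud_a_min_from_regions(mother_area_px: float, bud_area_px: float,
                           frac: float = 0.38) -> float:
    """Size-relative threshold computed from the mother+bud region pair.

    Algebraically identical to ``frac x mother area`` (the bud fires when
    ``bud >= frac/(1+frac) x (mother + bud)``), but measured on the summed
    region areas: pixels the bud's footprint carves out of the mother's
    region stay inside the sum, so the threshold is insensitive to how the
    segmenter splits the neck.
    """
    return frac / (1.0 + frac) * (float(mother_area_px) + float(bud_area_px))
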