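"""Optimal-concentration selection and antibody-panel cost comparison.

Each antibody's optimal concentration is the lowest dilution that still
detects the target with near-full separation quality; antibodies with no
signal at any concentration are dropped.  The cost proxy for a panel is
its *relative antibody amount*: the sum of the retained antibodies'
concentration factors divided by the full panel size, so the tested
panel (everything at 1x) scores 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import ValidationError
from .thresholding import DetectCall

OPTIMAL_CLASSES = ("2x", "1x", "0.2x", "0.04x", "drop")
CLASS_WEIGHTS = {"2x": 2.0, "1x": 1.0, "0.2x": 0.2, "0.04x": 0.04, "drop": 0.0}


@dataclass(frozen=True)
class OptimizationParams:
    quality_fraction: float = 0.8   # required share of the best separation


@dataclass
class PanelPlan:
    optimal_class: dict[str, str]   # antibody_id -> class
    relative_amount: float
    n_retained: int

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in OPTIMAL_CLASSES}
        for c in self.optimal_class.values():
            counts[c] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"antibody_id": list(self.optimal_class),
             "optimal_class": list(self.optimal_class.values())})


def select_optimal_concentration(
    calls_by_arm: dict[str, DetectCall],
    params: OptimizationParams | None = None,
) -> str:
    """Pick one antibody's optimal concentration class.

    Rules: not detectable anywhere -> drop; otherwise the lowest-factor
    detectable arm whose separation retains at least ``quality_fraction``
    of the best separation across detectable arms.  The double
    concentration is selected only when it is the only detectable arm or
    when every arm at or below 1x fails the quality bar.
    """
    params = params or OptimizationParams()
    required = set(CLASS_WEIGHTS) - {"drop"}
    missing = required - set(calls_by_arm)
    if missing:
        raise ValidationError(f"missing arms in calls: {sorted(missing)}")
    detectable = {a: c for a, c in calls_by_arm.items() if c.detectable}
    if not detectable:
        return "drop"

    def quality(call) -> float:
        # an arm where essentially every cell stains above the isotype
        # background has no negative population left to separate from:
        # complete separation is trivially achieved, so such arms rank
        # above any finite mixture separation
        if (call.mode == "positive5"
                or call.above_background_fraction >= 0.9):
            return float("inf")
        return call.separation

    best = max(quality(c) for c in detectable.values())
    for arm in ("0.04x", "0.2x", "1x", "2x"):  # ascending factor
        c = detectable.get(arm)
        if c is None:
            continue
        if best == 0 or quality(c) >= params.quality_fraction * best:
            return arm
    # every detectable arm failed the bar (only possible via rounding);
    # fall back to the arm with the best separation
    return max(detectable, key=lambda a: quality(detectable[a]))


def relative_amount(class_counts: dict[str, int], n_total: int,
                    weights: dict[str, float] | None = None) -> float:
    """Sum of count * concentration-factor over classes, divided by the
    panel size; dropped antibodies contribute zero."""
    weights = weights or CLASS_WEIGHTS
    if sum(class_counts.values()) != n_total:
        raise ValidationError(
            f"class counts sum to {sum(class_counts.values())}, "
            f"expected {n_total}")
    return sum(class_counts.get(c, 0) * weights[c] for c in weights) / n_total


def compare_panels(plan_a_amount: float, plan_b_amount: float) -> float:
    """Percent reduction of plan A's antibody amount relative to plan B."""
    if plan_b_amount == 0:
        raise ValidationError("comparison panel has zero amount")
    return 100.0 * (1.0 - plan_a_amount / plan_b_amount)


def build_optimized_panel(
    calls: list[DetectCall],
    panel,
    params: OptimizationParams | None = None,
) -> PanelPlan:
    """Apply optimal-concentration selection across the panel.

    Isotype controls are always retained at 1x (they stay in the
    optimized panel as the background reference and are not titrated).
    """
    params = params or OptimizationParams()
    by_ab: dict[str, dict[str, DetectCall]] = {}
    for c in calls:
        by_ab.setdefault(c.antibody_id, {})[c.arm_label] = c
    iso = set(panel.isotype_ids)
    optimal: dict[str, str] = {}
    missing = [e.antibody_id for e in panel.entries
               if not e.is_isotype_control and e.antibody_id not in by_ab]
    if missing:
        raise ValidationError(f"calls missing for antibodies: {missing}")
    for e in panel.entries:
        if e.antibody_id in iso:
            optimal[e.antibody_id] = "1x"
        else:
            optimal[e.antibody_id] = select_optimal_concentration(
                by_ab[e.antibody_id], params)
    counts = {c: 0 for c in OPTIMAL_CLASSES}
    for c in optimal.values():
        counts[c] += 1
    amount = relative_amount(counts, panel.n_total)
    n_retained = sum(v for k, v in counts.items() if k != "drop")
    return PanelPlan(optimal_class=optimal, relative_amount=amount,
                     n_retained=n_retained)
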