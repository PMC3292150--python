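"""Six-rule type-1 fuzzy classifier labeling each second NF / TF / F.

Inputs are the elbow angle (degrees) and the angular oscillation (degrees SD
over 4-s blocks).  Antecedents are piecewise-linear triangular/trapezoidal
membership functions; inference is the product of the two antecedent
memberships; the single winning label is the consequent of the rule with the
greatest firing strength (ties resolve toward the more severe class).

Angle terms are parameterized from the two published boundaries: angles above
89 degrees are fully non-fatigued, angles below 86.5 fully fatigued, with
linear overlap between.  Oscillation terms cross at 0.6 degrees SD, the
oscillation level marking the transition out of non-fatigue.  The exact
breakpoints of the oscillation terms are a parameterization (only the 0.6
crossover is fixed by the source material) and can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    FatigueClass,
    LabelSeries,
    Trial,
    ValidationError,
    align_labels_to_seconds,
)
from .preprocess import gonio_oscillation

__all__ = [
    "MembershipFunction",
    "FuzzyRule",
    "RuleFiring",
    "FuzzyLabeler",
    "membership",
    "classify_sample",
    "label_trial",
    "default_labeler",
    "NoRuleFiredWarning",
]


class NoRuleFiredWarning(UserWarning):
    """All rule firing strengths were zero; NF returned by convention."""


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership: 'triangular' (a<=b<=c) or 'trapezoidal'
    (a<=b<=c<=d).  A repeated boundary pair collapses that ramp into an open
    shoulder (membership stays 1 beyond it), so supports can be unbounded."""

    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {"triangular": 3, "trapezoidal": 4}.get(self.shape)
        if expected is None:
            raise ValidationError(f"unknown membership shape {self.shape!r}")
        if len(self.breakpoints) != expected:
            raise ValidationError(
                f"{self.shape} membership needs {expected} breakpoints; "
                f"got {len(self.breakpoints)}"
            )
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValidationError("breakpoints must be sorted ascending")

    def __call__(self, x):
        return membership(self, x)


def membership(mf: MembershipFunction, x) -> np.ndarray | float:
    """Evaluate a membership function at scalar or array ``x``; values in [0, 1]."""
    if mf.shape == "triangular":
        a, b, c = mf.breakpoints
        bps = (a, b, b, c)
    else:
        bps = mf.breakpoints
    a, b, c, d = bps
    x = np.asarray(x, dtype=float)
    if a == b:  # open left shoulder: no rising ramp
        left = np.ones_like(x)
    else:
        left = np.where(x >= b, 1.0, np.clip((x - a) / (b - a), 0.0, 1.0))
    if c == d:  # open right shoulder: no falling ramp
        right = np.ones_like(x)
    else:
        right = np.where(x <= c, 1.0, np.clip((d - x) / (d - c), 0.0, 1.0))
    out = np.minimum(left, right)
    return float(out) if out.ndim == 0 else out


# Default parameterization.  Angle terms reproduce the published crisp
# regions (>89 NF, <86.5 F) with linear overlap between; oscillation terms
# cross at 0.6 degrees SD.
DEFAULT_ANGLE_MFS: dict[str, MembershipFunction] = {
    "NF": MembershipFunction("trapezoidal", (86.5, 89.0, 180.0, 180.0)),
    "TF": MembershipFunction("triangular", (86.5, 87.75, 89.0)),
    "F": MembershipFunction("trapezoidal", (0.0, 0.0, 86.5, 89.0)),
}
DEFAULT_OSC_MFS: dict[str, MembershipFunction] = {
    "Low": MembershipFunction("trapezoidal", (0.0, 0.0, 0.4, 0.8)),
    "High": MembershipFunction("trapezoidal", (0.4, 0.8, 10.0, 10.0)),
}


@dataclass(frozen=True)
class FuzzyRule:
    angle_term: str  # one of NF / TF / F
    osc_term: str    # Low / High
    consequent: FatigueClass


# Rule base: (angle term, oscillation term) -> label.
RULE_BASE: tuple[FuzzyRule, ...] = (
    FuzzyRule("NF", "Low", FatigueClass.NON_FATIGUE),
    FuzzyRule("NF", "High", FatigueClass.TRANSITION_TO_FATIGUE),
    FuzzyRule("TF", "Low", FatigueClass.TRANSITION_TO_FATIGUE),
    FuzzyRule("TF", "High", FatigueClass.TRANSITION_TO_FATIGUE),
    FuzzyRule("F", "Low", FatigueClass.FATIGUE),
    FuzzyRule("F", "High", FatigueClass.FATIGUE),
)


@dataclass(frozen=True)
class RuleFiring:
    rule: FuzzyRule
    strength: float  # product of the two antecedent memberships


@dataclass(frozen=True)
class FuzzyLabeler:
    angle_mfs: dict[str, MembershipFunction] = field(
        default_factory=lambda: dict(DEFAULT_ANGLE_MFS))
    osc_mfs: dict[str, MembershipFunction] = field(
        default_factory=lambda: dict(DEFAULT_OSC_MFS))
    rules: tuple[FuzzyRule, ...] = RULE_BASE

    def firings(self, angle: float, osc: float) -> list[RuleFiring]:
        out = []
        for rule in self.rules:
            strength = float(
                membership(self.angle_mfs[rule.angle_term], angle)
                * membership(self.osc_mfs[rule.osc_term], osc)
            )
            out.append(RuleFiring(rule, strength))
        return out

    def classify_sample(self, angle: float, osc: float) -> tuple[FatigueClass, RuleFiring]:
        """Product inference over all rules; winner takes all, ties toward the
        more severe class.  If no rule fires, NF is returned with a warning."""
        if not 0 <= angle <= 180:
            raise ValidationError(f"angle {angle} outside [0, 180] degrees")
        if osc < 0:
            raise ValidationError(f"oscillation {osc} must be non-negative")
        firings = self.firings(angle, osc)
        winner = max(firings, key=lambda f: (f.strength, int(f.rule.consequent)))
        if winner.strength == 0.0:
            warnings.warn(
                "no fuzzy rule fired; defaulting to NON_FATIGUE",
                NoRuleFiredWarning,
            )
            return FatigueClass.NON_FATIGUE, winner
        return winner.rule.consequent, winner

    def classify_samples(self, angle: np.ndarray, osc: np.ndarray) -> np.ndarray:
        """Vectorized winner-take-all classification; returns int codes."""
        mu_angle = {t: membership(mf, angle) for t, mf in self.angle_mfs.items()}
        mu_osc = {t: membership(mf, osc) for t, mf in self.osc_mfs.items()}
        # order rules severe-first so argmax's first-max rule breaks ties
        # toward the more severe consequent
        ordered = sorted(self.rules, key=lambda r: -int(r.consequent))
        strengths = np.stack(
            [mu_angle[r.angle_term] * mu_osc[r.osc_term] for r in ordered]
        )
        consequents = np.array([int(r.consequent) for r in ordered])
        winners = consequents[np.argmax(strengths, axis=0)]
        dead = strengths.max(axis=0) == 0.0
        if np.any(dead):
            warnings.warn(
                f"{int(dead.sum())} samples fired no rule; defaulting to NON_FATIGUE",
                NoRuleFiredWarning,
            )
            winners = np.where(dead, int(FatigueClass.NON_FATIGUE), winners)
        return winners

    def label_trial(self, trial: Trial, osc_window_s: float = 4.0) -> LabelSeries:
        """Label a trial per second from its goniometer trace."""
        if trial.duration_s < osc_window_s:
            raise ValidationError(
                f"trial of {trial.duration_s:.1f} s is shorter than one "
                f"{osc_window_s}-s oscillation block"
            )
        osc = gonio_oscillation(trial.gonio_angle, trial.fs_gonio, osc_window_s)
        codes = self.classify_samples(trial.gonio_angle, osc)
        return align_labels_to_seconds(
            [FatigueClass(int(c)) for c in codes], trial.fs_gonio
        )


def default_labeler() -> FuzzyLabeler:
    return FuzzyLabeler()


def classify_sample(angle: float, osc: float) -> tuple[FatigueClass, RuleFiring]:
    """Module-level convenience using the default parameterization."""
    return default_labeler().classify_sample(angle, osc)


def label_trial(trial: Trial) -> LabelSeries:
    """Label a trial per second using the default parameterization."""
    return default_labeler().label_trial(trial)
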