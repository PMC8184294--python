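"""Published reference values for manual versus automated highway driving.

A highway driving study with 12 drivers, each driving the same scenario
once manually and once under conditional (SAE level 3) automation,
reported the distribution of visual attention over 13 areas of interest
(AOIs) and the signed PLS-regression coefficients of the oculometric
indicators that discriminate the two states. Those printed values serve
two roles here:

* as the default targets of the synthetic gaze simulator
  (:mod:`gazestate.simulate`), whose condition-specific Markov chains are
  built to reproduce the reported dwell profiles and whose automated
  condition over-expresses the reported automated-associated transitions;
* as inputs to worked-example analyses (condition differences, the
  sign census of the selected transitions, and the entering/exiting
  net-flow classification of AOIs).

All dwell values are percentages of driving time; coefficients are on the
standardised-indicator scale and only their sign and relative magnitude
are meaningful.
"""

from __future__ import annotations

# Canonical AOI order used everywhere in the package.
AOI_CODES: tuple[str, ...] = (
    "RC", "Up", "Down", "Left", "Right", "CM", "LM", "RM",
    "LS", "RS", "D", "HMI", "Others",
)

AOI_NAMES: dict[str, str] = {
    "RC": "Road Centre",
    "Up": "Up Area",
    "Down": "Down Area",
    "Left": "Left Area",
    "Right": "Right Area",
    "CM": "Central Mirror",
    "LM": "Left Mirror",
    "RM": "Right Mirror",
    "LS": "Left Screen",
    "RS": "Right Screen",
    "D": "Dashboard",
    "HMI": "HMI",
    "Others": "Others Area",
}

# Reported percentage of driving time spent in each AOI, per condition.
# Columns do not sum to exactly 100 (printing precision); consumers that
# need a probability vector must normalise.
DWELL_PCT_MANUAL: dict[str, float] = {
    "RC": 67.45, "Up": 14.74, "Down": 0.32, "Left": 1.561, "Right": 2.91,
    "CM": 4.084, "LM": 0.137, "RM": 0.01, "LS": 2.6, "RS": 2.679,
    "D": 2.08, "HMI": 0.01, "Others": 1.48,
}

DWELL_PCT_AUTOMATED: dict[str, float] = {
    "RC": 40.76, "Up": 17.99, "Down": 0.67, "Left": 2.09, "Right": 4.46,
    "CM": 6.9, "LM": 0.31, "RM": 0.07, "LS": 7.14, "RS": 6.78,
    "D": 4.45, "HMI": 0.31, "Others": 8.03,
}

# Reported condition difference (automated minus manual), as printed.
DWELL_PCT_DIFFERENCE: dict[str, float] = {
    "RC": -26.69, "RM": 0.06, "LM": 0.173, "HMI": 0.3, "Down": 0.35,
    "Left": 0.529, "Right": 1.55, "D": 2.37, "CM": 2.816, "Up": 3.25,
    "RS": 4.101, "LS": 4.54, "Others": 6.55,
}

# Signed PLS coefficients of the static indicators retained by the
# reported static-only model, and their value in the combined
# static+dynamic model. Positive = manual-associated.
STATIC_COEFFICIENTS: list[tuple[str, float, float]] = [
    ("RC", 0.257, 0.058),
    ("D", -0.149, -0.034),
    ("Others", -0.171, -0.039),
    ("LS", -0.191, -0.043),
    ("RS", -0.194, -0.044),
    ("CM", -0.203, -0.046),
    ("Down", -0.202, -0.046),
]

# Signed PLS coefficients of the 32 transition (dynamic) indicators
# retained by the reported dynamic-only model: (origin, destination,
# dynamic-model coefficient, combined-model coefficient).
TRANSITION_COEFFICIENTS: list[tuple[str, str, float, float]] = [
    ("Left", "RC", 0.064, 0.051),
    ("Up", "RC", 0.058, 0.047),
    ("RS", "RC", 0.057, 0.045),
    ("Down", "RC", 0.055, 0.044),
    ("Right", "RC", 0.052, 0.042),
    ("LS", "RC", 0.052, 0.041),
    ("D", "LS", 0.048, 0.039),
    ("RM", "LM", 0.046, 0.037),
    ("RS", "Down", 0.046, 0.037),
    ("Others", "RC", 0.046, 0.037),
    ("RC", "Down", 0.045, 0.036),
    ("HMI", "CM", 0.044, 0.035),
    ("D", "RC", 0.041, 0.033),
    ("Others", "D", 0.042, 0.033),
    ("HMI", "Others", -0.033, -0.025),
    ("Right", "D", -0.040, -0.032),
    ("CM", "D", -0.040, -0.032),
    ("Down", "HMI", -0.044, -0.035),
    ("Left", "CM", -0.046, -0.036),
    ("RC", "HMI", -0.046, -0.037),
    ("CM", "LM", -0.047, -0.037),
    ("Others", "Others", -0.046, -0.037),
    ("Up", "Up", -0.048, -0.039),
    ("RC", "Others", -0.049, -0.039),
    ("Down", "Down", -0.052, -0.042),
    ("CM", "RS", -0.056, -0.044),
    ("Others", "LS", -0.057, -0.044),
    ("Left", "Right", -0.059, -0.047),
    ("Left", "Left", -0.057, -0.05),
    ("Down", "CM", -0.067, -0.052),
    ("RC", "CM", -0.069, -0.055),
    ("HMI", "HMI", -0.081, -0.065),
]


def manual_transitions() -> list[tuple[str, str]]:
    """Transitions whose reported dynamic coefficient is positive
    (manual-driving signature)."""
    return [(a, b) for a, b, dyn, _ in TRANSITION_COEFFICIENTS if dyn > 0]


def automated_transitions() -> list[tuple[str, str]]:
    """Transitions whose reported dynamic coefficient is negative
    (automated-driving signature)."""
    return [(a, b) for a, b, dyn, _ in TRANSITION_COEFFICIENTS if dyn < 0]
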