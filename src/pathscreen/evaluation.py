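"""Dose-response AUC, ROC biomarker evaluation, and Bliss synergy.

dr-AUC is the trapezoidal area of fractional viability over unit-spaced
concentration indices: 0 means complete kill at every dose, 15 a flat
100%-viability curve over the standard 16 concentrations, and values above
n_conc - 1 indicate drug-induced proliferation.  The Bliss index is the
observed combination viability over the independence expectation
v_a * v_b; an index below 0.5 calls synergy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class DoseResponseCurve:
    """Fractional viabilities (1.0 = untreated) at ascending concentrations."""

    viability: np.ndarray

    def __post_init__(self) -> None:
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.ndim != 1 or len(self.viability) < 2:
            raise ValueError("need viability at >= 2 concentrations")
        if not np.all(np.isfinite(self.viability)) or (self.viability < 0).any():
            raise ValueError("viabilities must be finite and >= 0")

    @property
    def n_conc(self) -> int:
        return len(self.viability)


@dataclass
class BlissResult:
    viability_a: float
    viability_b: float
    viability_ab: float
    index: float | None
    synergistic: bool
    threshold: float = 0.5


def dose_response_auc(curve: DoseResponseCurve) -> float:
    """Trapezoidal dr-AUC over unit-spaced concentration indices.

    A flat viability v over 16 points integrates to 15 * v, anchoring the
    published 0 (complete kill) and 15 (no killing) endpoints.
    """
    return float(np.trapezoid(curve.viability, dx=1.0))


def roc_curve_auc(
    scores: np.ndarray, labels: np.ndarray, positive_low_score: bool = False
) -> float:
    """ROC AUC: probability a positive outranks a negative, ties at 0.5.

    ``positive_low_score`` evaluates the convention where smaller scores
    predict the positive class (e.g. low pathway activity predicting
    sensitivity); the returned AUC is then for the negated scores.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("need both classes present")
    return float(roc_auc_score(y, -s if positive_low_score else s))


def bliss_synergy(
    viability_a: float,
    viability_b: float,
    viability_ab: float,
    threshold: float = 0.5,
) -> BlissResult:
    """Bliss-independence synergy call for one drug pair.

    index = v_ab / (v_a * v_b); 1 at independence, < threshold synergistic.
    A vanishing expected viability (either single agent already kills
    everything) leaves the index undefined and the call negative.
    """
    for name, v in (("viability_a", viability_a), ("viability_b", viability_b),
                    ("viability_ab", viability_ab)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    expected = viability_a * viability_b
    if expected < 1e-9:
        return BlissResult(viability_a, viability_b, viability_ab,
                           index=None, synergistic=False, threshold=threshold)
    index = viability_ab / expected
    return BlissResult(viability_a, viability_b, viability_ab,
                       index=index, synergistic=index < threshold, threshold=threshold)
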