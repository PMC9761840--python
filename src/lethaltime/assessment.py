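"""Predicted-vs-observed assessment: model deviation ratio and labels.

MDR = predicted LC50 / observed LC50. A ratio near 1 means the mixture
behaved additively; conventional cut-offs label MDR > 2 synergistic,
MDR < 0.5 antagonistic, and anything in [0.5, 2] additive. Separately,
MDR values inside the open interval (0.5, 2) are considered "valid" in the
compliance sense. Acute LC50s are binned into the standard aquatic-hazard
categories: [0.1, 1) mg/L highly toxic, [1, 10) moderately toxic,
[10, 100) slightly toxic; every interval is half-open [lo, hi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

SYNERGISTIC = "synergistic"
ADDITIVE = "additive"
ANTAGONISTIC = "antagonistic"

HIGHLY_TOXIC = "highly toxic"
MODERATELY_TOXIC = "moderately toxic"
SLIGHTLY_TOXIC = "slightly toxic"
OUT_OF_SCHEME = "out-of-scheme"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (display convention)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class MdrResult:
    predicted: float  # mg/L
    observed: float  # mg/L
    mdr: float  # full precision predicted/observed
    valid: bool  # 0.5 < mdr < 2
    interaction: str

    @property
    def mdr_display(self) -> float:
        """MDR rounded half-up to 2 decimals, as reported in tables."""
        return round_half_up(self.mdr, 2)


def classify_interaction(mdr: float) -> str:
    """Synergistic (> 2), additive ([0.5, 2]), antagonistic (< 0.5)."""
    if mdr <= 0:
        raise DomainError("MDR must be positive")
    if mdr > 2.0:
        return SYNERGISTIC
    if mdr < 0.5:
        return ANTAGONISTIC
    return ADDITIVE


def mdr(predicted: float, observed: float) -> MdrResult:
    """Model deviation ratio of a predicted against an observed LC50."""
    if predicted <= 0:
        raise DomainError("predicted LC50 must be positive")
    if observed <= 0:
        raise DomainError("observed LC50 must be positive (division by zero)")
    ratio = predicted / observed
    return MdrResult(
        predicted=predicted,
        observed=observed,
        mdr=ratio,
        valid=0.5 < ratio < 2.0,
        interaction=classify_interaction(ratio),
    )


def classify_toxicity(lc50: float) -> str:
    """Standard acute-toxicity category of a 96-h LC50 in mg/L."""
    if lc50 <= 0:
        raise DomainError("LC50 must be positive")
    if 0.1 <= lc50 < 1.0:
        return HIGHLY_TOXIC
    if 1.0 <= lc50 < 10.0:
        return MODERATELY_TOXIC
    if 10.0 <= lc50 < 100.0:
        return SLIGHTLY_TOXIC
    return OUT_OF_SCHEME
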