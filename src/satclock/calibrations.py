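"""Fossil calibration priors and the packaged aquatic-bird calibration table.

A calibration is a minimum-age constraint on the divergence of a named clade,
derived from the oldest fossil confidently assignable to it, plus a prior
shape describing how far above the minimum the true age may plausibly sit.

The packaged table carries seven vetted minima (MY): crown Podicipedidae 8.7,
stem Anhingidae 23.0, stem Pelecanidae 28.3, crown Mirandornithes 32.6,
stem Sulidae 33.0, stem Fregatidae 51.8 and stem Spheniscidae 60.5.  The
standard set used by the reference analysis is the six that exclude the
anhinga constraint; the anhinga minimum is the optional seventh, added only
by specific sensitivity runs.  Default prior shape: lognormal offset above
the minimum with log-SD 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from . import trees

__all__ = [
    "CalibrationPrior",
    "DEFAULT_CALIBRATIONS",
    "STANDARD_SIX",
    "YOUNGEST_TWO",
    "calibration_by_label",
    "PHOENICOPTERIDAE_CALIBRATION",
]

SHAPES = ("lognormal", "normal", "uniform")


@dataclass(frozen=True)
class CalibrationPrior:
    """A minimum-age constraint on the MRCA of ``clade``.

    ``spread`` is the prior's scale: the lognormal log-SD, the normal SD, or
    ignored for uniform; ``soft_max`` is an optional soft maximum age (MY)
    used by the uniform shape and by widened lognormal variants.
    """

    label: str
    clade: frozenset
    min_age: float
    shape: str = "lognormal"
    spread: float = 1.0
    soft_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_age <= 0:
            raise ValueError(f"{self.label}: min_age must be > 0")
        if self.shape not in SHAPES:
            raise ValueError(f"{self.label}: unknown prior shape {self.shape!r}")
        if not self.clade:
            raise ValueError(f"{self.label}: empty clade")
        if self.spread <= 0:
            raise ValueError(f"{self.label}: spread must be > 0")
        if self.soft_max is not None and self.soft_max <= self.min_age:
            raise ValueError(f"{self.label}: soft_max must exceed min_age")

    def with_shape(self, shape: str, spread: float = None, soft_max: float = None):
        kw = {"shape": shape}
        if spread is not None:
            kw["spread"] = spread
        if soft_max is not None:
            kw["soft_max"] = soft_max
        return replace(self, **kw)


def _cal(label: str, min_age: float) -> CalibrationPrior:
    return CalibrationPrior(label=label, clade=trees.NODE_CLADES[label], min_age=min_age)


#: All seven vetted constraints, youngest first.
DEFAULT_CALIBRATIONS: tuple[CalibrationPrior, ...] = (
    _cal("crown_Podicipedidae", 8.7),
    _cal("stem_Anhingidae", 23.0),
    _cal("stem_Pelecanidae", 28.3),
    _cal("crown_Mirandornithes", 32.6),
    _cal("stem_Sulidae", 33.0),
    _cal("stem_Fregatidae", 51.8),
    _cal("divergence_Sphenisciformes_Procellariiformes", 60.5),
)

#: The reference analysis' six constraints (anhinga excluded).
STANDARD_SIX = tuple(c for c in DEFAULT_CALIBRATIONS if c.label != "stem_Anhingidae")

#: "Youngest constraints only": crown Podicipedidae + crown Mirandornithes.
YOUNGEST_TWO = tuple(
    c for c in STANDARD_SIX if c.label in ("crown_Podicipedidae", "crown_Mirandornithes")
)

#: The extra crown-flamingo minimum exercised by two sensitivity runs.
PHOENICOPTERIDAE_CALIBRATION = CalibrationPrior(
    label="crown_Phoenicopteridae",
    clade=trees.NODE_CLADES["crown_Phoenicopteridae"],
    min_age=5.33,
)


def calibration_by_label(label: str) -> CalibrationPrior:
    for c in DEFAULT_CALIBRATIONS + (PHOENICOPTERIDAE_CALIBRATION,):
        if c.label == label:
            return c
    raise KeyError(f"no packaged calibration named {label!r}")
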