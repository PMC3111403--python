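"""Equal-potency fixed-ratio (ray) combination design from two ED50s.

The mixture is constrained so each compound contributes 50% of the
combination's potency: the dose fraction of each drug is proportional to
its own ED50 (``fraction_a = ed50_a / (ed50_a + ed50_b)``), so that at a
total dose equal to the mean of the two ED50s, each component sits at half
its own ED50-equivalent.

A display ratio rounds each ED50 to the nearest multiple of 5 μM (ties to
the even multiple). Downstream arithmetic always uses the exact fractions;
the rounded ratio is a label.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = ["FixedRatioDesign", "design_fixed_ratio", "component_doses", "round_to_nearest_5"]


def round_to_nearest_5(x: float) -> int:
    """Round ``x`` to the nearest multiple of 5, half-to-even multiple."""
    if not x == x or x in (float("inf"), float("-inf")):
        raise ValueError("x must be finite")
    return int(round(x / 5.0) * 5)


@dataclass(frozen=True)
class FixedRatioDesign:
    """Equal-potency dose fractions derived from two monotherapy ED50s.

    Attributes
    ----------
    ed50_a, ed50_b : float
        Monotherapy ED50s in μM.
    fraction_a, fraction_b : float
        Dose fractions of each drug in the mixture; sum to 1 and are
        proportional to the ED50s.
    rounded_ratio : tuple of int
        Display ratio (μM:μM), nearest-5 rounding of each ED50.
    """

    ed50_a: float
    ed50_b: float

    def __post_init__(self):
        for name, v in (("ed50_a", self.ed50_a), ("ed50_b", self.ed50_b)):
            if not (v == v and 0 < v < float("inf")):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def fraction_a(self) -> float:
        return self.ed50_a / (self.ed50_a + self.ed50_b)

    @property
    def fraction_b(self) -> float:
        return self.ed50_b / (self.ed50_a + self.ed50_b)

    @property
    def rounded_ratio(self) -> tuple[int, int]:
        return (round_to_nearest_5(self.ed50_a), round_to_nearest_5(self.ed50_b))

    @property
    def ratio_label(self) -> str:
        a, b = self.rounded_ratio
        return f"{a}:{b}"

    def working_ratio(self) -> tuple[int, int]:
        """Rounded display ratio reduced to smallest integers (e.g. 60:40 -> 3:2)."""
        a, b = self.rounded_ratio
        f = Fraction(a, b)
        return (f.numerator, f.denominator)

    def component_doses(self, total_dose: float) -> tuple[float, float]:
        return component_doses((self.fraction_a, self.fraction_b), total_dose)


def design_fixed_ratio(ed50_a: float, ed50_b: float) -> FixedRatioDesign:
    """Build the equal-potency fixed-ratio design from two ED50s (μM).

    Examples
    --------
    >>> design_fixed_ratio(36.7, 34.7).rounded_ratio
    (35, 35)
    >>> design_fixed_ratio(56.5, 28.0).rounded_ratio
    (55, 30)
    """
    return FixedRatioDesign(ed50_a, ed50_b)


def component_doses(design_or_fractions, total_dose: float) -> tuple[float, float]:
    """Split ``total_dose`` μM into component doses along the fixed ratio.

    Parameters
    ----------
    design_or_fractions : FixedRatioDesign or (fraction_a, fraction_b)
        Fractions must sum to 1 within 1e-12.
    total_dose : float
        Total mixture dose, μM, >= 0.

    Returns
    -------
    (dose_a, dose_b) summing to ``total_dose`` exactly.
    """
    if isinstance(design_or_fractions, FixedRatioDesign):
        fa, fb = design_or_fractions.fraction_a, design_or_fractions.fraction_b
    else:
        fa, fb = map(float, design_or_fractions)
    if abs(fa + fb - 1.0) > 1e-12:
        raise ValueError(f"fractions must sum to 1 within 1e-12, got {fa} + {fb}")
    if not total_dose >= 0:
        raise ValueError("total_dose must be >= 0")
    dose_a = fa * total_dose
    return (dose_a, total_dose - dose_a)
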