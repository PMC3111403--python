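"""Loewe additivity for fixed-ratio mixtures: theoretical additive curve,
Combination Index, and the actual-vs-additive curve comparison.

Given monotherapy 4PL fits for drugs A and B and a mixture of fixed dose
fractions (f_a, f_b), the Tallarida construction finds, for each percent
effect x, the total mixture dose Z_add(x) that Loewe additivity predicts:

    f_a*Z / Dx_a(x) + f_b*Z / Dx_b(x) = 1
    =>  Z_add(x) = 1 / (f_a/Dx_a(x) + f_b/Dx_b(x))

where Dx_a, Dx_b are the equi-effective monotherapy doses obtained by
inverting the fitted curves.  Fitting a 4PL to the (Z_add(x), response(x))
points yields the "theoretical additive curve" against which the actually
observed mixture curve is compared.

The Combination Index at effect x for a mixture containing component doses
(d1, d2) is

    CI = d1/Dx_1 + d2/Dx_2

with CI < 1 synergy, CI = 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import FixedRatioDesign, component_doses
from .dose_response import (
    DoseResponseData,
    EffectRangeError,
    FourParamLogistic,
    FourParamLogisticResults,
)

__all__ = [
    "AdditiveCurve",
    "CombinationIndexResult",
    "SynergyReport",
    "additive_total_dose",
    "build_additive_curve",
    "combination_index",
    "compare_curves",
    "LoeweSynergyAnalysis",
]

LN10 = np.log(10.0)


def _fractions(design_or_fractions) -> tuple[float, float]:
    if isinstance(design_or_fractions, FixedRatioDesign):
        return design_or_fractions.fraction_a, design_or_fractions.fraction_b
    fa, fb = map(float, design_or_fractions)
    if abs(fa + fb - 1.0) > 1e-12:
        raise ValueError(f"fractions must sum to 1, got {fa} + {fb}")
    return fa, fb


def additive_total_dose(
    effect_pct: float,
    fit_a: FourParamLogisticResults,
    fit_b: FourParamLogisticResults,
    fraction_a: float,
    fraction_b: float,
) -> float:
    """Loewe-additive total mixture dose (μM) at ``effect_pct``.

    With equal-potency fractions (f_a proportional to ED50_a) the 50%-effect
    value reduces algebraically to ``(ED50_a + ED50_b)/2``.
    """
    fa, fb = _fractions((fraction_a, fraction_b))
    dxa = fit_a.dose_for_effect(effect_pct)
    dxb = fit_b.dose_for_effect(effect_pct)
    return 1.0 / (fa / dxa + fb / dxb)


@dataclass(frozen=True)
class AdditiveCurve:
    """Theoretical additive curve: doses over an effect grid plus its 4PL refit.

    ``max_abs_residual`` records how far the additive isobole departs from
    an exact 4PL shape (zero when the two monotherapy curves coincide).
    """

    effect_grid: np.ndarray
    total_dose: np.ndarray
    response: np.ndarray
    fit: FourParamLogisticResults
    max_abs_residual: float

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "effect_pct": self.effect_grid,
                "additive_total_dose_um": self.total_dose,
                "response_pct": self.response,
            }
        )


class _FixedCurve:
    """Closed-form 4PL curve defined by parameters alone (no data)."""

    def __init__(self, params):
        self.params = np.asarray(params, float)

    @property
    def bottom(self):
        return float(self.params[0])

    @property
    def top(self):
        return float(self.params[1])

    def dose_for_effect(self, effect_pct):
        e = effect_pct / 100.0
        if not 0.0 < e < 1.0:
            raise EffectRangeError(f"effect_pct={effect_pct} outside (0, 100)")
        return float(10.0 ** (self.params[2] - np.log10(e / (1.0 - e)) / self.params[3]))


def _additive_points(curve_a, curve_b, fa, fb, grid, asymptotes):
    z = np.empty(grid.size)
    for i, e in enumerate(grid):
        z[i] = 1.0 / (fa / curve_a.dose_for_effect(e) + fb / curve_b.dose_for_effect(e))
    if asymptotes == "mean":
        top = 0.5 * (curve_a.top + curve_b.top)
        bottom = 0.5 * (curve_a.bottom + curve_b.bottom)
    elif asymptotes == "a":
        top, bottom = curve_a.top, curve_a.bottom
    elif asymptotes == "b":
        top, bottom = curve_b.top, curve_b.bottom
    else:
        raise ValueError(f"unknown asymptotes convention {asymptotes!r}")
    resp = top - grid / 100.0 * (top - bottom)
    return z, resp


def _propagated_cov(fit_a, fit_b, fa, fb, grid, asymptotes, phi0):
    """Covariance of the additive refit parameters, propagated from the
    monotherapy fits by one-sided finite differences.

    The constructed additive points are a smooth deterministic function of
    the 8 monotherapy parameters; J = d(phi)/d(theta) maps the block
    covariance of the two fits onto the refit parameters.
    """
    theta = np.concatenate([fit_a.params, fit_b.params])
    scales = np.array([1.0, 1.0, 1e-3, 1e-3, 1.0, 1.0, 1e-3, 1e-3])
    steps = np.maximum(np.abs(theta) * 1e-4, scales * 1e-3)
    J = np.zeros((4, 8))
    for i in range(8):
        th = theta.copy()
        th[i] += steps[i]
        z, resp = _additive_points(_FixedCurve(th[:4]), _FixedCurve(th[4:]), fa, fb, grid, asymptotes)
        data = DoseResponseData("additive (perturbed)", z, resp)
        phi = FourParamLogistic(data).fit(init=phi0).params
        J[:, i] = (phi - phi0) / steps[i]
    C = np.zeros((8, 8))
    C[:4, :4] = fit_a.cov
    C[4:, 4:] = fit_b.cov
    return J @ C @ J.T


def build_additive_curve(
    fit_a: FourParamLogisticResults,
    fit_b: FourParamLogisticResults,
    fractions,
    effect_grid=None,
    asymptotes: str = "mean",
    propagate_uncertainty: bool = True,
) -> AdditiveCurve:
    """Construct and refit the theoretical additive curve.

    Parameters
    ----------
    fractions : FixedRatioDesign or (fraction_a, fraction_b)
    effect_grid : array-like, optional
        Percent-effect levels, strictly inside (0, 100). Default 1..99 in
        steps of 1 — dense enough for a stable refit while avoiding the
        asymptote singularities.
    asymptotes : {"mean", "a", "b"}
        Response scale for the constructed points: mean of the two
        monotherapy tops/bottoms (default), or those of one drug.
    propagate_uncertainty : bool
        When True (default), the refit's covariance additionally carries
        the monotherapy-fit parameter uncertainty, propagated through the
        construction by the delta method — the constructed points are
        noiseless, so the refit's own residual covariance alone would
        understate the additive curve's uncertainty drastically.

    Raises
    ------
    ValueError
        If fewer than 5 valid grid points remain.
    """
    fa, fb = _fractions(fractions)
    grid = np.arange(1.0, 100.0) if effect_grid is None else np.asarray(effect_grid, float)
    if np.any((grid <= 0) | (grid >= 100)):
        raise EffectRangeError("effect grid must lie strictly inside (0, 100)")
    if grid.size < 5:
        raise ValueError("need at least 5 effect-grid points to construct the additive curve")
    z, resp = _additive_points(fit_a, fit_b, fa, fb, grid, asymptotes)
    data = DoseResponseData("theoretical additive", z, resp)
    fit = FourParamLogistic(data).fit()
    max_resid = float(np.max(np.abs(fit.predict(z) - resp)))
    if propagate_uncertainty:
        cov = fit.cov + _propagated_cov(fit_a, fit_b, fa, fb, grid, asymptotes, fit.params)
        fit = FourParamLogisticResults(
            model=fit.model,
            params=fit.params,
            cov=cov,
            n_obs=fit.n_obs,
            residual_df=min(fit_a.residual_df, fit_b.residual_df),
            rss=fit.rss,
            diagnostics=fit.diagnostics,
        )
    return AdditiveCurve(grid, z, resp, fit, max_resid)


@dataclass(frozen=True)
class CombinationIndexResult:
    """Combination Index at one effect level.

    ``d1, d2`` are the component doses in the mixture; ``dx1, dx2`` the
    equi-effective monotherapy doses.  ``ci = d1/dx1 + d2/dx2``.
    ``ci_conf_int`` is a delta-method interval (level chosen by the caller)
    when parameter uncertainty was propagated, None otherwise.
    """

    effect_pct: float
    d1: float
    d2: float
    dx1: float | None
    dx2: float | None
    ci: float
    ci_conf_int: tuple[float, float] | None = None

    @property
    def classification(self) -> str:
        if self.ci < 1.0:
            return "synergistic"
        if self.ci > 1.0:
            return "antagonistic"
        return "additive"


def combination_index(
    d1: float,
    d2: float,
    fit_a: FourParamLogisticResults,
    fit_b: FourParamLogisticResults,
    effect_pct: float,
) -> CombinationIndexResult:
    """CI = d1/Dx_1 + d2/Dx_2 at ``effect_pct``.

    Domain errors from inverting either monotherapy curve propagate.
    The formula is linear in (d1, d2); decompositions of the Loewe-additive
    dose give CI = 1 identically.
    """
    dx1 = fit_a.dose_for_effect(effect_pct)
    dx2 = fit_b.dose_for_effect(effect_pct)
    ci = d1 / dx1 + d2 / dx2
    return CombinationIndexResult(float(effect_pct), float(d1), float(d2), dx1, dx2, float(ci))


def _ci_with_uncertainty(
    fit_actual: FourParamLogisticResults,
    fit_a: FourParamLogisticResults | None,
    fit_b: FourParamLogisticResults | None,
    fit_additive: FourParamLogisticResults,
    fa: float,
    fb: float,
    effect_pct: float,
    alpha: float = 0.05,
) -> CombinationIndexResult:
    """CI at the actual mixture's equi-effective dose, with a delta-method CI.

    Uses the exact mixture fractions. When the monotherapy fits are
    available the variance propagates their log10(ED50) uncertainty and the
    mixture's; otherwise CI is the dose ratio Z_actual/Z_additive at the
    effect level and the additive fit's uncertainty stands in.
    """
    z = fit_actual.dose_for_effect(effect_pct)
    d1, d2 = fa * z, fb * z
    v_act = float(fit_actual.cov[2, 2])
    if fit_a is not None and fit_b is not None:
        res = combination_index(d1, d2, fit_a, fit_b, effect_pct)
        ci = res.ci
        term1 = d1 / res.dx1
        term2 = d2 / res.dx2
        var = LN10**2 * (
            ci**2 * v_act
            + term1**2 * float(fit_a.cov[2, 2])
            + term2**2 * float(fit_b.cov[2, 2])
        )
        df = min(fit_actual.residual_df, fit_a.residual_df, fit_b.residual_df)
        dx1, dx2 = res.dx1, res.dx2
    else:
        z_add = fit_additive.dose_for_effect(effect_pct)
        ci = z / z_add
        var = LN10**2 * ci**2 * (v_act + float(fit_additive.cov[2, 2]))
        df = min(fit_actual.residual_df, fit_additive.residual_df)
        dx1 = dx2 = None
    # interval on the log scale: CI is a positive ratio-like quantity whose
    # sampling distribution is close to lognormal, so the Wald interval is
    # built for log(CI) and exponentiated
    tq = stats.t.ppf(1.0 - alpha / 2.0, df)
    se_log = np.sqrt(max(var, 0.0)) / ci
    half = tq * se_log
    return CombinationIndexResult(
        float(effect_pct),
        d1,
        d2,
        dx1,
        dx2,
        float(ci),
        (float(ci * np.exp(-half)), float(ci * np.exp(half))),
    )


@dataclass(frozen=True)
class SynergyReport:
    """Verdict from comparing the actual mixture curve with the additive one.

    The verdict is evidence-based: "synergistic" requires either the
    Combination Index's interval (90% by default, i.e. a 5% directional
    test) to fall below 1 or a directional non-overlap of the two fits'
    95% confidence intervals (greater potency, or a significantly
    shallower hillslope widening the effective dose span); mirror-image
    evidence yields "antagonistic"; otherwise "additive".
    """

    fit_actual: FourParamLogisticResults
    fit_additive: FourParamLogisticResults
    delta_log10_ed50: float
    ed50_ci_nonoverlap: bool
    delta_hillslope: float
    hillslope_ci_nonoverlap: bool
    ci_at_ed50: CombinationIndexResult
    verdict: str
    effect_for_ci: float = 50.0
    notes: tuple = field(default=())

    def summary(self) -> str:
        a, t = self.fit_actual, self.fit_additive
        ci = self.ci_at_ed50
        lo, hi = ci.ci_conf_int if ci.ci_conf_int else (float("nan"), float("nan"))
        lines = [
            "Loewe synergy analysis (fixed-ratio mixture)",
            f"  actual mixture : ED50 {a.ed50:8.3f} uM, hillslope {a.hillslope:7.3f}",
            f"  additive curve : ED50 {t.ed50:8.3f} uM, hillslope {t.hillslope:7.3f}",
            f"  delta log10(ED50): {self.delta_log10_ed50:+.4f}"
            f"   95% CI non-overlap: {self.ed50_ci_nonoverlap}",
            f"  delta hillslope  : {self.delta_hillslope:+.4f}"
            f"   95% CI non-overlap: {self.hillslope_ci_nonoverlap}",
            f"  Combination Index at {ci.effect_pct:.0f}% effect: {ci.ci:.3f}"
            f"   (interval {lo:.3f}, {hi:.3f})",
            f"  verdict: {self.verdict}",
        ]
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


def _nonoverlap(fit1, fit2, row: str) -> bool:
    c1 = fit1.conf_int().loc[row]
    c2 = fit2.conf_int().loc[row]
    return bool(c1["upper"] < c2["lower"] or c2["upper"] < c1["lower"])


def compare_curves(
    fit_actual: FourParamLogisticResults,
    fit_additive: FourParamLogisticResults,
    design,
    fit_mono_a: FourParamLogisticResults | None = None,
    fit_mono_b: FourParamLogisticResults | None = None,
    effect_for_ci: float = 50.0,
    verdict_alpha: float = 0.10,
) -> SynergyReport:
    """Compare the fitted actual-mixture curve against the additive curve.

    Parameters
    ----------
    design : FixedRatioDesign or (fraction_a, fraction_b)
        The mixture's exact dose fractions (never the rounded display
        ratio), used to decompose the mixture dose into components.
    fit_mono_a, fit_mono_b : optional
        Monotherapy fits; when given, the Combination Index uses the true
        equi-effective monotherapy doses and propagates their uncertainty.
    verdict_alpha : float
        Two-sided level of the Combination-Index interval driving the
        verdict. The default 0.10 makes each directional call a 5% test,
        so at most ~5% of truly additive mixtures are called synergistic;
        the reported parameter non-overlap flags always use 95% intervals.
    """
    fa, fb = _fractions(design)
    dl = fit_actual.log10_ed50 - fit_additive.log10_ed50
    dh = fit_actual.hillslope - fit_additive.hillslope
    ed50_flag = _nonoverlap(fit_actual, fit_additive, "log10_ed50")
    hill_flag = _nonoverlap(fit_actual, fit_additive, "hillslope")
    ci_res = _ci_with_uncertainty(
        fit_actual, fit_mono_a, fit_mono_b, fit_additive, fa, fb, effect_for_ci,
        alpha=verdict_alpha,
    )

    notes = []
    lo, hi = ci_res.ci_conf_int
    if hi < 1.0:
        verdict = "synergistic"
    elif lo > 1.0:
        verdict = "subadditive/antagonistic"
    elif ed50_flag:
        verdict = "synergistic" if dl < 0 else "subadditive/antagonistic"
    elif hill_flag:
        # a significantly shallower mixture slope widens the span of doses
        # where the mixture outperforms the additive expectation
        verdict = (
            "synergistic"
            if abs(fit_actual.hillslope) < abs(fit_additive.hillslope)
            else "subadditive/antagonistic"
        )
        notes.append("verdict driven by hillslope difference at comparable ED50s")
    else:
        verdict = "additive"
    return SynergyReport(
        fit_actual=fit_actual,
        fit_additive=fit_additive,
        delta_log10_ed50=float(dl),
        ed50_ci_nonoverlap=ed50_flag,
        delta_hillslope=float(dh),
        hillslope_ci_nonoverlap=hill_flag,
        ci_at_ed50=ci_res,
        verdict=verdict,
        effect_for_ci=float(effect_for_ci),
        notes=tuple(notes),
    )


class LoeweSynergyAnalysis:
    """End-to-end fixed-ratio synergy analysis from raw dose-response data.

    Fits 4PLs to both monotherapies and the mixture, constructs the
    theoretical additive curve, and compares.  ``fit()`` returns a
    :class:`SynergyReport`.
    """

    def __init__(
        self,
        mono_a: DoseResponseData,
        mono_b: DoseResponseData,
        combo: DoseResponseData,
        fractions=None,
        effect_grid=None,
        asymptotes: str = "mean",
    ):
        self.mono_a = mono_a
        self.mono_b = mono_b
        self.combo = combo
        self.fractions = fractions
        self.effect_grid = effect_grid
        self.asymptotes = asymptotes
        self.fit_a_: FourParamLogisticResults | None = None
        self.fit_b_: FourParamLogisticResults | None = None
        self.fit_combo_: FourParamLogisticResults | None = None
        self.additive_: AdditiveCurve | None = None

    def fit(self, effect_for_ci: float = 50.0) -> SynergyReport:
        self.fit_a_ = FourParamLogistic(self.mono_a).fit()
        self.fit_b_ = FourParamLogistic(self.mono_b).fit()
        self.fit_combo_ = FourParamLogistic(self.combo).fit()
        if self.fractions is None:
            design = FixedRatioDesign(self.fit_a_.ed50, self.fit_b_.ed50)
            fracs = (design.fraction_a, design.fraction_b)
        else:
            fracs = _fractions(self.fractions)
        self.additive_ = build_additive_curve(
            self.fit_a_, self.fit_b_, fracs, self.effect_grid, self.asymptotes
        )
        return compare_curves(
            self.fit_combo_,
            self.additive_.fit,
            fracs,
            fit_mono_a=self.fit_a_,
            fit_mono_b=self.fit_b_,
            effect_for_ci=effect_for_ci,
        )
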