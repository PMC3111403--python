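"""Four-parameter logistic (4PL) dose-response modelling.

The model is the GraphPad "log(inhibitor) vs. response -- variable slope"
sigmoid

    y(d) = bottom + (top - bottom) / (1 + 10**(hillslope * (log10(ED50) - log10(d))))

parameterised by ``(bottom, top, log10_ed50, hillslope)``.  A negative
hillslope gives a curve that decreases with dose (the usual orientation for
growth-inhibition data expressed as % of vehicle control, ~100 at dose 0);
at the ED50 the response is the midpoint ``(top + bottom) / 2``.

"Percent effect" throughout this package means the percentage of the fitted
span ``top - bottom`` that has been suppressed, so a 50% effect corresponds
exactly to the ED50 and the inverse (dose for a given effect) has the closed
form

    log10(d) = log10(ED50) - log10(e / (1 - e)) / hillslope,   e = effect/100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseData",
    "FourParamLogistic",
    "FourParamLogisticResults",
    "FitError",
    "EffectRangeError",
    "four_pl",
    "fit_4pl",
]

PARAM_NAMES = ("bottom", "top", "log10_ed50", "hillslope")


class FitError(RuntimeError):
    """Nonlinear regression failed; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EffectRangeError(ValueError):
    """Requested effect lies at or beyond the curve's asymptotes."""


def four_pl(dose, bottom, top, log10_ed50, hillslope):
    """Evaluate the 4PL model at ``dose`` (scalar or array, in μM).

    Dose 0 is handled as the analytic limit: ``top`` for a decreasing curve
    (hillslope < 0), ``bottom`` for an increasing one.
    """
    scalar = np.isscalar(dose) or np.ndim(dose) == 0
    d = np.atleast_1d(np.asarray(dose, dtype=float))
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    logd = np.full(d.shape, -np.inf)
    np.log10(d, out=logd, where=(d > 0))
    expo = hillslope * (log10_ed50 - logd)
    # limit at dose 0: exponent -> -sign(hillslope)*inf, i.e. response -> top
    # for a decreasing (hillslope < 0) curve
    expo = np.clip(expo, -300.0, 300.0)
    out = bottom + (top - bottom) / (1.0 + 10.0 ** expo)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class DoseResponseData:
    """Raw (dose, response) observations for one compound or mixture.

    Parameters
    ----------
    compound : str
        Label of the compound or fixed-ratio mixture.
    dose : array-like of float
        Doses in μM, all finite and >= 0.
    response : array-like of float
        Responses as % of vehicle control.
    replicate : sequence of str, optional
        Replicate identifiers (purely descriptive; replicate wells are fit
        as individual points).
    """

    compound: str
    dose: np.ndarray
    response: np.ndarray
    replicate: tuple = field(default=())

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise ValueError("dose and response must be 1-D arrays of equal length")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("all doses must be finite and >= 0")
        if not np.all(np.isfinite(r)):
            raise ValueError("all responses must be finite")
        if np.unique(d[d > 0]).size < 4:
            raise ValueError("need at least 4 distinct nonzero doses")
        rep = tuple(self.replicate) if len(self.replicate) else tuple("" for _ in d)
        if len(rep) != d.size:
            raise ValueError("replicate must match dose length")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "response", r)
        object.__setattr__(self, "replicate", rep)

    def __len__(self):
        return self.dose.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound,
                "dose_um": self.dose,
                "replicate": self.replicate,
                "response_pct": self.response,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compound: str | None = None) -> "DoseResponseData":
        if compound is not None:
            df = df[df["compound"] == compound]
            if df.empty:
                raise ValueError(f"no rows for compound {compound!r}")
        labels = df["compound"].unique()
        if len(labels) != 1:
            raise ValueError(f"expected a single compound, got {list(labels)}")
        return cls(
            compound=str(labels[0]),
            dose=df["dose_um"].to_numpy(float),
            response=df["response_pct"].to_numpy(float),
            replicate=tuple(df["replicate"].astype(str)) if "replicate" in df else (),
        )


class FourParamLogistic:
    """Four-parameter logistic dose-response model.

    Fit with ordinary (unweighted) nonlinear least squares, matching plain
    sigmoid-curve regression as done in standard curve-fitting software.

    Parameters
    ----------
    data : DoseResponseData
        The observations. At least 5 points are required (residual degrees
        of freedom must be positive).

    Examples
    --------
    >>> data = DoseResponseData("drug", [1, 3, 10, 30, 100],
    ...                         [98, 90, 52, 12, 2])
    >>> res = FourParamLogistic(data).fit()
    >>> round(res.ed50, 1)  # doctest: +SKIP
    10.3
    """

    def __init__(self, data: DoseResponseData):
        self.data = data
        if len(data) < 5:
            raise ValueError("at least 5 observations are required to fit a 4PL")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, compound: str | None = None) -> "FourParamLogistic":
        return cls(DoseResponseData.from_frame(df, compound))

    # -- deterministic warm start -------------------------------------------------
    def _initial_params(self) -> np.ndarray:
        d, r = self.data.dose, self.data.response
        top = float(np.max(r))
        bottom = float(np.min(r))
        span = top - bottom
        pos = d > 0
        logd = np.log10(d[pos])
        y = r[pos]
        # average per distinct dose, sort by log-dose
        df = pd.DataFrame({"logd": logd, "y": y}).groupby("logd", as_index=False).mean()
        xs, ys = df["logd"].to_numpy(), df["y"].to_numpy()
        half = bottom + span / 2.0
        # interpolate log-dose where the (monotone trend) response crosses half-span
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        crossings = np.nonzero(np.diff(np.sign(ys - half)) != 0)[0]
        if crossings.size:
            i = crossings[0]
            x0, x1, y0, y1 = xs[i], xs[i + 1], ys[i], ys[i + 1]
            log10_ed50 = x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x0
        else:
            log10_ed50 = float(np.median(xs))
        # hillslope from the logit-linearised responses:
        # log10((top - y)/(y - bottom)) = hillslope*(logd - log10_ed50)
        eps = max(span, 1.0) * 1e-3
        yc = np.clip(y, bottom + eps, top - eps)
        z = np.log10((top - yc) / (yc - bottom))
        slope = np.polyfit(logd, z, 1)[0] if np.ptp(logd) > 0 else -1.0
        hillslope = float(slope) if slope != 0 else -1.0
        return np.array([bottom, top, log10_ed50, hillslope])

    def fit(self, init=None, ftol: float = 1e-10) -> "FourParamLogisticResults":
        """Fit by unweighted least squares.

        Parameters
        ----------
        init : sequence of 4 floats, optional
            Starting values ``(bottom, top, log10_ed50, hillslope)``;
            defaults to a deterministic heuristic warm start.
        ftol : float
            Convergence tolerance on the cost function.

        Raises
        ------
        FitError
            If the responses have zero span or the optimizer fails to
            converge; ``.diagnostics`` carries the optimizer message.
        """
        d, r = self.data.dose, self.data.response
        if np.ptp(r) == 0:
            raise FitError(
                "responses have zero span; a sigmoid cannot be identified",
                {"span": 0.0},
            )
        x0 = np.asarray(init, dtype=float) if init is not None else self._initial_params()

        def resid(p):
            return four_pl(d, *p) - r

        sol = optimize.least_squares(resid, x0, method="lm", ftol=ftol, xtol=1e-12, gtol=1e-12)
        if not sol.success:
            raise FitError(
                f"4PL fit did not converge: {sol.message}",
                {"status": sol.status, "message": sol.message, "cost": float(sol.cost)},
            )
        params = sol.x
        # canonical orientation: top > bottom (the 4PL is invariant under
        # swapping asymptotes while negating the hillslope)
        T = np.eye(4)
        if params[0] > params[1]:
            T = np.array(
                [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, -1.0]]
            )
            params = T @ params
        if params[1] <= params[0]:
            raise FitError("degenerate fit: top <= bottom", {"params": params.tolist()})

        n, k = r.size, 4
        dof = n - k
        rss = float(np.sum(resid(params) ** 2))
        s2 = rss / dof
        J = sol.jac @ T.T  # jacobian in canonical parameter order/sign
        JTJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(JTJ)
        cov = (cov + cov.T) / 2.0
        return FourParamLogisticResults(
            model=self,
            params=params,
            cov=cov,
            n_obs=n,
            residual_df=dof,
            rss=rss,
            diagnostics={"nfev": sol.nfev, "status": sol.status, "message": sol.message},
        )


class FourParamLogisticResults:
    """Fitted 4PL parameters with covariance and Wald confidence intervals.

    Attributes
    ----------
    params : ndarray
        ``(bottom, top, log10_ed50, hillslope)`` in canonical orientation
        (top > bottom).
    cov : ndarray
        4x4 parameter covariance from the Jacobian at the optimum.
    n_obs, residual_df : int
    """

    param_names = PARAM_NAMES

    def __init__(self, model, params, cov, n_obs, residual_df, rss, diagnostics=None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.n_obs = int(n_obs)
        self.residual_df = int(residual_df)
        self.rss = float(rss)
        self.diagnostics = diagnostics or {}

    # parameter accessors
    @property
    def bottom(self) -> float:
        return float(self.params[0])

    @property
    def top(self) -> float:
        return float(self.params[1])

    @property
    def log10_ed50(self) -> float:
        return float(self.params[2])

    @property
    def hillslope(self) -> float:
        return float(self.params[3])

    @property
    def ed50(self) -> float:
        """ED50 in μM (back-transformed from log10)."""
        return float(10.0 ** self.params[2])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the parameters."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def cov_params(self) -> np.ndarray:
        return self.cov.copy()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Student-t Wald confidence intervals with ``residual_df`` dof."""
        tq = stats.t.ppf(1.0 - alpha / 2.0, self.residual_df)
        lo = self.params - tq * self.bse
        hi = self.params + tq * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(self.param_names))

    def predict(self, dose) -> float | np.ndarray:
        """Model response (% of control) at ``dose`` μM (dose >= 0)."""
        return four_pl(dose, *self.params)

    def dose_for_effect(self, effect_pct: float) -> float:
        """Dose (μM) producing ``effect_pct`` percent of the span suppressed.

        ``effect_pct`` must lie strictly inside (0, 100); 50 returns the
        ED50 exactly.  Values at or beyond the asymptotes raise
        :class:`EffectRangeError`.
        """
        e = float(effect_pct) / 100.0
        if not 0.0 < e < 1.0:
            raise EffectRangeError(
                f"effect_pct={effect_pct} is outside the achievable open interval (0, 100)"
            )
        logd = self.params[2] - np.log10(e / (1.0 - e)) / self.params[3]
        return float(10.0 ** logd)

    def effect_at_dose(self, dose: float) -> float:
        """Percent of span suppressed at ``dose`` (inverse of dose_for_effect)."""
        y = self.predict(dose)
        return float(100.0 * (self.top - y) / (self.top - self.bottom))

    def params_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "std_err": self.bse,
                "ci_lower": ci["lower"].to_numpy(),
                "ci_upper": ci["upper"].to_numpy(),
            },
            index=list(self.param_names),
        )

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        pf = self.params_frame()
        lines = [
            "Four-parameter logistic fit",
            f"  compound: {self.model.data.compound}",
            f"  n_obs: {self.n_obs}   residual_df: {self.residual_df}   RSS: {self.rss:.4g}",
            f"  ED50: {self.ed50:.4g} uM",
            "",
            pf.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<FourParamLogisticResults {self.model.data.compound!r}: "
            f"ed50={self.ed50:.4g} uM, hillslope={self.hillslope:.3g}>"
        )


def fit_4pl(data: DoseResponseData, init=None) -> FourParamLogisticResults:
    """Convenience wrapper: fit a 4PL to ``data`` and return the results."""
    return FourParamLogistic(data).fit(init=init)
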