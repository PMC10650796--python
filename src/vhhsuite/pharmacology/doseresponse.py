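"""Four-parameter logistic (4PL) dose-response fitting.

The response at dose x is modelled as

    y = bottom + (Emax - bottom) / (1 + (EC50 / x)**hill)

with EC50 > 0 and hill > 0 (ascending curves; Emax is the top plateau).
:class:`FourPLModel` is built from dose/response arrays and fitted by
least squares; standard errors come from the Jacobian at the optimum.
EC50 is parameterised internally on the log scale, both for positivity
and because dose grids are logarithmic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares


@dataclass(frozen=True)
class FourPLParams:
    """4PL parameters: bottom and emax in response units, ec50 in M."""

    bottom: float
    emax: float
    ec50: float
    hill: float = 1.0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.emax < self.bottom:
            raise ValueError("Emax must be >= bottom")


def fourpl(x, bottom, emax, ec50, hill):
    """Evaluate the 4PL curve; x may be scalar or array, in M."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # extreme hill values saturate cleanly
        return bottom + (emax - bottom) / (1.0 + (ec50 / x) ** hill)


class FourPLModel:
    """Dose-response model over (dose, response) observations.

    Replicates are passed as repeated dose values; optional ``weights``
    multiply the residuals (1/SD weighting).
    """

    def __init__(self, dose, response, weights=None):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response must align")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive (molar)")
        self.weights = (np.ones_like(self.dose) if weights is None
                        else np.asarray(weights, dtype=float))
        if np.unique(self.dose).size < 5:
            warnings.warn("fewer than 5 distinct doses; 4PL fit may be ill-determined",
                          stacklevel=2)

    @classmethod
    def from_dataframe(cls, df, dose="dose", response="response", weights=None):
        w = df[weights].to_numpy() if weights else None
        return cls(df[dose].to_numpy(), df[response].to_numpy(), w)

    def _start(self) -> np.ndarray:
        """Quartile-based initial values: plateaus from the response range,
        EC50 from the dose bracketing the half response, hill = 1."""
        order = np.argsort(self.dose)
        d, y = self.dose[order], self.response[order]
        lo, hi = float(np.min(y)), float(np.max(y))
        mid = 0.5 * (lo + hi)
        above = np.nonzero(y >= mid)[0]
        ec50_0 = float(d[above[0]]) if above.size else float(np.exp(np.mean(np.log(d))))
        return np.array([lo, hi, np.log(ec50_0), 1.0])

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        bottom, emax, log_ec50, hill = theta
        return fourpl(self.dose, bottom, emax, np.exp(log_ec50), hill)

    def fit(self, start: FourPLParams | None = None,
            fix_bottom: float | None = None) -> "FourPLResults":
        """Least-squares fit.

        ``fix_bottom`` pins the lower plateau (pass 0.0 for
        baseline-subtracted responses, whose zero-dose value is zero by
        construction); with no doses below the EC50 a free bottom is not
        identifiable and trades off against EC50 and hill.
        """
        theta0 = (np.array([start.bottom, start.emax, np.log(start.ec50), start.hill])
                  if start is not None else self._start())
        free = np.array([fix_bottom is None, True, True, True])
        if fix_bottom is not None:
            theta0[0] = fix_bottom

        def expand(tfree):
            full = theta0.copy()
            full[free] = tfree
            return full

        def resid(tfree):
            return self.weights * (self._predict(expand(tfree)) - self.response)

        sol = least_squares(resid, theta0[free], method="lm", xtol=1e-14, ftol=1e-14,
                            max_nfev=20000)
        if not sol.success:
            raise RuntimeError(f"4PL fit did not converge: {sol.message}")
        bottom, emax, log_ec50, hill = expand(sol.x)
        if emax < bottom:
            # (b, e, h) -> (e, b, -h) leaves the curve invariant; pick the
            # canonical orientation with Emax as the upper plateau
            bottom, emax, hill = emax, bottom, -hill
        params = FourPLParams(bottom, emax, float(np.exp(log_ec50)), hill)
        n, p = sol.fun.size, int(free.sum())
        dof = max(n - p, 1)
        s2 = float(np.sum(sol.fun**2)) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_free = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov_free = np.full((p, p), np.nan)
        cov_theta = np.zeros((4, 4))
        idx = np.nonzero(free)[0]
        cov_theta[np.ix_(idx, idx)] = cov_free
        # delta method for EC50 (internal parameter is log EC50)
        grad = np.diag([1.0, 1.0, params.ec50, 1.0])
        with np.errstate(over="ignore", invalid="ignore"):
            cov = grad @ cov_theta @ grad
        return FourPLResults(self, params, cov, float(np.sqrt(np.mean(sol.fun**2))), dof)


class FourPLResults:
    """Fitted 4PL curve: estimates, standard errors, CIs, summary."""

    _names = ("bottom", "emax", "ec50", "hill")

    def __init__(self, model: FourPLModel, params: FourPLParams,
                 cov: np.ndarray, rmse: float, dof: int):
        self.model = model
        self.params = params
        self.cov = cov
        self.rmse = rmse
        self.dof = dof

    @property
    def bottom(self):
        return self.params.bottom

    @property
    def emax(self):
        return self.params.emax

    @property
    def ec50(self):
        return self.params.ec50

    @property
    def hill(self):
        return self.params.hill

    @property
    def bse(self) -> dict[str, float]:
        return dict(zip(self._names, np.sqrt(np.diag(self.cov))))

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Approximate (1-alpha) Wald intervals from the curvature."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.dof)
        est = [self.bottom, self.emax, self.ec50, self.hill]
        se = np.sqrt(np.diag(self.cov))
        return {n: (e - tcrit * s, e + tcrit * s)
                for n, e, s in zip(self._names, est, se)}

    def predict(self, dose=None):
        x = self.model.dose if dose is None else np.asarray(dose, float)
        return fourpl(x, self.bottom, self.emax, self.ec50, self.hill)

    def summary(self) -> str:
        se = self.bse
        est = {"bottom": self.bottom, "emax": self.emax,
               "ec50": self.ec50, "hill": self.hill}
        lines = ["4PL dose-response fit", "=" * 44,
                 f"{'parameter':<10}{'estimate':>14}{'std err':>14}", "-" * 44]
        for name in self._names:
            lines.append(f"{name:<10}{est[name]:>14.4g}{se[name]:>14.3g}")
        lines += ["-" * 44,
                  f"residual RMS: {self.rmse:.4g} over {self.model.dose.size} points"]
        return "\n".join(lines)


@dataclass
class FitComparison:
    """Potency/efficacy shift between a control and a treated fit."""

    ec50_fold_shift: float     # control EC50 / treated EC50 (>1: left shift)
    delta_log_ec50: float      # log10(treated) - log10(control)
    emax_ratio: float          # treated Emax / control Emax
    ec50_ci_overlap: bool
    emax_ci_overlap: bool


def compare_fits(control: FourPLResults, treated: FourPLResults,
                 alpha: float = 0.05) -> FitComparison:
    """Report EC50 fold-shift, Emax ratio and approximate CI overlap.

    CI overlap is a coarse screen, not a formal test: non-overlapping
    95% intervals imply a difference, overlapping ones are inconclusive.
    """
    ci_c, ci_t = control.conf_int(alpha), treated.conf_int(alpha)

    def overlap(a, b):
        return a[0] <= b[1] and b[0] <= a[1]

    return FitComparison(
        ec50_fold_shift=control.ec50 / treated.ec50,
        delta_log_ec50=float(np.log10(treated.ec50) - np.log10(control.ec50)),
        emax_ratio=treated.emax / control.emax,
        ec50_ci_overlap=overlap(ci_c["ec50"], ci_t["ec50"]),
        emax_ci_overlap=overlap(ci_c["emax"], ci_t["emax"]),
    )
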