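"""1:1 (Langmuir) binding kinetics for biolayer interferometry.

Association at analyte concentration C follows

    R(t) = R_eq(C) * (1 - exp(-k_obs * t)),   k_obs = k_on*C + k_off,
    R_eq(C) = R_max * C / (C + K_D),          K_D = k_off / k_on,

and dissociation from the level R_0 reached at the end of association

    R(t) = R_0 * exp(-k_off * (t - t_d)).

:class:`LangmuirModel` fits k_on, k_off and R_max globally across all
concentrations (shared parameters, the standard treatment for 1:1 BLI
sensorgram series); :class:`LangmuirResults` carries the estimates,
their standard errors from the local curvature and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class LangmuirParams:
    """1:1 kinetic constants: k_on [1/(M*s)], k_off [1/s], R_max [RU]."""

    kon: float
    koff: float
    rmax: float

    def __post_init__(self):
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("rate constants must be positive")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant K_D = k_off / k_on [M]."""
        return self.koff / self.kon


def association(t, conc, kon, koff, rmax):
    """Closed-form association-phase response."""
    t = np.asarray(t, dtype=float)
    kobs = kon * conc + koff
    req = rmax * conc / (conc + koff / kon)
    return req * (1.0 - np.exp(-kobs * t))


def dissociation(t, r0, koff, t_start=0.0):
    """Closed-form dissociation-phase response from level ``r0``."""
    t = np.asarray(t, dtype=float)
    return r0 * np.exp(-koff * (t - t_start))


def sensorgram(t, conc, params: LangmuirParams, t_dissoc: float):
    """Full association+dissociation trace on one time grid.

    Association runs on t <= t_dissoc, dissociation continues from the
    model's association level at t_dissoc (continuous trace).
    """
    t = np.asarray(t, dtype=float)
    r = association(np.minimum(t, t_dissoc), conc, params.kon, params.koff, params.rmax)
    r0 = association(t_dissoc, conc, params.kon, params.koff, params.rmax)
    dis = t > t_dissoc
    r = np.where(dis, dissociation(t, r0, params.koff, t_dissoc), r)
    return r


class LangmuirModel:
    """Global 1:1 fit of referenced sensorgrams over analyte concentrations.

    Parameters
    ----------
    time : 1-D array, seconds; shared grid covering association then
        dissociation.
    responses : 2-D array, shape (n_concentrations, n_times).
    concentrations : 1-D array of molar analyte concentrations.
    t_dissoc : float, start of the dissociation phase in seconds.
    """

    def __init__(self, time, responses, concentrations, t_dissoc):
        self.time = np.asarray(time, dtype=float)
        self.responses = np.atleast_2d(np.asarray(responses, dtype=float))
        self.concentrations = np.atleast_1d(np.asarray(concentrations, dtype=float))
        self.t_dissoc = float(t_dissoc)
        if self.responses.shape != (self.concentrations.size, self.time.size):
            raise ValueError("responses must be (n_concentrations, n_times)")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    # -- initial values ------------------------------------------------

    def _start(self) -> np.ndarray:
        rmax0 = max(float(np.nanmax(self.responses)), 1e-12) * 1.2
        # k_off from a log-linear fit to the dissociation tail of the
        # highest-concentration trace
        hi = int(np.argmax(self.concentrations))
        dis = self.time > self.t_dissoc
        koff0 = 1e-3
        y = self.responses[hi, dis]
        t = self.time[dis]
        pos = y > 1e-6 * rmax0
        if pos.sum() >= 3:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            if slope < 0:
                koff0 = -slope
        # k_on from the 63% rise time of the same trace
        assoc = self.time <= self.t_dissoc
        ya, ta = self.responses[hi, assoc], self.time[assoc]
        plateau = float(ya[-1]) if ya.size else rmax0
        kon0 = 1e4
        if plateau > 0:
            cross = np.nonzero(ya >= 0.632 * plateau)[0]
            if cross.size and ta[cross[0]] > 0:
                kobs = 1.0 / ta[cross[0]]
                kon0 = max((kobs - koff0) / self.concentrations[hi], koff0 / 10 / self.concentrations[hi])
        return np.log([kon0, koff0, rmax0])

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        params = LangmuirParams(*np.exp(theta))
        return np.vstack([sensorgram(self.time, c, params, self.t_dissoc)
                          for c in self.concentrations])

    def fit(self, start: LangmuirParams | None = None) -> "LangmuirResults":
        """Least-squares global fit; rates parameterised on the log scale
        to enforce positivity."""
        theta0 = (np.log([start.kon, start.koff, start.rmax])
                  if start is not None else self._start())

        def resid(theta):
            return (self._predict(theta) - self.responses).ravel()

        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise RuntimeError(f"Langmuir fit did not converge: {sol.message}")
        params = LangmuirParams(*np.exp(sol.x))
        n, p = sol.fun.size, 3
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        dof = max(n - p, 1)
        s2 = float(np.sum(sol.fun**2)) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov_log = np.full((p, p), np.nan)
        # delta method back to the natural scale
        scale = np.exp(sol.x)
        cov = cov_log * np.outer(scale, scale)
        return LangmuirResults(self, params, cov, rmse)


class LangmuirResults:
    """Fitted 1:1 kinetics with uncertainties and diagnostics."""

    _names = ("kon", "koff", "rmax")

    def __init__(self, model: LangmuirModel, params: LangmuirParams,
                 cov: np.ndarray, rmse: float):
        self.model = model
        self.params = params
        self.cov = cov
        self.rmse = rmse

    @property
    def kon(self) -> float:
        return self.params.kon

    @property
    def koff(self) -> float:
        return self.params.koff

    @property
    def rmax(self) -> float:
        return self.params.rmax

    @property
    def kd(self) -> float:
        return self.params.kd

    @property
    def bse(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.cov))
        return dict(zip(self._names, se))

    @property
    def kd_se(self) -> float:
        """Delta-method standard error of K_D = k_off/k_on."""
        g = np.array([-self.koff / self.kon**2, 1.0 / self.kon, 0.0])
        return float(np.sqrt(g @ self.cov @ g))

    def predict(self, time=None):
        t = self.model.time if time is None else np.asarray(time, float)
        return np.vstack([sensorgram(t, c, self.params, self.model.t_dissoc)
                          for c in self.model.concentrations])

    def summary(self) -> str:
        se = self.bse
        lines = [
            "1:1 Langmuir kinetic fit",
            "=" * 46,
            f"{'parameter':<10}{'estimate':>14}{'std err':>14}",
            "-" * 46,
            f"{'k_on':<10}{self.kon:>14.4g}{se['kon']:>14.3g}   1/(M*s)",
            f"{'k_off':<10}{self.koff:>14.4g}{se['koff']:>14.3g}   1/s",
            f"{'R_max':<10}{self.rmax:>14.4g}{se['rmax']:>14.3g}   RU",
            f"{'K_D':<10}{self.kd:>14.4g}{self.kd_se:>14.3g}   M",
            "-" * 46,
            f"residual RMS: {self.rmse:.4g} RU over "
            f"{self.model.responses.size} points, "
            f"{self.model.concentrations.size} concentrations",
        ]
        return "\n".join(lines)


def bli_double_subtract(sample, nr_control, blank, rezero_index: int | None = 0):
    """Double-reference a sensorgram: sample - NR control - blank.

    All three traces must share one time grid.  ``rezero_index`` shifts
    the referenced trace so that it is zero at that sample (pass None to
    skip re-zeroing).
    """
    sample = np.asarray(sample, dtype=float)
    nr_control = np.asarray(nr_control, dtype=float)
    blank = np.asarray(blank, dtype=float)
    if not (sample.shape == nr_control.shape == blank.shape):
        raise ValueError("sensorgram grids do not match")
    ref = sample - nr_control - blank
    if rezero_index is not None:
        ref = ref - np.take(ref, [rezero_index], axis=-1)
    return ref
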