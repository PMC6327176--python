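"""Two-state equilibrium denaturation: model, six-parameter fit, ΔΔG.

The linear extrapolation model treats unfolding free energy as linear in
denaturant concentration, ΔG(D) = ΔG° − m·D, with the observed signal a
population-weighted mix of two linear baselines:

    K(D)   = exp(−(ΔG° − m·D) / RT)
    fU(D)  = K / (1 + K)
    y(D)   = (γ0F + mF·D)·(1 − fU) + (γ0U + mU·D)·fU

Six parameters are fitted: ΔG° (kcal/mol), m (kcal/mol/M), the folded and
unfolded baseline intercepts γ0F, γ0U and slopes mF, mU. The transition
midpoint is Cm = ΔG°/m, and stability differences between proteins follow
ΔΔG = (Cm,A − Cm,B)·(m_A + m_B)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "TwoStateParams",
    "DenaturationCurve",
    "TwoStateFitError",
    "two_state_signal",
    "fraction_unfolded",
    "fit_two_state",
    "ddg_between",
]

GAS_CONSTANT_KCAL = 1.987e-3   # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15   # K (25 °C)


@dataclass
class TwoStateParams:
    """The six fitted parameters of the two-state denaturation model."""

    dG0: float    # kcal/mol, unfolding free energy in water
    m: float      # kcal/mol/M, denaturant sensitivity
    g0F: float    # folded baseline intercept (signal units)
    g0U: float    # unfolded baseline intercept
    mF: float = 0.0   # folded baseline slope, signal/M
    mU: float = 0.0   # unfolded baseline slope

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("m-value must be positive")

    @property
    def cm(self) -> float:
        """Midpoint denaturant concentration, M."""
        return self.dG0 / self.m

    def as_array(self) -> np.ndarray:
        return np.array([self.dG0, self.m, self.g0F, self.g0U,
                         self.mF, self.mU])


@dataclass
class DenaturationCurve:
    """Signal vs denaturant concentration at fixed temperature."""

    concentrations: np.ndarray   # M, strictly increasing, >= 0
    signals: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.signals, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentrations and signals must be equal-"
                             "length 1-D arrays")
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be >= 0 and strictly "
                             "increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self.concentrations, self.signals = c, y


class TwoStateFitError(RuntimeError):
    """The curve shows no detectable unfolding transition."""


def fraction_unfolded(dG0: float, m: float, D, T: float = DEFAULT_TEMPERATURE,
                      ):
    """Unfolded population K/(1+K); overflow-safe logistic evaluation."""
    D = np.asarray(D, dtype=float)
    # K/(1+K) with K = exp(-(dG0 - m D)/RT) is the logistic of the
    # negated exponent; expit never overflows
    return expit(-(dG0 - m * D) / (GAS_CONSTANT_KCAL * T))


def two_state_signal(params: TwoStateParams, D,
                     T: float | None = None):
    """Model signal at denaturant concentration(s) D."""
    T = DEFAULT_TEMPERATURE if T is None else T
    if T <= 0:
        raise ValueError("temperature must be positive")
    D = np.asarray(D, dtype=float)
    fu = fraction_unfolded(params.dG0, params.m, D, T)
    folded = params.g0F + params.mF * D
    unfolded = params.g0U + params.mU * D
    out = folded * (1.0 - fu) + unfolded * fu
    return float(out) if out.ndim == 0 else out


def _initial_guesses(curve: DenaturationCurve) -> list[np.ndarray]:
    c, y = curve.concentrations, curve.signals
    n = len(c)
    k = max(2, n // 4)
    gF = float(np.mean(y[:k]))
    gU = float(np.mean(y[-k:]))
    # Cm seeded from the steepest-slope point of the smoothed signal
    dy = np.gradient(y, c)
    cm0 = float(c[int(np.argmax(np.abs(dy)))])
    cm0 = min(max(cm0, c[1]), c[-2]) if n > 3 else cm0
    guesses = []
    for m0 in (1.0, 2.0, 4.0):
        guesses.append(np.array([m0 * cm0, m0, gF, gU, 0.0, 0.0]))
    return guesses


def fit_two_state(curve: DenaturationCurve,
                  max_nfev: int = 2000,
                  min_amplitude_sigmas: float = 3.0,
                  ) -> tuple[TwoStateParams, dict]:
    """Nonlinear least-squares fit of the six two-state parameters.

    Multi-start: the midpoint is seeded from the steepest-slope point and
    several m-values are tried; the best solution by residual norm wins.
    Deterministic. Raises :class:`TwoStateFitError` when the curve shows
    no transition (baseline separation indistinguishable from noise).

    Returns the parameters plus diagnostics (RMS residual, residuals,
    the fitted Cm).
    """
    c, y = curve.concentrations, curve.signals
    if len(c) < 8:
        raise ValueError("need at least 8 points spanning baselines and "
                         "transition")
    T = curve.temperature

    def residuals(theta: np.ndarray) -> np.ndarray:
        dG0, m, gF, gU, mF, mU = theta
        fu = expit(-(dG0 - m * c) / (GAS_CONSTANT_KCAL * T))
        model = (gF + mF * c) * (1.0 - fu) + (gU + mU * c) * fu
        return model - y

    best = None
    lo = np.array([-np.inf, 1e-6, -np.inf, -np.inf, -np.inf, -np.inf])
    hi = np.full(6, np.inf)
    for x0 in _initial_guesses(curve):
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                max_nfev=max_nfev)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise TwoStateFitError("all fit starts failed")
    dG0, m, gF, gU, mF, mU = best.x
    resid = residuals(best.x)
    rms = float(np.sqrt(np.mean(resid ** 2)))

    # transition-detection gate: the baseline separation at the fitted
    # midpoint must exceed the residual noise by a clear margin
    cm = dG0 / m
    amplitude = abs((gU + mU * cm) - (gF + mF * cm))
    noise = max(rms, 1e-12)
    in_range = c[0] <= cm <= c[-1]
    if not in_range or amplitude < min_amplitude_sigmas * noise:
        raise TwoStateFitError(
            f"no detectable transition (midpoint {cm:.2f} M, amplitude "
            f"{amplitude:.3g}, noise {noise:.3g})")
    params = TwoStateParams(dG0=float(dG0), m=float(m), g0F=float(gF),
                            g0U=float(gU), mF=float(mF), mU=float(mU))
    diagnostics = {"rms_residual": rms, "residuals": resid, "cm": params.cm,
                   "n_points": len(c)}
    return params, diagnostics


def ddg_between(a: TwoStateParams, b: TwoStateParams) -> float:
    """Stability difference ΔΔG = (Cm,A − Cm,B)(m_A + m_B)/2, kcal/mol."""
    return (a.cm - b.cm) * (a.m + b.m) / 2.0
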