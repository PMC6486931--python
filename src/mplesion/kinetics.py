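"""Contrast-enhancement kinetics: the sigmoid-times-exponential curve model.

The signal-time course of a contrast-enhancing lesion is modelled as an
asymmetric generalised logistic function (wash-in) multiplied by an
exponential term (washout / terminal drift):

    C(t) = G * (1 - (1 + (2**alpha - 1) * exp((t - t_half) / tau)) ** (-1/alpha))
             * exp(beta * t**k)

with ``G`` the enhancement scale, ``alpha`` the asymmetry of the sigmoid,
``tau`` its steepness (seconds), ``t_half`` the time of half maximum of the
sigmoid (seconds), and ``beta``/``k`` the scale and exponent of the
exponential term.  ``beta < 0`` yields washout after the wash-in phase (the
malignant pattern); ``beta = 0`` yields persistent enhancement saturating at
``G`` (the benign pattern).

Fitting is bounded nonlinear least squares with a few seeded restarts;
curve summaries (AuC, Cmax, Tmax, T1/2, MDER) are evaluated on the fitted
curve over a seven-minute window from contrast arrival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "KineticParams",
    "KineticFit",
    "enhancement_curve",
    "enhancement_curve_derivative",
    "fit_kinetic",
    "curve_summaries",
    "SUMMARY_WINDOW_S",
]

#: summary window: seven minutes from start of contrast enhancement.
SUMMARY_WINDOW_S = 420.0

PARAM_NAMES = ("G", "alpha", "tau", "t_half", "beta", "k")


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the enhancement curve model."""

    G: float
    alpha: float
    tau: float
    t_half: float
    beta: float
    k: float

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.G < 0:
            raise ValueError(f"G must be non-negative, got {self.G}")

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.alpha, self.tau, self.t_half, self.beta, self.k])


def enhancement_curve(params, times) -> np.ndarray:
    """Evaluate the kinetic model C(t) at the given times (seconds).

    ``params`` is a :class:`KineticParams` or a length-6 sequence
    ``(G, alpha, tau, t_half, beta, k)``.  Times must be finite and
    non-negative (t**k is real only for t >= 0).
    """
    if not isinstance(params, KineticParams):
        params = KineticParams(*params)
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return _curve(t, *params.as_array())


def _curve(t, G, alpha, tau, t_half, beta, k):
    # exponent clipped to keep exp() finite far past t_half; the sigmoid is
    # already saturated there so the clip does not change values materially.
    z = np.clip((t - t_half) / tau, -700.0, 700.0)
    u = 1.0 + (2.0**alpha - 1.0) * np.exp(z)
    sigmoid = 1.0 - u ** (-1.0 / alpha)
    with np.errstate(invalid="ignore"):
        growth = np.exp(beta * np.power(t, k))
    return G * sigmoid * growth


def enhancement_curve_derivative(params, times) -> np.ndarray:
    """Analytic derivative dC/dt of the kinetic model.

    With u(t) = 1 + (2**a - 1) exp((t - t_half)/tau),

        C   = G * (1 - u**(-1/a)) * E,        E = exp(beta * t**k)
        C'  = G * [ u' / (a * tau') * u**(-1/a - 1) * E
                    + (1 - u**(-1/a)) * beta * k * t**(k-1) * E ]

    where u' = (2**a - 1) exp((t - t_half)/tau) / tau.
    """
    if not isinstance(params, KineticParams):
        params = KineticParams(*params)
    G, alpha, tau, t_half, beta, k = params.as_array()
    t = np.asarray(times, dtype=float)
    z = np.clip((t - t_half) / tau, -700.0, 700.0)
    e = (2.0**alpha - 1.0) * np.exp(z)
    u = 1.0 + e
    E = np.exp(beta * np.power(t, k))
    sig = 1.0 - u ** (-1.0 / alpha)
    d_sig = (e / (alpha * tau)) * u ** (-1.0 / alpha - 1.0)
    # at t = 0 the t**(k-1) factor diverges for k < 1; the curve itself is
    # ~0 there so the envelope term is dropped at the origin.
    with np.errstate(divide="ignore", invalid="ignore"):
        d_env = beta * k * np.where(t > 0, np.power(np.maximum(t, 1e-300), k - 1.0), 0.0)
    return G * (d_sig * E + sig * d_env * E)


@dataclass
class KineticFit:
    """Fitted curve parameters plus summaries over the 7-min window.

    ``converged`` is False when no restart produced a finite optimum; the
    summaries are still evaluated on the best parameters found so callers
    can flag rather than silently drop the lesion.
    """

    params: KineticParams
    residual: float
    converged: bool
    auc: float = field(default=np.nan)
    c_max: float = field(default=np.nan)
    t_max: float = field(default=np.nan)
    t_half_obs: float = field(default=np.nan)
    mder: float = field(default=np.nan)

    def summaries(self) -> dict[str, float]:
        return {
            "AuC": self.auc,
            "Cmax": self.c_max,
            "Tmax": self.t_max,
            "T1/2": self.t_half_obs,
            "MDER": self.mder,
        }


def curve_summaries(params: KineticParams, window: float = SUMMARY_WINDOW_S) -> dict[str, float]:
    """Summaries of the fitted curve over [0, window] seconds.

    AuC by numeric quadrature; Cmax/Tmax by dense grid plus bounded local
    refinement; T1/2 the earliest time at which C reaches Cmax/2; MDER the
    maximum of the analytic derivative.
    """
    grid = np.linspace(0.0, window, 2001)
    c = enhancement_curve(params, grid)
    auc = float(integrate.trapezoid(c, grid))

    i_max = int(np.argmax(c))
    lo = grid[max(i_max - 1, 0)]
    hi = grid[min(i_max + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: -enhancement_curve(params, [t])[0], bounds=(lo, hi), method="bounded"
        )
        t_max = float(res.x)
        c_max = float(-res.fun)
        if c_max < c[i_max]:  # refinement must not lose the grid optimum
            t_max, c_max = float(grid[i_max]), float(c[i_max])
    else:
        t_max, c_max = float(grid[i_max]), float(c[i_max])

    half = c_max / 2.0
    t_half_obs = t_max
    above = np.nonzero(c >= half)[0]
    if above.size:
        i = int(above[0])
        if i == 0 or c[i] == half:
            t_half_obs = float(grid[i])
        else:
            t_half_obs = float(
                optimize.brentq(lambda t: enhancement_curve(params, [t])[0] - half, grid[i - 1], grid[i])
            )

    d = enhancement_curve_derivative(params, grid)
    i_d = int(np.argmax(d))
    lo = grid[max(i_d - 1, 0)]
    hi = grid[min(i_d + 1, len(grid) - 1)]
    mder = float(d[i_d])
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: -enhancement_curve_derivative(params, [t])[0], bounds=(lo, hi), method="bounded"
        )
        mder = max(mder, float(-res.fun))
    return {"AuC": auc, "Cmax": c_max, "Tmax": t_max, "T1/2": t_half_obs, "MDER": mder}


def fit_kinetic(times, values, n_starts: int = 3, seed: int = 0) -> KineticFit:
    """Fit the kinetic model to an observed curve by bounded least squares.

    ``times`` are seconds from contrast arrival (strictly positive so that
    t**k stays well defined for k < 1); ``values`` the curve samples.  A few
    seeded restarts mitigate local minima of the non-convex objective.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and of equal length")
    if t.size < 6:
        raise ValueError("need at least 6 points to fit 6 parameters")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive (shift the origin)")

    rng = np.random.default_rng(seed)
    span = float(t[-1] - t[0])
    y_max = float(np.max(np.abs(y))) or 1.0

    #        G             alpha      tau          t_half        beta        k
    lower = [0.0,          0.05,      1e-2,        0.0,          -1e-1,      0.25]
    upper = [10.0 * y_max, 20.0,      10.0 * span, 2.0 * span,   1e-2,      2.0]

    def residual(p):
        return _curve(t, *p) - y

    best = None
    for s in range(n_starts):
        x0 = np.array(
            [
                max(y_max, 1e-6) * (1.0 + 0.2 * rng.standard_normal()),
                1.0 + 0.5 * rng.random(),
                max(span / 10.0, 1.0) * (1.0 + 0.5 * rng.random()),
                float(t[np.argmin(np.abs(y - y_max / 2.0))]) * (1.0 + 0.1 * rng.standard_normal()),
                -1e-4 * rng.random(),
                1.0,
            ]
        )
        x0 = np.clip(x0, lower, upper)
        try:
            sol = optimize.least_squares(residual, x0, bounds=(lower, upper), method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        params = KineticParams(y_max, 1.0, span / 10.0, span / 2.0, 0.0, 1.0)
        return KineticFit(params=params, residual=np.inf, converged=False,
                          **_summary_kwargs(params))
    params = KineticParams(*best.x)
    rms = float(np.sqrt(2.0 * best.cost / t.size))
    fit = KineticFit(params=params, residual=rms, converged=bool(best.success),
                     **_summary_kwargs(params))
    return fit


def _summary_kwargs(params: KineticParams) -> dict[str, float]:
    s = curve_summaries(params)
    return {
        "auc": s["AuC"],
        "c_max": s["Cmax"],
        "t_max": s["Tmax"],
        "t_half_obs": s["T1/2"],
        "mder": s["MDER"],
    }
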