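"""Two-state thermal unfolding: Gibbs-Helmholtz free energy, folded and
unfolded populations, baseline-weighted fluorescence melt curves and their
nonlinear least-squares fitting.

The model is the classic two-state equilibrium N <-> U with

    dG(T) = dHm * (1 - T/Tm) + dCp * [(T - Tm) - T * ln(T/Tm)]

and fraction unfolded fU = K/(1+K), K = exp(-dG/(R T)). The observed
fluorescence ratio is the population-weighted sum of a linear native
baseline and a quadratic unfolded baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .constants import R_GAS

__all__ = [
    "TwoStateThermo",
    "BaselineParams",
    "MeltFitResult",
    "delta_g_unfold",
    "fraction_unfolded",
    "predict_signal",
    "fit_melt_curve",
    "population_shift",
    "melting_midpoint",
]

#: Reporting floor on the fitted Tm uncertainty, K (repeat-experiment based).
TM_UNCERTAINTY_FLOOR = 0.3


@dataclass
class TwoStateThermo:
    """Thermodynamic parameters of a two-state unfolding equilibrium.

    Attributes
    ----------
    tm : melting temperature, K.
    dhm : van't Hoff enthalpy of unfolding at Tm, J/mol.
    dcp : heat-capacity change of unfolding, J/(mol K); 0 fixes the
        enthalpy to be temperature independent.
    """

    tm: float
    dhm: float
    dcp: float = 0.0

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError("Tm must be positive (Kelvin)")


@dataclass
class BaselineParams:
    """Pre- and post-transition baselines of a melt curve.

    Native baseline: a_n0 + g_n*(T - t_ref); unfolded baseline:
    a_u0 + g1_u*(T - t_ref) + g2_u*(T - t_ref)**2.
    """

    a_n0: float = 1.0
    g_n: float = 0.0
    a_u0: float = 0.0
    g1_u: float = 0.0
    g2_u: float = 0.0
    t_ref: float = 298.15


@dataclass
class MeltFitResult:
    thermo: TwoStateThermo
    baselines: BaselineParams
    errors: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = False
    message: str = ""


def delta_g_unfold(temperature, thermo: TwoStateThermo):
    """Free energy of unfolding dG(T) in J/mol (Gibbs-Helmholtz).

    Positive below Tm for a cooperative unfolder, zero at Tm.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    tm, dhm, dcp = thermo.tm, thermo.dhm, thermo.dcp
    dg = dhm * (1.0 - t / tm) + dcp * ((t - tm) - t * np.log(t / tm))
    return dg if dg.shape else float(dg)


def fraction_unfolded(temperature, thermo: TwoStateThermo):
    """Equilibrium fraction of unfolded protein, fU = K/(1+K) in [0, 1]."""
    t = np.asarray(temperature, dtype=float)
    dg = np.asarray(delta_g_unfold(t, thermo))
    # K/(1+K) with K = exp(-dG/RT); logistic form is overflow-safe
    x = -dg / (R_GAS * t)
    fu = 1.0 / (1.0 + np.exp(-x))
    return fu if fu.shape else float(fu)


def predict_signal(temperature, thermo: TwoStateThermo, baselines: BaselineParams):
    """Baseline-weighted two-state fluorescence signal.

    f(T) = bN(T)*(1-fU) + bU(T)*fU with a linear native and quadratic
    unfolded baseline, both referenced to t_ref.
    """
    t = np.asarray(temperature, dtype=float)
    fu = np.asarray(fraction_unfolded(t, thermo))
    dt = t - baselines.t_ref
    b_n = baselines.a_n0 + baselines.g_n * dt
    b_u = baselines.a_u0 + baselines.g1_u * dt + baselines.g2_u * dt**2
    f = b_n * (1.0 - fu) + b_u * fu
    return f if f.shape else float(f)


def melting_midpoint(thermo: TwoStateThermo, bracket: tuple[float, float] = (250.0, 450.0)) -> float:
    """Numerically locate the temperature where fU = 0.5 (equals Tm)."""
    return brentq(lambda t: fraction_unfolded(t, thermo) - 0.5, *bracket)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[TwoStateThermo, BaselineParams]:
    """Data-driven starting point: Tm from the steepest signal slope,
    baselines from linear fits to the first and last 15% of points."""
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    dy = np.gradient(ys, ts)
    tm0 = float(ts[np.argmax(np.abs(dy))])
    n_edge = max(3, len(ts) // 7)
    t_ref = float(ts.mean())
    c_n = np.polyfit(ts[:n_edge] - t_ref, ys[:n_edge], 1)
    c_u = np.polyfit(ts[-n_edge:] - t_ref, ys[-n_edge:], 1)
    thermo = TwoStateThermo(tm=tm0, dhm=3.0e5, dcp=0.0)
    base = BaselineParams(
        a_n0=float(c_n[1]), g_n=float(c_n[0]),
        a_u0=float(c_u[1]), g1_u=float(c_u[0]), g2_u=0.0, t_ref=t_ref,
    )
    return thermo, base


def fit_melt_curve(
    temperature: Sequence[float],
    signal: Sequence[float],
    sigma: Sequence[float] | None = None,
    fit_dcp: bool = False,
    initial: tuple[TwoStateThermo, BaselineParams] | None = None,
) -> MeltFitResult:
    """Weighted nonlinear least-squares fit of a two-state melt curve.

    Free parameters: Tm, dHm, (optionally dCp) and the five baseline
    coefficients. Inverse-variance weights when ``sigma`` is given.
    A curve without a transition in range yields ``converged=False``
    rather than an exception. Reported Tm uncertainty is floored at
    0.3 K, the repeat-experiment reproducibility of the measurement.
    """
    t = np.asarray(temperature, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 20:
        raise ValueError("need at least 20 points spanning the transition")
    w = 1.0 / np.asarray(sigma, dtype=float) if sigma is not None else np.ones_like(y)

    if initial is None:
        thermo0, base0 = _initial_guess(t, y)
    else:
        thermo0, base0 = initial
    t_ref = base0.t_ref

    def unpack(p):
        tm, dhm = p[0], p[1]
        dcp = p[2] if fit_dcp else 0.0
        off = 3 if fit_dcp else 2
        base = BaselineParams(*p[off:off + 5], t_ref=t_ref)
        return TwoStateThermo(tm=tm, dhm=dhm, dcp=dcp), base

    p0 = [thermo0.tm, thermo0.dhm]
    lo = [t.min() - 50.0, 1e3]
    hi = [t.max() + 50.0, 5e6]
    if fit_dcp:
        p0 += [max(thermo0.dcp, 0.0)]
        lo += [0.0]
        hi += [1e5]
    p0 += [base0.a_n0, base0.g_n, base0.a_u0, base0.g1_u, base0.g2_u]
    lo += [-np.inf] * 5
    hi += [np.inf] * 5

    def resid(p):
        thermo, base = unpack(p)
        return w * (predict_signal(t, thermo, base) - y)

    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", x_scale="jac")
    thermo, base = unpack(sol.x)
    rss = float(np.sum(sol.fun**2))

    # covariance from the Jacobian at the solution
    errors: dict[str, float] = {}
    dof = max(t.size - sol.x.size, 1)
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * rss / dof
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        names = ["tm", "dhm"] + (["dcp"] if fit_dcp else []) + [
            "a_n0", "g_n", "a_u0", "g1_u", "g2_u"]
        errors = dict(zip(names, perr.tolist()))
        errors["tm"] = max(errors["tm"], TM_UNCERTAINTY_FLOOR)
    except np.linalg.LinAlgError:
        pass

    # a transition outside the sampled range (or no transition) is flagged,
    # not raised: the sigmoid is then degenerate with the baselines
    in_range = t.min() < thermo.tm < t.max()
    span = fraction_unfolded(t.max(), thermo) - fraction_unfolded(t.min(), thermo)
    converged = bool(sol.success and in_range and span > 0.5)
    msg = sol.message if converged else "no resolvable transition inside the temperature range"
    return MeltFitResult(thermo=thermo, baselines=base, errors=errors,
                         rss=rss, converged=converged, message=msg)


def population_shift(thermo: TwoStateThermo, d_tm: float, t_eval: float) -> tuple[float, float]:
    """Folded fraction at ``t_eval`` before and after a Tm increase of
    ``d_tm`` K with dHm (and dCp) held fixed."""
    before = 1.0 - fraction_unfolded(t_eval, thermo)
    shifted = TwoStateThermo(tm=thermo.tm + d_tm, dhm=thermo.dhm, dcp=thermo.dcp)
    after = 1.0 - fraction_unfolded(t_eval, shifted)
    return float(before), float(after)
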