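"""CPMG relaxation dispersion: R2,eff computation, exchange screening,
two-site Bloch-McConnell and Carver-Richards engines, grouped global
fitting, dw sign determination and random-coil correlation.

The exchange model is a ground state A interconverting with a minor
state B (population pB < 0.5) at total rate kex = kAB + kBA, with a
15N chemical shift difference dw (ppm). R2,eff(nu_CPMG) is measured as
-(1/Trelax) ln(I/I0) over a constant-time relaxation element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import linregress

from .constants import ppm_to_rad

__all__ = [
    "DispersionCurve",
    "ExchangeParams",
    "GroupFit",
    "r2eff",
    "sigma_floor",
    "flag_dispersive",
    "simulate_bm",
    "simulate_cr",
    "fit_group",
    "dw_sign",
    "peak_positions_hsqc_hmqc",
    "correlate_dw_secondary",
]

#: Absolute and relative error floors on R2,eff, s^-1.
SIGMA_ABS_FLOOR = 0.3
SIGMA_REL_FLOOR = 0.02

#: Dispersion screen: DR2 and reduced chi^2 of a flat fit must both exceed these.
DR2_THRESHOLD = 1.5
CHI2_RED_THRESHOLD = 4.0


@dataclass
class ExchangeParams:
    """Two-site exchange parameters for one residue (dw) within a
    (pB, kex) process; r2_0 maps 1H field MHz -> exchange-free rate."""

    p_b: float
    k_ex: float
    dw_ppm: float
    r2_0: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_b < 0.5:
            raise ValueError("pB must lie in [0, 0.5)")
        if self.k_ex < 0:
            raise ValueError("kex must be non-negative")


@dataclass
class DispersionCurve:
    residue: int
    field_mhz: float
    t_relax: float
    nu_cpmg: np.ndarray
    r2_eff: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2_eff = np.asarray(self.r2_eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_CPMG must be positive")


@dataclass
class GroupFit:
    residues: list[int]
    p_b: float
    k_ex: float
    dw_ppm: dict[int, float]
    r2_0: dict[tuple[int, float], float]
    chi2_red: float
    converged: bool = True


def r2eff(i: float, i0: float, t_relax: float) -> float:
    """Effective transverse rate -(1/Trelax) ln(I/I0).

    I > I0 is permitted and yields a (physically suspect) negative rate;
    callers are expected to flag such points.
    """
    if i <= 0 or i0 <= 0:
        raise ValueError("intensities must be positive")
    return float(-np.log(i / i0) / t_relax)


def sigma_floor(r2_values: Sequence[float], duplicate_rmsd: float = 0.0) -> np.ndarray:
    """Per-point uncertainty: max(duplicate rmsd, 0.3 s^-1, 2% of R2,eff)."""
    r2 = np.asarray(r2_values, dtype=float)
    return np.maximum.reduce([
        np.full_like(r2, duplicate_rmsd),
        np.full_like(r2, SIGMA_ABS_FLOOR),
        SIGMA_REL_FLOOR * np.abs(r2),
    ])


def flag_dispersive(curve: DispersionCurve) -> tuple[bool, dict]:
    """Exchange screen: DR2 = R2,eff(lowest nu) - R2,eff(highest nu) must
    exceed 1.5 s^-1 AND the flat (no-exchange) fit must have reduced
    chi^2 > 4."""
    if curve.nu_cpmg.size < 5:
        raise ValueError("need at least 5 dispersion points to screen")
    order = np.argsort(curve.nu_cpmg)
    dr2 = float(curve.r2_eff[order[0]] - curve.r2_eff[order[-1]])
    w = 1.0 / curve.sigma**2
    flat = float(np.sum(w * curve.r2_eff) / np.sum(w))
    dof = curve.nu_cpmg.size - 1
    chi2_red = float(np.sum(((curve.r2_eff - flat) / curve.sigma) ** 2) / dof)
    is_dispersive = (dr2 > DR2_THRESHOLD) and (chi2_red > CHI2_RED_THRESHOLD)
    return is_dispersive, {"dr2": dr2, "chi2_red_flat": chi2_red, "r2_flat": flat}


# ------------------------------------------------------- simulation engines

def _echo_count(nu: float, t_relax: float) -> int:
    """Number of tau-180-tau echo units in the constant-time element.

    nu_CPMG = n_echo / Trelax with tau = 1/(4 nu); requests incompatible
    with an integer echo count are rounded to the nearest >= 1.
    """
    return max(1, int(round(nu * t_relax)))


def simulate_bm(params: ExchangeParams, nu_cpmg: Sequence[float], field_mhz: float,
                t_relax: float) -> np.ndarray:
    """Numerical two-site Bloch-McConnell CPMG simulation.

    In-phase single-quantum magnetization evolves under the complex 2x2
    Liouvillian (exchange + offset + intrinsic R2) through the echo
    train; ideal instantaneous 180 pulses act as complex conjugation.
    R2,eff is taken from the ground-state component after Trelax,
    referenced to I0 simulated without the relaxation element.
    """
    p_b, k_ex = params.p_b, params.k_ex
    p_a = 1.0 - p_b
    k_ab, k_ba = p_b * k_ex, p_a * k_ex
    dw = ppm_to_rad(params.dw_ppm, field_mhz)
    r2a = params.r2_0.get(field_mhz, next(iter(params.r2_0.values())) if params.r2_0 else 0.0)
    r2b = r2a

    out = np.empty(len(nu_cpmg))
    m0 = np.array([p_a, p_b], dtype=complex)
    liou_base = np.array([
        [-r2a - k_ab, k_ba],
        [k_ab, -r2b - k_ba - 1j * dw],
    ], dtype=complex)

    for i, nu in enumerate(np.asarray(nu_cpmg, dtype=float)):
        if p_b == 0.0 or dw == 0.0:
            out[i] = r2a
            continue
        n_echo = _echo_count(nu, t_relax)
        tau = t_relax / (4.0 * n_echo)  # echo unit: tau - 180 - 2tau - 180 - tau
        prop_tau = expm(liou_base * tau)
        prop_2tau = prop_tau @ prop_tau
        # an ideal 180 conjugates coherences: C P C = conj(P)
        unit = prop_tau @ np.conj(prop_2tau) @ prop_tau
        m = np.linalg.matrix_power(unit, n_echo) @ m0
        intensity = abs(m[0]) / p_a
        out[i] = -np.log(intensity) / t_relax
    return out


def carver_richards_72(params: ExchangeParams, nu_cpmg: Sequence[float],
                       field_mhz: float) -> np.ndarray:
    """Classic Carver-Richards (1972) approximation to R2,eff.

    Describes the asymptotic decay eigenvalue only; it neglects the
    initial-condition amplitude factor, which biases R2,eff at low
    pulsing rates in slow exchange. :func:`simulate_cr` is the exact
    closed form of the same family.
    """
    p_b, k_ex = params.p_b, params.k_ex
    p_a = 1.0 - p_b
    dw = ppm_to_rad(params.dw_ppm, field_mhz)
    r2a = params.r2_0.get(field_mhz, next(iter(params.r2_0.values())) if params.r2_0 else 0.0)
    r2b = r2a
    nu = np.asarray(nu_cpmg, dtype=float)
    if p_b == 0.0 or dw == 0.0 or k_ex == 0.0:
        return np.full_like(nu, r2a)

    tau_cp = 1.0 / (2.0 * nu)  # inter-180-pulse spacing
    dr = r2a - r2b  # zero here, kept for clarity of the general form
    psi = (dr + p_a * k_ex - p_b * k_ex) ** 2 - dw**2 + 4.0 * p_a * p_b * k_ex**2
    zeta = 2.0 * dw * (dr + p_a * k_ex - p_b * k_ex)
    root = np.sqrt(psi**2 + zeta**2)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
    eta_plus = tau_cp / np.sqrt(2.0) * np.sqrt(psi + root)
    eta_minus = tau_cp / np.sqrt(2.0) * np.sqrt(np.maximum(root - psi, 0.0))
    arg = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
    return 0.5 * (r2a + r2b + k_ex - (1.0 / tau_cp) * np.arccosh(np.maximum(arg, 1.0)))


def _expm2x2(m: np.ndarray, t: float) -> np.ndarray:
    """Analytic exponential of a 2x2 complex matrix times ``t`` via its
    eigenvalues (no series/Pade approximation)."""
    tr = m[0, 0] + m[1, 1]
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    disc = np.sqrt(tr * tr - 4.0 * det + 0j)
    lam_p = 0.5 * (tr + disc)
    lam_m = 0.5 * (tr - disc)
    eye = np.eye(2, dtype=complex)
    if abs(lam_p - lam_m) < 1e-12 * max(abs(lam_p), 1.0):
        return np.exp(lam_p * t) * (eye + t * (m - lam_p * eye))
    b_p = (m - lam_m * eye) / (lam_p - lam_m)
    b_m = (m - lam_p * eye) / (lam_m - lam_p)
    return np.exp(lam_p * t) * b_p + np.exp(lam_m * t) * b_m


def simulate_cr(params: ExchangeParams, nu_cpmg: Sequence[float],
                field_mhz: float, t_relax: float = 0.04) -> np.ndarray:
    """Exact closed-form R2,eff for two-site CPMG exchange.

    Carver-Richards-family analytical solution: the echo-unit propagator
    (tau - 180 - 2tau - 180 - tau) is built from the analytic eigenvalue
    decomposition of the 2x2 exchange Liouvillian and raised to the echo
    count through its own eigenvalues, with the initial-condition
    amplitude retained exactly. Reduces to the classic Carver-Richards
    expression in the many-echo limit; unlike it, remains exact in slow
    exchange at low pulsing rates.
    """
    p_b, k_ex = params.p_b, params.k_ex
    p_a = 1.0 - p_b
    k_ab, k_ba = p_b * k_ex, p_a * k_ex
    dw = ppm_to_rad(params.dw_ppm, field_mhz)
    r2a = params.r2_0.get(field_mhz, next(iter(params.r2_0.values())) if params.r2_0 else 0.0)
    nu = np.asarray(nu_cpmg, dtype=float)
    if p_b == 0.0 or dw == 0.0 or k_ex == 0.0:
        return np.full_like(nu, r2a)

    liou = np.array([
        [-r2a - k_ab, k_ba],
        [k_ab, -r2a - k_ba - 1j * dw],
    ], dtype=complex)
    m0 = np.array([p_a, p_b], dtype=complex)

    out = np.empty(nu.size)
    for i, v in enumerate(nu):
        n_echo = _echo_count(float(v), t_relax)
        tau = t_relax / (4.0 * n_echo)
        e1 = _expm2x2(liou, tau)
        e2 = _expm2x2(liou, 2.0 * tau)
        unit = e1 @ np.conj(e2) @ e1
        tr = unit[0, 0] + unit[1, 1]
        det = unit[0, 0] * unit[1, 1] - unit[0, 1] * unit[1, 0]
        disc = np.sqrt(tr * tr - 4.0 * det + 0j)
        mu_p, mu_m = 0.5 * (tr + disc), 0.5 * (tr - disc)
        eye = np.eye(2, dtype=complex)
        if abs(mu_p - mu_m) < 1e-12 * max(abs(mu_p), 1.0):
            amp = m0[0] + n_echo * ((unit - mu_p * eye) @ m0)[0] / mu_p
            signal = mu_p**n_echo * amp
        else:
            a_p = ((unit - mu_m * eye) @ m0)[0] / (mu_p - mu_m)
            a_m = ((unit - mu_p * eye) @ m0)[0] / (mu_m - mu_p)
            signal = mu_p**n_echo * a_p + mu_m**n_echo * a_m
        out[i] = -np.log(abs(signal) / p_a) / t_relax
    return out


def luz_meiboom(params: ExchangeParams, nu_cpmg: Sequence[float],
                field_mhz: float) -> np.ndarray:
    """Fast-exchange limit closed form (independent cross-check)."""
    nu = np.asarray(nu_cpmg, dtype=float)
    dw = ppm_to_rad(params.dw_ppm, field_mhz)
    r2_0 = params.r2_0.get(field_mhz, 0.0)
    p_a, p_b, k_ex = 1.0 - params.p_b, params.p_b, params.k_ex
    phi = p_a * p_b * dw**2
    return r2_0 + (phi / k_ex) * (1.0 - (4.0 * nu / k_ex) * np.tanh(k_ex / (4.0 * nu)))


# ---------------------------------------------------------------- fitting

def fit_group(
    curves: dict[int, list[DispersionCurve]],
    p0: tuple[float, float] | None = None,
    n_starts: int = 8,
    rng: np.random.Generator | int | None = None,
) -> GroupFit:
    """Global two-site fit of grouped dispersion curves.

    Shared (pB, kex) across all residues in the group; per-residue dw
    and per-residue-per-field R2,0. Multi-start over a log-spaced kex
    grid guards against local minima; the Carver-Richards form is the
    fit function (cross-validated against Bloch-McConnell in the suite).
    """
    rng = np.random.default_rng(rng)
    residues = sorted(curves)
    fields: list[tuple[int, float]] = []
    for res in residues:
        for c in curves[res]:
            fields.append((res, c.field_mhz))

    # initial dw per residue from the total dispersion amplitude
    dw0 = {}
    for res in residues:
        c = curves[res][0]
        dr2 = max(float(np.max(c.r2_eff) - np.min(c.r2_eff)), 0.1)
        dw0[res] = min(max(np.sqrt(dr2) * 1.0, 0.5), 6.0)

    def pack(p_b, k_ex, dws, r20s):
        return np.concatenate([[np.log(p_b / (0.5 - p_b)), np.log(k_ex)],
                               [dws[r] for r in residues],
                               [r20s[k] for k in fields]])

    def unpack(x):
        p_b = 0.5 / (1.0 + np.exp(-x[0]))
        k_ex = np.exp(x[1])
        dws = dict(zip(residues, x[2:2 + len(residues)]))
        r20s = dict(zip(fields, x[2 + len(residues):]))
        return p_b, k_ex, dws, r20s

    def resid(x):
        p_b, k_ex, dws, r20s = unpack(x)
        res_list = []
        for res in residues:
            for c in curves[res]:
                pars = ExchangeParams(p_b=min(p_b, 0.4999), k_ex=k_ex,
                                      dw_ppm=abs(dws[res]),
                                      r2_0={c.field_mhz: r20s[(res, c.field_mhz)]})
                model = simulate_cr(pars, c.nu_cpmg, c.field_mhz, c.t_relax)
                res_list.append((model - c.r2_eff) / c.sigma)
        return np.concatenate(res_list)

    r20_init = {(res, f): float(np.min([np.min(c.r2_eff) for c in curves[res]
                                        if c.field_mhz == f]))
                for (res, f) in fields}

    n_data = sum(c.nu_cpmg.size for res in residues for c in curves[res])
    n_par = 2 + len(residues) + len(fields)
    best = None
    kex_grid = ([p0[1]] if p0 is not None
                else np.geomspace(100.0, 10000.0, n_starts).tolist())
    pb_start = p0[0] if p0 is not None else 0.01
    for kex_start in kex_grid:
        dws = {r: dw0[r] * (1.0 + 0.1 * rng.standard_normal()) for r in residues}
        x0 = pack(pb_start, kex_start, dws, r20_init)
        try:
            sol = least_squares(resid, x0, x_scale="jac", max_nfev=400 * n_par)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("group fit failed from every start")

    p_b, k_ex, dws, r20s = unpack(best.x)
    chi2_red = float(2.0 * best.cost / max(n_data - n_par, 1))
    return GroupFit(residues=residues, p_b=float(p_b), k_ex=float(k_ex),
                    dw_ppm={r: abs(float(v)) for r, v in dws.items()},
                    r2_0={k: float(v) for k, v in r20s.items()},
                    chi2_red=chi2_red, converged=bool(best.success))


# ------------------------------------------------------------ dw sign

def peak_positions_hsqc_hmqc(p_b: float, k_ex: float, dw_n_ppm: float,
                             dw_h_ppm: float, field_mhz: float) -> tuple[float, float]:
    """Model-based 15N peak positions (ppm) in HSQC vs HMQC spectra.

    The observed ground-state line position is the imaginary part of the
    slowly decaying eigenvalue of the two-site exchange Liouvillian. The
    HSQC 15N dimension evolves single-quantum 15N coherence; the HMQC
    15N dimension evolves zero- and double-quantum coherence whose
    effective shift differences are dw_N -/+ dw_H, and its apparent peak
    is the mean of the two lines. Exchange shifts the SQ and MQ lines
    differently, which encodes the sign of dw_N.
    """
    from .constants import n15_larmor_rad

    wn = n15_larmor_rad(field_mhz)
    wh = 2.0 * np.pi * field_mhz * 1e6

    def line(dw_rad: float) -> float:
        k_ab, k_ba = p_b * k_ex, (1.0 - p_b) * k_ex
        liou = np.array([[-k_ab, k_ba], [k_ab, -k_ba - 1j * dw_rad]], dtype=complex)
        evals = np.linalg.eigvals(liou)
        slow = evals[np.argmax(evals.real)]  # slowest-decaying line
        return float(-slow.imag)  # rad/s offset of the observed peak

    sq = line(dw_n_ppm * 1e-6 * wn) / wn * 1e6
    zq = line(dw_n_ppm * 1e-6 * wn - dw_h_ppm * 1e-6 * wh) / wn * 1e6
    dq = line(dw_n_ppm * 1e-6 * wn + dw_h_ppm * 1e-6 * wh) / wn * 1e6
    mq = 0.5 * (zq + dq)
    return sq, mq


def dw_sign(delta_hsqc_ppm: float, delta_hmqc_ppm: float,
            threshold_ppm: float = 0.011) -> int:
    """Sign of dw(15N) from the HSQC-HMQC 15N peak position difference.

    Returns +1 when the minor state is downfield of the major state,
    -1 when upfield, 0 when |difference| <= threshold (undetermined).
    The default threshold corresponds to ~1 Hz at a 900 MHz 1H field.

    Convention: in the slow-exchange perturbative regime (|dw_H| well
    below |dw_N|) the multiple-quantum lines are shifted further from
    the major state than the single-quantum line, so a downfield minor
    state (dw_N > 0) makes HSQC - HMQC negative. This rule is validated
    in the test suite against the Liouvillian peak-position model
    rather than asserted from literature.
    """
    diff = delta_hsqc_ppm - delta_hmqc_ppm
    if abs(diff) <= threshold_ppm:
        return 0
    return 1 if diff < 0 else -1


def correlate_dw_secondary(signed_dw: np.ndarray, major_shifts: np.ndarray,
                           random_coil_shifts: np.ndarray) -> dict:
    """Regress signed dw against the secondary shift (random coil - major).

    A slope near 1 indicates the minor state resembles a random coil.
    Residues with residuals beyond 2 sd are flagged as outliers.
    """
    dw = np.asarray(signed_dw, dtype=float)
    sec = np.asarray(random_coil_shifts, dtype=float) - np.asarray(major_shifts, dtype=float)
    if dw.size < 5:
        raise ValueError("need at least 5 signed dw values")
    if np.allclose(dw, dw[0]):
        # degenerate (e.g. all-zero) response: slope 0 by construction
        return {"slope": 0.0, "intercept": float(dw[0]), "r": 0.0,
                "outliers": np.array([], dtype=int)}
    fit = linregress(sec, dw)
    residuals = dw - (fit.slope * sec + fit.intercept)
    sd = np.std(residuals)
    outliers = np.where(np.abs(residuals) > 2.0 * sd)[0] if sd > 0 else np.array([], dtype=int)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue), "outliers": outliers}
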