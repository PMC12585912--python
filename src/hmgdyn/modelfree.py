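"""Backbone 15N relaxation analysis: exponential decay fitting, hetNOE,
rotational diffusion tensor estimation from R2/R1, and Lipari-Szabo
model-free fitting with Mandel-style model selection.

The forward model is the standard dipolar + CSA description of amide 15N
relaxation. With J(w) the model-free spectral density (2/5 prefactor
included) and d, c the dipolar and CSA interaction constants,

    R1  = d^2/4 [J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c^2 J(wN)
    R2  = d^2/8 [4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
          + c^2/6 [4 J(0) + 3 J(wN)] + Rex
    NOE = 1 + d^2/4 (gH/gN) [6 J(wH+wN) - J(wH-wN)] / R1

Five per-residue models are supported: 1 (S2), 2 (S2, te), 3 (S2, Rex),
4 (S2, te, Rex), 5 (S2f, S2, te). Model selection follows the staged
goodness-of-fit / F-test procedure with a parametric-bootstrap null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .constants import GAMMA_H, GAMMA_N, PhysicalConstants
from .io import StructureModel

__all__ = [
    "RelaxationRates",
    "DiffusionTensor",
    "ModelFreeParams",
    "fit_decay",
    "compute_noe",
    "spectral_density",
    "spectral_density_axial",
    "predict_rates",
    "estimate_diffusion_tensor",
    "anisotropy_diagnostic",
    "modelfree_fit",
]

#: Relative error floor applied to R1, R2 and NOE uncertainties.
NOISE_FLOOR = 0.03


@dataclass
class RelaxationRates:
    """Per-residue R1, R2 (s^-1) and hetNOE with uncertainties.

    Uncertainties are floored at 3% of the measured value on access.
    """

    residues: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    noe: np.ndarray
    r1_err: np.ndarray | None = None
    r2_err: np.ndarray | None = None
    noe_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("r1", "r2"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("r1", "r2", "noe"):
            err = getattr(self, f"{name}_err")
            floor = NOISE_FLOOR * np.abs(getattr(self, name))
            if err is None:
                setattr(self, f"{name}_err", floor)
            else:
                setattr(self, f"{name}_err", np.maximum(np.asarray(err, float), floor))


@dataclass
class DiffusionTensor:
    """Global rotational diffusion tensor.

    model is 'isotropic', 'axial' or 'anisotropic'; tau_m is the global
    correlation time 1/(6 Diso) in seconds; ratio is Dpar/Dperp; the
    unique axis is given by polar angles (theta, phi) in radians in the
    structure frame.
    """

    model: str
    tau_m: float
    ratio: float = 1.0
    theta: float = 0.0
    phi: float = 0.0
    stats: dict = field(default_factory=dict)

    @property
    def d_iso(self) -> float:
        return 1.0 / (6.0 * self.tau_m)

    @property
    def d_par(self) -> float:
        return 3.0 * self.d_iso * self.ratio / (2.0 + self.ratio)

    @property
    def d_perp(self) -> float:
        return 3.0 * self.d_iso / (2.0 + self.ratio)

    @property
    def axis(self) -> np.ndarray:
        st = np.sin(self.theta)
        return np.array([st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)])


@dataclass
class ModelFreeParams:
    """Model-free parameters for one residue."""

    residue: int
    model: int
    s2: float
    te: float = 0.0        # seconds
    rex: float = 0.0       # s^-1 at the analysis field
    s2f: float = 1.0
    errors: dict = field(default_factory=dict)
    chi2: float = float("nan")
    flagged: bool = False


# ----------------------------------------------------------------- decays

def fit_decay(delays: Sequence[float], intensities: Sequence[float],
              sigma: Sequence[float] | None = None) -> tuple[float, float, float, float]:
    """Weighted mono-exponential fit I(t) = I0 exp(-R t).

    Returns (rate, i0, rate_err, i0_err). Duplicate delays are simply
    additional observations. Requires >= 3 points (2 allowed only when
    noiseless closed-form inversion is possible, i.e. exactly 2 distinct
    delays determine the line in log space).
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.any(y <= 0):
        raise ValueError("intensities must be positive for a decay fit")
    if t.size < 2:
        raise ValueError("need at least two delay points")
    w = 1.0 / np.asarray(sigma, float) if sigma is not None else np.ones_like(y)

    # log-linear start, then nonlinear refinement on the raw intensities
    slope, icpt = np.polyfit(t, np.log(y), 1)
    p0 = [max(-slope, 0.0), np.exp(icpt)]
    if t.size == 2:
        return -slope, float(np.exp(icpt)), 0.0, 0.0

    def resid(p):
        return w * (p[1] * np.exp(-p[0] * t) - y)

    sol = least_squares(resid, p0, bounds=([0.0, 0.0], [np.inf, np.inf]))
    dof = max(t.size - 2, 1)
    rss = float(np.sum(sol.fun**2))
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * rss / dof
        perr = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        perr = np.array([np.nan, np.nan])
    return float(sol.x[0]), float(sol.x[1]), float(perr[0]), float(perr[1])


def compute_noe(i_sat: float, i0: float,
                sigma_sat: float = 0.0, sigma_0: float = 0.0) -> tuple[float, float]:
    """Steady-state heteronuclear NOE ratio Isat/I0 with propagated error."""
    if i0 <= 0:
        raise ValueError("reference intensity must be positive")
    noe = i_sat / i0
    err = abs(noe) * np.hypot(
        sigma_sat / i_sat if i_sat != 0 else 0.0, sigma_0 / i0
    )
    return float(noe), float(err)


# -------------------------------------------------------- spectral density

def spectral_density(omega, s2: float, tau_c: float, te: float = 0.0):
    """Lipari-Szabo spectral density (isotropic tumbling), s/rad.

    J(w) = 2/5 [S2 tau/(1+(w tau)^2) + (1-S2) tau'/(1+(w tau')^2)],
    1/tau' = 1/tau + 1/te. te = 0 collapses the internal term.
    """
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("S2 must lie in [0, 1]")
    w = np.asarray(omega, dtype=float)
    j = s2 * tau_c / (1.0 + (w * tau_c) ** 2)
    if te > 0.0 and s2 < 1.0:
        tp = tau_c * te / (tau_c + te)
        j = j + (1.0 - s2) * tp / (1.0 + (w * tp) ** 2)
    j = 0.4 * j
    return j if j.shape else float(j)


def _axial_weights(cos_alpha: float) -> np.ndarray:
    c2 = cos_alpha**2
    s2_ = 1.0 - c2
    return np.array([(3.0 * c2 - 1.0) ** 2 / 4.0, 3.0 * s2_ * c2, 0.75 * s2_**2])


def spectral_density_axial(omega, s2: float, tensor: DiffusionTensor,
                           cos_alpha: float, te: float = 0.0):
    """Model-free spectral density for axially symmetric diffusion.

    Three-Lorentzian sum over modes with rates (6Dperp, 5Dperp+Dpar,
    2Dperp+4Dpar) weighted by the angle alpha between the NH vector and
    the unique axis.
    """
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    taus = 1.0 / np.array([
        6.0 * tensor.d_perp,
        5.0 * tensor.d_perp + tensor.d_par,
        2.0 * tensor.d_perp + 4.0 * tensor.d_par,
    ])
    weights = _axial_weights(cos_alpha)
    j = np.zeros_like(w)
    for a_k, tau_k in zip(weights, taus):
        j += a_k * s2 * tau_k / (1.0 + (w * tau_k) ** 2)
        if te > 0.0 and s2 < 1.0:
            tp = tau_k * te / (tau_k + te)
            j += a_k * (1.0 - s2) * tp / (1.0 + (w * tp) ** 2)
    j = 0.4 * j
    return j if np.asarray(omega).shape else float(j[0])


# ------------------------------------------------------------ rate model

def predict_rates(s2: float, tensor: DiffusionTensor, constants: PhysicalConstants,
                  te: float = 0.0, rex: float = 0.0, s2f: float = 1.0,
                  nh_vector: np.ndarray | None = None) -> tuple[float, float, float]:
    """Forward-calculate (R1, R2, NOE) for one residue.

    For an axial tensor the NH vector (structure frame) is required to
    set the mode weights. The extended model (s2f < 1) rescales the slow
    order parameter: J uses S2 = s2f*s2s with the fast motion assumed
    too fast to contribute its own Lorentzian.
    """
    wh, wn = constants.omega_h, constants.omega_n
    freqs = np.array([0.0, abs(wn), abs(wh - wn), abs(wh), abs(wh + wn)])
    s2_total = s2 * s2f

    if tensor.model == "axial":
        if nh_vector is None:
            raise ValueError("axial diffusion tensor requires an NH vector")
        v = np.asarray(nh_vector, float)
        cos_a = float(np.dot(v / np.linalg.norm(v), tensor.axis))
        jw = np.array([spectral_density_axial(f, s2_total, tensor, cos_a, te) for f in freqs])
    else:
        jw = np.array([spectral_density(f, s2_total, tensor.tau_m, te) for f in freqs])

    j0, jn, jhmn, jh, jhpn = jw
    d2 = constants.d_dipolar**2
    c2 = constants.c_csa**2
    r1 = d2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (d2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
          + c2 / 6.0 * (4.0 * j0 + 3.0 * jn) + rex)
    sigma = d2 / 4.0 * (6.0 * jhpn - jhmn)
    noe = 1.0 + (GAMMA_H / GAMMA_N) * sigma / r1
    return float(r1), float(r2), float(noe)


# ------------------------------------------------- diffusion tensor (R2/R1)

def _local_tau_m(r2_over_r1: float, constants: PhysicalConstants) -> float:
    """Invert the rigid (S2=1, te=0, Rex=0) R2/R1 ratio for a local tau_m."""
    from scipy.optimize import brentq

    def f(tau):
        tensor = DiffusionTensor("isotropic", tau)
        r1, r2, _ = predict_rates(1.0, tensor, constants)
        return r2 / r1 - r2_over_r1

    return brentq(f, 0.5e-9, 60e-9)


def _mean_nh_vectors(models: list[StructureModel], residues: np.ndarray) -> dict[int, np.ndarray]:
    """Normalized mean N->H unit vector over the ensemble, per residue."""
    from .rdc import extract_nh_vectors

    acc: dict[int, np.ndarray] = {}
    count: dict[int, int] = {}
    for m in models:
        vecs = extract_nh_vectors(m, build_h=True)
        for r, v in vecs.items():
            acc[r] = acc.get(r, np.zeros(3)) + v
            count[r] = count.get(r, 0) + 1
    out = {}
    for r in residues:
        r = int(r)
        if r in acc:
            v = acc[r] / count[r]
            out[r] = v / np.linalg.norm(v)
    return out


def estimate_diffusion_tensor(
    rates: RelaxationRates,
    structure: StructureModel | list[StructureModel],
    noe_cutoff: float = 0.5,
    constants: PhysicalConstants | None = None,
    alpha: float = 0.05,
) -> DiffusionTensor:
    """Estimate the rotational diffusion tensor from R2/R1 ratios.

    Each retained residue (hetNOE > cutoff, to exclude flexible sites)
    yields a local correlation time from its rigid-limit R2/R1 ratio,
    hence a local diffusion coefficient D_loc = 1/(6 tau_loc). In the
    quadratic approximation D_loc = 0.5 * n^T (Tr(D) I - D) n for NH
    unit vector n, which is fit for isotropic, axially symmetric and
    fully anisotropic D; nested models are compared by F-test at
    ``alpha`` and the simplest adequate model is returned.
    """
    constants = constants or PhysicalConstants()
    models = structure if isinstance(structure, list) else [structure]

    keep = rates.noe > noe_cutoff
    residues = rates.residues[keep]
    nh = _mean_nh_vectors(models, residues)
    mask = np.array([int(r) in nh for r in residues])
    residues = residues[mask]
    if residues.size < 6:
        raise ValueError("fewer than 6 residues available for tensor estimation")

    ratios = (rates.r2[keep][mask]) / (rates.r1[keep][mask])
    # simple propagation of the ratio error into D_loc via finite difference
    d_loc = np.empty(residues.size)
    for i, ratio in enumerate(ratios):
        d_loc[i] = 1.0 / (6.0 * _local_tau_m(float(ratio), constants))
    vecs = np.array([nh[int(r)] for r in residues])

    # quadric design: D_loc = 0.5 n^T (Tr(D) I - D) n = n^T Q n, Q symmetric
    n = vecs
    design = np.column_stack([
        n[:, 0] ** 2, n[:, 1] ** 2, n[:, 2] ** 2,
        2 * n[:, 0] * n[:, 1], 2 * n[:, 0] * n[:, 2], 2 * n[:, 1] * n[:, 2],
    ])

    def fit_quadric(basis: np.ndarray) -> tuple[np.ndarray, float]:
        coef, *_ = np.linalg.lstsq(basis, d_loc, rcond=None)
        rss = float(np.sum((basis @ coef - d_loc) ** 2))
        return coef, rss

    # isotropic: Q = Diso * I  -> single coefficient on (nx^2+ny^2+nz^2)=1
    d_iso = float(np.mean(d_loc))
    rss_iso = float(np.sum((d_loc - d_iso) ** 2))

    # full quadric (6 parameters) == fully anisotropic
    coef6, rss_aniso = fit_quadric(design)
    q_full = np.array([
        [coef6[0], coef6[3], coef6[4]],
        [coef6[3], coef6[1], coef6[5]],
        [coef6[4], coef6[5], coef6[2]],
    ])

    # axial: constrain Q to two distinct eigenvalues; take the full-quadric
    # eigenframe, average the closest eigenvalue pair
    evals, evecs = np.linalg.eigh(q_full)
    gaps = np.abs(np.diff(evals))
    if gaps[0] <= gaps[1]:
        pair, unique = (0, 1), 2
    else:
        pair, unique = (1, 2), 0
    q_perp_eig = float(np.mean(evals[list(pair)]))
    q_par_eig = float(evals[unique])
    axis = evecs[:, unique]
    proj = (n @ axis) ** 2
    basis_ax = np.column_stack([proj, 1.0 - proj])
    coef_ax, rss_axial = fit_quadric(basis_ax)
    q_par, q_perp = float(coef_ax[0]), float(coef_ax[1])

    n_pts = residues.size
    stats: dict[str, float] = {"rss_isotropic": rss_iso, "rss_axial": rss_axial,
                               "rss_anisotropic": rss_aniso, "n_residues": n_pts}

    def f_test(rss_small, p_small, rss_big, p_big):
        if rss_big <= 0 or n_pts <= p_big:
            return 1.0
        fstat = ((rss_small - rss_big) / (p_big - p_small)) / (rss_big / (n_pts - p_big))
        return float(f_dist.sf(max(fstat, 0.0), p_big - p_small, n_pts - p_big))

    p_iso_ax = f_test(rss_iso, 1, rss_axial, 4)
    p_ax_aniso = f_test(rss_axial, 4, rss_aniso, 6)
    stats["p_iso_vs_axial"] = p_iso_ax
    stats["p_axial_vs_anisotropic"] = p_ax_aniso

    if p_iso_ax >= alpha:
        return DiffusionTensor("isotropic", tau_m=1.0 / (6.0 * d_iso), stats=stats)

    # recover D from Q eigenvalues (Q = (Tr(D) I - D)/2): along the unique
    # axis q_par = D_perp; perpendicular q_perp = (D_par + D_perp)/2
    d_perp = q_par
    d_par = 2.0 * q_perp - d_perp
    if d_perp <= 0 or d_par <= 0:
        return DiffusionTensor("isotropic", tau_m=1.0 / (6.0 * d_iso), stats=stats)
    d_iso_ax = (d_par + 2.0 * d_perp) / 3.0
    theta = float(np.arccos(np.clip(abs(axis[2]), -1, 1)))
    phi = float(np.arctan2(axis[1], axis[0] if abs(axis[0]) > 1e-12 else 1e-12))
    if p_ax_aniso >= alpha:
        return DiffusionTensor("axial", tau_m=1.0 / (6.0 * d_iso_ax),
                               ratio=d_par / d_perp, theta=theta, phi=phi, stats=stats)
    # fully anisotropic selected: principal values from D = Tr(Q) I - 2 Q;
    # per-residue spectral densities keep the axial form (see methods note)
    d_evals = np.sum(evals) - 2.0 * evals
    return DiffusionTensor("anisotropic", tau_m=1.0 / (2.0 * np.sum(evals)),
                           ratio=float(np.max(d_evals) / np.min(d_evals)),
                           theta=theta, phi=phi, stats=stats)


def anisotropy_diagnostic(rates: RelaxationRates) -> dict[str, np.ndarray]:
    """Per-residue R1*R2 products and R2/R1 ratios with propagated errors.

    Exchange-broadened residues elevate both; flexible residues depress
    both, so the joint profile separates Rex from flexibility.
    """
    prod = rates.r1 * rates.r2
    ratio = rates.r2 / rates.r1
    rel = np.sqrt((rates.r1_err / rates.r1) ** 2 + (rates.r2_err / rates.r2) ** 2)
    return {
        "residue": rates.residues,
        "r1r2": prod,
        "r1r2_err": prod * rel,
        "r2_over_r1": ratio,
        "r2_over_r1_err": ratio * rel,
    }


# --------------------------------------------------------- model-free fit

_MODEL_PARAMS = {
    1: ("s2",),
    2: ("s2", "te"),
    3: ("s2", "rex"),
    4: ("s2", "te", "rex"),
    5: ("s2f", "s2", "te"),
}

_BOUNDS = {"s2": (0.0, 1.0), "te": (0.0, 10e-9), "rex": (0.0, 50.0), "s2f": (0.0, 1.0)}
_START = {"s2": 0.85, "te": 50e-12, "rex": 2.0, "s2f": 0.95}


def _fit_single_model(model: int, obs: np.ndarray, sig: np.ndarray,
                      tensor: DiffusionTensor, constants: PhysicalConstants,
                      nh_vector: np.ndarray | None) -> tuple[dict, float, np.ndarray]:
    names = _MODEL_PARAMS[model]

    def expand(p):
        kw = dict(zip(names, p))
        s2 = kw.pop("s2")
        return s2, kw

    def resid(p):
        s2, kw = expand(p)
        r1, r2, noe = predict_rates(s2, tensor, constants, nh_vector=nh_vector, **kw)
        return (np.array([r1, r2, noe]) - obs) / sig

    p0 = [_START[n] for n in names]
    lo = [_BOUNDS[n][0] for n in names]
    hi = [_BOUNDS[n][1] for n in names]
    sol = least_squares(resid, p0, bounds=(lo, hi), x_scale="jac")
    chi2 = float(np.sum(sol.fun**2))
    s2, kw = expand(sol.x)
    params = {"s2": s2, **kw}
    return params, chi2, sol.x


def modelfree_fit(
    rates: RelaxationRates,
    tensor: DiffusionTensor,
    constants: PhysicalConstants | None = None,
    structure: StructureModel | list[StructureModel] | None = None,
    alpha_gof: float = 0.05,
    alpha_f: float = 0.20,
    n_bootstrap: int = 500,
    rng: np.random.Generator | int | None = None,
) -> list[ModelFreeParams]:
    """Per-residue Lipari-Szabo fits with staged model selection.

    For each residue, models 1-5 are fit to (R1, R2, NOE) by weighted
    least squares with the diffusion tensor held fixed. Selection:
    model 1 or 2/3 is accepted if its chi^2 passes a goodness-of-fit
    test against a parametric-bootstrap null at ``alpha_gof``; nested
    extensions (1->2, 1->3, 2->4, 3->4) must improve chi^2 by an F-test
    at ``alpha_f``. If no model passes, the lowest-AIC model is
    reported with ``flagged=True``.
    """
    constants = constants or PhysicalConstants()
    rng = np.random.default_rng(rng)
    nh = None
    if tensor.model == "axial":
        if structure is None:
            raise ValueError("axial tensor requires a structure for NH vectors")
        models = structure if isinstance(structure, list) else [structure]
        nh = _mean_nh_vectors(models, rates.residues)

    results: list[ModelFreeParams] = []
    for i, res in enumerate(rates.residues):
        obs = np.array([rates.r1[i], rates.r2[i], rates.noe[i]])
        sig = np.array([rates.r1_err[i], rates.r2_err[i], rates.noe_err[i]])
        vec = nh.get(int(res)) if nh is not None else None

        fits = {}
        for m in (1, 2, 3, 4, 5):
            try:
                fits[m] = _fit_single_model(m, obs, sig, tensor, constants, vec)
            except Exception:
                continue

        chosen, flagged = _select_model(fits, obs, sig, tensor, constants, vec,
                                        alpha_gof, alpha_f, n_bootstrap, rng)
        params, chi2, _ = fits[chosen]
        results.append(ModelFreeParams(
            residue=int(res), model=chosen,
            s2=params["s2"], te=params.get("te", 0.0), rex=params.get("rex", 0.0),
            s2f=params.get("s2f", 1.0), chi2=chi2, flagged=flagged,
        ))
    return results


def _bootstrap_critical_chi2(model: int, params: dict, sig: np.ndarray,
                             tensor: DiffusionTensor, constants: PhysicalConstants,
                             nh_vector: np.ndarray | None, alpha: float,
                             n_rep: int, rng: np.random.Generator) -> float:
    """Critical chi^2 for the goodness-of-fit test: refit synthetic data
    generated from the fitted model (parametric bootstrap null)."""
    kw = {k: v for k, v in params.items() if k != "s2"}
    r1, r2, noe = predict_rates(params["s2"], tensor, constants,
                                nh_vector=nh_vector, **kw)
    mu = np.array([r1, r2, noe])
    chi2s = np.empty(n_rep)
    for k in range(n_rep):
        synth = mu + rng.normal(0.0, sig)
        synth[0] = max(synth[0], 1e-3)
        synth[1] = max(synth[1], 1e-3)
        _, chi2s[k], _ = _fit_single_model(model, synth, sig, tensor, constants, nh_vector)
    return float(np.quantile(chi2s, 1.0 - alpha))


def _select_model(fits, obs, sig, tensor, constants, nh_vector,
                  alpha_gof, alpha_f, n_rep, rng) -> tuple[int, bool]:
    n_obs = 3

    def chi2(m):
        return fits[m][1]

    def n_par(m):
        return len(_MODEL_PARAMS[m])

    def passes_gof(m):
        crit = _bootstrap_critical_chi2(m, fits[m][0], sig, tensor, constants,
                                        nh_vector, alpha_gof, n_rep, rng)
        return chi2(m) <= crit

    def f_improves(small, big):
        dof_big = n_obs - n_par(big)
        if dof_big <= 0:
            # no residual dof: require a large drop in chi^2 instead
            return chi2(big) < 0.5 * chi2(small)
        num = (chi2(small) - chi2(big)) / (n_par(big) - n_par(small))
        den = chi2(big) / dof_big
        if den <= 0:
            return True
        p = float(f_dist.sf(num / den, n_par(big) - n_par(small), dof_big))
        return p < alpha_f

    # Stage 1: accept the simplest model whose chi^2 is consistent with noise
    if 1 in fits and passes_gof(1):
        return 1, False
    for m in (2, 3):
        if m in fits and passes_gof(m):
            # the nested extension must also be statistically warranted
            if 1 in fits and not f_improves(1, m):
                continue
            return m, False
    for m in (4, 5):
        if m in fits and chi2(m) < 1e-6:
            return m, False
    # nothing passes: report lowest AIC with a warning flag
    aic = {m: chi2(m) + 2 * n_par(m) for m in fits}
    best = min(aic, key=aic.get)
    return best, True
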