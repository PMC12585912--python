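"""Four-state conformational-selection vs induced-fit flux model.

The binding square couples folding and DNA binding:

        U  <--kf/ku-->  F
        |               |
   kon_U*D/koff_U  kon_F*D/koff_F
        |               |
        UD <--kf'/ku'-> FD

with U/F the unfolded/folded free protein and UD/FD their DNA-bound
counterparts, D the free DNA concentration (pseudo-first-order).
Thermodynamic cycle closure (kf/ku)(kon_F/koff_F) =
(kon_U/koff_U)(kf'/ku') is enforced, so the stationary state of the
closed system is a true equilibrium with vanishing net edge fluxes.

The conformational-selection (CS) vs induced-fit (IF) decomposition
therefore quantifies the relaxation fluxes: starting from the unbound
state (U and F at their folding equilibrium, no complex), the net flux
into FD through the F->FD edge (CS pathway: fold first, then bind) is
compared with the flux through the UD->FD edge (IF pathway: bind first,
then fold), each integrated over the whole approach to equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import R_GAS
from .thermal import TwoStateThermo, fraction_unfolded

__all__ = [
    "FourStateScheme",
    "FluxResult",
    "rates_from_exchange",
    "equilibrium_from_thermo",
    "steady_state_flux",
    "flux_scan",
    "default_scheme",
]

STATES = ("U", "F", "UD", "FD")
CYCLE_TOL = 1e-6


@dataclass
class FourStateScheme:
    """Rate constants of the binding square (first-order rates s^-1,
    bimolecular kon in M^-1 s^-1, D in M)."""

    kf: float        # U -> F
    ku: float        # F -> U
    kon_f: float     # F + D -> FD
    koff_f: float    # FD -> F
    kon_u: float     # U + D -> UD
    koff_u: float    # UD -> U
    kf_prime: float  # UD -> FD
    ku_prime: float  # FD -> UD
    d_conc: float    # free DNA, M

    def __post_init__(self) -> None:
        rates = [self.kf, self.ku, self.kon_f, self.koff_f,
                 self.kon_u, self.koff_u, self.kf_prime, self.ku_prime]
        if any(r < 0 for r in rates):
            raise ValueError("all rate constants must be non-negative")
        self._check_cycle()

    def _check_cycle(self) -> None:
        rates = [self.kf, self.ku, self.kon_f, self.koff_f,
                 self.kon_u, self.koff_u, self.kf_prime, self.ku_prime]
        if min(rates) == 0.0:
            return  # an open edge (zero rate) breaks the cycle legitimately
        lhs = (self.kf / self.ku) * (self.kon_f / self.koff_f)
        rhs = (self.kon_u / self.koff_u) * (self.kf_prime / self.ku_prime)
        if abs(lhs - rhs) > CYCLE_TOL * max(abs(lhs), abs(rhs)):
            raise ValueError(
                f"thermodynamic cycle not closed: (kf/ku)(konF/koffF)={lhs:.6g} "
                f"vs (konU/koffU)(kf'/ku')={rhs:.6g}")

    def rate_matrix(self) -> np.ndarray:
        """Column-stochastic generator K with dp/dt = K p, state order
        (U, F, UD, FD)."""
        d = self.d_conc
        k = np.zeros((4, 4))
        pairs = [
            (0, 1, self.kf, self.ku),                    # U <-> F
            (1, 3, self.kon_f * d, self.koff_f),         # F <-> FD
            (0, 2, self.kon_u * d, self.koff_u),         # U <-> UD
            (2, 3, self.kf_prime, self.ku_prime),        # UD <-> FD
        ]
        for i, j, fwd, back in pairs:
            k[j, i] += fwd
            k[i, i] -= fwd
            k[i, j] += back
            k[j, j] -= back
        return k

    def equilibrium(self) -> np.ndarray:
        """Stationary populations of the closed system."""
        k = self.rate_matrix()
        if np.allclose(k, 0.0):
            raise ValueError("all rates are zero")
        _, _, vt = np.linalg.svd(k)
        p = np.abs(vt[-1])
        return p / p.sum()


def _safe_ratio(a: float, b: float) -> float | None:
    if a == 0.0 and b == 0.0:
        return None
    if b == 0.0:
        return None
    return a / b


@dataclass
class FluxResult:
    """Integrated relaxation fluxes through the two binding pathways."""

    cs_flux: float        # net flux into FD via F->FD (population units)
    if_flux: float        # net flux into FD via UD->FD
    cs_fraction: float
    populations: np.ndarray = field(default_factory=lambda: np.zeros(4))
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(4))


def rates_from_exchange(p_b: float, k_ex: float) -> tuple[float, float]:
    """(ku, kf) from CPMG exchange parameters, identifying the minor
    state with the unfolded species: ku = pB*kex, kf = (1-pB)*kex."""
    if not 0.0 < p_b < 1.0:
        raise ValueError("pB must lie in (0, 1)")
    return p_b * k_ex, (1.0 - p_b) * k_ex


def equilibrium_from_thermo(thermo: TwoStateThermo, temperature: float,
                            ku: float, kf: float,
                            tolerance_factor: float = 2.0) -> dict:
    """Cross-check the thermal unfolded fraction against kinetic rates.

    Compares fraction_unfolded(T) with pU = ku/(ku+kf); a mismatch
    beyond ``tolerance_factor`` produces a diagnostic flag, never an
    exception (the two experiments probe different conditions).
    """
    p_u_thermo = fraction_unfolded(temperature, thermo)
    p_u_kinetic = ku / (ku + kf)
    ratio = p_u_thermo / p_u_kinetic if p_u_kinetic > 0 else np.inf
    consistent = (1.0 / tolerance_factor) <= ratio <= tolerance_factor
    return {
        "p_unfolded_thermo": float(p_u_thermo),
        "p_unfolded_kinetic": float(p_u_kinetic),
        "ratio": float(ratio),
        "consistent": bool(consistent),
    }


def _unbound_initial(scheme: FourStateScheme) -> np.ndarray:
    """Free protein at its folding equilibrium, no complex formed."""
    if scheme.kf + scheme.ku > 0:
        p_f = scheme.kf / (scheme.kf + scheme.ku)
    else:
        p_f = 0.5
    return np.array([1.0 - p_f, p_f, 0.0, 0.0])


def steady_state_flux(scheme: FourStateScheme,
                      p0: np.ndarray | None = None) -> FluxResult:
    """Pathway fluxes of the relaxation from the unbound state to the
    bound equilibrium, in closed form.

    With dp/dt = K p and stationary state p_inf, the time-integrated
    deviation X = int_0^inf (p(t) - p_inf) dt solves K X = p_inf - p0
    on the complement of the null space (group-inverse solve). The net
    instantaneous flux through any edge vanishes at equilibrium, so its
    time integral is a finite linear functional of X:

        CS flux = kon_F*D*X_F - koff_F*X_FD   (entry via F->FD)
        IF flux = kf'*X_UD    - ku'*X_FD      (entry via UD->FD)

    and CS fraction = CS/(CS+IF). The eigenvalue spectrum of K is
    returned for relaxation-time analysis.
    """
    k = scheme.rate_matrix()
    if np.allclose(k, 0.0):
        raise ValueError("all rates are zero")
    p_inf = scheme.equilibrium()
    if p0 is None:
        p0 = _unbound_initial(scheme)
    rhs = p_inf - p0
    # group-inverse solve: minimum-norm least-squares solution is exact on
    # range(K) and orthogonal to the left null space since sum(rhs) = 0
    x, *_ = np.linalg.lstsq(k, rhs, rcond=None)

    d = scheme.d_conc
    # an entry edge with zero forward rate constant carries no entry flux
    # (the backward leak of a driven cycle is not pathway flux)
    if scheme.kon_f * d == 0.0:
        cs = 0.0
    else:
        cs = scheme.kon_f * d * x[1] - scheme.koff_f * x[3]
    if scheme.kf_prime == 0.0 or scheme.kon_u * d == 0.0:
        if_ = 0.0
    else:
        if_ = scheme.kf_prime * x[2] - scheme.ku_prime * x[3]
    cs = max(float(cs), 0.0)
    if_ = max(float(if_), 0.0)
    total = cs + if_
    fraction = cs / total if total > 0 else float("nan")
    return FluxResult(cs_flux=cs, if_flux=if_, cs_fraction=fraction,
                      populations=p_inf, eigenvalues=np.linalg.eigvals(k))


def default_scheme(
    temperature: float = 310.0,
    d_conc: float = 1e-6,
    thermo: TwoStateThermo | None = None,
    k_ex: float = 3500.0,
    kon: float = 1e8,
    kd_folded: float = 1e-8,
    bound_thermo: TwoStateThermo | None = None,
) -> FourStateScheme:
    """Preset scheme built from the measured quantities.

    Folding rates come from the CPMG exchange rate with populations
    re-derived from the thermal two-state parameters at ``temperature``;
    both conformers bind with the same diffusion-limited kon; the folded
    state binds with affinity ``kd_folded``; the bound-state folding
    equilibrium comes from the DNA-bound melt parameters (the Tm shift);
    UD->FD folding proceeds at kf (folding not slowed by nonspecific
    binding) and koff_U follows from cycle closure.
    """
    thermo = thermo or TwoStateThermo(tm=311.8, dhm=176e3)
    bound_thermo = bound_thermo or TwoStateThermo(tm=340.6, dhm=472e3)
    p_u = fraction_unfolded(temperature, thermo)
    ku, kf = p_u * k_ex, (1.0 - p_u) * k_ex
    koff_f = kon * kd_folded
    kf_prime = kf
    # bound-state folding equilibrium constant from the bound melt curve
    k_fold_bound = (1.0 - fraction_unfolded(temperature, bound_thermo)) / \
        max(fraction_unfolded(temperature, bound_thermo), 1e-12)
    ku_prime = kf_prime / k_fold_bound
    # closure: (kf/ku)(kon_F/koff_F) = (kon_U/koff_U)(kf'/ku')
    koff_u = kon / ((kf / ku) * (kon / koff_f) * (ku_prime / kf_prime))
    return FourStateScheme(kf=kf, ku=ku, kon_f=kon, koff_f=koff_f,
                           kon_u=kon, koff_u=koff_u,
                           kf_prime=kf_prime, ku_prime=ku_prime, d_conc=d_conc)


def flux_scan(
    d_range: np.ndarray,
    t_range: np.ndarray,
    thermo: TwoStateThermo | None = None,
    **preset_kwargs,
) -> list[dict]:
    """CS fraction over a grid of DNA concentration and temperature.

    Folding rates are re-derived from fraction_unfolded(T) at each
    temperature; all other preset choices are forwarded.
    """
    thermo = thermo or TwoStateThermo(tm=311.8, dhm=176e3)
    rows = []
    for t in np.atleast_1d(t_range):
        for d in np.atleast_1d(d_range):
            scheme = default_scheme(temperature=float(t), d_conc=float(d),
                                    thermo=thermo, **preset_kwargs)
            result = steady_state_flux(scheme)
            rows.append({"temperature": float(t), "d_conc": float(d),
                         "cs_fraction": result.cs_fraction,
                         "cs_flux": result.cs_flux, "if_flux": result.if_flux})
    return rows
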