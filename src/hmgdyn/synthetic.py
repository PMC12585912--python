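"""Synthetic data generators for every pipeline input.

Each generator is a deterministic function of its parameters and a seed,
producing data with the statistical structure the downstream analyses
assume: two-state melt curves with linear/quadratic baselines on the
288-368 K ramp, mono-exponential 15N relaxation decays on the measured
delay lists with a 3% noise floor, two-site-exchange dispersion profiles
on the 900/1200 MHz nu_CPMG grids with the 0.3 s^-1 / 2% error floor,
RDCs from a known alignment tensor on an ideal three-helix toy
structure, and titration peak trajectories under fast or slow exchange
at the measured molar-ratio series.

Default parameter presets are the study's fitted values (free and bound
melt parameters, the two exchange groups, the 9.25/14.2 ns tumbling
times) so that tests exercise the experimentally relevant regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cpmg as cpmg_mod
from . import modelfree as mf
from . import rdc as rdc_mod
from .constants import PhysicalConstants
from .io import StructureModel
from .thermal import BaselineParams, TwoStateThermo, predict_signal

__all__ = [
    "GeneratorConfig",
    "MeltCurve",
    "RelaxationDataset",
    "PRESETS",
    "TEMPERATURE_GRID",
    "R1_DELAYS",
    "R2_DELAYS",
    "NU_CPMG_900",
    "NU_CPMG_1200",
    "T_RELAX",
    "TITRATION_RATIOS",
    "gen_melt_curve",
    "gen_relaxation_data",
    "gen_dispersion_data",
    "gen_toy_structure",
    "gen_rdc_data",
    "gen_titration_series",
]

# ----------------------------------------------------- acquisition grids

#: NanoDSF ramp: 1 K/min from 288 to 368 K.
TEMPERATURE_GRID = np.arange(288.0, 368.0 + 0.5, 1.0)

#: R1 relaxation delays, s (300 ms measured in duplicate).
R1_DELAYS = np.array([0.010, 0.100, 0.200, 0.300, 0.300, 0.500, 1.000, 1.500])

#: R2 (CPMG train at 505 Hz) relaxation delays, s (110.74 ms duplicated).
R2_DELAYS = np.array([0.01582, 0.03164, 0.04746, 0.06328, 0.0791, 0.09492,
                      0.11074, 0.11074, 0.12656, 0.14238, 0.1582, 0.17402,
                      0.18984])

#: nu_CPMG grids, Hz, duplicate points repeated as acquired.
NU_CPMG_900 = np.array([25, 50, 75, 100, 100, 125, 150, 200, 250, 300, 400,
                        500, 500, 600, 700, 800, 800, 1000, 1250, 1500, 2000.0])
NU_CPMG_1200 = np.array([33.3, 66.7, 66.7, 100, 133.3, 166.7, 200, 233.3,
                         266.7, 333.3, 400, 400, 466.7, 566.7, 666.7, 800,
                         800, 900, 1000, 1500, 2000.0])

#: Constant-time relaxation delay per 1H field, s.
T_RELAX = {900.0: 0.040, 1200.0: 0.030}

#: Titration molar-equivalent series (free state included as 0).
TITRATION_RATIOS = np.array([0.0, 0.1, 0.3, 0.5, 0.7, 1.0, 1.2])

#: Fitted-parameter presets for the experimentally characterized states.
PRESETS = {
    "free": {"thermo": TwoStateThermo(tm=311.8, dhm=176e3), "tau_m": 9.25e-9},
    "bound": {"thermo": TwoStateThermo(tm=340.6, dhm=472e3), "tau_m": 14.2e-9},
    "high_salt": {"thermo": TwoStateThermo(tm=319.4, dhm=180.1e3)},
    "group1": {"p_b": 0.0069, "k_ex": 3500.0, "dw_range": (1.78, 5.42)},
    "group2": {"p_b": 0.012, "k_ex": 860.0, "dw_range": (1.24, 2.28)},
}

#: Default relative noise of the fluorescence-ratio melt signal; the
#: instrument noise is not characterized in the source data, 0.5% is a
#: realistic figure for nanoDSF ratio traces (config-exposed).
MELT_NOISE_DEFAULT = 0.005


@dataclass
class GeneratorConfig:
    """Root seed plus acquisition grids and noise levels.

    A fixed seed makes every generator byte-reproducible; each data kind
    draws from an independent child stream so partial regeneration does
    not perturb the others.
    """

    seed: int = 0
    melt_noise: float = MELT_NOISE_DEFAULT
    relax_noise: float = 0.03
    rdc_noise_hz: float = 1.0
    temperature_grid: np.ndarray = field(default_factory=lambda: TEMPERATURE_GRID.copy())
    r1_delays: np.ndarray = field(default_factory=lambda: R1_DELAYS.copy())
    r2_delays: np.ndarray = field(default_factory=lambda: R2_DELAYS.copy())
    nu_grids: dict = field(default_factory=lambda: {900.0: NU_CPMG_900.copy(),
                                                    1200.0: NU_CPMG_1200.copy()})
    titration_ratios: np.ndarray = field(default_factory=lambda: TITRATION_RATIOS.copy())

    _STREAMS = {"melt": 1, "relax": 2, "cpmg": 3, "rdc": 4, "titration": 5, "structure": 6}

    def rng(self, kind: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, self._STREAMS[kind]])


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ------------------------------------------------------------ melt curves

@dataclass
class MeltCurve:
    temperature: np.ndarray
    signal: np.ndarray
    sigma: np.ndarray
    thermo_true: TwoStateThermo | None = None
    baselines_true: BaselineParams | None = None


def gen_melt_curve(
    thermo: TwoStateThermo | None = None,
    baselines: BaselineParams | None = None,
    grid: Sequence[float] | None = None,
    noise: float = MELT_NOISE_DEFAULT,
    seed=0,
) -> MeltCurve:
    """Two-state melt curve with Gaussian noise (equilibrium at every T).

    Noise is relative: sd = noise * |clean signal| per point. Defaults
    are the free-state parameters and the 288-368 K ramp.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    thermo = thermo or PRESETS["free"]["thermo"]
    # default baselines give a 0.5-unit transition step on a ~1.0 ratio
    # signal (realistic for a fold burying two tryptophans); together with
    # the 0.5% noise this reproduces the sub-0.3 K technical repeatability
    # of the Tm that the measurement reports
    baselines = baselines or BaselineParams(a_n0=1.0, g_n=-0.0008, a_u0=1.5,
                                            g1_u=0.0015, g2_u=-8e-6, t_ref=328.0)
    t = np.asarray(grid if grid is not None else TEMPERATURE_GRID, dtype=float)
    rng = _rng_from(seed)
    clean = predict_signal(t, thermo, baselines)
    sigma = noise * np.abs(clean)
    y = clean + rng.normal(0.0, sigma) if noise > 0 else clean.copy()
    return MeltCurve(temperature=t, signal=y, sigma=np.where(sigma > 0, sigma, 1.0),
                     thermo_true=thermo, baselines_true=baselines)


# ------------------------------------------------------- relaxation data

@dataclass
class RelaxationDataset:
    """Forward-generated decays and NOE measurements per residue."""

    residues: np.ndarray
    r1_decays: dict      # residue -> (delays, intensities, sigma)
    r2_decays: dict
    noe: pd.DataFrame    # residue-indexed: i_sat, i0, noe, noe_err
    rates_true: pd.DataFrame
    tau_m: float
    field_mhz: float


def gen_relaxation_data(
    params: Mapping[int, dict],
    tensor: mf.DiffusionTensor | None = None,
    field_mhz: float = 600.0,
    r1_delays: Sequence[float] | None = None,
    r2_delays: Sequence[float] | None = None,
    noise: float = 0.03,
    seed=0,
    nh_vectors: Mapping[int, np.ndarray] | None = None,
) -> RelaxationDataset:
    """Mono-exponential decay tables and a NOE table from the model-free
    forward rate calculator.

    ``params`` maps residue -> {'s2', optionally 'te', 'rex', 's2f'};
    the default tensor is isotropic tumbling at 9.25 ns. Intensities
    carry Gaussian noise with sd = noise * I (floored at 3% relative,
    the uncertainty convention of the downstream analysis).
    """
    tensor = tensor or mf.DiffusionTensor("isotropic", tau_m=PRESETS["free"]["tau_m"])
    constants = PhysicalConstants(field_mhz=field_mhz)
    t1 = np.asarray(r1_delays if r1_delays is not None else R1_DELAYS, float)
    t2 = np.asarray(r2_delays if r2_delays is not None else R2_DELAYS, float)
    if t1.size < 3 or t2.size < 3:
        raise ValueError("delay lists need at least 3 points for downstream fits")
    noise = max(noise, 0.0)
    rng = _rng_from(seed)

    residues = np.array(sorted(params), dtype=int)
    r1_decays, r2_decays = {}, {}
    noe_rows, rate_rows = [], []
    i0 = 1.0
    for res in residues:
        p = params[int(res)]
        vec = nh_vectors.get(int(res)) if nh_vectors else None
        r1, r2, noe = mf.predict_rates(p["s2"], tensor, constants,
                                       te=p.get("te", 0.0), rex=p.get("rex", 0.0),
                                       s2f=p.get("s2f", 1.0), nh_vector=vec)
        for delays, rate, store in ((t1, r1, r1_decays), (t2, r2, r2_decays)):
            clean = i0 * np.exp(-rate * delays)
            sd = np.maximum(noise, 0.0) * clean
            vals = clean + rng.normal(0.0, sd) if noise > 0 else clean
            store[int(res)] = (delays, np.clip(vals, 1e-12, None),
                               np.maximum(sd, 0.03 * clean))
        i_sat_clean = noe * i0
        sd_pair = noise * i0
        if noise > 0:
            i_sat = i_sat_clean + rng.normal(0.0, abs(sd_pair))
            i_ref = i0 + rng.normal(0.0, abs(sd_pair))
        else:
            i_sat, i_ref = i_sat_clean, i0
        noe_val, noe_err = mf.compute_noe(i_sat, i_ref, abs(sd_pair), abs(sd_pair))
        noe_rows.append({"residue": int(res), "i_sat": i_sat, "i0": i_ref,
                         "noe": noe_val, "noe_err": max(noe_err, 0.03 * abs(noe_val))})
        rate_rows.append({"residue": int(res), "r1": r1, "r2": r2, "noe": noe})

    return RelaxationDataset(
        residues=residues, r1_decays=r1_decays, r2_decays=r2_decays,
        noe=pd.DataFrame(noe_rows).set_index("residue"),
        rates_true=pd.DataFrame(rate_rows).set_index("residue"),
        tau_m=tensor.tau_m, field_mhz=field_mhz,
    )


# ------------------------------------------------------- dispersion data

def gen_dispersion_data(
    exchange: Mapping[int, cpmg_mod.ExchangeParams],
    fields: Sequence[float] = (900.0, 1200.0),
    nu_grids: Mapping[float, np.ndarray] | None = None,
    t_relax: Mapping[float, float] | None = None,
    noise: bool = True,
    seed=0,
) -> dict[int, list[cpmg_mod.DispersionCurve]]:
    """Two-site dispersion profiles from the Bloch-McConnell simulator.

    Gaussian noise with sd = max(0.3 s^-1, 2% of R2,eff); duplicate nu
    points are independent noise realizations, as acquired.
    """
    nu_grids = nu_grids or {f: {900.0: NU_CPMG_900, 1200.0: NU_CPMG_1200}[f] for f in fields}
    t_relax = t_relax or {f: T_RELAX[f] for f in fields}
    rng = _rng_from(seed)
    out: dict[int, list[cpmg_mod.DispersionCurve]] = {}
    for res, pars in exchange.items():
        curves = []
        for f in fields:
            nus = np.asarray(nu_grids[f], dtype=float)
            clean = cpmg_mod.simulate_bm(pars, nus, f, t_relax[f])
            sigma = cpmg_mod.sigma_floor(clean)
            vals = clean + rng.normal(0.0, sigma) if noise else clean.copy()
            curves.append(cpmg_mod.DispersionCurve(
                residue=int(res), field_mhz=f, t_relax=t_relax[f],
                nu_cpmg=nus, r2_eff=vals, sigma=sigma))
        out[int(res)] = curves
    return out


# -------------------------------------------------------- toy structures

# ideal backbone internal coordinates (lengths A, angles deg)
_B_NCA, _B_CAC, _B_CN, _B_CO = 1.458, 1.525, 1.329, 1.231
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom d given chain a-b-c and internal coords."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_helix(n_res: int) -> dict[str, np.ndarray]:
    """Backbone coordinates of an ideal alpha helix (phi -57, psi -47)."""
    # bootstrap first residue in an arbitrary frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_NCA, 0.0, 0.0])
    c0 = _place_atom(n0 + np.array([0.0, 1.0, 0.0]), n0, ca0, _B_CAC, _A_NCAC, -60.0)
    atoms = {"N": [n0], "CA": [ca0], "C": [c0]}
    for i in range(1, n_res):
        n_i = _place_atom(atoms["N"][-1], atoms["CA"][-1], atoms["C"][-1],
                          _B_CN, _A_CACN, _PSI)
        ca_i = _place_atom(atoms["CA"][-1], atoms["C"][-1], n_i,
                           _B_NCA, _A_CNCA, _OMEGA)
        c_i = _place_atom(atoms["C"][-1], n_i, ca_i, _B_CAC, _A_NCAC, _PHI)
        atoms["N"].append(n_i)
        atoms["CA"].append(ca_i)
        atoms["C"].append(c_i)
    # carbonyl O in the peptide plane, trans to the next N
    atoms["O"] = [
        _place_atom(atoms["N"][i], atoms["CA"][i], atoms["C"][i],
                    _B_CO, _A_CACO, _PSI + 180.0)
        for i in range(n_res)
    ]
    return {k: np.array(v) for k, v in atoms.items()}


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    from scipy.spatial.transform import Rotation

    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    if s < 1e-12:
        if np.dot(a, b) > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular
        perp = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = v / s
    angle = np.arctan2(s, np.dot(a, b))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def gen_toy_structure(
    lengths: Sequence[int] = (12, 10, 14),
    angles: Sequence[float] = (120.0, 107.0),
    separation: float = 18.0,
) -> StructureModel:
    """Ideal poly-alanine helical segments with prescribed inter-axis angles.

    ``angles[k-1]`` is the requested angle (degrees) between the
    directed axis of segment 1 and that of segment k+1; a single length
    builds one helix. Segments are laid out on a line with ``separation``
    A between origins; overlapping placements raise. The constructed
    angles are recovered by the geometry module within 2 degrees.
    """
    if any(not 0.0 < a < 180.0 for a in angles):
        raise ValueError("inter-axis angles must lie in (0, 180) degrees")
    if len(angles) != max(len(lengths) - 1, 0):
        raise ValueError("need one angle per segment beyond the first")

    nums, rnames, anames, elems, coords = [], [], [], [], []
    next_res = 1
    all_segments = []
    for k, n_res in enumerate(lengths):
        if n_res < 6:
            raise ValueError("each helix segment needs at least 6 residues")
        bb = _ideal_helix(n_res)
        ca = bb["CA"]
        axis = np.linalg.svd(ca - ca.mean(axis=0))[2][0]
        if np.dot(ca[-1] - ca[0], axis) < 0:
            axis = -axis
        # target direction: segment 1 along +z; others tilted in the xz-plane,
        # successive segments rotated about z to avoid coincident placement
        if k == 0:
            target = np.array([0.0, 0.0, 1.0])
        else:
            ang = np.radians(angles[k - 1])
            azim = 0.5 * np.pi * (k - 1)
            target = np.array([np.sin(ang) * np.cos(azim),
                               np.sin(ang) * np.sin(azim), np.cos(ang)])
        rot = _rotation_between(axis, target)
        origin = np.array([separation * k, 0.0, 0.0])
        seg_coords = {name: (bb[name] - ca.mean(axis=0)) @ rot.T + origin
                      for name in ("N", "CA", "C", "O")}
        all_segments.append(seg_coords)
        for i in range(n_res):
            for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                nums.append(next_res + i)
                rnames.append("ALA")
                anames.append(name)
                elems.append(elem)
                coords.append(seg_coords[name][i])
        next_res += n_res + 2  # numbering gap marks the chain break

    # overlap check between segment CA traces
    for i in range(len(all_segments)):
        for j in range(i + 1, len(all_segments)):
            d = np.linalg.norm(all_segments[i]["CA"][:, None, :] -
                               all_segments[j]["CA"][None, :, :], axis=-1)
            if d.min() < 3.0:
                raise ValueError("overlapping segments")

    model = StructureModel(
        model_index=1,
        residue_numbers=np.array(nums, dtype=int),
        residue_names=rnames, atom_names=anames, elements=elems,
        coords=np.array(coords),
    )
    return model


def toy_segment_ranges(lengths: Sequence[int]) -> list[range]:
    """Residue ranges of the segments built by :func:`gen_toy_structure`."""
    out, start = [], 1
    for n in lengths:
        out.append(range(start, start + n))
        start += n + 2
    return out


# -------------------------------------------------------------- RDC data

def default_alignment_tensor(da: float = 12.0, rhombicity: float = 0.2,
                             euler_deg: Sequence[float] = (140.0, 170.0, 0.0)) -> rdc_mod.AlignmentTensor:
    """Alignment tensor (Hz) whose back-calculated couplings span roughly
    the measured -13...25 Hz range on a well-distributed vector set."""
    from scipy.spatial.transform import Rotation

    azz = 2.0 * da
    axx = -da * (1.0 - 1.5 * rhombicity)
    ayy = -da * (1.0 + 1.5 * rhombicity)
    frame = Rotation.from_euler("zyz", np.radians(euler_deg)).as_matrix()
    s = frame @ np.diag([axx, ayy, azz]) @ frame.T
    s -= np.eye(3) * np.trace(s) / 3.0  # kill numerical trace residue
    return rdc_mod.AlignmentTensor(s)


def gen_rdc_data(
    structure: StructureModel,
    tensor: rdc_mod.AlignmentTensor | None = None,
    noise_hz: float = 1.0,
    seed=0,
    build_h: bool = True,
) -> dict[int, float]:
    """Observed RDCs: tensor projection on each NH vector plus noise."""
    tensor = tensor or default_alignment_tensor()
    vectors = rdc_mod.extract_nh_vectors(structure, build_h=build_h)
    if len(vectors) < 5:
        raise ValueError("fewer than 5 NH vectors: alignment tensor underdetermined")
    rng = _rng_from(seed)
    clean = rdc_mod.back_calc_rdc(tensor, vectors)
    return {r: float(v + (rng.normal(0.0, noise_hz) if noise_hz > 0 else 0.0))
            for r, v in clean.items()}


# ---------------------------------------------------------- titration

def gen_titration_series(
    free_shifts: pd.DataFrame,
    bound_shifts: pd.DataFrame,
    regime: Mapping[int, str] | str = "fast",
    ratios: Sequence[float] | None = None,
    intermediate_shifts: pd.DataFrame | None = None,
    switch_ratio: float = 0.3,
    shift_noise: tuple[float, float] = (0.0, 0.0),
    seed=0,
):
    """Peak trajectories across a titration under tight-binding occupancy.

    ``free_shifts``/``bound_shifts``: residue-indexed DataFrames with
    columns ``h`` and ``n`` (ppm). Fraction bound is min(ratio, 1)
    (stoichiometric limit). Fast-exchange residues move linearly between
    endpoints with full intensity; slow-exchange residues keep the free
    position while its intensity decays with (1 - f), vanishing (NaN)
    at saturation. An optional intermediate state (reached at
    ``switch_ratio``) makes trajectories two-phase for direction-change
    analysis. Returns a :class:`~hmgdyn.csp.TitrationSeries`.
    """
    from .csp import TitrationSeries

    ratios = np.asarray(ratios if ratios is not None else TITRATION_RATIOS, float)
    if np.any(np.diff(ratios) <= 0):
        raise ValueError("molar ratios must be sorted ascending")
    rng = _rng_from(seed)
    residues = free_shifts.index
    if isinstance(regime, str):
        regime = {int(r): regime for r in residues}

    def position(res, ratio):
        f = min(ratio, 1.0)
        p_free = free_shifts.loc[res].to_numpy(dtype=float)
        p_bound = bound_shifts.loc[res].to_numpy(dtype=float)
        if intermediate_shifts is not None and res in intermediate_shifts.index:
            p_int = intermediate_shifts.loc[res].to_numpy(dtype=float)
            if f <= switch_ratio:
                return p_free + (f / switch_ratio) * (p_int - p_free)
            return p_int + ((f - switch_ratio) / (1.0 - switch_ratio)) * (p_bound - p_int)
        return p_free + f * (p_bound - p_free)

    sh, sn, inten = {}, {}, {}
    for j, ratio in enumerate(ratios):
        col_h, col_n, col_i = [], [], []
        f = min(ratio, 1.0)
        for res in residues:
            if regime[int(res)] == "fast":
                pos = position(res, ratio)
                intensity = 1.0
            else:  # slow exchange: follow the free-state peak
                pos = free_shifts.loc[res].to_numpy(dtype=float)
                intensity = 1.0 - f
                if intensity <= 1e-9:
                    col_h.append(np.nan)
                    col_n.append(np.nan)
                    col_i.append(np.nan)
                    continue
            noise_h, noise_n = shift_noise
            col_h.append(pos[0] + (rng.normal(0.0, noise_h) if noise_h > 0 else 0.0))
            col_n.append(pos[1] + (rng.normal(0.0, noise_n) if noise_n > 0 else 0.0))
            col_i.append(intensity)
        sh[j], sn[j], inten[j] = col_h, col_n, col_i

    shifts_h = pd.DataFrame(sh, index=residues)
    shifts_n = pd.DataFrame(sn, index=residues)
    intensities = pd.DataFrame(inten, index=residues)
    return TitrationSeries(ratios=ratios, shifts_h=shifts_h,
                           shifts_n=shifts_n, intensities=intensities)
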