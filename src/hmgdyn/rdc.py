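"""Residual dipolar couplings and structure geometry.

Alignment-tensor determination by linear (SVD) least squares on backbone
N-H RDCs, RDC back-calculation and Q-factors; Kabsch superposition RMSD
and principal-axis inter-helix angles for structure comparison.

The RDC of an N-H bond with unit vector n in the alignment frame is the
tensor projection D = n^T A n with A the symmetric traceless alignment
matrix expressed directly in Hz (A absorbs the dipolar prefactor), so
Da = Azz/2 and rhombicity R = (2/3)(Axx - Ayy)/Azz in the principal
frame ordered |Azz| >= |Ayy| >= |Axx|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io import StructureModel

__all__ = [
    "AlignmentTensor",
    "RDCFit",
    "extract_nh_vectors",
    "svd_fit_tensor",
    "back_calc_rdc",
    "q_factor",
    "ensemble_q",
    "kabsch",
    "backbone_rmsd",
    "helix_axis",
    "inter_helix_angle",
]

#: Amide N-H bond length used when building missing H atoms, Angstrom.
R_NH_BUILD = 1.02

BACKBONE_HEAVY = ("N", "CA", "C", "O")


@dataclass
class AlignmentTensor:
    """Saupe-style alignment matrix in Hz (symmetric, traceless)."""

    saupe: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.saupe, dtype=float)
        if s.shape != (3, 3) or not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("alignment matrix must be symmetric 3x3")
        if abs(np.trace(s)) > 1e-6 * max(1.0, np.abs(s).max()):
            raise ValueError("alignment matrix must be traceless")
        self.saupe = s

    @property
    def principal_values(self) -> np.ndarray:
        """Eigenvalues ordered by increasing |value| (Axx, Ayy, Azz)."""
        vals = np.linalg.eigvalsh(self.saupe)
        return vals[np.argsort(np.abs(vals))]

    @property
    def da(self) -> float:
        """Axial magnitude Da = Azz/2, Hz."""
        return float(self.principal_values[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        """R = (2/3)(Axx - Ayy)/Azz, |R| <= 2/3."""
        axx, ayy, azz = self.principal_values
        return float((2.0 / 3.0) * (axx - ayy) / azz)

    @property
    def euler_angles(self) -> tuple[float, float, float]:
        """z-y-z Euler angles (radians) of the principal axis frame."""
        from scipy.spatial.transform import Rotation

        vals = np.linalg.eigvalsh(self.saupe)
        order = np.argsort(np.abs(vals))
        frame = np.linalg.eigh(self.saupe)[1][:, order]
        if np.linalg.det(frame) < 0:
            frame[:, 0] *= -1
        return tuple(Rotation.from_matrix(frame).as_euler("zyz"))


@dataclass
class RDCFit:
    tensor: AlignmentTensor
    observed: dict[int, float]
    calculated: dict[int, float]
    q: float
    rms: float


def _build_amide_h(model: StructureModel, residue: int) -> np.ndarray | None:
    """Place H on the bisector-opposed direction in the peptide plane,
    1.02 A from N (requires N, CA and the preceding C')."""
    n = model.atom(residue, "N")
    ca = model.atom(residue, "CA")
    c_prev = model.atom(residue - 1, "C")
    if n is None or ca is None or c_prev is None:
        return None
    u1 = (c_prev - n) / np.linalg.norm(c_prev - n)
    u2 = (ca - n) / np.linalg.norm(ca - n)
    bisector = u1 + u2
    norm = np.linalg.norm(bisector)
    if norm < 1e-8:
        return None
    return n - R_NH_BUILD * bisector / norm


def extract_nh_vectors(model: StructureModel, build_h: bool = True) -> dict[int, np.ndarray]:
    """Unit N->H bond vectors per residue.

    Prolines (no amide H) and residues missing N are skipped; when the
    amide H is absent and ``build_h`` is set it is constructed from the
    peptide-plane geometry. Returns an empty dict (callers warn) when
    nothing can be extracted.
    """
    out: dict[int, np.ndarray] = {}
    for res in model.residues:
        res = int(res)
        idx = np.where(model.residue_numbers == res)[0]
        if len(idx) and model.residue_names[idx[0]] == "PRO":
            continue
        n = model.atom(res, "N")
        if n is None:
            continue
        h = model.atom(res, "H")
        if h is None:
            h = model.atom(res, "HN")
        if h is None and build_h:
            h = _build_amide_h(model, res)
        if h is None:
            continue
        v = h - n
        out[res] = v / np.linalg.norm(v)
    return out


def _design_row(n: np.ndarray) -> np.ndarray:
    """Five independent components of n^T A n for traceless symmetric A,
    parameterized as (Axx, Ayy, Axy, Axz, Ayz) with Azz = -Axx - Ayy."""
    x, y, z = n
    return np.array([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def _tensor_from_params(p: np.ndarray) -> AlignmentTensor:
    axx, ayy, axy, axz, ayz = p
    s = np.array([
        [axx, axy, axz],
        [axy, ayy, ayz],
        [axz, ayz, -axx - ayy],
    ])
    return AlignmentTensor(s)


def svd_fit_tensor(vectors: Mapping[int, np.ndarray], observed: Mapping[int, float]) -> RDCFit:
    """Linear least-squares (SVD) fit of the alignment tensor.

    Solves the five independent Saupe elements from >= 5 residues
    common to the vector set and the observed RDC table; raises on
    degenerate (coplanar/collinear) vector geometry.
    """
    common = sorted(set(vectors) & set(observed))
    if len(common) < 5:
        raise ValueError("need at least 5 residues with both an NH vector and an RDC")
    a = np.array([_design_row(vectors[r]) for r in common])
    d = np.array([observed[r] for r in common])
    if np.all(np.abs(d) < 1e-12):
        raise ValueError("all observed RDCs are zero")
    rank = np.linalg.matrix_rank(a, tol=1e-8 * np.abs(a).max())
    if rank < 5:
        raise ValueError("degenerate vector geometry")
    p, *_ = np.linalg.lstsq(a, d, rcond=None)
    tensor = _tensor_from_params(p)
    calc = {r: float(_design_row(vectors[r]) @ p) for r in common}
    obs = {r: float(observed[r]) for r in common}
    q = q_factor(list(obs.values()), list(calc.values()))
    rms = float(np.sqrt(np.mean([(obs[r] - calc[r]) ** 2 for r in common])))
    return RDCFit(tensor=tensor, observed=obs, calculated=calc, q=q, rms=rms)


def back_calc_rdc(tensor: AlignmentTensor, vectors: Mapping[int, np.ndarray]) -> dict[int, float]:
    """Back-calculate D = n^T A n (Hz) for each NH vector."""
    return {r: float(v @ tensor.saupe @ v) for r, v in vectors.items()}


def q_factor(observed: Iterable[float], calculated: Iterable[float]) -> float:
    """Cornilescu Q = rms(D_obs - D_calc) / rms(D_obs)."""
    obs = np.asarray(list(observed), dtype=float)
    calc = np.asarray(list(calculated), dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 RDC pairs")
    rms_obs = np.sqrt(np.mean(obs**2))
    if rms_obs == 0:
        raise ValueError("observed RDCs are all zero")
    return float(np.sqrt(np.mean((obs - calc) ** 2)) / rms_obs)


def ensemble_q(models: list[StructureModel], observed: Mapping[int, float],
               build_h: bool = True) -> tuple[float, float, list[float]]:
    """Per-conformer tensor fits: mean and sd of the Q-factor.

    sd is NaN for a single model (flagged undefined).
    """
    qs = []
    for m in models:
        vectors = extract_nh_vectors(m, build_h=build_h)
        qs.append(svd_fit_tensor(vectors, observed).q)
    mean = float(np.mean(qs))
    sd = float(np.std(qs, ddof=1)) if len(qs) > 1 else float("nan")
    return mean, sd, qs


# ---------------------------------------------------------------- geometry

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition (rotation, translation, rmsd)."""
    mob_c = mobile - mobile.mean(axis=0)
    tgt_c = target - target.mean(axis=0)
    h = mob_c.T @ tgt_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = mob_c @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt_c) ** 2, axis=1))))
    trans = target.mean(axis=0) - rot @ mobile.mean(axis=0)
    return rot, trans, rmsd


def backbone_rmsd(model_a: StructureModel, model_b: StructureModel,
                  residues: Iterable[int] | None = None,
                  atom_names: Iterable[str] = BACKBONE_HEAVY) -> float:
    """Heavy-backbone RMSD (A) after Kabsch superposition.

    Default atom set N, CA, C', O over the residues common to both
    models (or an explicit range).
    """
    if residues is None:
        residues = sorted(set(model_a.residues) & set(model_b.residues))
    atom_names = tuple(atom_names)
    pairs_a, pairs_b = [], []
    for r in residues:
        for a in atom_names:
            xa, xb = model_a.atom(int(r), a), model_b.atom(int(r), a)
            if xa is not None and xb is not None:
                pairs_a.append(xa)
                pairs_b.append(xb)
    if len(pairs_a) < 3:
        raise ValueError("fewer than 3 matched atoms for superposition")
    _, _, rmsd = kabsch(np.array(pairs_a), np.array(pairs_b))
    return rmsd


def helix_axis(model: StructureModel, residues: Iterable[int],
               residual_threshold: float = 3.0) -> tuple[np.ndarray, float]:
    """Helix axis as the principal component of the CA trace, oriented
    N->C. Returns (unit axis, rms distance of CA atoms from the axis in
    A); an alpha helix gives ~2.3 A (the CA radius), and a residual
    above the threshold indicates non-helical geometry (caller may
    warn)."""
    res = sorted(int(r) for r in residues)
    if len(res) < 6:
        raise ValueError("need at least 6 residues to define a helix axis")
    ca = []
    for r in res:
        xyz = model.atom(r, "CA")
        if xyz is None:
            raise KeyError(f"CA of residue {r} missing")
        ca.append(xyz)
    ca = np.array(ca)
    centered = ca - ca.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    resid = float(np.sqrt(np.mean(np.sum((centered - np.outer(centered @ axis, axis)) ** 2, axis=1))))
    return axis, resid


def inter_helix_angle(model: StructureModel, range_a: Iterable[int],
                      range_b: Iterable[int]) -> float:
    """Angle (degrees, [0, 180)) between two directed N->C helix axes.

    Directed axes make supplementary packings distinct: parallel
    duplicated helices give ~0, antiparallel ~180.
    """
    axis_a, _ = helix_axis(model, range_a)
    axis_b, _ = helix_axis(model, range_b)
    cosang = float(np.clip(np.dot(axis_a, axis_b), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))
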