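"""Titration chemical-shift-perturbation analysis.

CSP between two titration points is the weighted displacement
sqrt(dH^2 + (dN/6)^2) in ppm. Significance thresholds are the 10%
trimmed mean of all residue CSPs plus one or two standard deviations
of the trimmed set. Trajectory-direction comparison between the early
and late titration phases distinguishes binding modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "TitrationSeries",
    "ThresholdSet",
    "csp",
    "thresholds",
    "csp_table",
    "intensity_ratios",
    "trajectory_compare",
    "compare_conditions",
]

#: 15N scaling factor in the combined-shift formula.
N_SCALE = 6.0

#: Displacements below this (ppm) leave a trajectory direction undefined.
MIN_DISPLACEMENT = 0.005


@dataclass
class TitrationSeries:
    """Peak positions and intensities across a molar-ratio series.

    shifts_h / shifts_n: DataFrames indexed by residue, one column per
    ratio point (ppm). intensities: same layout; NaN marks a residue
    broadened beyond detection at that point.
    """

    ratios: np.ndarray
    shifts_h: pd.DataFrame
    shifts_n: pd.DataFrame
    intensities: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if np.any(np.diff(self.ratios) <= 0):
            raise ValueError("molar ratio points must be sorted ascending")
        if self.ratios[0] != 0.0:
            raise ValueError("series must start at the free state (ratio 0)")

    def point_index(self, ratio: float) -> int:
        idx = np.where(np.isclose(self.ratios, ratio))[0]
        if idx.size == 0:
            raise KeyError(f"no titration point at ratio {ratio}")
        return int(idx[0])


@dataclass
class ThresholdSet:
    trimmed_mean: float
    plus_1sd: float
    plus_2sd: float
    n_used: int = 0


def csp(d_h: float, d_n: float) -> float:
    """Combined 1H/15N chemical shift perturbation in ppm."""
    return float(np.sqrt(np.asarray(d_h) ** 2 + (np.asarray(d_n) / N_SCALE) ** 2))


def thresholds(csps: Sequence[float], trim: float = 0.10) -> ThresholdSet:
    """Outlier-robust significance levels from all residue CSPs.

    The largest ``trim`` fraction of values is removed (one-sided trim,
    the convention for CSP thresholds where perturbed residues are the
    outliers); mean and sd are computed on the remaining set. NaNs are
    excluded and counted out.
    """
    vals = np.asarray(csps, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise ValueError("need at least 10 residues for robust thresholds")
    n_trim = int(np.floor(trim * vals.size))
    kept = np.sort(vals)[: vals.size - n_trim] if n_trim else np.sort(vals)
    mean = float(np.mean(kept))
    sd = float(np.std(kept))
    return ThresholdSet(trimmed_mean=mean, plus_1sd=mean + sd,
                        plus_2sd=mean + 2.0 * sd, n_used=int(kept.size))


def csp_table(series: TitrationSeries, ratio_a: float = 0.0,
              ratio_b: float = 1.0) -> pd.DataFrame:
    """Per-residue CSP between two titration points with threshold
    classification (0 = below trimmed mean + 1 sd, 1 = above +1 sd,
    2 = above +2 sd)."""
    ia, ib = series.point_index(ratio_a), series.point_index(ratio_b)
    d_h = series.shifts_h.iloc[:, ib] - series.shifts_h.iloc[:, ia]
    d_n = series.shifts_n.iloc[:, ib] - series.shifts_n.iloc[:, ia]
    values = np.sqrt(d_h**2 + (d_n / N_SCALE) ** 2)
    thr = thresholds(values.to_numpy())
    cls = np.zeros(len(values), dtype=int)
    cls[values.to_numpy() > thr.plus_1sd] = 1
    cls[values.to_numpy() > thr.plus_2sd] = 2
    return pd.DataFrame({
        "residue": series.shifts_h.index,
        "csp": values.to_numpy(),
        "classification": cls,
    }).set_index("residue")


def intensity_ratios(series: TitrationSeries, ratio_a: float,
                     ratio_b: float) -> pd.DataFrame:
    """I(point B)/I(point A) per residue; residues undetectable at B are
    flagged 'broadened beyond detection' with a NaN ratio."""
    if series.intensities is None:
        raise ValueError("series has no intensities")
    ia, ib = series.point_index(ratio_a), series.point_index(ratio_b)
    i_a = series.intensities.iloc[:, ia]
    i_b = series.intensities.iloc[:, ib]
    ratio = i_b / i_a
    flag = i_b.isna() & i_a.notna()
    return pd.DataFrame({
        "residue": series.intensities.index,
        "intensity_ratio": ratio.to_numpy(),
        "broadened_beyond_detection": flag.to_numpy(),
    }).set_index("residue")


def _window_vector(series: TitrationSeries, residue, lo: float, hi: float) -> np.ndarray:
    """(dH, dN/6) displacement across a ratio window."""
    sel = (series.ratios >= lo - 1e-9) & (series.ratios <= hi + 1e-9)
    idx = np.where(sel)[0]
    if idx.size < 2:
        raise ValueError(f"fewer than 2 titration points in window [{lo}, {hi}]")
    i0, i1 = idx[0], idx[-1]
    d_h = series.shifts_h.loc[residue].iloc[i1] - series.shifts_h.loc[residue].iloc[i0]
    d_n = series.shifts_n.loc[residue].iloc[i1] - series.shifts_n.loc[residue].iloc[i0]
    return np.array([d_h, d_n / N_SCALE])


def trajectory_compare(series: TitrationSeries,
                       early: tuple[float, float] = (0.0, 0.3),
                       late: tuple[float, float] = (0.7, 1.0)) -> pd.DataFrame:
    """Angle between early- and late-phase CSP direction vectors.

    The direction vector is (dH, dN/6) across each window's endpoints;
    the angle (degrees) is undefined (NaN, flagged) when a window's
    displacement is below 0.005 ppm. The linearity score is the squared
    cosine alignment of all trajectory steps (1 = collinear).
    """
    rows = []
    for res in series.shifts_h.index:
        v_early = _window_vector(series, res, *early)
        v_late = _window_vector(series, res, *late)
        n_e, n_l = np.linalg.norm(v_early), np.linalg.norm(v_late)
        if n_e < MIN_DISPLACEMENT or n_l < MIN_DISPLACEMENT:
            angle, undefined = float("nan"), True
        else:
            cosang = float(np.clip(v_early @ v_late / (n_e * n_l), -1.0, 1.0))
            angle, undefined = float(np.degrees(np.arccos(cosang))), False

        # linearity: fraction of step variance along the dominant direction
        steps = []
        for i in range(1, series.ratios.size):
            dh = series.shifts_h.loc[res].iloc[i] - series.shifts_h.loc[res].iloc[i - 1]
            dn = series.shifts_n.loc[res].iloc[i] - series.shifts_n.loc[res].iloc[i - 1]
            steps.append([dh, dn / N_SCALE])
        steps = np.array(steps)
        if np.allclose(steps, 0.0):
            linearity = float("nan")
        else:
            s = np.linalg.svd(steps, compute_uv=False)
            linearity = float(s[0] ** 2 / np.sum(s**2))
        rows.append({"residue": res, "angle_deg": angle,
                     "undefined": undefined, "linearity": linearity})
    return pd.DataFrame(rows).set_index("residue")


def compare_conditions(csps_a: pd.Series | dict, csps_b: pd.Series | dict,
                       threshold_set_a: ThresholdSet | None = None,
                       threshold_set_b: ThresholdSet | None = None) -> dict:
    """Pairwise comparison of per-residue CSPs from two conditions.

    Residues missing from either table are excluded pairwise. Returns
    the paired table, the Spearman rank correlation, and the residues
    exceeding the +1 sd threshold in either condition (when thresholds
    are supplied).
    """
    a = pd.Series(csps_a, dtype=float)
    b = pd.Series(csps_b, dtype=float)
    common = a.index.intersection(b.index)
    common = [r for r in common if np.isfinite(a[r]) and np.isfinite(b[r])]
    if len(common) < 10:
        raise ValueError("need at least 10 common residues")
    paired = pd.DataFrame({"csp_a": a[common], "csp_b": b[common]})
    paired["difference"] = paired.csp_a - paired.csp_b
    rho, pval = spearmanr(paired.csp_a, paired.csp_b)
    exceed: list = []
    if threshold_set_a is not None:
        exceed += [r for r in common if a[r] > threshold_set_a.plus_1sd]
    if threshold_set_b is not None:
        exceed += [r for r in common if b[r] > threshold_set_b.plus_1sd]
    return {"table": paired, "spearman_rho": float(rho), "p_value": float(pval),
            "exceeding": sorted(set(exceed))}
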