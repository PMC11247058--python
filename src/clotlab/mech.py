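"""Compressive mechanical characterisation of clot sections.

Cyclic unconfined-compression records (time, strain, force) are reduced to
four characteristics:

* low-strain secant stiffness: OLS slope of nominal stress on strain
  (fraction) over the 0-10 % strain window of the first loading branch, kPa;
* high-strain secant stiffness: the same over 75-80 % strain, kPa;
* hysteresis loss: energy dissipated over the first loading-unloading cycle
  as a percentage of the loading energy (trapezoidal areas), %;
* plastic strain: the strain at which stress first returns to baseline on
  the first unloading branch, by linear interpolation, %.

Strain is nominal (displacement over the initial 2 mm section thickness),
compressive positive; interfaces carry strain in %, fits use fractions.
Force is converted to nominal stress with the initial cross-sectional area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SectionGeometry",
    "MechTrace",
    "CycleBranch",
    "MechFeatures",
    "LOW_STRAIN_WINDOW",
    "HIGH_STRAIN_WINDOW",
    "to_nominal_stress",
    "segment_cycles",
    "secant_modulus",
    "hysteresis_loss",
    "plastic_strain",
    "extract_features",
]

#: default secant-stiffness strain windows, % strain
LOW_STRAIN_WINDOW: Tuple[float, float] = (0.0, 10.0)
HIGH_STRAIN_WINDOW: Tuple[float, float] = (75.0, 80.0)

#: default stress tolerance for "returned to baseline", kPa
BASELINE_TOL_KPA = 0.01


@dataclass(frozen=True)
class SectionGeometry:
    """Initial geometry of a 2 mm-thick clot section."""

    cross_sectional_area: float  # mm^2
    feret_diameter: float  # mm
    thickness: float = 2.0  # mm

    def __post_init__(self) -> None:
        if not self.cross_sectional_area > 0:
            raise ValueError("cross_sectional_area must be > 0")
        if not self.feret_diameter > 0:
            raise ValueError("feret_diameter must be > 0")


@dataclass(frozen=True)
class MechTrace:
    """Sampled cyclic compression record. strain in %, force in N."""

    time: np.ndarray
    strain: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        t, e, f = map(np.asarray, (self.time, self.strain, self.force))
        if not (t.shape == e.shape == f.shape) or t.ndim != 1:
            raise ValueError("time/strain/force must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("time must be non-decreasing")
        if e.size and (e.min() < -1e-9 or e.max() >= 100):
            raise ValueError("strain must lie in [0, 100) %")


@dataclass(frozen=True)
class CycleBranch:
    """One loading-unloading cycle. Branches share the peak-strain sample.

    ``loading``/``unloading`` are (n, 2) arrays of (strain %, stress kPa).
    """

    cycle_index: int
    loading: np.ndarray
    unloading: np.ndarray

    @property
    def peak_strain(self) -> float:
        return float(self.loading[-1, 0])

    @property
    def peak_stress(self) -> float:
        return float(self.loading[-1, 1])


@dataclass(frozen=True)
class MechFeatures:
    """The four extracted characteristics plus per-cycle peak stresses."""

    low_strain_stiffness: float  # kPa
    high_strain_stiffness: float  # kPa
    hysteresis_loss: float  # %
    plastic_strain: float  # %
    peak_stress_per_cycle: Tuple[float, ...] = field(default_factory=tuple)
    plastic_no_return: bool = False


def to_nominal_stress(trace: MechTrace, geometry: SectionGeometry) -> np.ndarray:
    """Nominal stress channel in kPa: force (N) / initial area (mm^2) * 1000."""
    area = geometry.cross_sectional_area
    if not area > 0:
        raise ValueError("cross-sectional area must be > 0")
    return np.asarray(trace.force, dtype=float) / area * 1000.0


def segment_cycles(
    strain: np.ndarray,
    stress: np.ndarray,
    expected_cycles: int,
    prominence: float = 5.0,
) -> list[CycleBranch]:
    """Split a cyclic record into loading/unloading branches.

    Peaks are strain maxima of at least ``prominence`` (% strain). Each
    cycle runs valley -> peak (loading) -> next valley (unloading); the peak
    sample is shared by both branches of its cycle, valley samples are shared
    between neighbouring cycles.

    Raises ``ValueError`` if fewer than ``expected_cycles`` excursions are
    found, reporting the detected count.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    peaks, _ = find_peaks(strain, prominence=prominence)
    # a trace ending mid-plateau at its last peak is still a peak
    if len(peaks) < expected_cycles:
        raise ValueError(
            f"{len(peaks)} cycles detected, expected {expected_cycles} "
            f"(strain peak prominence {prominence}%)"
        )
    peaks = peaks[:expected_cycles]
    branches: list[CycleBranch] = []
    prev_valley = 0
    for k, p in enumerate(peaks):
        seg_end = peaks[k + 1] if k + 1 < len(peaks) else strain.size - 1
        valley = p + int(np.argmin(strain[p : seg_end + 1]))
        loading = np.column_stack([strain[prev_valley : p + 1], stress[prev_valley : p + 1]])
        unloading = np.column_stack([strain[p : valley + 1], stress[p : valley + 1]])
        branches.append(CycleBranch(cycle_index=k + 1, loading=loading, unloading=unloading))
        prev_valley = valley
    return branches


def secant_modulus(branch: CycleBranch, window: Tuple[float, float] = LOW_STRAIN_WINDOW) -> float:
    """OLS slope of stress (kPa) on strain (fraction) over a strain window.

    The window is closed and in % strain; the fit uses the loading branch
    with a free intercept. Requires at least two in-window samples.
    """
    lo, hi = window
    e = branch.loading[:, 0]
    s = branch.loading[:, 1]
    sel = (e >= lo) & (e <= hi)
    if sel.sum() < 2:
        raise ValueError(
            f"secant window [{lo}, {hi}]% contains {int(sel.sum())} samples; need >= 2"
        )
    x = e[sel] / 100.0  # fraction
    y = s[sel]
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError(f"secant window [{lo}, {hi}]% has zero strain variance")
    return float(xc @ (y - y.mean()) / denom)


def _branch_area(branch_xy: np.ndarray) -> float:
    """Trapezoidal area under stress over strain (fraction), sign-corrected."""
    e = branch_xy[:, 0] / 100.0
    s = branch_xy[:, 1]
    return abs(float(np.trapezoid(s, e)))


def hysteresis_loss(cycle: CycleBranch) -> float:
    """Dissipated energy of one cycle as % of the loading energy.

    100 * (A_load - A_unload) / A_load with trapezoidal areas of stress over
    strain on each branch.
    """
    a_load = _branch_area(cycle.loading)
    if a_load <= 0:
        raise ValueError("loading branch has non-positive area; cannot normalise")
    a_unload = _branch_area(cycle.unloading)
    return 100.0 * (a_load - a_unload) / a_load


def plastic_strain(
    cycle: CycleBranch,
    baseline: float = 0.0,
    baseline_tol: float = BASELINE_TOL_KPA,
) -> Tuple[float, bool]:
    """Residual strain where stress returns to baseline on unloading.

    Walks the unloading branch from the peak towards minimum strain and
    returns the strain (in %) at which stress first falls to
    ``baseline + baseline_tol``, linearly interpolated between the bracketing
    samples. If stress never returns, the minimum applied strain is returned
    together with ``no_return=True``.
    """
    e = cycle.unloading[:, 0]
    s = cycle.unloading[:, 1]
    level = baseline + baseline_tol
    below = s <= level
    if not below.any():
        return float(e[-1]), True
    i = int(np.argmax(below))  # first sample at/under the level
    if i == 0:
        return float(e[0]), False
    e0, e1 = e[i - 1], e[i]
    s0, s1 = s[i - 1], s[i]
    if s0 == s1:
        return float(e1), False
    frac = (s0 - level) / (s0 - s1)
    return float(e0 + frac * (e1 - e0)), False


def extract_features(
    trace: MechTrace,
    geometry: SectionGeometry,
    expected_cycles: int = 10,
    low_window: Tuple[float, float] = LOW_STRAIN_WINDOW,
    high_window: Tuple[float, float] = HIGH_STRAIN_WINDOW,
    baseline: Optional[float] = None,
    baseline_tol: float = BASELINE_TOL_KPA,
    prominence: float = 5.0,
) -> MechFeatures:
    """Full reduction of one record to :class:`MechFeatures`.

    Stiffnesses come from the first loading branch, hysteresis and plastic
    strain from the first full cycle; all cycle peak stresses are retained as
    diagnostics. ``baseline`` defaults to the median stress of any pre-load
    samples (strain below 0.5 %) ahead of the first excursion, or 0.
    """
    stress = to_nominal_stress(trace, geometry)
    strain = np.asarray(trace.strain, dtype=float)
    cycles = segment_cycles(strain, stress, expected_cycles, prominence=prominence)
    first = cycles[0]
    if baseline is None:
        # pre-load = the initial strain plateau (hold at the starting strain)
        plateau = strain <= strain[0] + 0.05
        idx = int(np.argmax(~plateau)) if not plateau.all() else strain.size
        baseline = float(np.median(stress[: max(idx, 1)]))
    ep, no_return = plastic_strain(first, baseline=baseline, baseline_tol=baseline_tol)
    return MechFeatures(
        low_strain_stiffness=secant_modulus(first, low_window),
        high_strain_stiffness=secant_modulus(first, high_window),
        hysteresis_loss=hysteresis_loss(first),
        plastic_strain=ep,
        peak_stress_per_cycle=tuple(c.peak_stress for c in cycles),
        plastic_no_return=no_return,
    )
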