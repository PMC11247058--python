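"""Synthetic clot-analogue cohorts with known ground truth.

Every downstream stage (mechanics extraction, CT densitometry, histological
quantification, regression) is testable without any laboratory data because
this module generates its inputs from an explicit generative model:

* a factorial design of 3 platelet concentrations (30/90/270 x10^3/ul) by 5
  RBC volume fractions (0/0.5/2/5/40 %) over 6 donors, trimmed to 87 clots;
* a platelet-driven contraction model: the plasma/serum fraction retained
  after overnight contraction decays exponentially with platelet
  concentration while the RBC volume is conserved, so contraction
  concentrates RBCs; platelet area fraction follows a saturating (Hill)
  function of the platelet amount per retained volume; clot diameter scales
  with the cube root of the retained-volume fraction;
* linear observable models in (RBC %, platelet %) for NCCT density and the
  four compressive characteristics, and in (platelet %, diameter) for the
  CECT density increase, with additive HU noise and mean-corrected
  multiplicative lognormal noise on mechanics;
* cyclic stress-strain traces whose four characteristics are known in
  closed form: loading sigma = A*eps + B*eps^5 with (A, B) solved from the
  two secant-window slopes, and power-law unloading solved (by brentq) so
  that both the hysteresis ratio and the baseline-crossing plastic strain
  hit their targets exactly;
* aligned cylindrical NCCT/CECT phantoms and exact- or blob-style label
  masks.

All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from . import histo
from .ctimg import CTImage
from .mech import BASELINE_TOL_KPA, HIGH_STRAIN_WINDOW, LOW_STRAIN_WINDOW, MechFeatures, MechTrace, SectionGeometry
from .recipe import BlendingVolumes, ClotRecipe, DonorBlood, compute_blending_volumes

__all__ = [
    "LinearModel",
    "ContractionModel",
    "GenerativeTruth",
    "SyntheticClot",
    "DEFAULT_TRUTH",
    "DEFAULT_PLATELET_LEVELS",
    "DEFAULT_RBC_FRACTIONS",
    "default_donors",
    "generate_cohort",
    "cohort_table",
    "generate_mech_trace",
    "draw_feasible_features",
    "project_feasible_features",
    "window_poly_slope",
    "CTPhantomParams",
    "generate_ct_phantom",
    "generate_label_mask",
    "recovery_study",
]

DEFAULT_PLATELET_LEVELS: Tuple[float, ...] = (30.0, 90.0, 270.0)
DEFAULT_RBC_FRACTIONS: Tuple[float, ...] = (0.0, 0.005, 0.02, 0.05, 0.40)

#: conditions dropped (donor index from 1, platelet level, rbc fraction) so the
#: default design yields 87 clots, emulating the study's attrition from 90.
DEFAULT_DROPPED: Tuple[Tuple[int, float, float], ...] = (
    (2, 270.0, 0.0),
    (4, 90.0, 0.05),
    (6, 30.0, 0.005),
)

MAX_STRAIN_PCT = 80.0
STRAIN_RATE_PCT_S = 10.0


@dataclass(frozen=True)
class LinearModel:
    """y = b0 + b_rbc * RBC% + b_plt * platelet% (+ b_diam * diameter)."""

    b0: float
    b_rbc: float = 0.0
    b_plt: float = 0.0
    b_diam: float = 0.0

    def predict(self, rbc: float, plt: float, diam: float = 0.0) -> float:
        return self.b0 + self.b_rbc * rbc + self.b_plt * plt + self.b_diam * diam


@dataclass(frozen=True)
class ContractionModel:
    """Serum expulsion versus platelet concentration.

    ``serum_retained(P) = s_min + (1 - s_min) * exp(-k * P)`` is the fraction
    of the non-RBC volume retained after contraction; RBC volume is
    conserved. ``carryover`` is the trace RBC volume fraction present even
    in nominally RBC-free blends. Platelet area fraction is a Hill function
    of the platelet amount per retained volume.
    """

    s_min: float = 0.02
    k: float = 0.017484  # per 10^3 platelets/ul; serum_retained(30) = 0.60
    carryover: float = 0.0005
    occupancy_max: float = 0.95
    hill_exponent: float = 1.3
    hill_k: float = 929.0
    jitter_contraction: float = 0.10
    jitter_occupancy: float = 0.10
    rbc_cap_pct: float = 99.9

    def serum_retained(self, platelet_conc: float) -> float:
        return self.s_min + (1.0 - self.s_min) * math.exp(-self.k * platelet_conc)

    def realize(
        self,
        rbc_fraction: float,
        platelet_conc: float,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[float, float, float]:
        """(RBC content %, platelet content %, retained volume fraction)."""
        s = self.serum_retained(platelet_conc)
        occ_jit = 1.0
        if rng is not None and self.jitter_contraction > 0:
            s = float(np.clip(s * rng.lognormal(0.0, self.jitter_contraction), self.s_min / 2, 1.0))
            occ_jit = rng.lognormal(0.0, self.jitter_occupancy)
        f = rbc_fraction + self.carryover
        retained = f + (1.0 - f) * s
        rbc_pct = min(100.0 * f / retained, self.rbc_cap_pct)
        raw = platelet_conc * (1.0 - f) / retained
        h = self.hill_exponent
        occ = self.occupancy_max * raw**h / (raw**h + self.hill_k**h)
        plt_pct = float(np.clip(100.0 * occ * occ_jit, 0.0, 98.0))
        return rbc_pct, plt_pct, retained


@dataclass(frozen=True)
class GenerativeTruth:
    """All generative coefficients and noise scales, fully configurable."""

    ncct: LinearModel = LinearModel(b0=17.32, b_rbc=0.35, b_plt=0.22)
    cect: LinearModel = LinearModel(b0=76.0, b_plt=0.49, b_diam=-10.23)
    low_stiffness: LinearModel = LinearModel(b0=-0.26, b_rbc=-0.001, b_plt=0.09)
    high_stiffness: LinearModel = LinearModel(b0=-1.973, b_rbc=0.54, b_plt=10.22)
    hysteresis_loss: LinearModel = LinearModel(b0=80.97, b_rbc=-0.21, b_plt=-0.35)
    plastic_strain: LinearModel = LinearModel(b0=78.25, b_rbc=-0.26, b_plt=-0.67)
    hu_sigma: float = 3.0
    mech_sigma_log: float = 0.15
    contraction: ContractionModel = field(default_factory=ContractionModel)
    softening: float = 0.95  # per-cycle peak-stress scale factor
    syringe_diameter_large: float = 8.66  # mm, 3 ml syringe (RBC fraction < 40%)
    syringe_diameter_small: float = 4.78  # mm, 1 ml syringe (40% RBC)

    @property
    def mech_models(self) -> Dict[str, LinearModel]:
        return {
            "low_stiffness": self.low_stiffness,
            "high_stiffness": self.high_stiffness,
            "hysteresis_loss": self.hysteresis_loss,
            "plastic_strain": self.plastic_strain,
        }

    def zero_noise(self) -> "GenerativeTruth":
        return replace(
            self,
            hu_sigma=0.0,
            mech_sigma_log=0.0,
            contraction=replace(self.contraction, jitter_contraction=0.0, jitter_occupancy=0.0),
        )


DEFAULT_TRUTH = GenerativeTruth()

#: default donor haematology (whole-blood platelets x10^3/ul, haematocrit,
#: fibrinogen g/l), spanning the normal adult range
_DONOR_HAEMATOLOGY = (
    (170.0, 0.45, 3.2),
    (172.0, 0.40, 4.0),
    (242.0, 0.40, 3.0),
    (185.0, 0.43, 2.2),
    (146.0, 0.42, 2.8),
    (164.0, 0.39, 2.4),
)


def default_donors(n_donors: int = 6, rng: Optional[np.random.Generator] = None) -> List[DonorBlood]:
    """Donors with measured PRP platelet concentrations.

    PRP concentrations are drawn uniformly on 460-620 x10^3/ul so that the
    full factorial (270 x10^3/ul at 40% RBC volume) is feasible for every
    donor.
    """
    rng = rng or np.random.default_rng(0)
    donors = []
    for i in range(n_donors):
        wb, hct, fib = _DONOR_HAEMATOLOGY[i % len(_DONOR_HAEMATOLOGY)]
        donors.append(
            DonorBlood(
                donor_id=f"D{i + 1}",
                prp_platelet_conc=float(rng.uniform(460.0, 620.0)),
                wb_platelet_conc=wb,
                haematocrit=hct,
                fibrinogen=fib,
            )
        )
    return donors


@dataclass(frozen=True)
class SyntheticClot:
    """One generated clot: recipe, realized composition, truth, observables."""

    clot_id: str
    donor: DonorBlood
    recipe: ClotRecipe
    volumes: BlendingVolumes
    rbc_content: float  # realized, % of cross-section
    platelet_content: float
    retained_volume_fraction: float
    diameter: float  # mm
    true_values: Dict[str, float]  # noise-free linear predictions
    observed: Dict[str, float]  # linear truth + noise (cohort observables)
    softening: float = 0.95

    @property
    def geometry(self) -> SectionGeometry:
        area = math.pi * self.diameter**2 / 4.0
        return SectionGeometry(cross_sectional_area=area, feret_diameter=self.diameter)


def generate_cohort(
    truth: GenerativeTruth = DEFAULT_TRUTH,
    platelet_levels: Sequence[float] = DEFAULT_PLATELET_LEVELS,
    rbc_fractions: Sequence[float] = DEFAULT_RBC_FRACTIONS,
    n_donors: int = 6,
    dropped: Sequence[Tuple[int, float, float]] = DEFAULT_DROPPED,
    seed: int = 0,
) -> List[SyntheticClot]:
    """Generate the factorial cohort (default: 87 clots, deterministic per seed)."""
    rng = np.random.default_rng(seed)
    donors = default_donors(n_donors, rng)
    dropped_set = set(dropped)
    clots: List[SyntheticClot] = []
    for i, donor in enumerate(donors, start=1):
        for p in platelet_levels:
            for f in rbc_fractions:
                if (i, p, f) in dropped_set:
                    continue
                total = 1000.0 if f >= 0.40 else 3000.0
                recipe = ClotRecipe(target_platelet_conc=p, rbc_volume_fraction=f, total_volume=total)
                volumes = compute_blending_volumes(donor, recipe)
                rbc, plt, retained = truth.contraction.realize(f, p, rng)
                d0 = truth.syringe_diameter_small if f >= 0.40 else truth.syringe_diameter_large
                diameter = d0 * retained ** (1.0 / 3.0)
                true_vals = {
                    "ncct_density": truth.ncct.predict(rbc, plt),
                    "cect_increase": truth.cect.predict(rbc, plt, diameter),
                }
                for name, model in truth.mech_models.items():
                    true_vals[name] = model.predict(rbc, plt)
                observed = dict(true_vals)
                observed["ncct_density"] += rng.normal(0.0, truth.hu_sigma) if truth.hu_sigma else 0.0
                observed["cect_increase"] += rng.normal(0.0, truth.hu_sigma) if truth.hu_sigma else 0.0
                s = truth.mech_sigma_log
                for name in truth.mech_models:
                    if s > 0:
                        # mean-corrected lognormal: E[obs] equals the linear truth
                        observed[name] = true_vals[name] * rng.lognormal(-0.5 * s * s, s)
                clots.append(
                    SyntheticClot(
                        clot_id=f"{donor.donor_id}_P{p:g}_R{100 * f:g}",
                        donor=donor,
                        recipe=recipe,
                        volumes=volumes,
                        rbc_content=rbc,
                        platelet_content=plt,
                        retained_volume_fraction=retained,
                        diameter=diameter,
                        true_values=true_vals,
                        observed=observed,
                        softening=truth.softening,
                    )
                )
    return clots


def cohort_table(clots: Sequence[SyntheticClot]) -> pd.DataFrame:
    """Tidy per-clot DataFrame of design, blending, composition and observables."""
    rows = []
    for c in clots:
        row = {
            "clot_id": c.clot_id,
            "donor_id": c.donor.donor_id,
            "prp_platelet_conc": c.donor.prp_platelet_conc,
            "target_platelet_conc": c.recipe.target_platelet_conc,
            "rbc_volume_fraction": c.recipe.rbc_volume_fraction,
            "total_volume": c.recipe.total_volume,
            "v_prp": c.volumes.v_prp,
            "v_rbc": c.volumes.v_rbc,
            "v_pdp": c.volumes.v_pdp,
            "rbc_content": c.rbc_content,
            "platelet_content": c.platelet_content,
            "retained_volume_fraction": c.retained_volume_fraction,
            "diameter": c.diameter,
        }
        row.update(c.observed)
        row.update({f"true_{k}": v for k, v in c.true_values.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cyclic trace synthesis with closed-form features
# --------------------------------------------------------------------------


def window_poly_slope(power: int, lo_pct: float, hi_pct: float) -> float:
    """Continuous-OLS slope of eps^power regressed on eps over a strain window.

    Window bounds in % strain, strain handled as a fraction; closed form via
    exact polynomial moments.
    """
    a, b = lo_pct / 100.0, hi_pct / 100.0
    length = b - a

    def mom(p: int) -> float:
        return (b ** (p + 1) - a ** (p + 1)) / (p + 1)

    num = mom(power + 1) - mom(1) * mom(power) / length
    den = mom(2) - mom(1) ** 2 / length
    return num / den


class InfeasibleFeaturesError(ValueError):
    """Target feature set admits no valid loading/unloading construction."""


@dataclass(frozen=True)
class _TraceParams:
    """Solved curve family for one trace.

    Loading: sigma = A*eps + B*eps^5. Unloading over x = (eps-ep0)/(emax-ep0)
    uses the mix g(u) = w1*u + (1-w1)*u^m either directly
    (``sigma_max * g(x)``, convex, small enclosed area) or reflected
    (``sigma_max * (1 - g(1-x))``, concave, large enclosed area). The linear
    term of the mix keeps every slope finite, so the baseline crossing is
    sharp and trapezoidal integration is well behaved; the high power m
    controls the enclosed area.
    """

    A: float
    B: float
    sigma_max: float
    area_load: float
    ep0: float  # strain fraction where unloading stress vanishes
    w1: float  # linear-term weight of the mix
    m: float  # high power of the mix
    concave: bool  # True -> reflected mix (area coefficient > 1/2)
    mirror: bool  # reversible special case: unloading = reversed loading


def _solve_loading(low: float, high: float) -> Tuple[float, float]:
    k_lo = window_poly_slope(5, *LOW_STRAIN_WINDOW)
    k_hi = window_poly_slope(5, *HIGH_STRAIN_WINDOW)
    B = (high - low) / (k_hi - k_lo)
    A = low - B * k_lo
    if A <= 0 or B < 0:
        raise InfeasibleFeaturesError(
            f"no monotone loading curve for stiffness pair (low={low}, high={high}) kPa"
        )
    return A, B


def _load_area(A: float, B: float, emax: float = MAX_STRAIN_PCT / 100.0) -> float:
    return A * emax**2 / 2.0 + B * emax**6 / 6.0


_M_MAX = 200.0  # largest high-power exponent of the convex mix
_W1_MIN_PREFERRED = 0.05  # keep the linear term substantial when possible


def _solve_trace_params(
    low: float,
    high: float,
    hysteresis_pct: float,
    plastic_pct: float,
    baseline_tol: float = BASELINE_TOL_KPA,
) -> _TraceParams:
    """Solve the full curve family for exact target features.

    The unloading area coefficient c = A_unload / (sigma_max * w), with
    w = emax - ep0, selects the branch: c < 1/2 uses the mix g directly,
    c in [1/2, 1) the reflected mix with area coefficient 1 - c. The
    vanishing point ep0 is then shifted (fixed point, exact crossing by
    brentq) so that the strain where the unloading stress falls to
    ``baseline_tol`` — the extractor's operational plastic strain — equals
    the target.
    """
    A, B = _solve_loading(low, high)
    emax = MAX_STRAIN_PCT / 100.0
    sigma_max = A * emax + B * emax**5
    area_load = _load_area(A, B)
    if hysteresis_pct == 0.0 and plastic_pct == 0.0:
        return _TraceParams(A, B, sigma_max, area_load, 0.0, 1.0, 1.0, False, mirror=True)
    if not 0.0 < hysteresis_pct < 100.0:
        raise InfeasibleFeaturesError(f"hysteresis {hysteresis_pct}% outside (0, 100)")
    ep_star = plastic_pct / 100.0
    if not 0.0 <= ep_star < emax:
        raise InfeasibleFeaturesError(f"plastic strain {plastic_pct}% outside [0, 80)")
    area_unload = area_load * (1.0 - hysteresis_pct / 100.0)
    t = baseline_tol / sigma_max

    ep0 = ep_star
    w1 = 0.0
    m: float = 0.0
    concave = False
    for _ in range(100):
        w = emax - ep0
        if w <= 0:
            raise InfeasibleFeaturesError("unloading window collapsed; plastic target too high")
        c = area_unload / (sigma_max * w)
        if c >= 1.0:
            raise InfeasibleFeaturesError(
                f"hysteresis {hysteresis_pct:.1f}% below the absolute minimum for this "
                f"loading curve and plastic strain (unloading area would exceed its bound)"
            )
        concave = c >= 0.5
        c_mix = 1.0 - c if concave else c
        if m == 0.0:  # select the high power once; only ever increase it
            m = 8.0
            while m < _M_MAX and (
                c_mix < 1.0 / (m + 1.0) + 1e-9 or _w1_of(c_mix, m) < _W1_MIN_PREFERRED
            ):
                m = min(m * 2.0, _M_MAX)
        while m < _M_MAX and c_mix < 1.0 / (m + 1.0) + 1e-9:
            m = min(m * 2.0, _M_MAX)
        w1 = _w1_of(c_mix, m)
        if not 0.0 <= w1 <= 1.0:
            raise InfeasibleFeaturesError(
                f"hysteresis {hysteresis_pct:.1f}% outside the reachable range "
                f"for this loading curve and plastic strain"
            )
        if concave:
            # sigma(x) = sigma_max*(1 - g(1-x)); crossing where g(y) = 1 - t
            y_t = brentq(lambda y: w1 * y + (1.0 - w1) * y**m - (1.0 - t), 0.0, 1.0, xtol=1e-15)
            x_c = 1.0 - y_t
        else:
            x_c = brentq(lambda x: w1 * x + (1.0 - w1) * x**m - t, 0.0, 1.0, xtol=1e-15)
        ep0_new = ep_star - w * x_c
        if ep0_new < 0:
            raise InfeasibleFeaturesError(
                f"plastic strain target {plastic_pct:.2f}% below the baseline-crossing "
                f"width of the unloading curve"
            )
        if abs(ep0_new - ep0) < 1e-12:
            ep0 = ep0_new
            break
        ep0 = ep0_new
    else:
        raise InfeasibleFeaturesError("unloading construction did not converge")
    return _TraceParams(
        A, B, sigma_max, area_load, float(ep0), float(w1), float(m), concave, mirror=False
    )


def _w1_of(c: float, m: float) -> float:
    """Linear-term weight giving area coefficient c for the (linear, x^m) mix."""
    return (c - 1.0 / (m + 1.0)) / (0.5 - 1.0 / (m + 1.0))


def _loading_stress(params: _TraceParams, eps: np.ndarray) -> np.ndarray:
    return params.A * eps + params.B * eps**5


def _unloading_stress(params: _TraceParams, eps: np.ndarray) -> np.ndarray:
    if params.mirror:
        return _loading_stress(params, eps)
    emax = MAX_STRAIN_PCT / 100.0
    x = np.clip((eps - params.ep0) / (emax - params.ep0), 0.0, None)
    if params.concave:
        y = 1.0 - x
        return params.sigma_max * (1.0 - (params.w1 * y + (1.0 - params.w1) * y**params.m))
    return params.sigma_max * (params.w1 * x + (1.0 - params.w1) * x**params.m)


def feasible_feature_bounds(low: float, high: float, plastic_pct: float) -> Tuple[float, float]:
    """(min, max) hysteresis % reachable for a stiffness pair and plastic target."""
    A, B = _solve_loading(low, high)
    emax = MAX_STRAIN_PCT / 100.0
    sigma_max = A * emax + B * emax**5
    area_load = _load_area(A, B)
    w = emax - plastic_pct / 100.0
    c_max = 1.0 - 1.0 / (_M_MAX + 1.0)  # reflected-mix area limit
    c_min = 1.0 / (_M_MAX + 1.0)
    h_min = 100.0 * (1.0 - sigma_max * w * c_max / area_load)
    h_max = 100.0 * (1.0 - sigma_max * w * c_min / area_load)
    return max(h_min, 0.0), min(h_max, 100.0)


def generate_mech_trace(
    features: Mapping[str, float],
    diameter_mm: float,
    d_eps_pct: float = 0.1,
    n_cycles: int = 10,
    softening: float = 0.95,
    baseline_tol: float = BASELINE_TOL_KPA,
) -> Tuple[MechTrace, SectionGeometry, MechFeatures]:
    """Synthesise a cyclic record whose analytic features are the targets.

    ``features`` carries low_stiffness, high_stiffness (kPa),
    hysteresis_loss, plastic_strain (%). The returned
    :class:`~clotlab.mech.MechFeatures` are the analytic values (exact by
    construction); peak stresses decay by ``softening`` per cycle.
    """
    params = _solve_trace_params(
        features["low_stiffness"],
        features["high_stiffness"],
        features["hysteresis_loss"],
        features["plastic_strain"],
        baseline_tol=baseline_tol,
    )
    up = np.arange(0.0, MAX_STRAIN_PCT + d_eps_pct / 2, d_eps_pct)
    down = up[-2::-1]  # 80-d .. 0
    strain_parts: List[np.ndarray] = []
    stress_parts: List[np.ndarray] = []
    for k in range(n_cycles):
        scale = softening**k
        s_up = up if k == 0 else up[1:]  # valley sample shared between cycles
        strain_parts.append(s_up)
        stress_parts.append(scale * _loading_stress(params, s_up / 100.0))
        strain_parts.append(down)
        stress_parts.append(scale * _unloading_stress(params, down / 100.0))
    strain = np.concatenate(strain_parts)
    stress = np.concatenate(stress_parts)
    time = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(strain)) / STRAIN_RATE_PCT_S)])
    geometry = SectionGeometry(
        cross_sectional_area=math.pi * diameter_mm**2 / 4.0, feret_diameter=diameter_mm
    )
    force = stress * geometry.cross_sectional_area / 1000.0
    trace = MechTrace(time=time, strain=strain, force=force)
    analytic = MechFeatures(
        low_strain_stiffness=features["low_stiffness"],
        high_strain_stiffness=features["high_stiffness"],
        hysteresis_loss=features["hysteresis_loss"],
        plastic_strain=features["plastic_strain"],
        peak_stress_per_cycle=tuple(params.sigma_max * softening**k for k in range(n_cycles)),
    )
    return trace, geometry, analytic


def draw_feasible_features(
    rng: np.random.Generator,
    n: int = 1,
    baseline_tol: float = BASELINE_TOL_KPA,
) -> List[Dict[str, float]]:
    """Draw random feature targets from the feasible region (by rejection)."""
    out: List[Dict[str, float]] = []
    while len(out) < n:
        low = float(np.exp(rng.uniform(np.log(0.2), np.log(12.0))))
        high = low * float(np.exp(rng.uniform(np.log(4.0), np.log(150.0))))
        plastic = float(rng.uniform(10.0, 70.0))
        try:
            h_lo, h_hi = feasible_feature_bounds(low, high, plastic)
        except InfeasibleFeaturesError:
            continue
        if h_lo + 2.0 >= min(h_hi, 95.0) - 1.0:
            continue
        hyst = float(rng.uniform(h_lo + 2.0, min(h_hi, 95.0) - 1.0))
        cand = {
            "low_stiffness": low,
            "high_stiffness": high,
            "hysteresis_loss": hyst,
            "plastic_strain": plastic,
        }
        try:
            _solve_trace_params(low, high, hyst, plastic, baseline_tol=baseline_tol)
        except InfeasibleFeaturesError:
            continue
        out.append(cand)
    return out


def project_feasible_features(
    features: Mapping[str, float],
    baseline_tol: float = BASELINE_TOL_KPA,
    max_iter: int = 40,
) -> Tuple[Dict[str, float], bool]:
    """Nearest feasible feature set for trace synthesis.

    Linear observable models can produce targets outside the curve family's
    feasible region (e.g. negative stiffness for platelet-poor clots);
    trace synthesis needs a physically valid set. Returns the projected
    features and a flag indicating whether any adjustment was applied.
    """
    low = max(float(features["low_stiffness"]), 0.05)
    high = max(float(features["high_stiffness"]), low * 1.5)
    plastic = float(np.clip(features["plastic_strain"], 1.0, 75.0))
    hyst = float(np.clip(features["hysteresis_loss"], 1.0, 99.0))
    adjusted = not (
        math.isclose(low, features["low_stiffness"])
        and math.isclose(high, features["high_stiffness"])
        and math.isclose(plastic, features["plastic_strain"])
        and math.isclose(hyst, features["hysteresis_loss"])
    )
    def solvable(h: float, p: float) -> bool:
        try:
            _solve_trace_params(low, high, h, p, baseline_tol=baseline_tol)
            return True
        except InfeasibleFeaturesError:
            return False

    for _ in range(max_iter):
        h_lo, h_hi = feasible_feature_bounds(low, high, plastic)
        h_clipped = float(np.clip(hyst, h_lo + 0.25, h_hi - 0.25))
        if not solvable(h_clipped, plastic):
            # the analytic bounds ignore the baseline-crossing shift; for soft
            # sections (tol a sizeable fraction of peak stress) the reachable
            # hysteresis ceiling is lower — bisect down to the feasible edge
            lo_h, hi_h = h_lo + 0.25, h_clipped
            if not solvable(lo_h, plastic):
                plastic = min(plastic + 1.0, 75.0)
                adjusted = True
                continue
            for _ in range(40):
                mid = 0.5 * (lo_h + hi_h)
                if solvable(mid, plastic):
                    lo_h = mid
                else:
                    hi_h = mid
            h_clipped = lo_h
        if not math.isclose(h_clipped, hyst):
            adjusted = True
        return (
            {
                "low_stiffness": low,
                "high_stiffness": high,
                "hysteresis_loss": h_clipped,
                "plastic_strain": plastic,
            },
            adjusted,
        )
    raise InfeasibleFeaturesError(f"could not project features {dict(features)} to feasibility")


# --------------------------------------------------------------------------
# CT phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CTPhantomParams:
    """Geometry and contrast model for the cylindrical scan phantom."""

    tube_diameter: float = 10.0  # mm, media-filled container
    voxel_size: Tuple[float, float, float] = (0.5, 0.12, 0.12)  # mm (z, y, x)
    media_hu: float = 10.0
    contrast_hu: float = 340.0  # media HU increase after contrast admixture
    noise_sigma: float = 3.0  # voxel HU noise
    clot_length: float = 6.0  # mm along z
    pad_slices: int = 2  # media-only slices capping each end


def generate_ct_phantom(
    clot: SyntheticClot,
    params: CTPhantomParams = CTPhantomParams(),
    seed: int = 0,
) -> Tuple[CTImage, CTImage]:
    """Aligned (NCCT, CECT) phantom pair for one clot.

    The clot cylinder carries the clot's NCCT density; the CECT grid adds
    the contrast increment to the media and the clot's CECT density
    increase (floored at 0, since contrast cannot remove attenuation) to
    clot voxels. With ``noise_sigma`` = 0 the ROI protocol recovers both
    densities exactly.
    """
    dz, dy, dx = params.voxel_size
    if clot.diameter >= params.tube_diameter:
        raise ValueError(
            f"clot diameter {clot.diameter:.2f} mm does not fit the "
            f"{params.tube_diameter:.2f} mm tube"
        )
    n_xy = int(np.ceil(params.tube_diameter / dx)) + 4
    nz = int(np.ceil(params.clot_length / dz)) + 2 * params.pad_slices
    cx = cy = n_xy * dx / 2.0
    x = (np.arange(n_xy) + 0.5) * dx
    y = (np.arange(n_xy) + 0.5) * dy
    xx, yy = np.meshgrid(x, y)
    in_clot_xy = (xx - cx) ** 2 + (yy - cy) ** 2 <= (clot.diameter / 2.0) ** 2
    mask = np.zeros((nz, n_xy, n_xy), dtype=bool)
    mask[params.pad_slices : nz - params.pad_slices] = in_clot_xy

    ncct_hu_val = clot.observed["ncct_density"]
    cect_inc = max(0.0, clot.observed["cect_increase"])
    ncct = np.full(mask.shape, params.media_hu, dtype=float)
    ncct[mask] = ncct_hu_val
    cect = np.full(mask.shape, params.media_hu + params.contrast_hu, dtype=float)
    cect[mask] = ncct_hu_val + cect_inc
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        ncct = ncct + rng.normal(0.0, params.noise_sigma, mask.shape)
        cect = cect + rng.normal(0.0, params.noise_sigma, mask.shape)
    voxel = (dz, dy, dx)
    return (
        CTImage(hu=ncct, voxel_size=voxel, clot_mask=mask),
        CTImage(hu=cect, voxel_size=voxel, clot_mask=mask.copy()),
    )


# --------------------------------------------------------------------------
# label masks
# --------------------------------------------------------------------------


def _clot_region_indices(shape: Tuple[int, int], n_pixels: int) -> Tuple[np.ndarray, np.ndarray]:
    """The n_pixels pixels nearest the grid centre (deterministic tie-break)."""
    ny, nx = shape
    if n_pixels > ny * nx:
        raise ValueError("requested clot region larger than the grid")
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy - (ny - 1) / 2.0) ** 2 + (xx - (nx - 1) / 2.0) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n_pixels]
    return np.unravel_index(order, shape)


def generate_label_mask(
    rbc_pct: float,
    platelet_pct: float,
    shape: Tuple[int, int] = (160, 160),
    style: Literal["exact", "blob"] = "exact",
    seed: int = 0,
    clot_pixels: int = 10_000,
    wbc_pct: float = 0.5,
    pixel_size: float = 0.23,
    blob_smoothing: float = 6.0,
) -> Tuple[histo.LabelMask, histo.LabelMask]:
    """(MSB-like, CD42b-like) label masks realising the given contents.

    ``exact`` style allocates pixel counts directly (contents are exact to
    the resolution of one pixel in ``clot_pixels``, i.e. 0.01% by default);
    ``blob`` style thresholds a smoothed Gaussian random field at the
    content quantile, giving spatially correlated component patches.
    """
    if rbc_pct < 0 or platelet_pct < 0 or rbc_pct + wbc_pct > 100.0 or platelet_pct > 100.0:
        raise ValueError(
            f"impossible composition: RBC {rbc_pct}%, platelet {platelet_pct}%, WBC {wbc_pct}%"
        )
    rng = np.random.default_rng(seed)
    region = _clot_region_indices(shape, clot_pixels)

    def build(class_pcts: Dict[int, float]) -> histo.LabelMask:
        labels = np.zeros(shape, dtype=np.uint8)
        labels[region] = histo.FIBRIN_OTHER
        if style == "exact":
            counts = {cls: int(round(p / 100.0 * clot_pixels)) for cls, p in class_pcts.items()}
            perm = rng.permutation(clot_pixels)
            start = 0
            for cls, cnt in counts.items():
                sel = perm[start : start + cnt]
                labels[region[0][sel], region[1][sel]] = cls
                start += cnt
        else:
            field_ = gaussian_filter(rng.standard_normal(shape), blob_smoothing)
            vals = field_[region]
            order = np.argsort(vals, kind="stable")
            start = 0
            for cls, p in class_pcts.items():
                cnt = int(round(p / 100.0 * clot_pixels))
                sel = order[start : start + cnt]
                labels[region[0][sel], region[1][sel]] = cls
                start += cnt
        return histo.LabelMask(labels=labels, pixel_size=pixel_size)

    msb = build({histo.RBC: rbc_pct, histo.WBC: wbc_pct})
    cd42b = build({histo.PLATELET: platelet_pct})
    return msb, cd42b


# --------------------------------------------------------------------------
# parameter-recovery study
# --------------------------------------------------------------------------

#: outcome -> (predictor columns, coefficient attribute names on the model)
RECOVERY_MODELS: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "ncct_density": (("rbc_content", "platelet_content"), ("b_rbc", "b_plt")),
    "cect_increase": (("platelet_content", "diameter"), ("b_plt", "b_diam")),
    "low_stiffness": (("rbc_content", "platelet_content"), ("b_rbc", "b_plt")),
    "high_stiffness": (("rbc_content", "platelet_content"), ("b_rbc", "b_plt")),
    "hysteresis_loss": (("rbc_content", "platelet_content"), ("b_rbc", "b_plt")),
    "plastic_strain": (("rbc_content", "platelet_content"), ("b_rbc", "b_plt")),
}


def _truth_model(truth: GenerativeTruth, outcome: str) -> LinearModel:
    if outcome == "ncct_density":
        return truth.ncct
    if outcome == "cect_increase":
        return truth.cect
    return truth.mech_models[outcome]


def recovery_study(
    truth: GenerativeTruth = DEFAULT_TRUTH,
    n_replicates: int = 200,
    seed: int = 0,
    n_donors: int = 6,
) -> pd.DataFrame:
    """Fit every generative model on replicate cohorts and score recovery.

    Each replicate regenerates the full cohort (fresh donors, contraction
    jitter and observable noise) and refits each outcome's multiple OLS
    with the generative predictors. The imaging outcomes carry additive HU
    noise and use classical t intervals; the mechanical outcomes carry
    multiplicative noise, so their intervals use heteroskedasticity-
    consistent (HC3) standard errors — classical intervals are not
    calibrated under variance proportional to the mean squared. Returns one
    row per (outcome, coefficient) with the truth, mean estimate, bias, 95%
    CI coverage and the Monte-Carlo standard error of the mean estimate.
    """
    from .stats import multiple_ols

    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    estimates: Dict[Tuple[str, str], List[float]] = {}
    covered: Dict[Tuple[str, str], List[bool]] = {}
    for rep_seed in seeds:
        table = cohort_table(generate_cohort(truth, n_donors=n_donors, seed=int(rep_seed)))
        for outcome, (preds, coef_names) in RECOVERY_MODELS.items():
            cov = "classical" if outcome in ("ncct_density", "cect_increase") else "HC3"
            res = multiple_ols(table[outcome], table[list(preds)], cov=cov)
            model = _truth_model(truth, outcome)
            for pred, coef_name in zip(preds, coef_names):
                key = (outcome, pred)
                beta_true = getattr(model, coef_name)
                lo, hi = res.ci95[pred]
                estimates.setdefault(key, []).append(res.beta[pred])
                covered.setdefault(key, []).append(lo <= beta_true <= hi)
    rows = []
    for (outcome, pred), est in estimates.items():
        preds, coef_names = RECOVERY_MODELS[outcome]
        coef_name = coef_names[preds.index(pred)]
        beta_true = getattr(_truth_model(truth, outcome), coef_name)
        est_arr = np.asarray(est)
        bias = float(est_arr.mean() - beta_true)
        mc_se = float(est_arr.std(ddof=1) / math.sqrt(len(est_arr)))
        rows.append(
            {
                "outcome": outcome,
                "predictor": pred,
                "beta_true": beta_true,
                "beta_mean": float(est_arr.mean()),
                "bias": bias,
                "rel_bias": bias / abs(beta_true) if beta_true != 0 else np.inf,
                "mc_se": mc_se,
                "coverage": float(np.mean(covered[(outcome, pred)])),
                "n_replicates": len(est),
            }
        )
    return pd.DataFrame(rows)
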