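"""Blending volumes for reconstituted blood clot analogues.

A clot analogue is mixed from three centrifugation fractions of citrated
blood: platelet-rich plasma (PRP), packed red blood cells (RBCs) and
platelet-depleted plasma (PDP). Given a donor's measured PRP platelet
concentration, the volumes that realise a target platelet concentration and
RBC volume fraction in a fixed total volume follow from conservation of
platelet number and of volume:

    v_prp = target_conc * total_volume / prp_conc
    v_rbc = rbc_volume_fraction * total_volume
    v_pdp = total_volume - v_prp - v_rbc

An infeasible recipe (the PRP and RBC volumes alone exceed the total) raises
:class:`InfeasibleRecipeError` rather than silently clamping, because a
clamped recipe would change the realised composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "DonorBlood",
    "ClotRecipe",
    "BlendingVolumes",
    "InfeasibleRecipeError",
    "compute_blending_volumes",
    "blend_table",
]

#: relative tolerance for volume conservation checks
VOLUME_RTOL = 1e-9


class InfeasibleRecipeError(ValueError):
    """Raised when no non-negative blending volumes realise the recipe."""


@dataclass(frozen=True)
class DonorBlood:
    """Measured blood values for one donor.

    Parameters
    ----------
    donor_id
        Donor label.
    prp_platelet_conc
        Measured platelet concentration of the donor's PRP fraction,
        in 10^3 platelets/ul. Must be positive.
    wb_platelet_conc
        Whole-blood platelet concentration (10^3 platelets/ul), optional.
    haematocrit
        Whole-blood haematocrit as a fraction in (0, 1), optional.
    fibrinogen
        Plasma fibrinogen in g/l, optional.
    """

    donor_id: str
    prp_platelet_conc: float
    wb_platelet_conc: Optional[float] = None
    haematocrit: Optional[float] = None
    fibrinogen: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.prp_platelet_conc > 0:
            raise ValueError(
                f"prp_platelet_conc must be > 0, got {self.prp_platelet_conc}"
            )
        if self.haematocrit is not None and not 0 < self.haematocrit < 1:
            raise ValueError(f"haematocrit must lie in (0, 1), got {self.haematocrit}")


@dataclass(frozen=True)
class ClotRecipe:
    """Target composition of one reconstituted clot.

    ``target_platelet_conc`` is in 10^3 platelets/ul (study levels 30, 90,
    270), ``rbc_volume_fraction`` a fraction in [0, 1) (study levels 0,
    0.005, 0.02, 0.05, 0.40) and ``total_volume`` in ul.
    """

    target_platelet_conc: float
    rbc_volume_fraction: float
    total_volume: float

    def __post_init__(self) -> None:
        if self.target_platelet_conc < 0:
            raise ValueError("target_platelet_conc must be >= 0")
        if not 0 <= self.rbc_volume_fraction < 1:
            raise ValueError("rbc_volume_fraction must lie in [0, 1)")
        if not self.total_volume > 0:
            raise ValueError("total_volume must be > 0")


@dataclass(frozen=True)
class BlendingVolumes:
    """Non-negative PRP/RBC/PDP volumes (ul) summing to the total volume."""

    v_prp: float
    v_rbc: float
    v_pdp: float

    @property
    def total(self) -> float:
        return self.v_prp + self.v_rbc + self.v_pdp


def compute_blending_volumes(donor: DonorBlood, recipe: ClotRecipe) -> BlendingVolumes:
    """Solve the two conservation equations for the blending volumes.

    Platelet number: ``v_prp * prp_conc = target_conc * total_volume``
    (PDP and packed RBCs are taken as platelet-free). Volume:
    ``v_prp + v_rbc + v_pdp = total_volume``.

    Raises
    ------
    InfeasibleRecipeError
        If the required PRP volume alone exceeds the total volume ("PRP too
        dilute") or PRP plus RBC volumes do (naming both components).
    """
    total = recipe.total_volume
    v_prp = recipe.target_platelet_conc * total / donor.prp_platelet_conc
    v_rbc = recipe.rbc_volume_fraction * total
    slack = total * VOLUME_RTOL
    if v_prp > total + slack:
        raise InfeasibleRecipeError(
            f"PRP too dilute: reaching {recipe.target_platelet_conc} x10^3/ul in "
            f"{total} ul requires {v_prp:.1f} ul of PRP at "
            f"{donor.prp_platelet_conc} x10^3/ul (donor {donor.donor_id})"
        )
    if v_prp + v_rbc > total + slack:
        raise InfeasibleRecipeError(
            f"PRP + RBC volumes exceed total: {v_prp:.1f} + {v_rbc:.1f} ul "
            f"> {total} ul (donor {donor.donor_id}); the PRP requirement is the "
            f"limiting component"
        )
    v_pdp = max(total - v_prp - v_rbc, 0.0)
    return BlendingVolumes(v_prp=v_prp, v_rbc=v_rbc, v_pdp=v_pdp)


def blend_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised CSV interface: append v_prp/v_rbc/v_pdp columns.

    Expects columns donor_id, prp_platelet_conc, target_platelet_conc,
    rbc_volume_fraction, total_volume. Any infeasible row raises.
    """
    required = {
        "donor_id",
        "prp_platelet_conc",
        "target_platelet_conc",
        "rbc_volume_fraction",
        "total_volume",
    }
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    out = cohort.copy()
    vols = [
        compute_blending_volumes(
            DonorBlood(donor_id=str(row.donor_id), prp_platelet_conc=row.prp_platelet_conc),
            ClotRecipe(
                target_platelet_conc=row.target_platelet_conc,
                rbc_volume_fraction=row.rbc_volume_fraction,
                total_volume=row.total_volume,
            ),
        )
        for row in cohort.itertuples(index=False)
    ]
    out["v_prp"] = [v.v_prp for v in vols]
    out["v_rbc"] = [v.v_rbc for v in vols]
    out["v_pdp"] = [v.v_pdp for v in vols]
    return out
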