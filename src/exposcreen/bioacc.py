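"""Bioaccumulation factor from a single-fish steady-state mass balance.

The B metric is the steady-state bioaccumulation factor BAF (L/kg): the
ratio of whole-body chemical concentration in a mid-trophic-level fish to
the concentration in the water it lives in, with dietary uptake included
and the diet assumed in lipid equilibrium with the water.  The metric is
deliberately simple -- its job in the screening scheme is to respond to
the chemical's hydrophobicity (K_OW) and its whole-body biotransformation
rate, which are the two inputs that matter for ranking.  Users who have
externally estimated BAF values supply them through
``ChemicalRecord.log_baf_override``, which always takes precedence.

Rate constants (per day, referenced to fish wet weight):

* gill uptake      k1 = E_W * G_V / W,     E_W = 1 / (1.85 + 155 / K_OW)
* gill elimination k2 = k1 / (L_fish * K_OW)
* dietary uptake   kD = E_D * G_D / W,     E_D = 1 / (3e-7 * K_OW + 2)
* fecal egestion   kE = egestion_factor * kD
* growth dilution  kG, biotransformation   kM

    BAF = (k1 + kD * L_diet * K_OW) / (k2 + kE + kG + kM)

with gill ventilation G_V = c_V * W^x_V / dissolved_oxygen (L/d) and
feeding rate G_D = c_D * W^0.85 (kg/d).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict, fields
from typing import Optional

from .records import ChemicalRecord

logger = logging.getLogger(__name__)

FEEDING_ALLOMETRY_EXPONENT = 0.85


@dataclass(frozen=True)
class FishParameters:
    """Physiology of the model fish (a generic mid-trophic-level forage fish)."""

    body_mass: float = 0.2                    # kg wet weight
    lipid_fraction: float = 0.05              # kg lipid / kg fish
    diet_lipid_fraction: float = 0.05         # kg lipid / kg food
    gill_ventilation_coefficient: float = 1400.0  # L/d per kg^x / (mg O2/L)
    gill_ventilation_exponent: float = 0.65
    dissolved_oxygen: float = 8.0             # mg/L
    feeding_rate_coefficient: float = 0.022   # kg food/d per kg^0.85
    growth_rate: float = 5e-4                 # 1/d
    egestion_factor: float = 0.125            # kE = factor * kD

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if not (0 < self.lipid_fraction < 1 and 0 < self.diet_lipid_fraction < 1):
            raise ValueError("lipid fractions must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BafResult:
    log_baf: float                  # log10 L/kg
    k1: float = float("nan")        # gill uptake, L/kg/d
    kd: float = float("nan")        # dietary uptake, 1/d
    k2: float = float("nan")        # gill elimination, 1/d
    ke: float = float("nan")        # egestion, 1/d
    kg: float = float("nan")        # growth dilution, 1/d
    km: float = float("nan")        # biotransformation, 1/d
    source: str = "model"           # "model" or "override"


def compute_baf(
    record: ChemicalRecord, fish: Optional[FishParameters] = None
) -> BafResult:
    """Steady-state BAF for one chemical; override honored when present."""
    fish = fish or FishParameters()

    if record.log_baf_override is not None:
        if not (-2.0 < record.log_baf_override < 12.0):
            warnings.warn(
                f"{record.chem_id}: log BAF override "
                f"{record.log_baf_override} outside (-2, 12); kept",
                stacklevel=2,
            )
        return BafResult(log_baf=float(record.log_baf_override), source="override")

    kow = record.kow
    w = fish.body_mass
    gv = (
        fish.gill_ventilation_coefficient
        * w ** fish.gill_ventilation_exponent
        / fish.dissolved_oxygen
    )  # L/d
    gd = fish.feeding_rate_coefficient * w ** FEEDING_ALLOMETRY_EXPONENT  # kg/d

    ew = 1.0 / (1.85 + 155.0 / kow)
    ed = 1.0 / (3e-7 * kow + 2.0)

    k1 = ew * gv / w
    k2 = k1 / (fish.lipid_fraction * kow)
    kd = ed * gd / w
    ke = fish.egestion_factor * kd
    kg = fish.growth_rate
    km = float(record.k_biotransform or 0.0)

    baf = (k1 + kd * fish.diet_lipid_fraction * kow) / (k2 + ke + kg + km)
    return BafResult(
        log_baf=math.log10(baf),
        k1=k1, kd=kd, k2=k2, ke=ke, kg=kg, km=km,
        source="model",
    )


def apply_baf_column(records, fish: Optional[FishParameters] = None):
    """BAF for a sequence of records, as a DataFrame with provenance.

    Columns: ``chem_id, log_baf, baf_source, baf_error``.  Per-record
    failures are flagged and the batch continues.
    """
    import pandas as pd

    fish = fish or FishParameters()
    rows = []
    for rec in records:
        row = {"chem_id": rec.chem_id, "baf_error": ""}
        try:
            res = compute_baf(rec, fish)
            row.update(log_baf=res.log_baf, baf_source=res.source)
        except Exception as exc:  # per-record isolation for batch screening
            logger.warning("BAF failed for %s: %s", rec.chem_id, exc)
            row.update(log_baf=float("nan"), baf_source="error",
                       baf_error=str(exc))
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["chem_id", "log_baf", "baf_source", "baf_error"]
    )
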