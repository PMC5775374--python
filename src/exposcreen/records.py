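"""Core record type for one chemical's identity and physicochemical inputs.

All partition ratios are log10 and dimensionless; degradation half-lives
are in hours (the convention of screening-level property estimation
software); the optional bioaccumulation override is log10 L/kg and the
optional whole-body biotransformation rate is 1/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional


class InvalidRecordError(ValueError):
    """A chemical record violates its physical invariants."""


@dataclass
class ChemicalRecord:
    """One chemical and the properties the screening pipeline needs.

    Parameters
    ----------
    chem_id : str
        Unique identifier (CAS-style string or any stable key).
    log_kow : float
        log10 octanol-water partition ratio.
    log_kaw : float
        log10 air-water partition ratio (dimensionless Henry's law constant).
    t_half_air, t_half_water, t_half_soil : float
        Degradation half-lives in hours; must be strictly positive.
    pka, pkb : float, optional
        Acid / base dissociation constants used by the ionizability filter.
    log_baf_override : float, optional
        Externally estimated log10 BAF (L/kg); takes precedence over the
        internal fish mass balance when present.
    k_biotransform : float, optional
        Whole-body biotransformation rate constant, 1/day (default 0).
    """

    chem_id: str
    log_kow: float
    log_kaw: float
    t_half_air: float
    t_half_water: float
    t_half_soil: float
    name: str = ""
    formula: Optional[str] = None
    smiles: Optional[str] = None
    pka: Optional[float] = None
    pkb: Optional[float] = None
    log_baf_override: Optional[float] = None
    k_biotransform: Optional[float] = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for attr in ("log_kow", "log_kaw"):
            v = getattr(self, attr)
            if v is None or not math.isfinite(float(v)):
                raise InvalidRecordError(
                    f"{self.chem_id}: {attr} must be finite, got {v!r}"
                )
        for attr in ("t_half_air", "t_half_water", "t_half_soil"):
            v = getattr(self, attr)
            if v is None or not math.isfinite(float(v)) or float(v) <= 0.0:
                raise InvalidRecordError(
                    f"{self.chem_id}: {attr} must be strictly positive and "
                    f"finite, got {v!r}"
                )
        if self.k_biotransform is not None and self.k_biotransform < 0:
            raise InvalidRecordError(
                f"{self.chem_id}: k_biotransform must be >= 0"
            )

    @property
    def kow(self) -> float:
        return 10.0 ** self.log_kow

    @property
    def kaw(self) -> float:
        return 10.0 ** self.log_kaw

    @property
    def koa(self) -> float:
        """Octanol-air partition ratio, K_OA = K_OW / K_AW."""
        return 10.0 ** (self.log_kow - self.log_kaw)
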