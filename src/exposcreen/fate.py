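"""Evaluative multimedia fate model: Pov, CTD_air, CTD_water and TE.

A three-compartment (air / water / soil) steady-state mass balance in the
Mackay fugacity tradition.  Chemical is characterized by its air-water and
octanol-water partition ratios and first-order degradation half-lives in
each compartment; the model converts these into

* ``Pov``  -- overall persistence (days): the mass-weighted residence time
  with respect to degradation in a closed system,
* ``CTD_air`` / ``CTD_water`` -- characteristic travel distances (km): the
  distance the chemical is carried in the mobile medium before its mass
  declines to 1/e, computed as medium velocity x mobile mass fraction x
  overall residence time for emission into that medium,
* ``TE`` -- transfer efficiency (%): the fraction of chemical emitted to
  air in a source region that is deposited to surface media in an
  identical remote region fed only by the source region's air outflow.

Fugacity capacities are expressed relative to water (Z_water = 1), which
is sufficient because only capacity ratios enter the rate constants.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .environment import EnvironmentParameters, default_environment
from .records import ChemicalRecord, InvalidRecordError

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

AIR, WATER, SOIL = 0, 1, 2
COMPARTMENTS = ("air", "water", "soil")

# log Kp (m^3/ug) = log K_OA + log f_om - 11.91 : octanol-air absorption
# model for partitioning of gas-phase chemical to aerosol organic matter.
AEROSOL_LOGKP_CONSTANT = -11.91

# Half-lives at or above this value (hours) are treated as "no degradation".
INFINITE_HALF_LIFE = 1e14


class FateModelError(RuntimeError):
    """Numerical failure (singular or non-convergent mass balance)."""


@dataclass(frozen=True)
class FateMetrics:
    """Persistence and long-range transport metrics for one chemical."""

    pov_days: float
    ctd_air_km: float
    ctd_water_km: float
    te_percent: float


@dataclass(frozen=True)
class SteadyState:
    """Solved closed-system steady state for one emission scenario."""

    emission_mode: str
    emission_rate: float                 # mol/h
    masses: np.ndarray                   # mol, (air, water, soil)
    degradation_rates: np.ndarray        # 1/h, per compartment
    exchange_matrix: np.ndarray          # 1/h, columns sum to zero

    @property
    def degradation_losses(self) -> np.ndarray:
        """Degradation loss rate per compartment, mol/h."""
        return self.degradation_rates * self.masses

    @property
    def intermedia_fluxes(self) -> Dict[Tuple[str, str], float]:
        """Directed intermedia transfer fluxes, mol/h."""
        out = {}
        for i in range(3):
            for j in range(3):
                if i != j and self.exchange_matrix[j, i] > 0:
                    out[(COMPARTMENTS[i], COMPARTMENTS[j])] = (
                        self.exchange_matrix[j, i] * self.masses[i]
                    )
        return out

    @property
    def mass_balance_error(self) -> float:
        """Relative closure error |emission - total degradation| / emission."""
        return abs(self.emission_rate - self.degradation_losses.sum()) / (
            self.emission_rate
        )


def partitioning_fractions(
    record: ChemicalRecord, env: EnvironmentParameters | None = None
) -> Dict[str, Dict[str, float]]:
    """Phase fractions of chemical within each bulk compartment.

    Air splits into gas and aerosol-sorbed chemical; water into truly
    dissolved and suspended-solids-sorbed; soil into pore-air, pore-water
    and solid-sorbed chemical.  Fractions in each compartment sum to 1.
    """
    env = env or default_environment()
    if not (math.isfinite(record.log_kow) and math.isfinite(record.log_kaw)):
        raise InvalidRecordError(f"{record.chem_id}: non-finite partition ratio")

    kaw = record.kaw
    kow = record.kow

    # Air: gas vs aerosol via the octanol-air absorption model.
    log_kp = (record.log_kow - record.log_kaw) + math.log10(
        env.aerosol_om_fraction
    ) + AEROSOL_LOGKP_CONSTANT
    kp_tsp = 10.0 ** log_kp * env.aerosol_tsp  # dimensionless
    phi = kp_tsp / (1.0 + kp_tsp)

    # Water: dissolved vs sorbed to suspended solids.
    koc = env.koc_from_kow_factor * kow              # L/kg
    kd_ss = koc * env.ss_oc_fraction                 # L/kg
    ss_ratio = kd_ss * env.water_ss_conc * 1e-3      # (L/kg)(kg/m^3)(m^3/L)
    f_dissolved = 1.0 / (1.0 + ss_ratio)

    # Soil: pore air / pore water / solids, on a fugacity-capacity basis.
    z_gas = kaw
    z_w = 1.0
    kd_soil = koc * env.soil_oc_fraction             # L/kg
    z_solid = kd_soil * env.SOLID_DENSITY_KG_L       # dimensionless vs water
    za = env.SOIL_AIR_FRACTION * z_gas
    zw = env.SOIL_WATER_FRACTION * z_w
    zs = env.SOIL_SOLID_FRACTION * z_solid
    z_soil = za + zw + zs

    return {
        "air": {"gas": 1.0 - phi, "aerosol": phi},
        "water": {"dissolved": f_dissolved, "sorbed": 1.0 - f_dissolved},
        "soil": {
            "pore_air": za / z_soil,
            "pore_water": zw / z_soil,
            "solids": zs / z_soil,
        },
    }


def _bulk_z(record: ChemicalRecord, env: EnvironmentParameters):
    """Bulk fugacity capacities (relative to water) and helper quantities."""
    fr = partitioning_fractions(record, env)
    phi = fr["air"]["aerosol"]
    f_diss = fr["water"]["dissolved"]
    z_gas = record.kaw
    # Bulk Z chosen so the aerosol/sorbed fractions come out as computed.
    # Guard the phi -> 1 limit (extremely sorbing chemicals).
    z_air = z_gas / max(1.0 - phi, 1e-15)
    z_water = 1.0 / max(f_diss, 1e-15)
    kd_soil = env.koc_from_kow_factor * record.kow * env.soil_oc_fraction
    z_solid = kd_soil * env.SOLID_DENSITY_KG_L
    z_soil = (
        env.SOIL_AIR_FRACTION * z_gas
        + env.SOIL_WATER_FRACTION * 1.0
        + env.SOIL_SOLID_FRACTION * z_solid
    )
    return z_air, z_water, z_soil, z_gas, z_solid, phi


def build_rate_matrix(
    record: ChemicalRecord, env: EnvironmentParameters | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """First-order intermedia exchange matrix T (1/h) and degradation vector.

    ``T[j, i]`` is the rate coefficient for transfer from compartment i to
    j; diagonal entries hold the negative column totals so that each
    column sums to zero (transfers conserve mass).  The degradation vector
    is ``ln 2 / t_half`` per compartment, with very long half-lives
    treated as non-degrading.

    Processes: air-water two-film diffusion, rain dissolution, wet and dry
    aerosol deposition; air-soil boundary-layer diffusion and deposition;
    soil volatilization; soil-to-water runoff of water and solids.
    """
    env = env or default_environment()
    z_air, z_water, z_soil, z_gas, z_solid, phi = _bulk_z(record, env)

    a_w, a_s = env.area_water, env.area_soil
    v = np.array([env.volume_air, env.volume_water, env.volume_soil])

    # D values (capacity-weighted conductances, m^3/h on the relative-Z scale)
    # Air-water diffusion (two-film; same D both directions).
    d_aw_diff = a_w / (
        1.0 / (env.mtc_air_side * max(z_gas, 1e-300))
        + 1.0 / (env.mtc_water_side * 1.0)
    )
    # One-way air -> water wet/dry processes.
    d_rain_w = a_w * env.rain_rate * 1.0
    d_wet_w = a_w * env.rain_rate * env.wet_scavenging_ratio * phi * z_air
    d_dry_w = a_w * env.particle_dep_velocity * phi * z_air

    # Air-soil diffusion through the atmospheric boundary layer.
    d_as_diff = a_s * env.mtc_air_soil * max(z_gas, 1e-300)
    d_rain_s = a_s * env.rain_rate * 1.0
    d_wet_s = a_s * env.rain_rate * env.wet_scavenging_ratio * phi * z_air
    d_dry_s = a_s * env.particle_dep_velocity * phi * z_air

    # Soil -> water runoff.
    d_run_w = a_s * env.soil_runoff_rate_water * 1.0
    d_run_s = a_s * env.soil_runoff_rate_solids * z_solid

    d = np.zeros((3, 3))  # d[j, i]: D value for i -> j
    d[WATER, AIR] = d_aw_diff + d_rain_w + d_wet_w + d_dry_w
    d[AIR, WATER] = d_aw_diff
    d[SOIL, AIR] = d_as_diff + d_rain_s + d_wet_s + d_dry_s
    d[AIR, SOIL] = d_as_diff
    d[WATER, SOIL] = d_run_w + d_run_s

    z_bulk = np.array([z_air, z_water, z_soil])
    t = d / (v * z_bulk)[None, :]  # rate constant i -> j, 1/h
    np.fill_diagonal(t, 0.0)
    np.fill_diagonal(t, -t.sum(axis=0))

    halves = np.array(
        [record.t_half_air, record.t_half_water, record.t_half_soil], float
    )
    k_deg = np.where(halves >= INFINITE_HALF_LIFE, 0.0, LN2 / halves)

    if not np.any(np.abs(t) > 0) and not np.any(k_deg > 0):
        raise FateModelError(
            f"{record.chem_id}: degenerate system (all rates zero)"
        )
    return t, k_deg


def solve_steady_state(
    record: ChemicalRecord,
    env: EnvironmentParameters | None = None,
    emission_mode: str = "air",
    emission_rate: float = 1.0,
) -> SteadyState:
    """Closed-system steady state for emission into one compartment.

    Solves ``(T - diag(k_deg)) m + e = 0`` by direct linear solve.  No
    advective losses: at steady state all emitted chemical is degraded,
    which is the premise of the overall-persistence metric.
    """
    env = env or default_environment()
    if emission_mode not in COMPARTMENTS:
        raise ValueError(f"unknown emission mode {emission_mode!r}")
    if emission_rate <= 0:
        raise ValueError("emission_rate must be > 0")

    t, k_deg = build_rate_matrix(record, env)
    if not np.any(k_deg > 0):
        raise FateModelError(
            f"{record.chem_id}: no degradation anywhere; closed-system "
            "steady state does not exist (infinite accumulation)"
        )
    a = t - np.diag(k_deg)
    e = np.zeros(3)
    e[COMPARTMENTS.index(emission_mode)] = emission_rate
    try:
        m = np.linalg.solve(a, -e)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FateModelError(f"{record.chem_id}: singular mass balance") from exc
    if not np.all(np.isfinite(m)) or np.any(m < -1e-9 * m.max()):
        raise FateModelError(f"{record.chem_id}: non-physical steady state")
    m = np.clip(m, 0.0, None)
    return SteadyState(
        emission_mode=emission_mode,
        emission_rate=emission_rate,
        masses=m,
        degradation_rates=k_deg,
        exchange_matrix=t,
    )


def compute_pov(state: SteadyState) -> float:
    """Overall persistence in days: total mass over total degradation rate."""
    total_loss = float(state.degradation_losses.sum())
    if total_loss <= 0.0:
        warnings.warn(
            "all half-lives effectively infinite; Pov reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return float(state.masses.sum()) / total_loss / 24.0


def compute_ctd(
    record: ChemicalRecord,
    env: EnvironmentParameters | None = None,
    medium: str = "air",
) -> float:
    """Characteristic travel distance (km) in air or water.

    CTD = u_medium x (mass fraction in medium) x overall residence time,
    for emission into that medium.
    """
    env = env or default_environment()
    if medium not in ("air", "water"):
        raise ValueError("CTD is defined for 'air' or 'water' only")
    state = solve_steady_state(record, env, emission_mode=medium)
    tau_h = compute_pov(state) * 24.0
    if not math.isfinite(tau_h):
        return math.inf
    idx = COMPARTMENTS.index(medium)
    mobile_fraction = float(state.masses[idx] / state.masses.sum())
    u = env.wind_speed if medium == "air" else env.water_current  # m/s
    return u * 3600.0 * mobile_fraction * tau_h / 1000.0  # km


def compute_te(
    record: ChemicalRecord, env: EnvironmentParameters | None = None
) -> float:
    """Transfer efficiency (%): remote-region deposition per unit emission.

    Two identical regions: region 1 receives the emission to air and loses
    chemical by advective air outflow (rate wind_speed / length_scale);
    that outflow is the sole input to region 2, which has the same outflow
    sink.  TE is the net air-to-surface deposition flux in region 2 as a
    percentage of the region-1 emission rate.
    """
    env = env or default_environment()
    t, k_deg = build_rate_matrix(record, env)
    k_adv = env.wind_speed * 3600.0 / env.length_scale  # 1/h, air only
    sink = np.diag(k_deg)
    sink[AIR, AIR] += k_adv
    a = t - sink

    emission = 1.0  # mol/h into region-1 air
    e1 = np.array([emission, 0.0, 0.0])
    try:
        m1 = np.linalg.solve(a, -e1)
        outflow = k_adv * m1[AIR]
        e2 = np.array([outflow, 0.0, 0.0])
        m2 = np.linalg.solve(a, -e2)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FateModelError(f"{record.chem_id}: singular TE system") from exc

    dep = (
        t[WATER, AIR] * m2[AIR] - t[AIR, WATER] * m2[WATER]
        + t[SOIL, AIR] * m2[AIR] - t[AIR, SOIL] * m2[SOIL]
    )
    te = 100.0 * dep / emission
    return float(min(max(te, 0.0), 100.0))


def compute_fate_metrics(
    record: ChemicalRecord, env: EnvironmentParameters | None = None
) -> FateMetrics:
    """All four fate metrics for one chemical.

    Pov is reported as the maximum over the three single-medium emission
    scenarios (a conservative screening convention); CTD_air uses the
    air-emission scenario, CTD_water the water-emission scenario, and TE
    the two-region air-emission construction.
    """
    env = env or default_environment()
    pov = max(
        compute_pov(solve_steady_state(record, env, emission_mode=mode))
        for mode in COMPARTMENTS
    )
    return FateMetrics(
        pov_days=pov,
        ctd_air_km=compute_ctd(record, env, "air"),
        ctd_water_km=compute_ctd(record, env, "water"),
        te_percent=compute_te(record, env),
    )


def fate_metrics_table(records, env: EnvironmentParameters | None = None):
    """Fate metrics for a sequence of records as a pandas DataFrame.

    Per-chemical failures do not abort the batch: the offending row gets
    NaN metrics and an entry in the ``fate_error`` column.
    """
    import pandas as pd

    env = env or default_environment()
    rows = []
    for rec in records:
        row = {"chem_id": rec.chem_id, "fate_error": ""}
        try:
            fm = compute_fate_metrics(rec, env)
            row.update(
                pov_days=fm.pov_days,
                ctd_air_km=fm.ctd_air_km,
                ctd_water_km=fm.ctd_water_km,
                te_percent=fm.te_percent,
            )
        except (FateModelError, InvalidRecordError) as exc:
            logger.warning("fate metrics failed for %s: %s", rec.chem_id, exc)
            row.update(
                pov_days=np.nan,
                ctd_air_km=np.nan,
                ctd_water_km=np.nan,
                te_percent=np.nan,
                fate_error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
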