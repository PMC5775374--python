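"""Synthetic chemical-property tables for pipeline testing and demos.

The real screening database (thousands of production chemicals with
software-estimated properties) and the 148-chemical reference list are not
redistributable, so this module generates statistically similar stand-ins:

* a *screening set* spanning the clipped property domain
  (log K_OW in [-4, 10], log K_AW in [-12, 3]) with right-skewed
  (log-normal) degradation half-lives, a configurable minority of
  ionizable records (pKa < 5 or pKb > 8), and molecular formulas whose
  element prevalences and halogen-count distributions mimic a commerce
  chemical inventory (~13% Cl, ~4% F, ~3% Br, mostly C/H/O/N skeletons);
* a *reference fixture* of well-characterized-contaminant-like records in
  the narrower reference property space (log K_OW in (-2, 10), log K_AW
  in (-10, 2)), biased toward persistent/bioaccumulative combinations so
  the raw profile scores span several orders of magnitude.

Everything is deterministic given (config, seed).  The fixture is
synthetic: it supports testing and demonstration, not regulatory
benchmarking against the real reference chemicals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .bioacc import FishParameters, compute_baf
from .curation import LOG_KAW_BOUNDS, LOG_KOW_BOUNDS
from .environment import (
    EnvironmentParameters,
    default_environment,
    parameterization_fingerprint,
)
from .fate import compute_fate_metrics
from .records import ChemicalRecord
from .scoring import PROFILES, ReferenceSet

# Element prevalence of the synthetic screening set (fraction of records
# containing >= 1 atom), shaped like a large chemicals-in-commerce
# inventory: oxygen and nitrogen common, chlorine ~13%, fluorine ~4%.
DEFAULT_ELEMENT_PREVALENCE: Dict[str, float] = {
    "F": 0.038, "Cl": 0.131, "Br": 0.029, "I": 0.003,
    "N": 0.363, "S": 0.101, "P": 0.030, "O": 0.816,
    "Si": 0.028, "B": 0.003,
}

# Per-element atom-count distributions given presence.  Halogen shapes:
# fluorination peaks at 3 atoms (terminal -CF3) with odd counts more
# common than even; chlorination peaks at 2 with 4 second; bromination and
# iodination are mostly single-atom.
DEFAULT_COUNT_DISTRIBUTIONS: Dict[str, Dict[int, float]] = {
    "F": {1: 0.25, 2: 0.14, 3: 0.32, 4: 0.06, 5: 0.09, 6: 0.04, 7: 0.06, 9: 0.04},
    "Cl": {1: 0.12, 2: 0.52, 3: 0.06, 4: 0.18, 5: 0.04, 6: 0.08},
    "Br": {1: 0.60, 2: 0.20, 3: 0.05, 4: 0.10, 5: 0.03, 6: 0.02},
    "I": {1: 0.80, 2: 0.10, 3: 0.10},
    "N": {1: 0.50, 2: 0.30, 3: 0.12, 4: 0.08},
    "S": {1: 0.80, 2: 0.15, 3: 0.05},
    "P": {1: 0.85, 2: 0.10, 3: 0.05},
    "O": {1: 0.35, 2: 0.30, 3: 0.15, 4: 0.10, 5: 0.05, 6: 0.05},
    "Si": {1: 0.40, 2: 0.25, 3: 0.15, 4: 0.10, 6: 0.05, 8: 0.05},
    "B": {1: 0.90, 2: 0.10},
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic screening-set generator."""

    n_chemicals: int = 1000
    log_kow_range: Tuple[float, float] = LOG_KOW_BOUNDS
    log_kaw_range: Tuple[float, float] = LOG_KAW_BOUNDS
    log_kow_mean: float = 3.0
    log_kow_sd: float = 2.5
    log_kaw_mean: float = -4.0
    log_kaw_sd: float = 3.0
    # log-normal half-lives (hours): medians ~100 h air, 900 h water,
    # 1800 h soil, with wide spread (right-skewed)
    half_life_log_mean: Dict[str, float] = field(
        default_factory=lambda: {
            "air": float(np.log(100.0)),
            "water": float(np.log(900.0)),
            "soil": float(np.log(1800.0)),
        }
    )
    half_life_log_sd: Dict[str, float] = field(
        default_factory=lambda: {"air": 1.5, "water": 1.2, "soil": 1.2}
    )
    ionizable_fraction: float = 0.315
    unknown_ionization_fraction: float = 0.05
    element_prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_PREVALENCE)
    )
    halogen_count_distributions: Dict[str, Dict[int, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COUNT_DISTRIBUTIONS.items()
        }
    )

    def __post_init__(self) -> None:
        if self.n_chemicals <= 0:
            raise ValueError("n_chemicals must be > 0")
        for rng in (self.log_kow_range, self.log_kaw_range):
            if not rng[0] < rng[1]:
                raise ValueError("property ranges must be ordered (low, high)")
        for name in ("ionizable_fraction", "unknown_ionization_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for el, p in self.element_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {el} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_clipped_normal(rng, mean, sd, lo, hi, n):
    return np.clip(rng.normal(mean, sd, n), lo, hi)


def _sample_counts(rng, dist: Dict[int, float], n: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys], float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=n, p=probs)


def _assemble_formula(c: int, h: int, hetero: Dict[str, int]) -> str:
    """Hill notation: C, H, then remaining elements alphabetically."""
    parts = []
    if c:
        parts.append(f"C{c if c > 1 else ''}")
    if h:
        parts.append(f"H{h if h > 1 else ''}")
    for el in sorted(hetero):
        n = hetero[el]
        if n:
            parts.append(f"{el}{n if n > 1 else ''}")
    return "".join(parts)


def generate_screening_set(
    config: Optional[SyntheticConfig] = None, seed: int = 0
) -> List[ChemicalRecord]:
    """Deterministic synthetic screening set of ChemicalRecord objects."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    n = config.n_chemicals

    log_kow = _sample_clipped_normal(
        rng, config.log_kow_mean, config.log_kow_sd, *config.log_kow_range, n=n
    )
    log_kaw = _sample_clipped_normal(
        rng, config.log_kaw_mean, config.log_kaw_sd, *config.log_kaw_range, n=n
    )
    halves = {
        c: np.exp(
            rng.normal(config.half_life_log_mean[c], config.half_life_log_sd[c], n)
        )
        for c in ("air", "water", "soil")
    }

    # Ionization: a configured minority is ionizable (pKa < 5 acids or
    # pKb > 8 bases, split evenly); a small fraction carries no estimate.
    u = rng.random(n)
    ionizable = u < config.ionizable_fraction
    unknown = (~ionizable) & (
        u < config.ionizable_fraction + config.unknown_ionization_fraction
    )
    acid = rng.random(n) < 0.5
    pka = np.full(n, np.nan)
    pkb = np.full(n, np.nan)
    pka[ionizable & acid] = rng.uniform(0.0, 4.999, int((ionizable & acid).sum()))
    pkb[ionizable & ~acid] = rng.uniform(8.001, 14.0, int((ionizable & ~acid).sum()))
    neutral = ~ionizable & ~unknown
    pka[neutral] = rng.uniform(5.0, 14.0, int(neutral.sum()))
    pkb[neutral] = rng.uniform(0.0, 8.0, int(neutral.sum()))

    # Structures: carbon backbone, heteroatoms by prevalence, hydrogens to
    # roughly complete the valences.
    c_counts = np.maximum(1, np.rint(np.exp(rng.normal(np.log(12.0), 0.6, n)))).astype(int)
    hetero_counts: Dict[str, np.ndarray] = {}
    for el, prev in config.element_prevalence.items():
        present = rng.random(n) < prev
        counts = np.zeros(n, int)
        dist = config.halogen_count_distributions.get(el, {1: 1.0})
        counts[present] = _sample_counts(rng, dist, int(present.sum()))
        hetero_counts[el] = counts

    records = []
    for i in range(n):
        het = {el: int(hetero_counts[el][i]) for el in hetero_counts}
        n_halogen = sum(het.get(x, 0) for x in ("F", "Cl", "Br", "I"))
        h = max(0, 2 * int(c_counts[i]) + 2 + het.get("N", 0) - n_halogen)
        records.append(
            ChemicalRecord(
                chem_id=f"SYN-{seed}-{i:06d}",
                name=f"synthetic chemical {i}",
                formula=_assemble_formula(int(c_counts[i]), h, het),
                log_kow=float(log_kow[i]),
                log_kaw=float(log_kaw[i]),
                t_half_air=float(halves["air"][i]),
                t_half_water=float(halves["water"][i]),
                t_half_soil=float(halves["soil"][i]),
                pka=None if np.isnan(pka[i]) else float(pka[i]),
                pkb=None if np.isnan(pkb[i]) else float(pkb[i]),
            )
        )
    return records


def generate_reference_fixture(
    n: int = 148,
    seed: int = 0,
    env: Optional[EnvironmentParameters] = None,
    fish: Optional[FishParameters] = None,
) -> Tuple[ReferenceSet, List[ChemicalRecord]]:
    """Synthetic benchmark chemicals and their ReferenceSet of raw scores.

    Records span the reference chemical space (log K_OW in (-2, 10),
    log K_AW in (-10, 2)) with long, widely spread half-lives so the raw
    profile scores cover several orders of magnitude, as a set of legacy
    persistent contaminants would.  The ReferenceSet is built by running
    the full metric pipeline (fate model + BAF) on the records and carries
    the parameterization fingerprint.
    """
    if n < 2:
        raise ValueError("reference fixture needs n >= 2")
    env = env or default_environment()
    fish = fish or FishParameters()
    rng = np.random.default_rng(seed)

    # Oversample, keep the first n with strictly positive raw scores.
    n_pool = int(np.ceil(n * 1.5)) + 8
    log_kow = rng.uniform(-2.0, 10.0, n_pool)
    log_kaw = rng.uniform(-10.0, 2.0, n_pool)
    t_air = np.exp(rng.normal(np.log(300.0), 1.6, n_pool))
    t_water = np.exp(rng.normal(np.log(2000.0), 1.4, n_pool))
    t_soil = np.exp(rng.normal(np.log(4000.0), 1.4, n_pool))

    kept_records: List[ChemicalRecord] = []
    raw: Dict[str, List[float]] = {p: [] for p in PROFILES}
    for i in range(n_pool):
        if len(kept_records) == n:
            break
        rec = ChemicalRecord(
            chem_id=f"REF-{seed}-{i:04d}",
            name=f"synthetic reference chemical {i}",
            log_kow=float(log_kow[i]),
            log_kaw=float(log_kaw[i]),
            t_half_air=float(t_air[i]),
            t_half_water=float(t_water[i]),
            t_half_soil=float(t_soil[i]),
        )
        fm = compute_fate_metrics(rec, env)
        baf = 10.0 ** compute_baf(rec, fish).log_baf
        vals = {
            "pop": fm.pov_days * baf * fm.te_percent,
            "vpvb": fm.pov_days * baf,
            "apc": fm.pov_days * fm.ctd_air_km,
            "wpc": fm.pov_days * fm.ctd_water_km,
        }
        if any(not np.isfinite(v) or v <= 0.0 for v in vals.values()):
            continue
        kept_records.append(rec)
        for p in PROFILES:
            raw[p].append(vals[p])
    if len(kept_records) < n:  # pragma: no cover - extremely unlikely
        raise RuntimeError("could not generate enough valid reference records")

    ref = ReferenceSet(
        raw={p: np.array(raw[p]) for p in PROFILES},
        fingerprint=parameterization_fingerprint(env, fish),
        provenance=f"synthetic fixture (seed={seed}, n={n})",
    )
    return ref, kept_records


def records_to_frame(records: List[ChemicalRecord]) -> pd.DataFrame:
    """Tabular view of a record list (the on-disk column schema)."""
    from .io import records_to_table

    return records_to_table(records)
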