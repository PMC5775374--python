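"""Hazard profile scores and percentile benchmarking against a reference set.

Four exposure-based hazard profiles, each a multiplicative combination of
persistence (Pov, days), bioaccumulation (BAF, L/kg) and long-range
transport metrics (TE in %, CTDs in km):

* POP  = Pov x BAF x TE        (persistent, bioaccumulative, deposited remotely)
* vPvB = Pov x BAF             (no long-range transport term)
* APC  = Pov x CTD_air         (persistence x mobility in air)
* WPC  = Pov x CTD_water       (persistence x mobility in water)

Raw products have arbitrary units, so chemicals are benchmarked against a
reference set of well-characterized contaminants: the score for a profile
is the percentile rank 100 * (# reference chemicals with strictly smaller
raw score) / N_ref.  With N_ref reference chemicals there are N_ref + 1
attainable scores, from 0 (below every reference chemical) to 100 (above
all of them).  Scores over 90 / under 10 define the priority selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

PROFILES = ("pop", "vpvb", "apc", "wpc")


class ReferenceMismatchError(RuntimeError):
    """Reference set and screened batch use different parameterizations."""


@dataclass(frozen=True)
class HazardScores:
    raw_pop: float
    raw_vpvb: float
    raw_apc: float
    raw_wpc: float
    s_pop: float = float("nan")
    s_vpvb: float = float("nan")
    s_apc: float = float("nan")
    s_wpc: float = float("nan")


@dataclass
class ReferenceSet:
    """Per-profile sorted raw scores of the benchmark chemicals."""

    raw: Dict[str, np.ndarray]
    fingerprint: str = ""
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        sizes = set()
        for p in PROFILES:
            if p not in self.raw:
                raise ValueError(f"reference set missing profile {p!r}")
            arr = np.sort(np.asarray(self.raw[p], dtype=float))
            if arr.size == 0:
                raise ValueError("reference set is empty")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(
                    f"reference raw scores for {p!r} must be finite and > 0"
                )
            self.raw[p] = arr
            sizes.add(arr.size)
        if len(sizes) != 1:
            raise ValueError("profiles must have identical reference sizes")

    @property
    def n_ref(self) -> int:
        return int(self.raw["pop"].size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f"raw_{p}": self.raw[p] for p in PROFILES})

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# fingerprint: {self.fingerprint}\n")
            fh.write(f"# provenance: {self.provenance}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "ReferenceSet":
        fingerprint, provenance = "", "file"
        with open(path, "r", encoding="utf-8") as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key = key.strip()
                if key == "fingerprint":
                    fingerprint = val.strip()
                elif key == "provenance":
                    provenance = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        raw = {p: df[f"raw_{p}"].to_numpy() for p in PROFILES}
        return cls(raw=raw, fingerprint=fingerprint, provenance=provenance)


def raw_scores(
    pov_days: float,
    log_baf: float,
    te_percent: float,
    ctd_air_km: float,
    ctd_water_km: float,
) -> HazardScores:
    """Multiplicative raw profile scores on linear metric scales."""
    baf = 10.0 ** log_baf
    vals = (pov_days, baf, te_percent, ctd_air_km, ctd_water_km)
    if any(v < 0 or not math.isfinite(v) for v in vals):
        raise ValueError("metrics must be finite and non-negative")
    return HazardScores(
        raw_pop=pov_days * baf * te_percent,
        raw_vpvb=pov_days * baf,
        raw_apc=pov_days * ctd_air_km,
        raw_wpc=pov_days * ctd_water_km,
    )


def percentile_score(raw, reference: np.ndarray):
    """Percentile rank of raw score(s) against sorted reference scores.

    score = 100 * (# reference values strictly below raw) / N_ref; ties
    with a reference value count as *not* exceeding it (conservative).
    Accepts a scalar or an array of raw values.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference set must be non-empty")
    counts = np.searchsorted(reference, np.asarray(raw, dtype=float), side="left")
    score = 100.0 * counts / reference.size
    return float(score) if np.isscalar(raw) or np.ndim(raw) == 0 else score


def score_table(
    table: pd.DataFrame,
    reference: ReferenceSet,
    fingerprint: Optional[str] = None,
) -> pd.DataFrame:
    """Raw and percentile scores for a metrics table.

    ``table`` must carry columns ``pov_days, log_baf, te_percent,
    ctd_air_km, ctd_water_km``.  When both the batch fingerprint and the
    reference fingerprint are known they must match; scoring against a
    reference computed under a different parameterization is invalid.
    """
    if (
        fingerprint
        and reference.fingerprint
        and fingerprint != reference.fingerprint
    ):
        raise ReferenceMismatchError(
            f"batch parameterization {fingerprint} does not match reference "
            f"set parameterization {reference.fingerprint}"
        )
    out = table.copy()
    baf = 10.0 ** out["log_baf"].to_numpy(dtype=float)
    pov = out["pov_days"].to_numpy(dtype=float)
    raw = {
        "pop": pov * baf * out["te_percent"].to_numpy(dtype=float),
        "vpvb": pov * baf,
        "apc": pov * out["ctd_air_km"].to_numpy(dtype=float),
        "wpc": pov * out["ctd_water_km"].to_numpy(dtype=float),
    }
    for p in PROFILES:
        out[f"raw_{p}"] = raw[p]
        out[f"s_{p}"] = percentile_score(raw[p], reference.raw[p])
    return out


@dataclass(frozen=True)
class PriorityFlags:
    over90: Dict[str, bool]
    under10: Dict[str, bool]
    spatial_class: str  # global / far_field / near_field / none


def priority_flags(
    scores: Dict[str, float], hi: float = 90.0, lo: float = 10.0
) -> PriorityFlags:
    """High/low priority flags and the spatial-coverage class.

    ``scores`` maps profile name -> percentile score.  Over-90 and
    under-10 use strict inequalities.  Spatial class precedence:
    near-field (vPvB fit) > far-field (POP fit) > global (APC or WPC fit).
    """
    over = {p: scores[f"s_{p}" if f"s_{p}" in scores else p] > hi for p in PROFILES}
    under = {p: scores[f"s_{p}" if f"s_{p}" in scores else p] < lo for p in PROFILES}
    if over["vpvb"]:
        spatial = "near_field"
    elif over["pop"]:
        spatial = "far_field"
    elif over["apc"] or over["wpc"]:
        spatial = "global"
    else:
        spatial = "none"
    return PriorityFlags(over90=over, under10=under, spatial_class=spatial)


def flag_table(scored: pd.DataFrame, hi: float = 90.0, lo: float = 10.0) -> pd.DataFrame:
    """Vectorized priority flags appended to a scored table."""
    out = scored.copy()
    for p in PROFILES:
        out[f"over90_{p}"] = out[f"s_{p}"] > hi
        out[f"under10_{p}"] = out[f"s_{p}"] < lo
    spatial = np.where(
        out["over90_vpvb"],
        "near_field",
        np.where(
            out["over90_pop"],
            "far_field",
            np.where(out["over90_apc"] | out["over90_wpc"], "global", "none"),
        ),
    )
    out["spatial_class"] = spatial
    return out


def priority_summary(flagged: pd.DataFrame) -> Dict[str, int]:
    """Counts of the priority selections and cross-profile combinations."""
    over = {p: flagged[f"over90_{p}"].to_numpy(bool) for p in PROFILES}
    under = {p: flagged[f"under10_{p}"].to_numpy(bool) for p in PROFILES}
    any_over = np.zeros(len(flagged), bool)
    for p in PROFILES:
        any_over |= over[p]
    all_under = np.ones(len(flagged), bool)
    for p in PROFILES:
        all_under &= under[p]
    all_zero = np.ones(len(flagged), bool)
    for p in PROFILES:
        all_zero &= flagged[f"s_{p}"].to_numpy(float) == 0.0

    summary: Dict[str, int] = {"n": int(len(flagged))}
    for p in PROFILES:
        summary[f"over90_{p}"] = int(over[p].sum())
        others = np.zeros(len(flagged), bool)
        for q in PROFILES:
            if q != p:
                others |= over[q]
        summary[f"over90_only_{p}"] = int((over[p] & ~others).sum())
    summary["over90_any"] = int(any_over.sum())
    summary["under10_all"] = int(all_under.sum())
    summary["score_zero_all"] = int(all_zero.sum())
    # Spatial-coverage scheme combinations.
    summary["vpvb90"] = int(over["vpvb"].sum())
    summary["pop90_not_vpvb90"] = int((over["pop"] & ~over["vpvb"]).sum())
    summary["apc90_not_pop90"] = int((over["apc"] & ~over["pop"]).sum())
    summary["wpc90_not_pop90"] = int((over["wpc"] & ~over["pop"]).sum())
    return summary
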