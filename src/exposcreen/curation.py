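"""Data curation: ionizability exclusion and partition-ratio domain clipping.

Chemicals likely to be ionized at environmentally relevant pH (pKa < 5 for
acids, pKb > 8 for bases) are removed because the neutral-species
partitioning and BAF estimates do not apply to them.  Partition ratios
predicted outside the experimental domain of the estimation models are
clipped to the domain extrema: log K_OW to [-4, 10] and log K_AW to
[-12, 3]; the fate metrics are insensitive to changes beyond those bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

from .records import ChemicalRecord

PKA_THRESHOLD = 5.0
PKB_THRESHOLD = 8.0
LOG_KOW_BOUNDS = (-4.0, 10.0)
LOG_KAW_BOUNDS = (-12.0, 3.0)


@dataclass
class CurationReport:
    n_input: int = 0
    n_removed_ionizable: int = 0
    n_clipped_kow: int = 0
    n_clipped_kaw: int = 0
    n_invalid: int = 0
    n_output: int = 0
    removed_ids: List[str] = field(default_factory=list)
    invalid_ids: List[str] = field(default_factory=list)

    def as_text(self) -> str:
        lines = [
            f"input records:        {self.n_input}",
            f"removed (ionizable):  {self.n_removed_ionizable}",
            f"removed (invalid):    {self.n_invalid}",
            f"clipped log_kow:      {self.n_clipped_kow}",
            f"clipped log_kaw:      {self.n_clipped_kaw}",
            f"output records:       {self.n_output}",
        ]
        return "\n".join(lines)


def filter_ionizable(
    records: Sequence[ChemicalRecord],
    pka_threshold: float = PKA_THRESHOLD,
    pkb_threshold: float = PKB_THRESHOLD,
) -> Tuple[List[ChemicalRecord], CurationReport]:
    """Remove records likely ionized at environmental pH.

    A record is removed iff its pKa is present and strictly below
    ``pka_threshold``, or its pKb is present and strictly above
    ``pkb_threshold`` (both comparisons strict, so boundary values are
    kept).  Records lacking both values are kept and flagged
    ``ionization_unknown``.
    """
    if not (math.isfinite(pka_threshold) and math.isfinite(pkb_threshold)):
        raise ValueError("ionizability thresholds must be finite")
    kept: List[ChemicalRecord] = []
    report = CurationReport(n_input=len(records))
    for rec in records:
        acidic = rec.pka is not None and rec.pka < pka_threshold
        basic = rec.pkb is not None and rec.pkb > pkb_threshold
        if acidic or basic:
            report.n_removed_ionizable += 1
            report.removed_ids.append(rec.chem_id)
            continue
        if rec.pka is None and rec.pkb is None:
            if "ionization_unknown" not in rec.flags:
                rec = replace(rec, flags=rec.flags + ["ionization_unknown"])
        kept.append(rec)
    report.n_output = len(kept)
    return kept, report


def clip_partition_ratios(
    records: Sequence[ChemicalRecord],
    kow_bounds: Tuple[float, float] = LOG_KOW_BOUNDS,
    kaw_bounds: Tuple[float, float] = LOG_KAW_BOUNDS,
) -> Tuple[List[ChemicalRecord], CurationReport]:
    """Clamp log K_OW and log K_AW to the estimation-model domain.

    Non-finite partition ratios cannot be clipped meaningfully; such
    records are excluded and reported as invalid.
    """
    out: List[ChemicalRecord] = []
    report = CurationReport(n_input=len(records))
    for rec in records:
        if not (math.isfinite(rec.log_kow) and math.isfinite(rec.log_kaw)):
            report.n_invalid += 1
            report.invalid_ids.append(rec.chem_id)
            continue
        changes = {}
        flags = list(rec.flags)
        if not kow_bounds[0] <= rec.log_kow <= kow_bounds[1]:
            changes["log_kow"] = min(max(rec.log_kow, kow_bounds[0]), kow_bounds[1])
            flags.append("clipped_log_kow")
            report.n_clipped_kow += 1
        if not kaw_bounds[0] <= rec.log_kaw <= kaw_bounds[1]:
            changes["log_kaw"] = min(max(rec.log_kaw, kaw_bounds[0]), kaw_bounds[1])
            flags.append("clipped_log_kaw")
            report.n_clipped_kaw += 1
        if changes:
            rec = replace(rec, flags=flags, **changes)
        out.append(rec)
    report.n_output = len(out)
    return out, report


def curate(
    records: Sequence[ChemicalRecord],
    pka_threshold: float = PKA_THRESHOLD,
    pkb_threshold: float = PKB_THRESHOLD,
    kow_bounds: Tuple[float, float] = LOG_KOW_BOUNDS,
    kaw_bounds: Tuple[float, float] = LOG_KAW_BOUNDS,
) -> Tuple[List[ChemicalRecord], CurationReport]:
    """Full curation: ionizability filter followed by domain clipping."""
    kept, rep_ion = filter_ionizable(records, pka_threshold, pkb_threshold)
    clipped, rep_clip = clip_partition_ratios(kept, kow_bounds, kaw_bounds)
    report = CurationReport(
        n_input=len(records),
        n_removed_ionizable=rep_ion.n_removed_ionizable,
        n_clipped_kow=rep_clip.n_clipped_kow,
        n_clipped_kaw=rep_clip.n_clipped_kaw,
        n_invalid=rep_clip.n_invalid,
        n_output=len(clipped),
        removed_ids=rep_ion.removed_ids,
        invalid_ids=rep_clip.invalid_ids,
    )
    return clipped, report
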