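"""End-to-end screening pipeline: curate -> fate metrics -> BAF -> scores.

Ties the stages together with provenance: a run manifest records the
parameterization fingerprint, per-stage row counts and any per-record
failures, and every input row is accounted for in exactly one of the
scored output, the removed-records sidecar or the error report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .bioacc import FishParameters, apply_baf_column
from .curation import CurationReport, curate
from .environment import (
    EnvironmentParameters,
    default_environment,
    parameterization_fingerprint,
)
from .fate import fate_metrics_table
from .io import read_chemical_table, records_to_table
from .records import ChemicalRecord
from .scoring import ReferenceSet, flag_table, priority_summary, score_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    scored: pd.DataFrame
    curation_report: CurationReport
    summary: Dict[str, int]
    manifest: Dict = field(default_factory=dict)
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)
    errors: List = field(default_factory=list)


def run_pipeline(
    source: Union[str, Path, Sequence[ChemicalRecord]],
    reference: ReferenceSet,
    env: Optional[EnvironmentParameters] = None,
    fish: Optional[FishParameters] = None,
    output_dir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Run the full screen on a table path or a sequence of records.

    Stages: curation (ionizability filter + domain clipping), multimedia
    fate metrics, BAF, raw profile scores, percentile benchmarking against
    ``reference``, priority flags and summary counts.  The reference set's
    parameterization fingerprint must match the one computed from
    ``env`` and ``fish`` (empty fingerprints skip the check).
    """
    env = env or default_environment()
    fish = fish or FishParameters()
    fingerprint = parameterization_fingerprint(env, fish)

    if isinstance(source, (str, Path)):
        records, _ = read_chemical_table(source)
        input_path = str(source)
    else:
        records = list(source)
        input_path = "<in-memory>"

    kept, report = curate(records)
    removed_ids = set(report.removed_ids) | set(report.invalid_ids)
    removed = records_to_table([r for r in records if r.chem_id in removed_ids])

    metrics = fate_metrics_table(kept, env)
    baf = apply_baf_column(kept, fish)
    # the input's optional override column is superseded by the computed
    # log_baf (which already honors overrides via baf_source)
    table = (
        records_to_table(kept)
        .rename(columns={"log_baf": "log_baf_input"})
        .merge(metrics, on="chem_id")
        .merge(baf, on="chem_id")
    )

    failed = table["fate_error"].ne("") | table["baf_error"].ne("")
    errors = [
        (row.chem_id, row.fate_error or row.baf_error)
        for row in table[failed].itertuples()
    ]
    ok = table[~failed].reset_index(drop=True)

    scored = score_table(ok, reference, fingerprint=fingerprint)
    flagged = flag_table(scored)
    summary = priority_summary(flagged)

    manifest = {
        "exposcreen_version": __version__,
        "input": input_path,
        "parameterization_fingerprint": fingerprint,
        "reference_provenance": reference.provenance,
        "n_reference": reference.n_ref,
        "stage_counts": {
            "input": report.n_input,
            "removed_ionizable": report.n_removed_ionizable,
            "removed_invalid": report.n_invalid,
            "curated": report.n_output,
            "metric_failures": int(failed.sum()),
            "scored": int(len(flagged)),
        },
        "environment": env.to_dict(),
        "fish": fish.to_dict(),
        "summary": summary,
    }

    result = PipelineResult(
        scored=flagged,
        curation_report=report,
        summary=summary,
        manifest=manifest,
        removed=removed,
        errors=errors,
    )
    if output_dir is not None:
        _write_outputs(result, Path(output_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.scored.to_csv(out / "scored.csv", index=False, encoding="utf-8")
    result.removed.to_csv(out / "removed.csv", index=False, encoding="utf-8")
    (out / "curation_report.txt").write_text(
        result.curation_report.as_text() + "\n", encoding="utf-8"
    )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    if result.errors:
        err = pd.DataFrame(result.errors, columns=["chem_id", "error"])
        err.to_csv(out / "errors.csv", index=False, encoding="utf-8")
    logger.info("pipeline outputs written to %s", out)
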