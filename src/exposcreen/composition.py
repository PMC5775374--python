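"""Structural composition analytics over molecular formulas.

Element presence statistics, atom-count histograms and the association
between element content and hazard score, computed from the Hill-notation
molecular formulas of a screened chemical table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACKED_ELEMENTS = ("C", "H", "F", "Cl", "Br", "I", "N", "S", "P", "O", "Si", "B")

# Standard atomic masses (g/mol) for molecular-weight statistics.
ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "F": 18.998, "Cl": 35.45, "Br": 79.904,
    "I": 126.904, "N": 14.007, "S": 32.06, "P": 30.974, "O": 15.999,
    "Si": 28.085, "B": 10.81,
    # a few common extras so arbitrary formulas still get a weight
    "Na": 22.990, "K": 39.098, "Ca": 40.078, "Mg": 24.305, "Al": 26.982,
    "Fe": 55.845, "Zn": 65.38, "Cu": 63.546, "Sn": 118.71, "Se": 78.971,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed molecular formula."""


@dataclass
class ElementCounts:
    counts: Dict[str, int] = field(default_factory=dict)
    other: Dict[str, int] = field(default_factory=dict)

    def get(self, element: str) -> int:
        return self.counts.get(element, self.other.get(element, 0))

    @property
    def molecular_weight(self) -> Optional[float]:
        mw = 0.0
        for el, n in {**self.counts, **self.other}.items():
            if el not in ATOMIC_MASS:
                return None
            mw += ATOMIC_MASS[el] * n
        return mw


def parse_formula(formula: str) -> ElementCounts:
    """Parse a Hill-notation molecular formula into per-element counts.

    Multi-digit counts are supported; charges, isotopes and parenthesized
    groups are not.  Element symbols outside the tracked set land in the
    ``other`` map.
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    pos = 0
    result = ElementCounts()
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"malformed formula {formula!r} at position {pos}: "
                f"{formula[pos:m.start()]!r}"
            )
        pos = m.end()
        el, num = m.group(1), int(m.group(2) or 1)
        target = result.counts if el in TRACKED_ELEMENTS else result.other
        target[el] = target.get(el, 0) + num
    if pos != len(formula):
        raise FormulaError(
            f"malformed formula {formula!r} at position {pos}: "
            f"{formula[pos:]!r}"
        )
    return result


def _formula_of(rec) -> Optional[str]:
    """Formula string for a record or table row; SMILES fallback if possible."""
    formula = getattr(rec, "formula", None)
    if formula is None and isinstance(rec, dict):
        formula = rec.get("formula")
    if formula:
        return formula
    smiles = getattr(rec, "smiles", None)
    if smiles is None and isinstance(rec, dict):
        smiles = rec.get("smiles")
    if smiles:
        try:
            from rdkit import Chem
            from rdkit.Chem.rdMolDescriptors import CalcMolFormula

            mol = Chem.MolFromSmiles(smiles)
            if mol is not None:
                return CalcMolFormula(mol)
        except ImportError:
            pass
    return None


def _parse_records(records) -> list:
    """(chem_id, ElementCounts) for parseable records; unparseable skipped."""
    if isinstance(records, pd.DataFrame):
        it: Iterable = (row for _, row in records.iterrows())
    else:
        it = records
    parsed = []
    for rec in it:
        cid = getattr(rec, "chem_id", None)
        if cid is None and isinstance(rec, (dict, pd.Series)):
            cid = rec.get("chem_id", "?")
        formula = _formula_of(rec)
        if not formula:
            logger.warning("no formula for %s; excluded from composition", cid)
            continue
        try:
            parsed.append((cid, parse_formula(formula)))
        except FormulaError as exc:
            logger.warning("unparseable formula for %s: %s", cid, exc)
    return parsed


def presence_summary(records) -> pd.DataFrame:
    """Per-element presence percentages plus molecular-weight statistics.

    One row per tracked heteroelement with the percentage and count of
    parseable records containing at least one atom of it, and one ``MW``
    row with min/max/median/mean molecular weight.
    """
    parsed = _parse_records(records)
    n = len(parsed)
    rows = []
    for el in TRACKED_ELEMENTS:
        if el in ("C", "H"):
            continue
        containing = sum(1 for _, ec in parsed if ec.get(el) > 0)
        rows.append(
            {
                "element": el,
                "n_containing": containing,
                "percent": 100.0 * containing / n if n else 0.0,
            }
        )
    summary = pd.DataFrame(rows)
    mws = [ec.molecular_weight for _, ec in parsed]
    mws = np.array([m for m in mws if m is not None], float)
    summary.attrs["n_parseable"] = n
    summary.attrs["mw"] = {
        "min": float(mws.min()) if mws.size else float("nan"),
        "max": float(mws.max()) if mws.size else float("nan"),
        "median": float(np.median(mws)) if mws.size else float("nan"),
        "mean": float(mws.mean()) if mws.size else float("nan"),
    }
    return summary


def atom_count_histogram(records, element: str) -> Dict[int, int]:
    """Frequency of per-structure atom counts among records containing it."""
    if element not in TRACKED_ELEMENTS:
        raise ValueError(f"unknown element {element!r}")
    hist: Dict[int, int] = {}
    for _, ec in _parse_records(records):
        n = ec.get(element)
        if n > 0:
            hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))


def element_score_association(
    records,
    scores: Sequence[float],
    element: str,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean atoms-per-structure of ``element`` within equal-width score bins.

    Bins partition [0, 100]; all structures in a bin (including those with
    zero atoms of the element) enter the mean.  Empty bins are reported
    with NaN means, not zeros.
    """
    if element not in TRACKED_ELEMENTS:
        raise ValueError(f"unknown element {element!r}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 100)):
        raise ValueError("scores must lie on [0, 100]")
    parsed = _parse_records(records)
    if len(parsed) != scores.size:
        raise ValueError("records and scores must align one-to-one")
    counts = np.array([ec.get(element) for _, ec in parsed], float)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(mask.sum()),
                "mean_atoms": float(counts[mask].mean()) if mask.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)
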