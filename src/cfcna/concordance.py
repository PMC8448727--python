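"""Cross-depth copy-number concordance metrics.

Two statistics over paired gene-level category tables from the same
patients called at two sequencing depths:

* per-gene concordance across the cohort: percentage of eligible patients
  (tumor fraction at or above a cutoff, default 3%) whose 3-level category
  matches between depths;
* per-patient concordance across a gene panel: percentage of panel genes
  whose category matches.

Amplifications are recategorized as gains first, so only gain / loss /
neutral are compared.  No-call pairs are excluded from both numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import NO_CALL


@dataclass
class ConcordanceInput:
    """Paired cohort tables (genes x patients) plus per-patient tumor
    fractions used for eligibility (taken from the deep-depth estimate)."""

    table_a: pd.DataFrame
    table_b: pd.DataFrame
    tumor_fraction: pd.Series
    min_tumor_fraction: float = 0.03

    def __post_init__(self) -> None:
        if list(self.table_a.index) != list(self.table_b.index) or list(
            self.table_a.columns
        ) != list(self.table_b.columns):
            raise ValueError("paired tables mismatch")
        missing = set(self.table_a.columns) - set(self.tumor_fraction.index)
        if missing:
            raise ValueError(f"tumor fraction missing for patients: {sorted(missing)}")

    @property
    def patients(self) -> list[str]:
        return list(self.table_a.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.table_a.index)

    def eligible_patients(self) -> list[str]:
        tf = self.tumor_fraction
        return [p for p in self.patients if tf[p] >= self.min_tumor_fraction]


def recategorize_for_concordance(category: str) -> str:
    """Collapse amplification into gain; propagate no-call."""
    if category == "amplification":
        return "gain"
    if category in ("gain", "loss", "neutral", NO_CALL):
        return category
    raise ValueError(f"unknown category: {category!r}")


def _match_series(a: pd.Series, b: pd.Series) -> pd.Series:
    """Boolean match per element after recategorization; NaN where either
    side is a no-call."""
    ra = a.map(recategorize_for_concordance)
    rb = b.map(recategorize_for_concordance)
    valid = (ra != NO_CALL) & (rb != NO_CALL)
    out = pd.Series(np.nan, index=a.index, dtype=float)
    out[valid] = (ra[valid] == rb[valid]).astype(float)
    return out


def gene_concordance(inp: ConcordanceInput, gene: str) -> float:
    """Percentage of eligible patients whose category matches at ``gene``."""
    if gene not in inp.table_a.index:
        raise KeyError("gene not in cohort table")
    eligible = inp.eligible_patients()
    if not eligible:
        raise ValueError("no eligible samples")
    matches = _match_series(
        inp.table_a.loc[gene, eligible], inp.table_b.loc[gene, eligible]
    ).dropna()
    if matches.empty:
        raise ValueError("no eligible samples")
    return round(100.0 * matches.sum() / len(matches), 1)


def patient_concordance(
    inp: ConcordanceInput, patient: str, gene_panel: Sequence[str]
) -> float:
    """Percentage of panel genes matching between depths for one patient."""
    if not list(gene_panel):
        raise ValueError("empty gene panel")
    if inp.tumor_fraction[patient] < inp.min_tumor_fraction:
        raise ValueError("below tumor-fraction threshold")
    panel = list(gene_panel)
    matches = _match_series(
        inp.table_a.loc[panel, patient], inp.table_b.loc[panel, patient]
    ).dropna()
    if matches.empty:
        raise ValueError("no callable genes for patient")
    return round(100.0 * matches.sum() / len(matches), 1)


def tf_band(tf: float) -> str:
    if tf < 0.03:
        return "<3%"
    if tf <= 0.04:
        return "3-4%"
    return ">4%"


def concordance_report(
    inp: ConcordanceInput, gene_panel: Sequence[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Per-gene and per-patient concordance tables.

    The per-patient table covers eligible patients only and carries a
    tumor-fraction band label (<3%, 3-4%, >4%).
    """
    panel = list(gene_panel) if gene_panel is not None else inp.genes
    if not panel:
        raise ValueError("empty gene panel")
    per_gene = pd.DataFrame(
        {
            "gene": panel,
            "concordance_pct": [gene_concordance(inp, g) for g in panel],
        }
    )
    rows = []
    for p in inp.eligible_patients():
        rows.append(
            {
                "patient": p,
                "tumor_fraction": float(inp.tumor_fraction[p]),
                "tf_band": tf_band(float(inp.tumor_fraction[p])),
                "concordance_pct": patient_concordance(inp, p, panel),
            }
        )
    per_patient = pd.DataFrame(
        rows, columns=["patient", "tumor_fraction", "tf_band", "concordance_pct"]
    )
    return {"per_gene": per_gene, "per_patient": per_patient}
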