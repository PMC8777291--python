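"""Cross-omics integration of circRNA DE, ORF prediction, protein DE and
peptide evidence into a tiered candidate table.

Tiers are nested: ``predicted`` (a circRNA with a selected
junction-spanning ORF), ``expression-consistent`` (additionally
significant at both omics layers with the same direction of change — the
headline filter for circRNA-encoded novel proteins), and
``peptide-validated`` (additionally supported by at least one MS peptide
overlapping the circRNA-unique protein region).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .circ_orf import ORFCandidate
from .peptide_match import ValidationVerdict

TIER_PREDICTED = "predicted"
TIER_CONSISTENT = "expression-consistent"
TIER_VALIDATED = "peptide-validated"
_TIER_RANK = {TIER_VALIDATED: 0, TIER_CONSISTENT: 1, TIER_PREDICTED: 2}


@dataclass
class IntegratedCandidate:
    circ_id: str
    circ_log2fc: float | None
    circ_p: float | None
    protein_id: str | None
    protein_log2fc: float | None
    protein_p: float | None
    direction_consistent: bool
    validated_by_peptides: bool
    tier: str
    orf: ORFCandidate | None = None
    missing_layers: tuple[str, ...] = ()


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def cross_omics_candidates(
    de_circ: pd.DataFrame,
    de_protein: pd.DataFrame,
    orf_selection: Mapping[str, ORFCandidate],
    verdicts: Mapping[str, ValidationVerdict] | None = None,
    circ_to_protein: Mapping[str, str] | None = None,
) -> list[IntegratedCandidate]:
    """One row per ORF-bearing circRNA, tiered by cross-omics support.

    ``expression-consistent`` requires circRNA significance (FC>2,
    p<0.05), protein significance (FC>1.5, p<0.05) and matching sign of
    change; ``peptide-validated`` additionally requires a unique-region
    peptide.  A circRNA missing from either DE table stays in the
    ``predicted`` tier with the missing layer annotated.
    """
    verdicts = verdicts or {}
    circ_to_protein = circ_to_protein or {}
    out = []
    for circ_id in sorted(orf_selection):
        orf = orf_selection[circ_id]
        missing = []
        c_fc = c_p = c_sig = None
        if circ_id in de_circ.index:
            row = de_circ.loc[circ_id]
            c_fc, c_p, c_sig = float(row["log2fc"]), float(row["p_value"]), bool(row["significant"])
        else:
            missing.append("circ_de")
        prot_id = circ_to_protein.get(circ_id)
        p_fc = p_p = p_sig = None
        if prot_id is not None and prot_id in de_protein.index:
            row = de_protein.loc[prot_id]
            p_fc, p_p, p_sig = float(row["log2fc"]), float(row["p_value"]), bool(row["significant"])
        else:
            missing.append("protein_de")
        consistent_dir = (
            c_fc is not None
            and p_fc is not None
            and _sign(c_fc) != 0
            and _sign(c_fc) == _sign(p_fc)
        )
        verdict = verdicts.get(circ_id)
        validated = bool(verdict and verdict.validated)
        tier = TIER_PREDICTED
        if c_sig and p_sig and consistent_dir:
            tier = TIER_VALIDATED if validated else TIER_CONSISTENT
        out.append(
            IntegratedCandidate(
                circ_id=circ_id,
                circ_log2fc=c_fc,
                circ_p=c_p,
                protein_id=prot_id,
                protein_log2fc=p_fc,
                protein_p=p_p,
                direction_consistent=consistent_dir,
                validated_by_peptides=validated,
                tier=tier,
                orf=orf,
                missing_layers=tuple(missing),
            )
        )
    out.sort(
        key=lambda c: (
            _TIER_RANK[c.tier],
            -(abs(c.circ_log2fc) if c.circ_log2fc is not None else -1.0),
            c.circ_id,
        )
    )
    return out


def candidates_table(candidates: Sequence[IntegratedCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "circ_id": c.circ_id,
                "tier": c.tier,
                "circ_log2fc": c.circ_log2fc,
                "circ_p": c.circ_p,
                "protein_id": c.protein_id,
                "protein_log2fc": c.protein_log2fc,
                "protein_p": c.protein_p,
                "direction_consistent": c.direction_consistent,
                "validated_by_peptides": c.validated_by_peptides,
                "orf_start_pos": c.orf.start_pos if c.orf else None,
                "orf_aa_length": c.orf.aa_length if c.orf else None,
                "orf_n_wraps": c.orf.n_wraps if c.orf else None,
                "unique_span": (
                    f"{c.orf.unique_span[0]}-{c.orf.unique_span[1]}" if c.orf else None
                ),
                "missing_layers": ",".join(c.missing_layers),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "circ_id", "tier", "circ_log2fc", "circ_p", "protein_id",
            "protein_log2fc", "protein_p", "direction_consistent",
            "validated_by_peptides", "orf_start_pos", "orf_aa_length",
            "orf_n_wraps", "unique_span", "missing_layers",
        ],
    )


def summarize_de(de: pd.DataFrame) -> dict:
    sig = de[de["significant"]]
    return {
        "n_features": int(len(de)),
        "n_significant": int(len(sig)),
        "n_up": int((sig["direction"] == "up").sum()),
        "n_down": int((sig["direction"] == "down").sum()),
    }


def write_report(
    candidates: Sequence[IntegratedCandidate],
    catalog_summary: dict | None,
    de_circ: pd.DataFrame,
    de_protein: pd.DataFrame,
    outdir: str,
) -> dict:
    """Write the candidate TSV and a JSON summary; byte-stable for
    identical inputs.  Returns the summary dict."""
    os.makedirs(outdir, exist_ok=True)
    table = candidates_table(candidates)
    table.to_csv(
        os.path.join(outdir, "candidates.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    tiers = {t: 0 for t in (TIER_VALIDATED, TIER_CONSISTENT, TIER_PREDICTED)}
    for c in candidates:
        tiers[c.tier] += 1
    summary = {
        "n_candidates": len(candidates),
        "tiers": tiers,
        "de_circ": summarize_de(de_circ),
        "de_protein": summarize_de(de_protein),
        "catalog": catalog_summary or {},
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
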