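"""End-to-end chain: simulate -> catalog -> DE -> ORF -> match -> integrate."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import circ_orf, diff_expr, integrate, peptide_match
from .circ_catalog import summarize_catalog
from .synthetic_data import SimulationConfig, SyntheticDataset, generate_dataset


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    de_circ: pd.DataFrame
    de_protein: pd.DataFrame
    orf_selection: dict
    verdicts: dict
    candidates: list
    catalog_summary: dict

    def consistent_ids(self) -> set[str]:
        return {
            c.circ_id
            for c in self.candidates
            if c.tier in (integrate.TIER_CONSISTENT, integrate.TIER_VALIDATED)
        }

    def validated_ids(self) -> set[str]:
        return {
            c.circ_id for c in self.candidates if c.tier == integrate.TIER_VALIDATED
        }


def run_pipeline(
    config: SimulationConfig,
    min_aa: int = circ_orf.DEFAULT_MIN_AA,
    de_test: str = "welch",
) -> PipelineResult:
    """Run the discovery chain on a synthetic dataset.

    The analysis stages see only what real data would provide: the call
    table with counts, genome + annotation, the protein abundance table,
    the observed peptide list and the circRNA-to-protein id map.  The
    planted truth is never consulted.
    """
    ds = generate_dataset(config)

    de_c = diff_expr.de_circ(ds.counts, test=de_test)
    de_p = diff_expr.de_protein(ds.protein_abundance, test=de_test)

    orf_selection: dict[str, circ_orf.ORFCandidate] = {}
    for rec in ds.records:
        template = circ_orf.CircularTemplate(rec.circ_id, rec.mature_seq)
        selected = circ_orf.select_orf(
            circ_orf.find_junction_orfs(template, min_aa=min_aa)
        )
        if selected is not None:
            orf_selection[rec.circ_id] = selected

    candidates = list(orf_selection.values())
    matches = peptide_match.match_peptides(ds.observed_peptides, candidates)
    verdicts = peptide_match.evaluate_validation(matches, candidates)

    integrated = integrate.cross_omics_candidates(
        de_c, de_p, orf_selection, verdicts, ds.circ_to_protein
    )
    catalog_summary = summarize_catalog(ds.records, de_c)
    return PipelineResult(
        dataset=ds,
        de_circ=de_c,
        de_protein=de_p,
        orf_selection=orf_selection,
        verdicts=verdicts,
        candidates=integrated,
        catalog_summary=catalog_summary,
    )
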