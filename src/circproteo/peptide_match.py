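"""In-silico tryptic digestion and MS peptide evidence for candidate proteins.

Matching is sequence-level: observed peptides (as identified by a search
engine) are located as exact substrings of each candidate protein, and a
candidate counts as validated only when at least one peptide overlaps its
circRNA-unique region — the junction-crossing / C-terminal stretch that
the linear parent protein cannot produce.  Peptides shared with the
parent contribute to coverage but never to validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pyteomics import parser as _pyt_parser

from .circ_orf import ORFCandidate

TRYPSIN_RULE = _pyt_parser.expasy_rules["trypsin"]  # cleave after K/R, not before P

DEFAULT_MISSED_CLEAVAGES = 2
DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 45
DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class TrypticPeptide:
    seq: str
    start_res: int  # 1-based inclusive
    end_res: int
    missed_cleavages: int


@dataclass(frozen=True)
class PeptideMatch:
    peptide_seq: str
    protein_id: str
    start_res: int
    end_res: int
    overlaps_unique: bool
    overlap_len: int


@dataclass(frozen=True)
class ValidationVerdict:
    circ_id: str
    n_peptides_total: int
    n_unique_peptides: int
    coverage_fraction: float
    validated: bool


def tryptic_digest(
    protein_seq: str,
    missed_cleavages: int = DEFAULT_MISSED_CLEAVAGES,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[TrypticPeptide]:
    """Tryptic fragments of a protein with up to ``missed_cleavages`` skips.

    Cleaves C-terminal to K or R except before P, keeps fragments whose
    length falls in [min_len, max_len], and records 1-based positions.
    """
    if not protein_seq:
        raise ValueError("empty protein")
    out = []
    for start0, pep in _pyt_parser.icleave(
        protein_seq, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=1
    ):
        if not min_len <= len(pep) <= max_len:
            continue
        n_missed = sum(
            1
            for i in range(len(pep) - 1)
            if pep[i] in "KR" and pep[i + 1] != "P"
        )
        out.append(
            TrypticPeptide(
                seq=pep,
                start_res=start0 + 1,
                end_res=start0 + len(pep),
                missed_cleavages=n_missed,
            )
        )
    out.sort(key=lambda p: (p.start_res, p.end_res))
    return out


def _interval_overlap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    return max(0, min(a_hi, b_hi) - max(a_lo, b_lo) + 1)


def match_peptides(
    observed_peptides: Iterable[str],
    candidates: Sequence[ORFCandidate],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[PeptideMatch]:
    """Locate observed peptides in candidate proteins, all occurrences.

    ``overlaps_unique`` is true when the match overlaps the candidate's
    unique region by at least ``min_overlap`` residues.
    """
    matches = []
    for pep in observed_peptides:
        if not pep:
            continue
        for cand in candidates:
            lo, hi = cand.unique_span
            start = 0
            while True:
                i = cand.protein_seq.find(pep, start)
                if i == -1:
                    break
                s, e = i + 1, i + len(pep)
                ov = _interval_overlap(s, e, lo, hi)
                matches.append(
                    PeptideMatch(
                        peptide_seq=pep,
                        protein_id=cand.circ_id,
                        start_res=s,
                        end_res=e,
                        overlaps_unique=ov >= min_overlap,
                        overlap_len=ov,
                    )
                )
                start = i + 1
    return matches


def evaluate_validation(
    matches: Sequence[PeptideMatch], candidates: Sequence[ORFCandidate]
) -> dict[str, ValidationVerdict]:
    """Aggregate peptide evidence per candidate.

    A candidate is validated iff at least one distinct peptide overlaps its
    unique region; coverage is the union of matched residue intervals over
    the protein length.
    """
    by_id: Mapping[str, list[PeptideMatch]] = {c.circ_id: [] for c in candidates}
    for m in matches:
        if m.protein_id in by_id:
            by_id[m.protein_id].append(m)
    verdicts = {}
    for cand in candidates:
        ms = by_id[cand.circ_id]
        peptides = {m.peptide_seq for m in ms}
        unique_peps = {m.peptide_seq for m in ms if m.overlaps_unique}
        covered = _union_length(sorted((m.start_res, m.end_res) for m in ms))
        verdicts[cand.circ_id] = ValidationVerdict(
            circ_id=cand.circ_id,
            n_peptides_total=len(peptides),
            n_unique_peptides=len(unique_peps),
            coverage_fraction=covered / cand.aa_length,
            validated=len(unique_peps) >= 1,
        )
    return verdicts


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_lo, cur_hi = None, None
    for lo, hi in intervals:
        if cur_hi is None or lo > cur_hi + 1:
            if cur_hi is not None:
                total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo + 1
    return total
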