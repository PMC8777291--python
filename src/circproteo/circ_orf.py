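"""Open reading frames on circular RNA templates.

The mature sequence of a circRNA is covalently closed: position 1 abuts
position L across the back-splice junction.  A ribosome loading on the
circle can read through that junction, so an ORF may start near the 3'
end of the linear representation and terminate after wrapping around one
or more times ("rolling-circle" translation).  Proteins produced this way
carry a junction-crossing stretch of residues that the linear parent
transcript cannot encode, which is what makes them detectable as novel
proteins.

Candidate filtering follows three rules: the ORF's codon span must cross
the back-splice junction at least once, the protein must be longer than
100 residues (``min_aa = 101``), and when several ORFs qualify on one
circle the shortest protein is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_ALPHABET = frozenset("ACGTN")

DEFAULT_MIN_AA = 101  # "more than 100 amino acid residues"
DEFAULT_MAX_WRAPS = 4


class SequenceAlphabetError(ValueError):
    """Template contains characters outside A/C/G/T/N."""


class AmbiguousPrimerError(ValueError):
    """A primer has multiple exact sites; all possible products are attached."""

    def __init__(self, products: list[dict]):
        super().__init__(
            f"ambiguous primer placement: {len(products)} possible products"
        )
        self.products = products


@dataclass(frozen=True)
class CircularTemplate:
    """A mature circular sequence; the junction lies between position L and 1."""

    circ_id: str
    mature_seq: str

    def __post_init__(self):
        seq = self.mature_seq.upper()
        object.__setattr__(self, "mature_seq", seq)
        if len(seq) < 1:
            raise ValueError("empty circular template")
        bad = set(seq) - _ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"{self.circ_id}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.mature_seq)


@dataclass(frozen=True)
class ORFCandidate:
    """One predicted ORF on a circular template.

    Positions are 1-based on the mature sequence.  ``n_wraps`` counts how
    many times the codon span (start codon through stop codon, when found)
    crosses the back-splice junction.  ``unique_span`` is the residue
    interval regarded as unattributable to the linear parent protein; with
    no parent given it runs from the junction-affected residue to the
    C-terminus.
    """

    circ_id: str
    start_pos: int
    frame: int
    aa_length: int
    protein_seq: str
    n_wraps: int
    stop_found: bool
    junction_residue_index: int
    unique_span: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.unique_span is None:
            object.__setattr__(
                self, "unique_span", (self.junction_residue_index, self.aa_length)
            )
        if not 1 <= self.junction_residue_index <= self.aa_length:
            raise ValueError("junction residue index outside the protein")
        lo, hi = self.unique_span
        if not (1 <= lo <= hi <= self.aa_length):
            raise ValueError("unique_span outside [1, aa_length]")


def _junction_residue_index(start0: int, aa_length: int, L: int) -> int:
    """First residue whose codon contains or follows the L->1 crossing.

    A codon with 0-based start s crosses the junction when s is in
    {L-2, L-1}; codons with s >= L lie wholly past it.  When the crossing
    falls inside the stop codon the last residue is reported (it abuts the
    junction).
    """
    for i in range(aa_length):
        if start0 + 3 * i >= L - 2:
            return i + 1
    return aa_length


def find_junction_orfs(
    template: CircularTemplate,
    min_aa: int = DEFAULT_MIN_AA,
    max_wraps: int = DEFAULT_MAX_WRAPS,
    include_rolling: bool = False,
) -> list[ORFCandidate]:
    """Enumerate junction-spanning ORFs of a circular template.

    Scans every ATG in the three sense frames of the circle (implemented on
    a ``max_wraps + 1``-fold concatenation), translates to the first
    in-frame stop, and keeps candidates whose codon span (including the
    stop codon) crosses the junction at least once and whose protein has at
    least ``min_aa`` residues (stop excluded).  ORFs with no stop within
    ``max_wraps`` traversals are "rolling" ORFs: reported with
    ``stop_found=False`` only when ``include_rolling`` is set, and never
    eligible for :func:`select_orf`.

    Returns candidates sorted by (aa_length, start_pos).
    """
    if min_aa < 1:
        raise ValueError(f"min_aa must be >= 1, got {min_aa}")
    L = len(template)
    if L < 3:
        return []
    seq = template.mature_seq
    extended = seq * (max_wraps + 1)
    limit = len(extended)

    out: list[ORFCandidate] = []
    seen: set[tuple[int, str]] = set()
    for start0 in range(L):
        if extended[start0 : start0 + 3] != START_CODON:
            continue
        # walk codons until a stop or until the span would wrap past max_wraps
        stop_found = False
        pos = start0
        while pos + 3 <= limit:
            codon = extended[pos : pos + 3]
            if codon in STOP_CODONS:
                stop_found = True
                break
            pos += 3
        if stop_found:
            span_end0 = pos + 2  # last base of the stop codon
            aa_len = (pos - start0) // 3
            protein = str(Seq(extended[start0:pos]).translate())
        else:
            # rolling ORF: cap the span at max_wraps full traversals
            span_end0 = limit - 1 - ((limit - start0) % 3)
            aa_len = (span_end0 + 1 - start0) // 3
            protein = str(Seq(extended[start0 : start0 + 3 * aa_len]).translate())
        n_wraps = span_end0 // L  # junction crossings: start0 < L always
        if n_wraps < 1 or aa_len < min_aa:
            continue
        if not stop_found and not include_rolling:
            continue
        key = (start0 % L, protein)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            ORFCandidate(
                circ_id=template.circ_id,
                start_pos=start0 + 1,
                frame=start0 % 3,
                aa_length=aa_len,
                protein_seq=protein,
                n_wraps=n_wraps,
                stop_found=stop_found,
                junction_residue_index=_junction_residue_index(start0, aa_len, L),
            )
        )
    out.sort(key=lambda c: (c.aa_length, c.start_pos, c.protein_seq))
    return out


def select_orf(candidates: Sequence[ORFCandidate]) -> ORFCandidate | None:
    """Pick the qualifying ORF with the fewest residues.

    Ties break by smallest start position, then lexicographically smallest
    protein.  Rolling (stop-less) candidates are excluded.  Returns None
    for an empty candidate list.
    """
    withstop = [c for c in candidates if c.stop_found]
    if not withstop:
        return None
    ids = {c.circ_id for c in withstop}
    if len(ids) > 1:
        raise ValueError(f"candidates from multiple templates: {sorted(ids)}")
    return min(withstop, key=lambda c: (c.aa_length, c.start_pos, c.protein_seq))


def derive_unique_region(
    candidate: ORFCandidate, parent_protein: str | None = None
) -> tuple[int, int]:
    """Residue interval of the candidate not attributable to the linear parent.

    With a parent protein, the unique suffix begins at the first residue u
    such that ``protein[u:]`` is absent from the parent as an exact
    substring while the one-residue-shorter suffix is present (substring
    absence of suffixes is monotone in length, so u is the boundary of
    attributability).  The interval is extended leftwards to include the
    junction residue when that lies before u.  With no parent — or when the
    whole protein occurs in the parent — the interval runs from the
    junction residue to the C-terminus.  Always non-empty.
    """
    aa = candidate.aa_length
    jri = candidate.junction_residue_index
    if parent_protein:
        p = candidate.protein_seq
        # smallest 1-based u whose suffix IS present in the parent
        u_present = None
        for u in range(1, aa + 1):
            if p[u - 1 :] in parent_protein:
                u_present = u
                break
        if u_present is None:
            return (1, aa)  # even the last residue is absent
        if u_present == 1:
            return (jri, aa)  # fully contained: fall back to the junction rule
        start = u_present - 1
        return (min(start, jri), aa)
    return (jri, aa)


def annotate_unique_regions(
    candidates: Iterable[ORFCandidate],
    parents: dict[str, str] | None = None,
) -> list[ORFCandidate]:
    """Return copies of candidates with ``unique_span`` filled in."""
    parents = parents or {}
    out = []
    for c in candidates:
        span = derive_unique_region(c, parents.get(c.circ_id))
        out.append(
            ORFCandidate(
                circ_id=c.circ_id,
                start_pos=c.start_pos,
                frame=c.frame,
                aa_length=c.aa_length,
                protein_seq=c.protein_seq,
                n_wraps=c.n_wraps,
                stop_found=c.stop_found,
                junction_residue_index=c.junction_residue_index,
                unique_span=span,
            )
        )
    return out


def _circular_sites(circle: str, query: str) -> list[int]:
    """0-based start positions (< L) of exact matches of query on the circle."""
    L = len(circle)
    doubled = circle * 2
    sites = []
    start = 0
    while True:
        i = doubled.find(query, start)
        if i == -1 or i >= L:
            break
        sites.append(i)
        start = i + 1
    return sites


def in_silico_circular_pcr(
    template: CircularTemplate, fwd_primer: str, rev_primer: str
) -> dict | None:
    """Predict the amplicon of a divergent primer pair on a circle.

    The forward primer anneals to the sense strand; the reverse primer's
    reverse complement is located downstream going around the circle.  The
    product runs from the forward primer's 5' end to the reverse primer's
    5'-end position (the last sense-strand base of its site).  Returns
    ``{"product_length", "spans_junction"}`` or None when either primer has
    no exact site.  A full-circle product counts as junction-spanning.
    Multiple sites for either primer raise :class:`AmbiguousPrimerError`
    listing every possible product.
    """
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    if len(fwd) < 10 or len(rev) < 10:
        raise ValueError("primers must be at least 10 nt")
    circle = template.mature_seq
    L = len(circle)
    rev_rc = str(Seq(rev).reverse_complement())
    fwd_sites = _circular_sites(circle, fwd)
    rev_sites = _circular_sites(circle, rev_rc)
    if not fwd_sites or not rev_sites:
        return None

    def product(f: int, r: int) -> dict:
        r_end = r + len(rev_rc) - 1  # 5' end of the reverse primer
        length = ((r_end - f) % L) + 1
        spans = (f + length - 1 >= L) or (length == L)
        return {"product_length": length, "spans_junction": spans}

    products = [product(f, r) for f in fwd_sites for r in rev_sites]
    if len(products) > 1:
        raise AmbiguousPrimerError(products)
    return products[0]
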