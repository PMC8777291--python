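"""circRNA catalog: call-table parsing, genomic-origin classification,
mature-sequence extraction and summary statistics.

A back-splice call is identified as ``chrom:start|end`` with 1-based
inclusive coordinates (the convention of GFF3 and of published circRNA
IDs such as chr14:44496991|44498906).  Each event is assigned exactly one
genomic origin class — CDS, 5'UTR, 3'UTR, exon (other), intron,
antisense or intergenic — by a fixed precedence rule, and its mature
(spliced) circular sequence is reconstructed from the genome and
annotation.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

ORIGIN_CLASSES = (
    "CDS",
    "5UTR",
    "3UTR",
    "exon_other",
    "intron",
    "antisense",
    "intergenic",
)

_CIRC_ID_RE = re.compile(r"^([^:|\s]+):(\d+)\|(\d+)$")


class CircIdParseError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


def parse_circ_id(text: str) -> tuple[str, int, int]:
    """Split ``chrom:start|end`` into components; start <= end enforced."""
    m = _CIRC_ID_RE.match(text.strip())
    if not m:
        raise CircIdParseError(f"malformed circRNA id: {text!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise CoordinateError(f"start > end in circRNA id: {text!r}")
    return chrom, start, end


def format_circ_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}|{end}"


@dataclass(frozen=True)
class Gene:
    """A gene with one (flattened) exon structure.

    All coordinates are 1-based inclusive genomic positions; interval
    lists are sorted by start and non-overlapping within each list.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()


class Annotation:
    """Gene models with fast interval lookup per chromosome."""

    def __init__(self, genes: Iterable[Gene], chrom_lengths: Mapping[str, int] | None = None):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chrom, g.start))
        self.chrom_lengths = dict(chrom_lengths or {})
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in self.genes:
            self._trees[g.chrom].addi(g.start, g.end + 1, g)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[Gene]:
        if chrom not in self._trees:
            if self.chrom_lengths and chrom not in self.chrom_lengths:
                raise KeyError(f"chromosome {chrom!r} absent from annotation")
            return []
        hits = [iv.data for iv in self._trees[chrom].overlap(start, end + 1)]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    @classmethod
    def from_gff3(cls, path: str) -> "Annotation":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        chrom_lengths: dict[str, int] = {}
        for d in db.directives:
            m = re.match(r"sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", d)
            if m:
                chrom_lengths[m.group(1)] = int(m.group(3))
        for g in db.features_of_type("gene"):
            exons, cds, utr5, utr3 = [], [], [], []
            for child in db.children(g.id, level=None):
                iv = (child.start, child.end)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            genes.append(
                Gene(
                    gene_id=g.id,
                    chrom=g.seqid,
                    start=g.start,
                    end=g.end,
                    strand=g.strand if g.strand in "+-" else "+",
                    exons=tuple(sorted(set(exons))),
                    cds=tuple(sorted(set(cds))),
                    utr5=tuple(sorted(set(utr5))),
                    utr3=tuple(sorted(set(utr3))),
                )
            )
        return cls(genes, chrom_lengths)


@dataclass
class CircRNARecord:
    """One back-splice event with optional classification and sequence."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."  # {+, -, .} with "." = unknown
    origin_class: str | None = None
    mature_seq: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.start > self.end:
            raise CoordinateError(f"{self.circ_id}: start > end")
        if self.strand not in "+-.":
            raise ValueError(f"{self.circ_id}: bad strand {self.strand!r}")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_id(cls, circ_id: str, strand: str = ".", **kw) -> "CircRNARecord":
        chrom, start, end = parse_circ_id(circ_id)
        return cls(circ_id=circ_id, chrom=chrom, start=start, end=end, strand=strand, **kw)


# ---------------------------------------------------------------------------
# origin classification


def _sites_in_exons(gene: Gene, start: int, end: int) -> bool:
    def hit(pos: int) -> bool:
        return any(s <= pos <= e for s, e in gene.exons)

    return hit(start) and hit(end)


def _overlap_total(intervals: Sequence[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start) + 1) for s, e in intervals)


def _exon_subclass(gene: Gene, start: int, end: int) -> str:
    """Dominant annotated exon type within the span: CDS > 5UTR > 3UTR,
    ties (or no typed overlap) -> exon_other."""
    overlaps = [
        ("CDS", _overlap_total(gene.cds, start, end)),
        ("5UTR", _overlap_total(gene.utr5, start, end)),
        ("3UTR", _overlap_total(gene.utr3, start, end)),
    ]
    best = max(o for _, o in overlaps)
    if best == 0:
        return "exon_other"
    winners = [name for name, o in overlaps if o == best]
    return winners[0] if len(winners) == 1 else "exon_other"


def _classify(
    record: CircRNARecord, annotation: Annotation
) -> tuple[str, Gene | None]:
    if annotation.chrom_lengths:
        if record.chrom not in annotation.chrom_lengths:
            raise KeyError(f"chromosome {record.chrom!r} absent from annotation")
    overlapping = annotation.overlapping_genes(record.chrom, record.start, record.end)
    if record.strand in "+-":
        same = [g for g in overlapping if g.strand == record.strand]
        opposite = [g for g in overlapping if g.strand != record.strand]
    else:
        same, opposite = list(overlapping), []
    for g in same:
        if _sites_in_exons(g, record.start, record.end):
            return _exon_subclass(g, record.start, record.end), g
    for g in same:
        if g.start <= record.start and record.end <= g.end:
            return "intron", g
    if not same and opposite:
        return "antisense", opposite[0]
    return "intergenic", None


def classify_origin(record: CircRNARecord, annotation: Annotation) -> str:
    """Assign exactly one origin class by the fixed precedence rule.

    Same-strand genes are considered first: if both back-splice sites fall
    in exons the event is exonic, subclassified by the dominant annotated
    exon type; an event fully inside a gene without satisfying the exon
    rule is intronic.  Events overlapping genes only on the opposite
    strand are antisense; everything else is intergenic.  Records of
    unknown strand are matched against genes of either strand.
    """
    return _classify(record, annotation)[0]


# ---------------------------------------------------------------------------
# sequence extraction


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a pyfaidx.Fasta or a plain mapping."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start - 1 : end].upper()
    return str(seq[start - 1 : end]).upper()


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extract_circ_sequence(
    record: CircRNARecord, genome, annotation: Annotation
) -> str:
    """Mature circular sequence of a back-splice event.

    For exonic origin classes the mature circle is the concatenation of
    the annotated exonic segments within [start, end] in transcript order
    (reverse-complemented for minus-strand events); for intron, antisense
    and intergenic events it is the raw genomic span.  The first base of
    the returned sequence is the back-splice acceptor side, so position 1
    abuts position L across the junction.  Unknown strand is treated as
    plus for extraction.
    """
    cls, gene = _classify(record, annotation)
    strand = record.strand if record.strand in "+-" else "+"
    if cls in ("CDS", "5UTR", "3UTR", "exon_other"):
        assert gene is not None
        segments = [
            (max(s, record.start), min(e, record.end))
            for s, e in gene.exons
            if s <= record.end and e >= record.start
        ]
        segments = _merge_intervals(segments)
        if not segments:
            raise RuntimeError(
                f"{record.circ_id}: exonic class {cls} but no exon overlap"
            )
        seq = "".join(_fetch(genome, record.chrom, s, e) for s, e in segments)
    else:
        seq = _fetch(genome, record.chrom, record.start, record.end)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def classify_and_extract(
    records: Iterable[CircRNARecord], genome, annotation: Annotation
) -> list[CircRNARecord]:
    """Convenience pass filling origin_class and mature_seq on copies."""
    out = []
    for r in records:
        cls = classify_origin(r, annotation)
        r2 = replace(r, origin_class=cls)
        r2.mature_seq = extract_circ_sequence(r2, genome, annotation)
        out.append(r2)
    return out


# ---------------------------------------------------------------------------
# call-table IO


def read_call_table(path: str) -> list[CircRNARecord]:
    """Read a circRNA call TSV.

    Accepts the native dialect (circ_id, chrom, start, end, strand,
    one column per sample) and a CIRI-style dialect (circRNA_ID, chr,
    circRNA_start, circRNA_end, junction_reads, strand; extra columns
    ignored).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if "circ_id" in cols:
        fixed = ["circ_id", "chrom", "start", "end", "strand"]
        sample_cols = [c for c in cols if c not in fixed]
        records = []
        for _, row in df.iterrows():
            records.append(
                CircRNARecord(
                    circ_id=row["circ_id"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row.get("strand", "."),
                    counts={c: int(row[c]) for c in sample_cols},
                )
            )
        return records
    if "circRNA_ID" in cols:
        records = []
        for _, row in df.iterrows():
            records.append(
                CircRNARecord(
                    circ_id=row["circRNA_ID"],
                    chrom=row["chr"],
                    start=int(row["circRNA_start"]),
                    end=int(row["circRNA_end"]),
                    strand=row.get("strand", ".") or ".",
                    counts=(
                        {"junction_reads": int(row["junction_reads"])}
                        if "junction_reads" in cols
                        else {}
                    ),
                )
            )
        return records
    raise ValueError(f"unrecognised call-table columns: {cols}")


def write_call_table(records: Sequence[CircRNARecord], path: str) -> None:
    sample_ids: list[str] = []
    for r in records:
        for s in r.counts:
            if s not in sample_ids:
                sample_ids.append(s)
    rows = []
    for r in records:
        row = {
            "circ_id": r.circ_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
        }
        row.update({s: r.counts.get(s, 0) for s in sample_ids})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summaries


def length_bin_label(length: int, bin_width: int = 100, open_end: int = 3000) -> str:
    if length > open_end:
        return f">{open_end}"
    lo = (length // bin_width) * bin_width
    if lo >= open_end:  # length == open_end exactly
        lo = open_end - bin_width
    return f"[{lo},{lo + bin_width})"


def summarize_catalog(
    records: Sequence[CircRNARecord],
    de_results: pd.DataFrame | None = None,
    bin_width: int = 100,
    open_end: int = 3000,
) -> dict:
    """Catalog summaries: length histogram, origin counts and per-chromosome
    up/down counts of significant DE events.

    Length is that of the mature sequence when available, else the genomic
    span.  ``de_results`` is a DE table indexed by circ_id (may be None).
    """
    length_hist: Counter = Counter()
    origin_counts: Counter = Counter()
    for r in records:
        length = len(r.mature_seq) if r.mature_seq else r.span_length
        length_hist[length_bin_label(length, bin_width, open_end)] += 1
        origin_counts[r.origin_class or "unclassified"] += 1
    chrom_updown: dict[str, dict[str, int]] = {}
    if de_results is not None and len(de_results):
        sig = de_results[de_results["significant"]]
        by_id = {r.circ_id: r for r in records}
        for fid, row in sig.iterrows():
            rec = by_id.get(fid)
            if rec is None or row["direction"] not in ("up", "down"):
                continue
            d = chrom_updown.setdefault(rec.chrom, {"up": 0, "down": 0})
            d[row["direction"]] += 1
    oc = {c: origin_counts.get(c, 0) for c in ORIGIN_CLASSES}
    for k, v in origin_counts.items():
        oc.setdefault(k, v)
    return {
        "n_records": len(records),
        "length_histogram": dict(sorted(length_hist.items())),
        "origin_counts": oc,
        "chrom_updown": chrom_updown,
    }
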