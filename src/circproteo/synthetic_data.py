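"""Synthetic multi-omics data with planted ground truth.

Generates a self-contained toy study emulating a two-group (Sham vs BOO)
bulk design: a random genome with gene models, a circRNA back-splice
catalog whose events have controlled genomic origins, a negative-binomial
junction-read count matrix with planted fold changes, and a matched
proteomics layer (iTRAQ-style relative abundances plus an observed
peptide list) in which a configurable subset of ORF-bearing circRNAs
carries sign-consistent protein changes.

Coding circRNAs are planted by *editing the genome* within the
back-splice span so that the mature circular sequence contains exactly
one junction-spanning ORF of more than 100 residues; every downstream
stage therefore runs on unmodified logic and recovery tests are honest
end-to-end checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import circ_orf
from .circ_catalog import (
    Annotation,
    CircRNARecord,
    Gene,
    format_circ_id,
    write_call_table,
)
from .diff_expr import BOO, SHAM, ExpressionMatrix
from .peptide_match import (
    DEFAULT_MIN_OVERLAP,
    tryptic_digest,
)

_NT = np.array(list("ACGT"))

# residues used for planted/decoy proteins; no M (extra starts), no P (keeps
# tryptic cleavage clean), K/R added separately at controlled spacing
_AA_POOL = "ACDEFGHILNQSTVWY"

# one codon per residue, all ending in C or G: with no codon ending in A or
# starting "TG" after an A, no spurious ATG can form across codon boundaries
_CODONS = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "CGC", "S": "AGC", "T": "ACC", "V": "GTC",
    "W": "TGG", "Y": "TAC",
}


class SizingError(ValueError):
    """The reference is too small for the requested gene/event layout."""


class PlacementError(RuntimeError):
    """An event of the requested origin class could not be placed."""


DEFAULT_ORIGIN_MIX = {
    "CDS": 0.50,
    "5UTR": 0.06,
    "3UTR": 0.08,
    "intron": 0.16,
    "antisense": 0.08,
    "intergenic": 0.12,
}


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic dataset.

    Defaults emulate the bladder-outlet-obstruction study layout: 8 Sham
    vs 7 BOO samples, a many-event circRNA catalog dominated by CDS-origin
    events, planted circRNA effects of |log2FC| = 2 (straddling the FC>2
    calling threshold), protein effects of |log2FC| = 1 (above the FC>1.5
    threshold), and negative-binomial junction counts.
    """

    n_chrom: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    n_circ: int = 200
    origin_mix: dict = field(default_factory=lambda: dict(DEFAULT_ORIGIN_MIX))
    coding_fraction: float = 0.10
    consistent_fraction: float = 0.60
    n_sham: int = 8
    n_boo: int = 7
    log2fc_planted: float = 2.0
    protein_log2fc: float = 1.0
    de_fraction: float = 0.20
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple = (10.0, 5000.0)
    fixed_baseline: float | None = None
    protein_sigma: float = 0.2
    peptide_detect_prob: float = 0.5
    n_decoy_factor: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "coding_fraction",
            "consistent_fraction",
            "de_fraction",
            "peptide_detect_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if any(w < 0 for w in self.origin_mix.values()) or not math.isclose(
            sum(self.origin_mix.values()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("origin_mix must be non-negative and sum to 1")
        unknown = set(self.origin_mix) - {
            "CDS", "5UTR", "3UTR", "intron", "antisense", "intergenic"
        }
        if unknown:
            raise ValueError(f"unsupported origin classes in mix: {sorted(unknown)}")
        if self.n_sham < 2 or self.n_boo < 2:
            raise ValueError("need at least 2 samples per group")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @classmethod
    def noise_free(cls, **overrides) -> "SimulationConfig":
        """A negligible-noise profile: Poisson counts at a fixed high
        baseline, near-zero protein noise, every peptide detected."""
        kw = dict(
            nb_dispersion=0.0,
            fixed_baseline=1000.0,
            protein_sigma=0.02,
            peptide_detect_prob=1.0,
        )
        kw.update(overrides)
        return cls(**kw)

    def sham_samples(self) -> list[str]:
        return [f"Sham_{i + 1}" for i in range(self.n_sham)]

    def boo_samples(self) -> list[str]:
        return [f"BOO_{i + 1}" for i in range(self.n_boo)]

    def groups(self) -> pd.Series:
        ids = self.sham_samples() + self.boo_samples()
        return pd.Series(
            [SHAM] * self.n_sham + [BOO] * self.n_boo, index=ids, name="group"
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["baseline_mean_range"] = list(d["baseline_mean_range"])
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "baseline_mean_range" in d:
            d["baseline_mean_range"] = tuple(d["baseline_mean_range"])
        return cls(**d)


@dataclass
class TruthEntry:
    """Planted ground truth for one circRNA."""

    circ_id: str
    is_coding: bool
    protein_seq: str  # empty when non-coding
    circ_log2fc: float
    protein_log2fc: float | None  # None when no protein-layer entry
    is_consistent_candidate: bool
    mature_length: int = 0
    orf_start_pos: int = 0
    junction_residue_index: int = 0


@dataclass
class TruthTable:
    entries: list[TruthEntry]

    def by_id(self) -> dict[str, TruthEntry]:
        return {e.circ_id: e for e in self.entries}

    def coding_ids(self) -> list[str]:
        return [e.circ_id for e in self.entries if e.is_coding]

    def consistent_ids(self) -> list[str]:
        return [e.circ_id for e in self.entries if e.is_consistent_candidate]

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.entries], sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        return cls([TruthEntry(**d) for d in json.loads(text)])


def protein_id_for(circ_id: str) -> str:
    return f"prot|{circ_id}"


# ---------------------------------------------------------------------------
# reference generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def generate_reference(config: SimulationConfig) -> tuple[dict, Annotation]:
    """Random genome plus a gene annotation.

    Each gene has 3-5 exons with 5'UTR / CDS / 3'UTR sub-features (the
    UTRs confined to the terminal exons), genes are non-overlapping, and
    the layout leaves intergenic gaps.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    genome = {
        f"chr{i + 1}": _random_seq(rng, config.chrom_length)
        for i in range(config.n_chrom)
    }
    genes: list[Gene] = []
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    for ci, chrom in enumerate(sorted(genome)):
        cursor = 1000  # leading intergenic margin
        for gi in range(per_chrom[ci]):
            n_exons = int(rng.integers(3, 6))
            exon_lens = rng.integers(200, 401, size=n_exons)
            intron_lens = rng.integers(150, 501, size=n_exons - 1)
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            gap = int(rng.integers(600, 1200))
            start = cursor + gap
            end = start + gene_len - 1
            if end > config.chrom_length - 1000:
                raise SizingError(
                    f"chromosome {chrom} too short for {per_chrom[ci]} genes "
                    f"of ~{gene_len} nt; increase chrom_length"
                )
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            # UTRs live in the terminal exons of the *transcript*
            first, last = (exons[0], exons[-1]) if strand == "+" else (
                exons[-1],
                exons[0],
            )
            u5_len = int(rng.integers(80, 151))
            u3_len = int(rng.integers(80, 151))
            if strand == "+":
                utr5 = (first[0], first[0] + u5_len - 1)
                utr3 = (last[1] - u3_len + 1, last[1])
                cds = []
                for s, e in exons:
                    cs, ce = max(s, utr5[1] + 1), min(e, utr3[0] - 1)
                    if cs <= ce:
                        cds.append((cs, ce))
            else:
                utr5 = (first[1] - u5_len + 1, first[1])
                utr3 = (last[0], last[0] + u3_len - 1)
                cds = []
                for s, e in exons:
                    cs, ce = max(s, utr3[1] + 1), min(e, utr5[0] - 1)
                    if cs <= ce:
                        cds.append((cs, ce))
            genes.append(
                Gene(
                    gene_id=f"gene_{chrom}_{gi + 1}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=tuple(exons),
                    cds=tuple(sorted(cds)),
                    utr5=(utr5,),
                    utr3=(utr3,),
                )
            )
            cursor = end
    ann = Annotation(genes, {c: config.chrom_length for c in genome})
    return genome, ann


# ---------------------------------------------------------------------------
# circRNA event generation with ORF planting


def _class_counts(mix: dict, n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n events over the mix."""
    order = sorted(mix)
    floors = {c: int(math.floor(mix[c] * n)) for c in order}
    rem = n - sum(floors.values())
    frac = sorted(order, key=lambda c: (-(mix[c] * n - floors[c]), c))
    for c in frac[:rem]:
        floors[c] += 1
    return floors


def _design_planted_circle(
    rng: np.random.Generator, mature_len: int, max_tries: int = 50
) -> tuple[str, str, int]:
    """A circular sequence of the given length whose only ORF is one planted
    junction-spanning ORF.  Returns (circle, protein, orf_start_pos 1-based)."""
    if mature_len < 306 + 6:
        raise PlacementError(f"mature length {mature_len} too short to plant an ORF")
    for _ in range(max_tries):
        n_aa_max = min(180, (mature_len - 3) // 3 - 1)
        n_aa = int(rng.integers(101, n_aa_max + 1))
        residues = ["M"]
        for i in range(1, n_aa):
            if i % 8 == 4:
                residues.append("K" if rng.random() < 0.5 else "R")
            else:
                residues.append(_AA_POOL[rng.integers(0, len(_AA_POOL))])
        protein = "".join(residues)
        orf_nt = "".join(_CODONS[a] for a in protein) + "TAA"
        # wrap >= 21 nt: after the stop codon's 3 nt, the junction region
        # still spans >= 5 protein residues (the unique-evidence minimum)
        w_nt = int(rng.integers(21, len(orf_nt) - 15))
        filler = "".join(("C", "T")[b] for b in rng.integers(0, 2, size=mature_len - len(orf_nt)))
        circle = orf_nt[-w_nt:] + filler + orf_nt[:-w_nt]
        start_pos = w_nt + len(filler) + 1
        doubled = circle * 2
        atg_positions = [
            i for i in range(mature_len) if doubled[i : i + 3] == "ATG"
        ]
        if atg_positions != [start_pos - 1]:
            continue
        template = circ_orf.CircularTemplate("planted", circle)
        cands = circ_orf.find_junction_orfs(template, min_aa=101)
        if len(cands) == 1 and cands[0].protein_seq == protein:
            return circle, protein, start_pos
    raise PlacementError("could not design a clean planted ORF")


def _splice_segments(gene: Gene, start: int, end: int) -> list[tuple[int, int]]:
    segs = [
        (max(s, start), min(e, end))
        for s, e in gene.exons
        if s <= end and e >= start
    ]
    return sorted(segs)


def _write_span(genome: dict, chrom: str, segments, new_seq: str) -> None:
    """Overwrite the given genomic segments (left to right) with new_seq."""
    g = genome[chrom]
    pos = 0
    for s, e in segments:
        seg_len = e - s + 1
        g = g[: s - 1] + new_seq[pos : pos + seg_len] + g[e:]
        pos += seg_len
    assert pos == len(new_seq)
    genome[chrom] = g


def generate_circ_events(
    genome: dict,
    annotation: Annotation,
    config: SimulationConfig,
    max_tries: int = 300,
) -> tuple[dict, list[CircRNARecord], TruthTable]:
    """Place circRNA events of the requested origin mix and plant coding ORFs.

    Returns an edited copy of the genome, the event records (with origin
    class, mature sequence and planted effect sizes recorded in the truth
    table), and the truth table itself.  Coding events claim their genomic
    span exclusively so that planting edits never leak into other events.
    """
    rng = np.random.default_rng(config.seed + 1)
    genome = dict(genome)
    counts = _class_counts(config.origin_mix, config.n_circ)
    n_coding = int(round(config.coding_fraction * config.n_circ))
    n_consistent = int(round(config.consistent_fraction * n_coding))

    # coding events go to classes with room for a >=312 nt mature sequence
    codable = [c for c in ("CDS", "intron", "antisense", "intergenic") if counts.get(c, 0)]
    coding_quota: dict[str, int] = {c: 0 for c in counts}
    remaining = n_coding
    for c in codable:
        take = min(counts[c], remaining)
        coding_quota[c] = take
        remaining -= take
    if remaining > 0:
        raise PlacementError(
            "coding_fraction too high for the origin mix: coding events need "
            "CDS/intron/antisense/intergenic classes"
        )

    claimed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    used_ids: set[str] = set()
    records: list[CircRNARecord] = []
    truth_rows: list[TruthEntry] = []

    genes_by_chrom: dict[str, list[Gene]] = {}
    for g in annotation.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    chroms = sorted(genome)

    def overlaps_claimed(chrom: str, s: int, e: int) -> bool:
        return any(s <= ce and e >= cs for cs, ce in claimed[chrom])

    def place(cls_name: str, coding: bool) -> tuple[CircRNARecord, Gene | None]:
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            genes = genes_by_chrom.get(chrom, [])
            if cls_name in ("CDS", "5UTR", "3UTR", "intron", "antisense") and not genes:
                continue
            gene = genes[int(rng.integers(0, len(genes)))] if genes else None
            if cls_name == "CDS":
                cds = gene.cds
                if len(cds) < 2:
                    continue
                i = int(rng.integers(0, len(cds) - 1))
                j = int(rng.integers(i + 1, len(cds)))
                s = int(rng.integers(cds[i][0], cds[i][1] + 1))
                e = int(rng.integers(cds[j][0], cds[j][1] + 1))
                if e - s < 100:
                    continue
                strand = gene.strand
            elif cls_name in ("5UTR", "3UTR"):
                iv = (gene.utr5 if cls_name == "5UTR" else gene.utr3)[0]
                if iv[1] - iv[0] < 70:
                    continue
                s = int(rng.integers(iv[0], iv[0] + 20))
                e = int(rng.integers(iv[1] - 20, iv[1] + 1))
                strand = gene.strand
            elif cls_name == "intron":
                introns = [
                    (gene.exons[k][1] + 1, gene.exons[k + 1][0] - 1)
                    for k in range(len(gene.exons) - 1)
                ]
                introns = [iv for iv in introns if iv[1] - iv[0] >= (330 if coding else 80)]
                if not introns:
                    continue
                iv = introns[int(rng.integers(0, len(introns)))]
                s = iv[0] + 2
                e = iv[1] - 2
                if coding and e - s + 1 < 312:
                    continue
                if not coding:
                    hi = min(iv[1] - 2, s + int(rng.integers(60, 400)))
                    e = max(s + 50, hi)
                strand = gene.strand
            elif cls_name == "antisense":
                span = int(rng.integers(330 if coding else 120, 600))
                if gene.end - gene.start < span + 10:
                    continue
                s = int(rng.integers(gene.start, gene.end - span))
                e = s + span - 1
                strand = "-" if gene.strand == "+" else "+"
            elif cls_name == "intergenic":
                span = int(rng.integers(330 if coding else 120, 600))
                s = int(rng.integers(1, annotation.chrom_lengths[chrom] - span))
                e = s + span - 1
                if annotation.overlapping_genes(chrom, s, e):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                gene = None
            else:
                raise PlacementError(f"cannot place origin class {cls_name!r}")
            if s >= e:
                continue
            if overlaps_claimed(chrom, s, e):
                continue
            circ_id = format_circ_id(chrom, s, e)
            if circ_id in used_ids:
                continue
            rec = CircRNARecord(
                circ_id=circ_id, chrom=chrom, start=s, end=e, strand=strand,
                origin_class=cls_name,
            )
            from .circ_catalog import classify_origin

            if classify_origin(rec, annotation) != cls_name:
                continue
            if coding:
                # a planted ORF needs >= 312 nt of mature sequence
                segs = (
                    _splice_segments(gene, s, e)
                    if cls_name in ("CDS", "5UTR", "3UTR")
                    else [(s, e)]
                )
                if sum(e2 - s2 + 1 for s2, e2 in segs) < 312:
                    continue
            return rec, gene
        raise PlacementError(
            f"could not place an event of class {cls_name!r} after {max_tries} tries"
        )

    # coding events first (they claim spans exclusively)
    plan: list[tuple[str, bool]] = []
    for cls_name in sorted(counts):
        n_cls = counts[cls_name]
        n_cod = coding_quota.get(cls_name, 0)
        plan.extend([(cls_name, True)] * n_cod)
        plan.extend([(cls_name, False)] * (n_cls - n_cod))
    plan.sort(key=lambda t: (not t[1],))  # coding first, class order retained

    coding_seen = 0
    for cls_name, coding in plan:
        rec, gene = place(cls_name, coding)
        used_ids.add(rec.circ_id)
        protein = ""
        orf_start = 0
        jri = 0
        if coding:
            claimed[rec.chrom].append((rec.start, rec.end))
            segs = (
                _splice_segments(gene, rec.start, rec.end)
                if cls_name in ("CDS", "5UTR", "3UTR")
                else [(rec.start, rec.end)]
            )
            mature_len = sum(e - s + 1 for s, e in segs)
            circle, protein, orf_start = _design_planted_circle(rng, mature_len)
            plus_seq = (
                circle
                if rec.strand == "+"
                else str(Seq(circle).reverse_complement())
            )
            _write_span(genome, rec.chrom, segs, plus_seq)
            rec.mature_seq = circle
            cand = circ_orf.find_junction_orfs(
                circ_orf.CircularTemplate(rec.circ_id, circle), min_aa=101
            )[0]
            jri = cand.junction_residue_index
            coding_seen += 1
        else:
            from .circ_catalog import extract_circ_sequence

            rec.mature_seq = extract_circ_sequence(rec, genome, annotation)
        records.append(rec)
        truth_rows.append(
            TruthEntry(
                circ_id=rec.circ_id,
                is_coding=coding,
                protein_seq=protein,
                circ_log2fc=0.0,
                protein_log2fc=None,
                is_consistent_candidate=False,
                mature_length=len(rec.mature_seq),
                orf_start_pos=orf_start,
                junction_residue_index=jri,
            )
        )

    # planted effect sizes: every coding event is DE; a fraction of the
    # non-coding background is DE as well
    by_id = {t.circ_id: t for t in truth_rows}
    coding_ids = [t.circ_id for t in truth_rows if t.is_coding]
    noncoding_ids = [t.circ_id for t in truth_rows if not t.is_coding]
    for cid in coding_ids:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        by_id[cid].circ_log2fc = sign * config.log2fc_planted
    n_bg = int(round(config.de_fraction * len(noncoding_ids)))
    bg = rng.choice(len(noncoding_ids), size=n_bg, replace=False) if n_bg else []
    for k in sorted(bg):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        by_id[noncoding_ids[int(k)]].circ_log2fc = sign * config.log2fc_planted
    # consistent candidates: sign-matched protein effect above the 1.5x bar
    idx = rng.choice(len(coding_ids), size=n_consistent, replace=False) if n_consistent else []
    consistent = {coding_ids[int(i)] for i in idx}
    for cid in coding_ids:
        t = by_id[cid]
        if cid in consistent:
            t.protein_log2fc = math.copysign(config.protein_log2fc, t.circ_log2fc)
            t.is_consistent_candidate = True
        else:
            t.protein_log2fc = 0.0

    order = {r.circ_id: i for i, r in enumerate(records)}
    truth_rows.sort(key=lambda t: order[t.circ_id])
    return genome, records, TruthTable(truth_rows)


# ---------------------------------------------------------------------------
# count + proteomics simulation


def simulate_counts(truth: TruthTable, config: SimulationConfig) -> ExpressionMatrix:
    """Negative-binomial junction-read counts for the two-group design.

    Per-feature baseline means are log-uniform over
    ``baseline_mean_range`` (or ``fixed_baseline`` when set); BOO-group
    means are scaled by 2**circ_log2fc.  ``nb_dispersion = 0`` gives the
    Poisson limit.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = len(truth.entries)
    if config.fixed_baseline is not None:
        base = np.full(n, float(config.fixed_baseline))
    else:
        lo, hi = config.baseline_mean_range
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    l2fc = np.array([t.circ_log2fc for t in truth.entries])
    mean_sham = base
    mean_boo = base * np.power(2.0, l2fc)

    def draw(means: np.ndarray, n_samples: int) -> np.ndarray:
        m = np.repeat(means[:, None], n_samples, axis=1)
        if config.nb_dispersion <= 0:
            return rng.poisson(m)
        r = 1.0 / config.nb_dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, p)

    sham = draw(mean_sham, config.n_sham)
    boo = draw(mean_boo, config.n_boo)
    ids = [t.circ_id for t in truth.entries]
    df = pd.DataFrame(
        np.hstack([sham, boo]),
        index=pd.Index(ids, name="circ_id"),
        columns=config.sham_samples() + config.boo_samples(),
        dtype=int,
    )
    lengths = pd.Series(
        [max(t.mature_length, 1) for t in truth.entries], index=df.index, dtype=float
    )
    return ExpressionMatrix(df, config.groups(), feature_lengths=lengths)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    res = []
    for i in range(length):
        if i % 9 == 5:
            res.append("K" if rng.random() < 0.5 else "R")
        else:
            res.append(_AA_POOL[rng.integers(0, len(_AA_POOL))])
    return "".join(res)


def simulate_proteomics(
    truth: TruthTable, config: SimulationConfig
) -> tuple[ExpressionMatrix, list[str]]:
    """iTRAQ-style abundance table and observed peptide list.

    Rows are the planted candidate proteins plus ``n_decoy_factor`` times
    as many decoy background proteins constructed tryptic-peptide-disjoint
    from every candidate.  Abundances are log-normal around group means;
    consistent candidates carry the planted sign-matched protein effect.
    The observed peptide list is the union of theoretical tryptic peptides
    of candidates and decoys, each retained with ``peptide_detect_prob``;
    every consistent candidate is guaranteed at least one peptide
    overlapping its unique (junction) region.
    """
    rng = np.random.default_rng(config.seed + 3)
    coding = [t for t in truth.entries if t.is_coding]
    cand_peptides: dict[str, list] = {
        t.circ_id: tryptic_digest(t.protein_seq) for t in coding
    }
    all_cand_peps = {p.seq for peps in cand_peptides.values() for p in peps}

    n_decoys = config.n_decoy_factor * len(coding)
    decoys: list[tuple[str, str]] = []
    tries = 0
    while len(decoys) < n_decoys and tries < n_decoys * 20 + 50:
        tries += 1
        seq = _random_protein(rng, int(rng.integers(120, 301)))
        peps = {p.seq for p in tryptic_digest(seq)}
        if peps & all_cand_peps:
            continue
        decoys.append((f"decoy_{len(decoys) + 1}", seq))

    ids = [protein_id_for(t.circ_id) for t in coding] + [d[0] for d in decoys]
    l2fc = np.array(
        [t.protein_log2fc or 0.0 for t in coding] + [0.0] * len(decoys)
    )
    base = np.exp(rng.uniform(np.log(100.0), np.log(10000.0), size=len(ids)))
    n_s, n_b = config.n_sham, config.n_boo
    noise = rng.normal(0.0, config.protein_sigma, size=(len(ids), n_s + n_b))
    means = np.hstack(
        [
            np.repeat(base[:, None], n_s, axis=1),
            np.repeat((base * np.power(2.0, l2fc))[:, None], n_b, axis=1),
        ]
    )
    values = means * np.power(2.0, noise)
    df = pd.DataFrame(
        values,
        index=pd.Index(ids, name="protein_id"),
        columns=config.sham_samples() + config.boo_samples(),
    )
    abundance = ExpressionMatrix(df, config.groups())

    observed: set[str] = set()
    for t in coding:
        peps = cand_peptides[t.circ_id]
        kept = [p for p in peps if rng.random() < config.peptide_detect_prob]
        if t.is_consistent_candidate:
            lo = t.junction_residue_index
            hi = len(t.protein_seq)
            uniques = [
                p
                for p in peps
                if min(p.end_res, hi) - max(p.start_res, lo) + 1
                >= DEFAULT_MIN_OVERLAP
            ]
            if uniques and not any(p in kept for p in uniques):
                kept.append(uniques[int(rng.integers(0, len(uniques)))])
        observed.update(p.seq for p in kept)
    for _, seq in decoys:
        for p in tryptic_digest(seq):
            if rng.random() < config.peptide_detect_prob:
                observed.add(p.seq)
    return abundance, sorted(observed)


# ---------------------------------------------------------------------------
# dataset bundle + writers


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict
    annotation: Annotation
    records: list[CircRNARecord]
    truth: TruthTable
    counts: ExpressionMatrix
    protein_abundance: ExpressionMatrix
    observed_peptides: list[str]

    @property
    def circ_to_protein(self) -> dict[str, str]:
        return {cid: protein_id_for(cid) for cid in self.truth.coding_ids()}


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic study: reference, events, counts, proteomics."""
    genome, ann = generate_reference(config)
    genome, records, truth = generate_circ_events(genome, ann, config)
    counts = simulate_counts(truth, config)
    for rec, t in zip(records, truth.entries):
        rec.counts = {
            s: int(v) for s, v in counts.values.loc[rec.circ_id].items()
        }
    abundance, peptides = simulate_proteomics(truth, config)
    return SyntheticDataset(
        config=config,
        genome=genome,
        annotation=ann,
        records=records,
        truth=truth,
        counts=counts,
        protein_abundance=abundance,
        observed_peptides=peptides,
    )


def write_fasta(genome: dict, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(annotation: Annotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(
                f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n"
            )
        for g in annotation.genes:
            cols = [g.chrom, "circproteo_sim"]

            def line(ftype, s, e, attrs):
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "circproteo_sim",
                            ftype,
                            str(s),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

            mrna_id = f"{g.gene_id}.t1"
            line("gene", g.start, g.end, f"ID={g.gene_id}")
            line("mRNA", g.start, g.end, f"ID={mrna_id};Parent={g.gene_id}")
            for k, (s, e) in enumerate(g.exons, 1):
                line("exon", s, e, f"ID={mrna_id}.exon{k};Parent={mrna_id}")
            for k, (s, e) in enumerate(g.cds, 1):
                line("CDS", s, e, f"ID={mrna_id}.cds{k};Parent={mrna_id}")
            for k, (s, e) in enumerate(g.utr5, 1):
                line(
                    "five_prime_UTR", s, e, f"ID={mrna_id}.utr5.{k};Parent={mrna_id}"
                )
            for k, (s, e) in enumerate(g.utr3, 1):
                line(
                    "three_prime_UTR", s, e, f"ID={mrna_id}.utr3.{k};Parent={mrna_id}"
                )


def write_dataset(ds: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write the dataset as plain-text files; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "calls": os.path.join(outdir, "circ_calls.tsv"),
        "protein_abundance": os.path.join(outdir, "protein_abundance.tsv"),
        "peptides": os.path.join(outdir, "peptides.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "groups": os.path.join(outdir, "sample_groups.tsv"),
        "config": os.path.join(outdir, "config.json"),
    }
    write_fasta(ds.genome, paths["genome"])
    write_gff3(ds.annotation, paths["annotation"])
    write_call_table(ds.records, paths["calls"])
    ds.protein_abundance.values.to_csv(paths["protein_abundance"], sep="\t")
    pd.DataFrame({"peptide": ds.observed_peptides}).to_csv(
        paths["peptides"], sep="\t", index=False
    )
    with open(paths["truth"], "w") as fh:
        fh.write(ds.truth.to_json())
    ds.counts.groups.rename("group").to_csv(paths["groups"], sep="\t")
    with open(paths["config"], "w") as fh:
        fh.write(ds.config.to_json())
    return paths
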