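import numpy as np
import pytest

from circproteo.circ_catalog import Annotation, Gene

# independent codon table for test oracles, built codon-by-codon (the
# implementation translates whole ORFs via Bio.Seq on a concatenated string)
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TO_AA = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_junction_orfs(
    seq: str, min_aa: int, max_wraps: int = 4, require_junction: bool = True
) -> set:
    """Brute-force circular ORF scan using modular indexing, independent of
    the concatenation-based implementation.  Returns {(start_pos, protein,
    n_wraps)} for stop-terminated junction-spanning ORFs (all stop-terminated
    ORFs when require_junction is False)."""
    L = len(seq)
    out = set()
    for s in range(L):
        codon = seq[s % L] + seq[(s + 1) % L] + seq[(s + 2) % L]
        if codon != "ATG":
            continue
        prot = []
        pos = s
        found = False
        while pos + 2 <= (max_wraps + 1) * L - 1:
            codon = seq[pos % L] + seq[(pos + 1) % L] + seq[(pos + 2) % L]
            if CODON_TO_AA[codon] == "*":
                found = True
                break
            prot.append(CODON_TO_AA[codon])
            pos += 3
        if not found:
            continue
        n_wraps = (pos + 2) // L
        if (n_wraps >= 1 or not require_junction) and len(prot) >= min_aa:
            out.add((s + 1, "".join(prot), n_wraps))
    return out


def random_circle(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def two_gene_annotation():
    """Hand-built annotation: a plus-strand gene with UTR/CDS structure on
    chr1, a minus-strand gene further along, and open intergenic space."""
    gene_plus = Gene(
        gene_id="gA",
        chrom="chr1",
        start=101,
        end=700,
        strand="+",
        exons=((101, 300), (401, 700)),
        cds=((201, 300), (401, 600)),
        utr5=((101, 200),),
        utr3=((601, 700),),
    )
    gene_minus = Gene(
        gene_id="gB",
        chrom="chr1",
        start=1001,
        end=1400,
        strand="-",
        exons=((1001, 1150), (1251, 1400)),
        cds=((1051, 1150), (1251, 1350)),
        utr5=((1351, 1400),),
        utr3=((1001, 1050),),
    )
    return Annotation([gene_plus, gene_minus], {"chr1": 2000})
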