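# Methods

## The circular-ORF model

A mature circRNA of length *L* is treated as a covalently closed
sequence: position 1 abuts position *L* across the back-splice junction,
with no inserted bases. ORF scanning considers the three sense frames
only (the circle is a single-stranded RNA; a config flag could extend to
six frames but antisense ORFs are biologically implausible here).
Implementation: every ATG with start position in 1..*L* on a
(`max_wraps`+1)-fold concatenation of the sequence is translated to the
first in-frame stop. The candidate's codon span — start codon through
stop codon inclusive — must cross the junction at least once
(`n_wraps` ≥ 1); this includes the case where only the stop codon
crosses, since the encoded protein still terminates via the circular
junction (the worked 12-nt example "TAAGCAATGGCA" → "MA" exercises
exactly this). Frames with no stop within `max_wraps` = 4 traversals are
*rolling* ORFs: reported on request with `stop_found = False`, never
eligible for selection, because the fewest-residue selection rule
presupposes a terminated product.

Filtering rules, applied as stated and boundary-tested:

* **junction requirement** — non-crossing ORFs are excluded outright;
* **length** — strictly more than 100 residues (`min_aa` = 101), with
  the stop codon excluded from the residue count;
* **selection** — among qualifying ORFs of one circle, the one with the
  fewest residues; ties break by smaller start position, then
  lexicographically smaller protein (a documented, deterministic order —
  whether the original selection was global or per-frame is unknowable
  from the description, so the global minimum is used).

Start codons are ATG only, standard genetic code. De-duplication keys on
(start position mod *L*, protein), so rotation-equivalent reports
collapse. Correctness is pinned to an independent brute-force oracle
(modular-indexing scan) over random templates, plus the property that
the union over all *L* rotations of junction-crossing calls equals the
complete stop-terminated ORF set of the circle.

`junction_residue_index` is the first residue whose codon contains or
follows the first junction crossing (codon start ≥ *L*−2 in 0-based
coordinates), clamped to the last residue when the crossing falls inside
the stop codon.

## Unique-region derivation

With no parent protein the unique region runs from the junction residue
to the C-terminus. With a parent, substring-absence of C-terminal
suffixes is monotone in suffix length, so there is a unique boundary
residue *u*: the suffix from *u* is absent from the parent while the
suffix from *u*+1 is present. The unique region starts at *u*, extended
leftwards to include the junction residue if needed; when the whole
protein occurs in the parent the junction rule is the fallback. This is
the exact-substring formalisation of "the stretch not attributable to
the linear parent".

## In-silico divergent PCR

The forward primer is located as an exact match on the sense circle, the
reverse primer via its reverse complement; the product runs from the
forward 5' end around the circle to the reverse primer's 5' end.
Products are capped at one full circumference; a full-circle product
counts as junction-spanning (its wrap point is the junction). Multiple
exact sites for either primer raise an ambiguity error carrying every
possible product, rather than silently picking one.

## Differential expression

TPM: per sample, count/length(kb) rescaled to sum to 10^6. Calling
thresholds are **strict** inequalities on the linear pseudocounted ratio
(mean+1 on the TPM/abundance scale), in either direction: > 2 for
circRNAs, > 1.5 for proteins, each combined with raw p < 0.05.
q-values (BH step-up, via statsmodels) are reported alongside but do not
gate the headline call — the FDR control described for the study applies
to peptide identification, not DE. The per-feature test is a documented
choice, not a claim about the original analysis (which names no test for
these layers): Welch's t on log2(x+1) by default, exact Mann-Whitney
optionally. The Mann-Whitney implementation enumerates all group
assignments of the pooled values for pooled n ≤ 16 (covering the 7-vs-8
design, correct under ties with the ½-count convention) and falls back
to the tie-corrected normal approximation above that; the two-sided p is
P(U ≤ U_min) + P(U ≥ n₁n₂ − U_min) under the permutation distribution.
Constant-zero features get p = 1 and direction "none" by convention.

Calibration, measured by the suite and the acceptance script: on
fully-null negative-binomial matrices (dispersion 0.1, baselines
log-uniform [10, 5000], 8 vs 7) the empirical type-I rate at α = 0.05 is
≈ 0.045–0.05; with planted log2FC = 2 at baseline mean 1000 in the
Poisson limit, power is ≈ 1.

## Origin classification

The genomic-origin partition uses a fixed precedence: same-strand genes
first — both back-splice sites in exons → exonic, subclassified by the
dominant typed overlap (CDS / 5'UTR / 3'UTR; ties or untyped → exon
other); fully inside a gene otherwise → intron; genes only on the
opposite strand → antisense; else intergenic. Unknown strand matches
genes of either strand and is treated as plus for extraction. Interval
queries run on an `intervaltree` index built from a gffutils-parsed
GFF3; the partition is invariant to annotation input order. Upstream
catalog descriptions sometimes distinguish "introns" from "intronic";
no definition separates them, so a single intron class is exposed.
Mature-sequence length (not genomic span) feeds the length histogram —
"circRNA length" most naturally means the molecule.

## The synthetic study

The generator emulates the study design, not raw data:
it starts at the call-table level (no reads, chimeric alignments or
spectra; no RNase-R chemistry) on a toy genome (default 2 × 100 kb, 20
genes of 3–5 exons with UTR/CDS structure).

* **Events**: 200 circRNAs apportioned exactly (largest remainder) over
  a default origin mix dominated by CDS (50%), with 5'UTR/3'UTR/intron/
  antisense/intergenic minorities; the exon-other class (a typed-overlap
  tie) is classifiable but not generated. Placement is rejection-sampled
  so the unmodified classifier reproduces the requested class.
* **Coding circRNAs** (10% by default, ~the scale of the candidate set
  in this kind of study): the genome is *edited* within the back-splice
  span so the mature circle contains exactly one junction-spanning ORF
  of 101–180 residues — a designed codon layout (all codons ending C/G,
  no M/P in the body, K/R every ~8 residues for tryptic coverage, C/T
  filler) structurally excludes stray ATGs, and the design is verified
  by running the real ORF scanner before acceptance. The ORF wraps the
  junction by ≥ 21 nt so the unique region always spans ≥ 5 residues.
  Coding events claim their span exclusively so edits never leak into
  other events. Coding events are drawn from classes whose mature
  sequence can reach 312 nt (CDS/intron/antisense/intergenic).
* **Counts**: negative-binomial (dispersion 0.1; 0 = Poisson limit),
  baselines log-uniform [10, 5000] (junction-read depth regime without
  zero-inflation), BOO means scaled by 2^log2FC. All coding circRNAs
  plus 20% of the background are planted at |log2FC| = 2 with random
  sign — straddling the FC > 2 threshold from both sides is exercised by
  dedicated boundary tests rather than the generator.
* **Proteomics**: candidate proteins plus 5× peptide-disjoint decoys,
  log-normal noise (σ = 0.2 on the log2 scale; no noise model is
  described for the original proteomics, so this is a package choice),
  consistent candidates (60% of coding) at sign-matched |log2FC| = 1
  (> log2 1.5), other candidates at 0. The observed peptide list is the
  union of theoretical tryptic peptides of candidates *and decoys*, each
  kept with `peptide_detect_prob` (decoys included so the
  decoy-specificity property is non-vacuous), with one unique-region
  peptide guaranteed per consistent candidate.
* **Group sizes** default to 8 Sham vs 7 BOO — the only replicate counts
  the emulated design states (its qPCR arm); the sequencing/proteomics
  replicate counts are not reported, so the qPCR design is borrowed
  rather than guessed.
* The "noise-free" profile is negligible-noise, not zero-noise (Poisson
  at fixed baseline 1000, protein σ = 0.02, every peptide detected): a
  literally zero-variance layer would make any location test degenerate.

Everything is deterministic given the config seed, to the byte, in both
in-memory objects and written files.

What passing recovery tests show — and what they do not: the planted
truths are clean (single isoform per locus, no shared peptides between
candidates, exact-substring peptide identification, no batch effects,
no compositional extremes in TPM). Recovery of planted candidates
therefore demonstrates the correctness of the chain's logic, not the
expected sensitivity on real tissue data, where isoform ambiguity,
shared peptides and noisier quantitation all reduce power.

## Numerical and formatting choices

Pseudocount 1.0 on the TPM/abundance scale before log2 ratios. TPM
conservation is asserted at 10⁻⁶ relative tolerance. Report files use
`%.6g` floats and sorted JSON keys so identical inputs give
byte-identical outputs. Coordinates are 1-based inclusive everywhere
(GFF3 convention, matching the magnitude of published back-splice IDs);
the junction sits between positions *L* and 1 with no inserted bases.
I and L are treated as distinct residues in peptide matching (exact
matching; an I=L equivalence would be the natural extension for MS
practice but is not the default contract).

## Known limitations

* Exon structures are flattened per gene; alternative splicing within a
  circle is not modelled, and overlapping same-strand genes (possible in
  real annotations, absent in the generator) would classify by the
  first-by-coordinate gene satisfying the exon rule.
* The DE layer is threshold-based (as specified for the emulated
  analysis), not a count-model GLM; no batch correction.
* Peptide evidence is sequence-level; no spectra, PSM-level FDR or
  reporter-ion quantitation.
* GO/KEGG enrichment and figure rendering are out of scope; the pipeline
  emits the underlying tables.
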