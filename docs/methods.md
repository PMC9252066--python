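# Methods

This note documents the models, conventions, parameters and numerical
choices behind each pipeline stage, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Coordinates and the annotation table

Genomic coordinates are 1-based and inclusive on both ends, the convention
of Phytozome locus records; all interval arithmetic assumes it. Chromosome
numbers are parsed from locus IDs of the form `Sobic.NNNG......` (the three
digits after the genome prefix), with an explicit chromosome column taking
precedence when present. The bundled annotation table carries no strand
column; strand defaults to `+` and only matters for promoter extraction,
where it must be supplied for real genomes.

Row invariants — CDS length divisible by three, protein length equal to
CDS/3 − 1 (the terminal stop excluded), domain spans inside the protein —
are fatal on the bundled fixtures and collected as warnings on user data,
with a strict flag to escalate.

## Nomenclature (40%/60% identity rules)

Pairwise identity is computed over a global Needleman–Wunsch alignment with
affine gaps (BLOSUM62, gap open 10, extend 0.5 — standard global-alignment
defaults; the aligner is Biopython's `PairwiseAligner`, whose first
enumerated traceback is deterministic). The identity denominator is the
full alignment length including gap columns — the conservative reading of
"X% identical" — and is configurable to the shorter-sequence length.
Threshold comparisons are strict (`>`): identity of exactly 40.0 or 60.0
falls to the lower tier. The published rules use "identical" and
"similarity" interchangeably; identity (not positive-score similarity) is
implemented, as a configurable choice.

Ties for best reference break by lowest family number, then lexicographic
reference ID. New subfamilies within an inherited family take the next
unused letter. Novel families receive the symbol `<root>novelK` with a
running index; this branch never arises on the bundled data. Splice
variants are lettered `a, b, c, …` by lexicographic transcript-ID rank
(not by suffix digit — annotation tables sometimes start at `.2`), and
single-transcript genes take no letter.

## Active-site patterns

The PROSITE pattern engine supports fixed residues, `[..]` allowed and
`{..}` forbidden sets, `x` wildcards, `(n)`/`(n,m)` repetition and `<`/`>`
anchors. Repetition ranges are explored with full backtracking, and the
scanner reports, per start position, the longest matching subsequence
(overlaps between distinct starts all kept) — equivalence with a
reachable-position dynamic-programming oracle is property-tested. Presence
semantics are used for the yes/no site flags: a protein has a site iff the
scan yields at least one match. Ambiguity handling is conservative: `X` in
a protein matches only wildcards; `B`/`Z` match only explicit set
membership.

The shipped PS00687/PS00070 pattern strings are editable configuration
(`data/prosite_patterns.txt`); they should be re-transcribed from the
current PROSITE entries before being relied on in a release, since the
accession — not the pattern text — is the stable identifier.

## Duplication classes, Ka/Ks, and dating

A homologous pair is **tandem** when both loci share a chromosome and the
inter-gene gap (upstream end to downstream start; zero when spans overlap)
is at most the 100-kb window. All remaining homologous pairs are
**segmental**. The literature criterion of ">90% sequence identity" for
segmental pairs contradicts the observed statistics of real segmental pairs
(Ks near 1.5–2.5 implies far lower CDS identity), so the tandem test takes
precedence and the 90% rule is retained only behind an optional strict
flag. Default pair discovery is all within-family locus pairs at ≥60%
protein identity; user-supplied pair lists bypass discovery.

Ka/Ks uses Nei–Gojobori (1986) counting. Synonymous site fractions per
codon position count the share of the three possible single-nucleotide
changes that preserve the amino acid, with changes to stop codons excluded
from both numerator and denominator (NG86 variants differ here; at the
divergence levels of interest the effect is below reporting precision).
Codon differences average over all minimal substitution pathways (1, 2, or
6 orderings), dropping pathways through stop codons; if every pathway is
blocked — possible only for 2–3 differences — the average falls back to all
pathways so the difference count stays conserved. Sites are averaged over
the two sequences, proportions are corrected with JC(p) = −(3/4)·ln(1 −
4p/3) (undefined at p ≥ 3/4, reported as saturated), and the ratio is
undefined when Ks = 0. Codon columns are obtained by back-threading a
protein alignment onto the CDS and dropping gap and ambiguous columns.

Dating is T = Ks/(2λ). The configuration default is λ = 6.1 × 10⁻⁹
substitutions/site/year, the value stated in the source workflow's methods;
the divergence times printed in its duplication table are, however, only
consistent with λ = 1.5 × 10⁻⁸. Both are supported (`--rate`); the
discrepancy is documented rather than resolved, and fixture-facing checks
use the table-implied rate explicitly.

**Reporting convention:** Ka, Ks and Ka/Ks are truncated — not rounded — to
4 decimals and times to 2 (0.1664/2.5295 → 0.0657, not 0.0658; 1.0913/0.03
→ 36.37, not 36.38). A 0/0 pair renders as `∞` with time
`Not determinable`; any other undefined value renders `NA`.

## Copy-number evolution

The published analysis reads ancestral copy numbers off family trees; here
the ancestral (MRCA) count is the number of cross-species ortholog
clusters, which reproduces every printed scenario deterministically without
a likelihood phylogeny (the tree route stays available through the
neighbor-joining utility). "At least N ancestral genes" is reported as
equality; the lower-bound nuance is noted here once. Losses for a lineage
are clusters where it is absent; gains are its extant surplus over the
clusters it occupies; the identity extant = ancestral − losses + gains then
holds by construction and is validated on every `ExpansionSummary`.
Clustering is reciprocal-best-hit seeding plus best-hit attachment above an
identity threshold, deterministic for a fixed input order with ties broken
by gene ID.

Neighbor joining is the standard Saitou–Nei agglomeration, implemented
in-package so the tie rule (smallest index pair on equal Q) is part of the
contract; recovery of additive trees is property-tested against dendropy's
tree comparison, and negative branch-length estimates are clamped to zero.

## Promoters and cis-elements

Promoters are length-L windows (default 1000 bp) immediately 5' of the
anchor: `[start−L, start−1]` for `+` genes, reverse complement of
`[end+1, end+L]` for `−` genes, truncated with a warning at chromosome
ends. The anchor is the annotated gene start by default and the
translation start when supplied — upstream sets extracted from gene records
and from CDS starts differ, so the choice is an explicit flag.

Scanning is IUPAC-aware on both strands with positions on the forward
promoter coordinate; `N` in a promoter matches nothing, and overlapping
matches of one motif all count (the reference web tool's overlap policy is
unpublished). The shipped catalog (`data/plantcare_catalog.tsv`) carries
PlantCARE-style consensi as editable configuration; because the underlying
matrices are not published, absolute counts from any particular catalog are
not treated as ground truth, and per-element reports count genes with at
least one occurrence. Promoter units may be genes or transcripts; both
modes are supported by passing the corresponding ID set.

## Expression and qPCR

Percent-of-maximum scales each gene row to its maximum across the provided
samples; this approximates, but is not identical to, proprietary
"expression potential" normalizations, so absolute published percentages
are treated as documentation examples only. All-zero rows are flagged
not-assessable. Condition averages are plain means over all gene × sample
cells of a group. High-expression counts use a strict > threshold (default
60%). Row clustering uses Manhattan (city-block) distance with
unweighted-average linkage via SciPy; the exact linkage default of the
original heatmap software is unstated, so UPGMA-style average linkage is
the documented choice.

2^−ΔΔCt: per condition ΔCt = Cq(target) − Cq(reference); each treated
replicate's ΔΔCt is taken against the mean control ΔCt; the fold change is
reported as mean ± standard error of the per-replicate 2^−ΔΔCt values
(SE on the fold-change scale, not on ΔΔCt then transformed, matching
"mean ± SE" reporting; ddof = 1, SE = 0 for a single replicate).

## Physicochemistry

Molecular weight sums average residue masses plus one water (18.0153 Da).
The isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14]
to |charge| < 10⁻⁴, using the Bjellqvist pKa set (N-term 7.5, C-term 3.55;
D 4.05, E 4.45, C 9.0, Y 10.0; H 5.98, K 10.0, R 12.0); the charge
function is strictly decreasing, so the root is unique. Summary means are
rounded half-up at the reporting precision (0 dp for lengths, 2 dp for MW
and pI); minima and maxima are exact. Since real family sequences are not
bundled, per-protein MW/pI are not recomputed — only the fixture-column
aggregates are asserted. Note that prose summaries sometimes transpose the
pI and MW labels (a mean pI of 6.59 and mean MW of 57.22 kDa); each
statistic is reported under its correct column here.

## Synthetic data: what passing tests show

Generators are pure functions of parameters and seed. Their defaults state
the study conditions: protein identities planted at 85/50/25% straddle the
40/60 thresholds; duplication pairs use 300 codons with 10 synonymous + 10
nonsynonymous substitutions (≈5% divergence, the regime of the real
pairs); promoters are 0.3–1 kb with exact planted counts; qPCR tables use
3 replicates and σ = 0.1 cycles of Gaussian Cq noise.

Deliberate simplifications: substitution-only protein evolution (no
indels, uniform residue usage), at most one nucleotide change per codon,
no codon-usage bias, motif-free backgrounds by iterative rejection repair,
multiplicative lognormal expression noise. Passing recovery tests
therefore shows the estimators are correct under their own model
assumptions — not that real divergent sequences (with indels, saturation,
or biased composition) would be recovered at the same accuracy. Identity
calibration is exact by construction (k = round((1 − p)·L) substitutions),
so no iterative recalibration is normally needed; the cap of 1000
iterations applies to background repair in the promoter generator.

Acceptance-facing recovery metrics use 10–20 seeded replicates per
quantity and the test suite up to 50 — sizes chosen to keep the whole
suite in the tens of seconds on one CPU while leaving the observed errors
an order of magnitude inside their tolerances (Ka/Ks recovery errors are
below 1% against a 25% bound; fold-change errors below ~5% against 15%).

## Known limitations

* Domain coordinates (PF00171 spans) are accepted as input, not computed —
  no HMM search is performed.
* Maximum-likelihood phylogenies, de novo motif discovery, synteny-block
  detection, localization prediction and structural modelling are out of
  scope; where the original workflow used them, this package either takes
  their outputs as inputs or substitutes the documented deterministic
  procedure (orthogroup counting, NJ utility).
* The PROSITE and PlantCARE catalogs ship as editable configuration and
  must be verified against the live databases before release-grade use.
* Expression percentages depend on the sample set provided; published
  values derived from proprietary sample collections are not reproducible
  from bundled data and are not asserted anywhere.
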