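# Methods

This note records the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where several defensible
options existed.

## Sequence handling and ORFs

ORFs are called on the forward strand only, reflecting cloned cDNA
input where orientation is known; a reverse-complement scan is
deliberately not the default. An ORF runs ATG→stop **inclusive of the
stop codon**, so a 783 nt ORF encodes 260 residues (261 codons). With
`allow_partial`, in-frame runs truncated at the sequence ends are
reported with the matching completeness flag cleared — the common case
for PCR-validated transcript sets where a handful of clones miss the
5' end. When a record's single "the ORF" is selected, complete ORFs are
preferred over longer truncated runs; a truncated run is used only when
no complete ORF passes the length threshold, since in intact clones a
random 5'-truncated frame run frequently outranks the genuine CDS by
raw length.

Translation uses the standard genetic code; ambiguous (N-containing)
codons translate to X under the lenient policy and X residues are
excluded from mass/pI computation and Ka/Ks sites, so no data are
invented for them.

## Codon alignment

Ortholog pairs are aligned at the protein level (global
Needleman–Wunsch, BLOSUM62, gap open −11 / extend −1 — fixed constants,
so alignments are reproducible bit-for-bit) and the gaps are projected
back onto codons. Every alignment gap is therefore codon-phased and
degapping recovers the inputs exactly, which the tests assert as a
round-trip invariant.

## Cysteine-signature classification

Spacing semantics: X<sub>n</sub> = exactly n residues strictly between
consecutive labelled cysteines; X<sub>a-b</sub> = a..b inclusive.

Two modes:

- `count_based` (default): six cysteines → Classic; four → Minus-C,
  disambiguated from CSP by the CSP gap check (or by a declared family
  hint, which wins); eight to ten with the conserved cysteine–proline
  dyad → Plus-C. This is the primary rule because cysteine **count** is
  the field's first-line subclassification criterion.
- `strict`: additionally requires every spacing to fall inside the
  class pattern. Spacings printed as single values (e.g. Minus-C "X32",
  "X18", all CSP values) are widened by a configurable tolerance
  (default ±2), because such patterns summarize an alignment of real,
  slightly variable sequences and cannot be simultaneously exact for
  every family member. Strict-mode disagreements are reported in the
  per-gap diagnostics rather than silently absorbed.

The Plus-C pattern is modelled with labelled cysteines
C1,C2,C3,C4,C4a,C5,C6,C6a; the conserved proline sits immediately after
C6 (so the C6–C6a gap of ten residues is the proline plus nine others),
and the trailing-length constraint (13–26 residues after C6a) is
enforced only in strict mode. In count-based mode the Plus-C hallmark
is implemented as "a proline immediately following a non-terminal
cysteine": requiring an adjacent C–C pair instead would contradict the
spacing pattern itself, whose smallest inter-cysteine gap is three.

Strict acceptance implies count-based acceptance for the same label
(strict is a refinement); the tests check this and verify the whole
classifier against an independently written declarative oracle on an
exhaustive grid of every range boundary ±1.

## Molecular mass and isoelectric point

Mass is the sum of average (not monoisotopic) residue masses plus one
water — the convention of standard proteomics servers. pI solves net
charge = 0 under Henderson–Hasselbalch over D, E, C, Y, H, K, R and the
termini with the Bjellqvist pKa set (N-terminal pKa depends on the
first residue); the constants ship in `physchem.py` and alternative
sets can be passed in. Net charge is strictly decreasing in pH, so the
root is unique; bisection stops at |charge| < 1e-4, which the tests
bound against a 0.001-step grid scan. Reported values use half-up
rounding at two decimals, matching how such tables are printed.

## Motif discovery

Site model: ZOOPS (zero or one occurrence per sequence), the default of
the standard EM motif tools. Each sequence has prior probability γ of
containing one occurrence, uniform over eligible starts; γ starts at
0.5 and is re-estimated each iteration (clipped to [1e-3, 0.999]).
PWM counts get pseudocount 0.01; EM stops when the observed-data
log-likelihood gains < 1e-6 or after 200 iterations. Per width (6–10),
20 starts are seeded from the most frequent data k-mers with ties
broken lexicographically — seeding depends on data content, not input
order, so motif ranks are stable under sequence permutation and no
random stream is consumed. Up to 8 motifs are found sequentially, each
round masking the confident occurrences (posterior > 0.5) of the motif
just found.

Motifs are ranked by information content × expected site count. This is
a deliberate simplification: the E-value objective of the online MEME
tool is not reproduced, so motif-pattern counts on real families are
qualitative; the pattern machinery is validated by planted-architecture
recovery instead (an 80/20 two-architecture mixture is recovered within
binomial tolerance). Scanning reports all positions with log-odds ≥ 0
against the background (configurable), resolving overlaps
best-score-first; with distinct scores this greedy rule provably equals
the lexicographically best non-overlapping subset, which the tests
confirm by exhaustive search.

## Ka/Ks (NG86)

Sites: each of the three positions of a sense codon contributes 1/3 of
a site per possible change, counting only changes to sense codons —
stop outcomes are excluded from the denominator, so a codon carries
between 2 and 3 sites (e.g. Trp TGG: 0 synonymous, 7/3 total). Note
this means S + N is slightly below 3 × codon columns; the
stop-exclusion convention is the one kept, as it is the classic NG86
treatment. Differences: each differing codon pair is decomposed by
averaging over all orderings of its single-base steps with equal
weights; orderings passing through stop codons are dropped, and a codon
pair whose every ordering is blocked is skipped (with a warning) from
both differences and sites. Gapped, ambiguous and stop-containing
columns are skipped. S and N are averaged over the two sequences;
p<sub>S</sub> = Sd/S and p<sub>N</sub> = Nd/N are Jukes–Cantor
corrected, d = −(3/4)·ln(1 − 4/3·p); p ≥ 3/4 is saturated and the rate
is undefined (NaN). Ka/Ks is NaN when Ka = Ks = 0 and +∞ when Ks = 0 <
Ka; both are excluded from medians. The median of an even number of
values is the mean of the two central ones.

The published per-pair table this package ships was produced with a
model-averaged estimator; NG86 was chosen here because it is fully
specified and desk-verifiable, so per-pair values on re-derived
alignments may deviate from the published ones. Medians of the
published values themselves, and the "every ratio < 1" bound, are exact
reproduction targets; per-pair re-estimation is not.

One estimator subtlety: under a purely synonymous substitution process
(ω = 0), path averaging can attribute a small nonsynonymous fraction to
codons hit twice (e.g. TTA→CTA→CTC has an ordering through TTC), so
estimated Ka is near — not exactly — zero; the generator invariant
(identical encoded proteins) is exact.

## Trees

Neighbor-joining agglomeration is delegated to scikit-bio on a
symmetric distance matrix; protein p-distances ignore, per pair, the
columns where either sequence is gapped. Bootstrap support resamples
alignment columns with replacement (default 1000 replicates) and scores
each internal bipartition of the original tree by the fraction of
replicate trees containing it; supports are written as fractions onto
internal node labels. On additive matrices NJ recovers topology and
branch lengths exactly, which the tests assert on a five-taxon case.

## qPCR expression

Primer efficiency: least-squares slope of mean Ct vs log10 input,
E% = (10^(−1/slope) − 1)·100; a slope of −3.3219 (perfect doubling) is
100%. Curves outside a configurable 90–110% band are flagged.

Quantification: technical replicates are averaged first; ΔCt =
Ct_target − Ct_reference per (tissue, biological replicate); relative
expression is 2^−ΔΔCt with ΔΔCt referenced to the calibrator tissue's
mean relative level in the **linear** domain. This makes the
calibrator's mean relative expression exactly 1 by construction; with
noise-free replicates it coincides with subtracting the calibrator's
mean ΔCt (the two differ only by Jensen's inequality under replicate
noise). Dispersion is reported as SE over biological replicates.

The "nested" ANOVA is implemented as technical-replicate averaging
followed by one-way ANOVA on biological replicates — for a balanced
design this is algebraically identical to the nested model's
between-tissue F test, which the tests verify against an independently
coded two-step computation. Tukey HSD (statsmodels) provides the
pairwise significance matrix; the compact letter display is assigned
greedily from the highest mean (a group joins an existing letter iff it
is not significantly different from every current member). All-equal
inputs are reported as p = 1 with a single shared letter rather than a
degenerate F.

Enrichment categories are an explicit operationalization (the
boundaries between "specific", "enriched" and "broad" are not uniquely
defined in the field): *tissue_specific(t)* requires the top mean in t,
Tukey separation from every other tissue, and a mean fold ≥ 50 versus
every other tissue; *tissue_enriched(t)* requires the separation but
not the fold bar; everything else is *broad*. The 50× default lets
genes with ~60-fold antennal enrichment — the low end reported for
antennae-specific chemosensory genes — qualify as specific; both the
fold bar and α are parameters. Categories are invariant under the
choice of calibrator tissue, since relabelling rescales all tissues
jointly.

## Synthetic data

One seed per `SimSpec`; each generator draws from a substream derived
by stable hashing of its operation name, so adding a generator never
shifts the streams of the others, and identical specs produce identical
bytes.

- `gen_family` places cysteines by sampling each class's spacings
  uniformly within the signature ranges (singleton spacings verbatim),
  fills the rest from a cysteine-free background so the planted
  signature is exact, prepends a signal peptide (15–27 aa: Met, charged
  n-region, L/I/V/F hydrophobic core, small residues at −3/−1), and
  back-translates with random synonymous codons plus a random stop.
  Full-length proteins fall in 124–260 aa, with per-class minima when a
  signature cannot fit. The class mixture defaults to the 26:10:2
  Classic/Minus-C/Plus-C proportions of the motivating gene set.
- `gen_ortholog_pairs` samples ancestral sense codons and evolves a
  descendant by Poisson(3·branch_len) single-base proposals per codon,
  accepting synonymous proposals always, nonsynonymous with probability
  ω, and rejecting stop-creating ones — so the realized dN/dS is ω by
  construction. Default branch length 0.4 yields Ks around 0.2–0.5,
  comparable to the published pairs' lower range.
- `gen_ct_table` plants fold effects on the Ct scale (one doubling =
  −1 cycle) around a flat reference gene, with Gaussian noise
  (default sd 0.2 cycles) on every measurement; truth categories follow
  the enrichment rules (specific ≥ 50×, enriched ≥ 4×).
- `plant_motifs` embeds consensus k-mers (per-position mutation
  probability 0.05) in order-preserving slots of background sequence.

What the generators deliberately do **not** emulate: empirical
amino-acid exchangeabilities, codon-usage bias, transition/transversion
bias, indels in ortholog pairs, inter-gene correlation in qPCR noise,
or signal peptides with atypical cleavage contexts. Passing
planted-truth tests therefore demonstrates the correctness of the
estimators and decision rules under the stated models, not robustness
to every property of real transcriptome data — on real sequences,
classification in strict mode and per-pair Ka/Ks values should be
expected to show the deviations discussed above.

## Problem sizes

Test and acceptance runs use 200-protein families, 50 ortholog pairs ×
300 codons per ω level, 30–100 motif-planted proteins with discovery
capped at the planted motif count, 200 planted qPCR genes (60 in the
acceptance script), and 50–1000 bootstrap replicates depending on
context — sizes at which every recovery statistic is comfortably inside
its tolerance while the whole suite stays fast.
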