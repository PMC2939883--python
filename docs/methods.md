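# Methods

## The screen

The package reconstructs, as testable code, an in silico survey for
carboxylate-clamp (CC) TPR proteins: proteins carrying at least one
three-motif tetratricopeptide-repeat domain whose clamp positions (K5 and N9
in motif I; N6 in motif II; K2 and R6 in motif III; 1-based within each
34-residue motif) retain residues compatible with binding the EEVD tails of
cytosolic Hsp90/Hsp70. The original survey ran a profile-HMM search over the
Arabidopsis and rice proteomes and then screened hits for the clamp
residues; this package replaces the HMM stage with a bespoke position-profile
scanner (below) and ships the survey's curated motif tables as fixtures so
the clamp stage, the census and the phylogeny are reproducible without any
database access. Equivalence with the original HMM search is not claimed —
only recovery of the curated CC-TPR sets, which the acceptance suite checks.

## Position profiles

Each motif (I, II, III) has a 34 × 20 profile trained on the pooled fixture
alignments: 72 rows for motifs I and III (36 Arabidopsis proteins, the human
Hop TPR2a reference — which the original alignment also included — and 35
rice proteins), 70 for motif II (two rows are printed with 33 residues and
are excluded; see "Register anomalies"). Column probabilities use a Laplace
pseudocount κ (default 1.0) over a uniform background:

    p_c(a) = (n_c(a) + κ) / (N + 20κ),   score_c(a) = log2(20 · p_c(a))

A window's score is the summed per-column log-odds; `X` scores 0. The uniform
background keeps the model free of external composition tables; profiles
serialize to JSON bit-exactly.

**Scan threshold.** Per motif, threshold = (minimum self-score of the
training rows) − 2.0 bits. The margin admits every training motif plus near
relatives while leaving a wide gap to random sequence: for motif I the
weakest training row scores 25.1 bits while 1000 uniform random 34-mers
average −33 bits (max −1.6). Motif II is the most degenerate (weakest row
−1.6 bits), so isolated spurious motif-II hits do occur in random sequence;
they are harmless because a positive verdict requires a complete I→II→III
chain, which random sequence essentially never produces (0 background false
positives in the benchmark).

## Domain assembly

Hits are chained I→II→III when both linkers (start of next minus end of
previous, minus 1) fall in [−2, 60] — the range spanned by the fixture
spacings (0 to 56, plus one documented −1 overlap) with headroom. Same-index
hits whose starts lie within 17 residues collapse to the local score maximum.
Among candidate chains, a maximal non-overlapping set is chosen greedily by
summed score, ties to the smallest start; this is exact at the observed
densities (at most two domains per protein). Proteins shorter than 34
residues scan to an empty hit list rather than an error.

## Register rescue

One fixture motif (AtTPR5 motif II, annotated start 118) shows the conserved
Asn at motif position 5; starting the motif at 117 places it at its canonical
position 6. The rescue generalizes this: for each motif a ±1 shift is applied
iff it **strictly increases the number of clamp positions with acceptable
status** (consensus or conservative); ties keep the annotated register.
Counting *acceptable* rather than exact-consensus matches is deliberate: the
Hop-ortholog third motifs carry a conservative K2→R with a chance lysine one
position downstream, and an exact-match criterion would shift them away from
their curated register without changing any verdict. The shift is limited to
±1 because that is the only documented slip. In fixture-only mode (no
full-length sequence) the shifted-in boundary residue is unknown and is
padded as `X`; no clamp position ever falls on the pad.

## Clamp rule and substitution classes

Each clamp position is typed by a partition of the 20 residues by side-chain
volume and polarity:

    {K,R,H} {D,E} {N,Q} {S,T} {F,Y,W} {L,I,V,M} {A,G} {C} {P}

identical → consensus, same class → conservative, otherwise (including X) →
radical. The partition is the coarsest standard physicochemical grouping
under which every replacement the source survey treats as conservative
(K↔R, N→Q) is within-class and every one it treats as radical (K→E, R→A,
R→M, N→S, N→D) is across-class; the survey itself cites volume/polarity
without printing a table.

A protein is CC-TPR positive when its best domain (max n_match, then max
summed profile score, then smallest start) keeps **min_matches = 3** of the 5
clamp positions acceptable. The survey's own accept/reject step was partly
manual; 3 is the smallest value consistent with its weakest accepted protein
(AtTPR4: three exact matches, two radical substitutions) and is exposed as
configuration rather than presented as the survey's literal rule.

## Register anomalies

Two fixture rows print 33 residues instead of 34 (AtTPR5 motif II and rice
Os05g03910 motif II, both consistent with a one-residue register slip in
their annotation). They are loaded exactly as printed, flagged
`length_anomaly`, excluded from profile training, and corrected by the
register rescue at classification time; clamp positions beyond a short
window would be typed radical and flagged, but after rescue all five
positions are readable for both rows.

## Architecture census

Positives are classed single_TPR / single_TPR_plus_domain / multi_TPR /
multi_TPR_plus_domain, split by novelty. The number of TPR domains and the
additional functional domains come from the packaged property table (or an
external annotation TSV standing in for an InterProScan run — domain-database
querying is out of scope); the verdict's own domain count is used when no
metadata matches. Name joins are hyphen-insensitive because the source tables
typeset some names inconsistently (AtToc64-III vs AtToc64III).

## Phylogeny

Distances are p-distances: 1 − identities / aligned non-gap columns, either
from pairwise global alignment of full-length sequences (BLOSUM62, gap open
−10, extend −0.5 — documented defaults, not values inferred from the original
procedure, which does not state its parameters) or column-wise from a
supplied alignment such as the concatenated 102-column motif alignment
(length-anomalous motifs padded with a leading gap, matching their register
reading). Pairs are aligned in a canonical orientation so the distance is
exactly symmetric even when co-optimal alignments differ. Trees are built
with neighbor joining (scikit-bio's implementation behind the module
surface), negative branch lengths clamped to 0. Bootstrap supports resample
alignment columns with replacement under a named seeded generator; the
support of each internal bipartition of the point tree is its recurrence
count among replicate trees. If all pairwise distances are zero the tree is
uninformative and every support is defined as n_replicates. The original
figure's topology and bootstrap values are not reproduction targets (they
depend on a full-length progressive alignment); the package asserts instead
the algorithmic properties — exact path-distance recovery on additive
matrices, agreement with a brute-force four-taxon oracle, and seed
reproducibility — and the desk-scale run in `analysis/03_phylogeny.py`
(71 leaves, 100 replicates) recovers known ortholog pairs.

## Synthetic proteomes

The generator emulates the statistical structure the screen assumes — and
only that: background proteins are i.i.d. draws from a uniform residue
background (matching the profile background); planted proteins embed one
I→II→III domain at a random interior offset, motifs drawn per-column from the
profile probabilities with clamp residues forced to consensus, linkers
uniform on [0, 60]; decoys additionally break 3–5 clamp positions (default 3)
with a residue from a different substitution class. Breaks are made
**register-robust**: the two flanking residues are also forced out of the
consensus class, so a ±1 rescue can never restore a broken position and the
decoy set probes the clamp rule rather than the rescue heuristic. Protein
lengths are uniform on [200, 800] residues (typical of the curated set, which
spans 161–1165). Generation is a pure function of the spec, seed included.

Not emulated: evolutionary divergence between planted motifs and the
profile, indels inside motifs, splice variants, natural residue composition,
and degenerate TPR-like repeats. Passing the benchmark therefore shows the
pipeline recovers domains of the kind the profiles describe and rejects
clamp-broken ones; it does not bound sensitivity to genuinely divergent
domains in real proteomes.

## Problem sizes and numerics

The packaged study is small by construction: 216 fixture motif rows, 150
synthetic proteins (50 per category) in the benchmark, 100 bootstrap
replicates in the analysis tree (1000 supported and used in the dedicated
bootstrap test). Scores are plain float64 sums of log-odds; column
probabilities are validated to sum to 1 within 1e-9; distance matrices to be
symmetric within 1e-12; NJ path-distance recovery is asserted to 1e-9. All
randomness flows through numpy `default_rng` with explicit seeds.

## Known limitations

- The clamp rule (min_matches = 3 over consensus-or-conservative) is a
  reconstruction of a partly manual decision; borderline proteins in new
  proteomes deserve inspection, for which verdict tables carry all five
  per-position statuses.
- The scanner has no insert/delete states, so TPR motifs interrupted by
  indels are found only if a shifted 34-mer still clears the threshold.
- The census depends on externally supplied domain annotations; it does not
  detect non-TPR domains itself.
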