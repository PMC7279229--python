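# Methods

## Motif model

The motif engine implements the degenerate consensus notation used in
plant/algal kinase surveys: fixed residue letters, single-position
alternations `(A/B/…)`, the wildcard `x`, and bounded wildcard runs
`x{m,n}` with 1 ≤ m ≤ n (zero-length wildcards are deliberately rejected —
every printed consensus has a fixed minimum span). Matching is exact: there
is no mismatch tolerance, no position weighting and no profile scoring.
All occurrences are reported, including overlapping ones and, for a
quantified wildcard, every expansion length; at a fixed start the shortest
expansion comes first, which makes match coordinates deterministic. The
unknown residue `X` satisfies no pattern position, including `x`, so
gap-filled stretches of a draft proteome cannot produce motif hits.

The MAPKK activation motif defaults to `GTx{2,3}YMSPER`. The two-wildcard
form `GTxxYMSPER` is the search string used in the literature, but the
printed *C. reinhardtii* MAPKK site (`GTVTTYMSPER`) is an 11-residue
instance with three variable positions; the bounded quantifier accepts
both. The strict form remains available (`strict_motifs`).

A pattern's specificity score `n_fixed` is its number of fully determined
(single-residue) positions: MAPK 11, ZIK 10, MAPKK 8, MEKK 7, RAF 6. This
is a strict total order, asserted in the tests so registry edits cannot
silently reorder family precedence. The overlaps that occur in practice —
every ZIK site is also a MEKK site, and many MEKK sites are RAF sites —
are resolved toward the more constrained motif, which is the more
informative one.

## Kinase-domain confirmation

The canonical eukaryotic protein-kinase domain reads, N→C: glycine-rich
P-loop (`IGxGxxGxV`), catalytic C-loop (`HRD(L/I/V)KPxN`), activation
segment (T-loop) carrying the family motif. Confirmation is an
ordered-loop spacing heuristic rather than a profile-HMM match: the C-loop
must end 5–80 aa before the activation motif and a P-loop must end
40–260 aa before the C-loop. Both windows reflect canonical ePK dimensions
and are configuration fields, since no numeric criterion is standard.
A loose P-loop (`GxGxxG`) is accepted in confirmed mode because genuine
MAPKs exist that lack the strict consensus; rejecting them on the strict
P-loop alone would contradict the inventories this pipeline reproduces.
`loose` mode gates only on the activation motif and exists for recall
exploration; all shipped defaults use `confirmed`.

The consensus docking domain (CDD) of a MAPK is sequence-variable across
proteins, so it is reported only as the coordinate region from the
activation-motif end to the sequence end, and never used for filtering.
Domain position (N-terminal / central / C-terminal) is the relative
position of the midpoint of the P-loop→T-loop span, thresholds 0.40/0.60.

Group rules: MAPK TEY → C, TDY → D, other TxY variants (TTY/TSY/TPY…) → E.
The D/E boundary among TDY kinases is phylogenetic, not motif-based, so the
rule path labels TDY proteins D with an explicit `ambiguous_DE` flag; when
a tree with anchor leaves of known group is supplied, the nearest anchor
(by path length) decides. RAF groups are assigned by signature in the order
G → H → A/C; groups B/D/E/F have heterogeneous activation sites and remain
`unassigned` on the rule path. The A/C split uses a C-terminal tail
threshold of 150 aa past the activation motif (configurable).

## Physicochemical properties

Molecular mass is the average (isotope-weighted) mass: the Expasy residue
mass table plus one water, fixed at 18.02 Da. Mass is undefined over `X`.
Theoretical pI follows the Bjellqvist model behind the Expasy ProtParam
service: Henderson–Hasselbalch net charge over the two termini (terminal
pKa depending on the terminal residue) and the D, E, C, Y, H, K, R side
chains. The charge is strictly decreasing in pH, so the zero is unique;
bisection on [0, 14] stops at |charge| < 1e−6 or a pH step < 1e−4. The
tests verify agreement with a 1e−4 pH-grid argmin to better than 1e−3 and
with Biopython's independent ProtParam implementation to 0.01. Reported
values are rounded to two decimals; internal values are full precision.

## Alignment and phylogenetics

Pairwise global alignment uses affine gaps (gap of length L costs
open + (L−1)·extend) with BLOSUM62, open −10, extend −0.5 — chosen to
approximate ClustalW-era protein defaults. It is backed by Biopython's
`PairwiseAligner`; optimality is tested against exhaustive enumeration on
short pairs. Percent identity counts identical pairs over columns with no
gap in either row. That denominator choice matters: for unrelated random
300-mers it yields ~28% identity (empirical maximum < 36% over 100 pairs),
so the duplicate-detection signal (~90% at mutation rate 0.1) is judged
against that background, not against zero.

The progressive MSA follows the ClustalW scheme: pairwise p-distances →
UPGMA guide tree (scipy average linkage) → profile–profile alignment with
column scores averaged over all residue pairs (gap symbols score 0) under
the same affine penalties. The DP is quadratic per merge and written in
Python; it is intended for family-sized inputs (tens of sequences), not
whole proteomes.

Evolutionary distances use the Poisson correction d = −ln(1 − p), p the
proportion of differing sites among columns gapped in neither row;
p ≥ 1 or zero comparable columns is an error. Trees come from canonical
neighbor joining with the Q criterion, lowest-index tie-break and negative
limb lengths clamped to zero; on additive matrices the topology and branch
lengths are recovered exactly (tested on random additive trees and
cross-checked against scikit-bio's NJ).

Bootstrap support resamples alignment columns with replacement; replicate
r draws from an independent RNG stream (seed, r), so results are
independent of evaluation order and reproducible from the single seed.
Within a replicate, a saturated pair (p ≥ 1, possible under resampling) is
capped at p = 1 − 1/(2·sites) instead of raising — a replicate must always
yield a tree. The consensus keeps bipartitions present in > 50% of
replicates (always mutually compatible), labels them with integer percent
support, and is built by size-descending insertion; Newick output renders
supports as internal node labels.

## Synthetic proteomes

The simulator generates exactly the structure the pipeline assumes, plus a
complete truth manifest, so recall and precision are exact checks rather
than statistical ones. Kinases are assembled as
flank | P-loop | spacer | C-loop | spacer | activation | tail with spacers
drawn uniformly inside the confirmed-mode windows. Background residues are
uniform over the 20 letters (configurable; uniformity keeps the spurious-
motif rate analyzable and low). Rejection sampling enforces the planted
truth: a sequence is regenerated if any activation motif more specific
than the intended family's appears anywhere (it would win precedence), if
a RAF's group signature disagrees with what was planted, or if a decoy
contains any activation motif at all. Near-miss decoys are full kinases
with one fixed activation-motif position substituted — loops present,
motif broken — and probe the classifier's specificity at its decision
boundary.

Default study conditions mirror the published *C. reinhardtii* inventory
this pipeline re-implements the analysis for: 17 MAPKs (3 TEY, 7 TDY, 7
other variants, apportioned exactly by largest remainder), 2 MAPKKs, 11
MEKKs, 94 RAFs, 3 ZIKs, 200 decoys (170 random + 30 near-miss), 17
chromosomes, eight RAF tandem pairs (second member a per-site
mutation-rate-0.1 duplicate of the first, planted loops protected), and
RAF clusters of five (given the group-G signature `GTRHYMAPEV`, as in the
published chromosome-11 cluster) and three.

Genome layout guarantees no *unplanned* tandem pair or cluster: units
(pairs, clusters, single genes) are dealt per family evenly across
chromosomes, then each chromosome is ordered greedily so that at least
three genes of other families separate same-family units — enough to break
both the adjacency rule (pairs) and the ≤ 2-intervening rule (clusters).
A planted cluster implies chained tandem pairs among its members; the
manifest lists those expected pairs explicitly so manifest equality is
well-defined. Infeasible requests (more clustered genes than the family
has, or not enough separators) raise a placement error.

What the simulator does **not** emulate: realistic residue composition,
indel evolution, rate heterogeneity, paralog families with intermediate
divergence, mis-annotated gene models, or alternative splicing. Passing
the suite therefore demonstrates correctness of the scanning, confirmation,
precedence, genomic and phylogenetic logic under the stated assumptions —
not robustness to the full messiness of real proteomes, where motif
variants outside the printed consensus would be missed by design
(exact-match scanning is a deliberate scope boundary).

## Problem sizes and determinism

The shipped tests and the acceptance script use family-sized phylogenies
(≈ 12 taxa, ≈ 120 columns, 100 bootstrap replicates), 50 random additive
matrices (n ≤ 8), 100 random peptides for the pI oracle, and 20 simulation
seeds for recall/precision; the full-structure simulation (327 proteins)
is used for the inventory and genome-context measurements. All randomness
flows from explicit seeds through `numpy.random.default_rng`; two runs
with the same inputs, configuration and seed produce byte-identical
outputs (timestamps excluded).

## Known limitations

- Exact-match motifs: a single substitution inside a consensus motif hides
  a true family member (near-miss decoys exploit exactly this). The
  published inventories used BLAST/HMM searches whose tolerance is not
  reproducible from the text; the exact-match scanner plus the loose mode
  brackets the behavior instead.
- MAPKK group B detection (nuclear-transport-factor domain) needs a
  profile database and is out of scope.
- The pairwise-alignment tie-break among co-optimal alignments follows
  Biopython's deterministic enumeration order; scores and identities are
  tie-break-independent.
- Maximum-likelihood tree inference is out of scope; the distance/NJ path
  is the implemented method.
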