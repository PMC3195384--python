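# Methods

## The estimand

Given a curated panel of distinct, equal-length, in-frame DRB exon-2 allele
sequences, the analysis asks whether nonsynonymous substitutions accumulate
faster than synonymous ones at the codons encoding the peptide-binding
region (PBR) of the MHC class II β1 domain — the signature of balancing /
positive selection — and quantifies allele divergence and relationships.

## Nei–Gojobori dN/dS with Jukes–Cantor correction

For each sense codon, the expected number of synonymous sites is
s = Σ_positions (synonymous single-base changes at that position)/3, with
n = 3 − s; changes that create stop codons count as nonsynonymous (the
classic unweighted NG86 convention).  Differences between two codons that
differ at k positions are classified by enumerating all k! orderings of
single-base steps, discarding orderings that pass through a stop codon, and
averaging the per-step classifications over the remaining orderings (all
orderings if none is stop-free).  Per pair of sequences, codon sites
containing a gap, an N, or an observed stop in either sequence are excluded
pairwise; S and N are the means of the two sequences' summed site counts
over the included codons, and pS = Sd/S, pN = Nd/N.  Multiple hits are
corrected with the one-parameter formula d = −(3/4)·ln(1 − 4p/3), undefined
(saturation) at p ≥ 3/4.

Panel-level dN, dS (and the K2P divergence d) are the arithmetic means over
all n(n−1)/2 unordered pairs — a mean of pairwise distances, not a pooled
concatenation — because the quantity of interest is the average divergence
among alleles.  Pairs hitting saturation or having no usable sites are
excluded with a logged count.

The whole pairwise layer is table-driven: site counts and pathway-averaged
differences are precomputed for all 64×64 codon-index pairs, so panel and
bootstrap computations reduce to integer gathers and matrix products.  The
per-codon and per-pair primitives remain exposed and are tested against
brute-force enumeration; the full pairwise pipeline is cross-checked against
an independent NG86 implementation (Biopython's `cal_dn_ds`).

## Nucleotide divergence (K2P)

The Kimura 2-parameter distance d = −(1/2)·ln((1 − 2P − Q)·√(1 − 2Q)) is
computed per pair with pairwise deletion of columns containing gap/N, where
P and Q are the transition and transversion proportions over comparable
sites.  It is reported per stratum on the stratum's nucleotide columns
(the partition-restricted columns for PBR/non-PBR rows).

## Bootstrap standard errors and the Z-test of positive selection

Standard errors come from a column bootstrap: the resampling unit is the
codon column for dN/dS and the nucleotide column for K2P.  Each replicate
redraws columns with replacement to the original length and recomputes the
mean pairwise statistic; the SE is the standard deviation (ddof = 1) across
replicates (default 1000).  Replicate random streams are spawned from the
run seed by replicate index (NumPy `SeedSequence.spawn`), so results are
reproducible and order-independent; replicates in which every pair saturates
are dropped.

Positive selection is tested one-tailed with
Z = (dN − dS)/√(SE²(dN) + SE²(dS)), P = 1 − Φ(Z) (alternative dN > dS).
The two bootstrap variances are treated as independent — no covariance term
— which makes the test somewhat conservative, the standard behaviour of the
bootstrap Z-test as implemented in the classic MEGA workflow.  When both SEs
are zero with equal estimates (monomorphic data) the test degenerates to
Z = 0, P = 0.5; zero variance with unequal estimates raises an error rather
than fabricating a Z.  dN/dS is carried at full precision and rendered to 2
decimals; P is rendered at 3 decimals truncated to `.000`/`1.000`.

## Codon partitions

Codon positions use the mature β1-domain numbering of DRB polymorphism
tables: the standard 78-codon exon-2 window spans residues 9–86, so a
partition records a `first_position` (9 for the bundled masks).  A shorter
75-codon window (residues 9–83) simply loses the trailing starred positions
85 and 86, leaving a 20-codon PBR — no special-casing.

Two bundled masks are shipped and the caller must choose explicitly:

* `table2-asterisks` — the 20 positions conventionally starred in
  interspecies DRB repertoire tables (9, 11, 13, 28, 30, 32, 37, 38, 47, 56,
  60, 61, 70, 71, 74, 78, 81, 82, 85, 86);
* `brown1993-22` — a 22-position contact-residue mask per the Brown et al.
  (1993) human DR1 structure.  The two positions beyond the starred 20 were
  an open design choice; this package uses the pocket-lining residues 65 and
  68, because the natural alternatives 57 and 67 are explicitly treated as
  non-PBR in the tables this layout mirrors.

Splitting a panel by mask preserves codon order within each stratum, and
re-interleaving the strata by recorded positions reconstructs the alignment
exactly (tested).

## Phylogeny

Trees are built on amino-acid distances: translate, remove every column with
a gap or X in any sequence (complete deletion), Poisson-correct the
differing fraction d = −ln(1 − p), and agglomerate with Saitou–Nei
Neighbor-Joining.  Q-criterion ties are broken on the lexicographically
smallest pair of cluster representatives and all iteration is in
label-sorted order, so the tree, its newick serialization and the total
branch length are byte-reproducible and invariant under taxon permutation.
Negative NJ branch lengths are clamped to zero with the deficit logged
(display-compatible with the common tools).  Bootstrap supports resample
residue columns, rebuild the tree, and report the percentage of replicates
containing each internal-edge bipartition of the point tree.  Newick output
carries 6-decimal branch lengths and supports as internal-node labels;
round-trips preserve topology, supports, and total length to the
serialization precision.

## Synthetic allele panels

The generator evolves each allele independently from a common stop-free
ancestral coding sequence (a star phylogeny): substitutions are proposed
uniformly over single-base changes, accepted with relative probability 1 if
synonymous and ω(stratum) if nonsynonymous, and never accepted if they
create a stop.  `branch_length` is the expected number of accepted
substitutions per codon per branch; per-allele counts are Poisson.  The
`exon2` preset is 22 alleles × 78 codons, ω_pbr = 3, ω_nonpbr = 0.5,
branch length 0.2 substitutions/codon — the scale of a single-species
exon-2 panel (pairwise nucleotide divergence ≈ 0.1–0.25/site, identity
range ≈ 85–95%).

What the generator emulates: the pairwise-divergence structure and the
PBR-confined excess of nonsynonymous change that the estimators consume.
What it does not emulate: genealogical correlation between alleles
(coalescent structure), recombination/gene conversion, transition/
transversion bias, codon-usage bias, and realistic per-site rate variation.
Passing tests therefore validate the estimators and their calibration under
a controlled generating process, not the biological fidelity of any real
panel.

Two systematic effects of the conventions are worth noting.  Because NG86
counts mutations *to* stop codons as nonsynonymous opportunity while the
generator (like real coding evolution) never accepts them, neutral (ω = 1)
simulations give a mean dN/dS slightly below 1 (≈ 0.94 at the preset scale).
Combined with the independent-variance Z-test, the neutral rejection rate
sits at ≈ 2–3%, conservatively below the nominal 5%.  Both values are
recomputed by the calibration driver and the acceptance script.

## Numerical and interface choices

* Single integer seed per run; every stream (bootstrap replicates,
  simulation branches) derives from it deterministically.
* Sub-seeds for per-panel/stratum/statistic bootstraps are a fixed affine
  function of the run seed, keeping reports byte-reproducible.
* Ambiguity codes other than N are mapped to N on read, with a warning.
* Deduplication compares exact normalized nucleotide strings.
* Saturation (JC p ≥ 3/4, K2P log-domain, Poisson p = 1) raises a typed
  error; the tree pipeline aborts naming the offending pair, the pairwise
  mean excludes and counts the pair.
* Test and calibration problem sizes (e.g. 400 neutral panels × 1000
  bootstrap replicates, 100 additive-tree trials) were chosen to keep
  Monte-Carlo error well inside the asserted bands while the full suite
  runs in about a minute.

## Limitations

* Unweighted NG86 only — no transition/transversion-weighted (modified)
  variant, no ML codon models; the dN/dS here is a panel mean, not a
  site-specific selection map.
* Distances assume rate homogeneity across sites (JC, Poisson) or the K2P
  two-class model; saturated pairs are excluded rather than modelled.
* The Z-test treats dN and dS bootstrap variances as independent
  (conservative).
* Input panels are assumed pre-aligned; no alignment, no database search,
  no network access anywhere in the analysis path.
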