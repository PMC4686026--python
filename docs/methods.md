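# Methods

`mthaplostat` implements the statistical core of a mitochondrial-haplotype
population survey: haplotype calling against a catalog of profiles at
polymorphic alignment columns, molecular diversity indices, a one-level
analysis of molecular variance (AMOVA) with permutation testing,
within/between-population pairwise-distance summaries, and median-joining
haplotype networks. The packaged reference data describe the African lion
(*Panthera leo*) 12S–16S mitochondrial fragment: 17 published haplotypes
(H1–H12 range-wide, Z1–Z5 from Zambia) over 31 polymorphic columns of a
1882-column alignment, and a sampling design of 165 Zambian individuals
across five areas grouped into an eastern (LV, CO, ZA) and a western
(KF, SI) region.

## Haplotype representation and calling

All statistics here depend only on the states at the polymorphic columns,
so haplotypes are stored as profiles — one symbol from {A, C, G, T, -} per
cataloged 1-based column — rather than full sequences. A sample matches a
haplotype exactly when its states at every diagnostic column equal the
profile. Non-matching samples sharing a state vector are minted as a new
haplotype, named deterministically in first-seen order by continuing the
highest existing index under the novel prefix (default "Z"). A minted
haplotype observed once is flagged `needs_verification`, reflecting the
field convention that singleton variants must be confirmed by re-sequencing
before acceptance. "N" never matches any state: samples with N at a
diagnostic column raise an explicit unresolvable-call error listing the
samples, rather than being assigned silently.

Polymorphic columns are those with ≥ 2 distinct non-N states. Each column
receives exactly one substitution class: *indel* if any row carries a gap
(counted per column, so a two-column deletion is two indels), otherwise
*transversion* if any observed base pair crosses the purine/pyrimidine
divide, otherwise *transition*. With the packaged profiles only two-state
base columns occur; for hypothetical multi-state columns the
any-cross-class-pair rule decides.

## Diversity indices

For haplotype counts n_h (total n, frequencies p_h = n_h/n):

- frequency sampling s.d.: sqrt(p(1−p)/(n−1)). The n−1 denominator (rather
  than n) is the variant consistent with the packaged survey table and is
  locked by a fixture test.
- gene diversity: h = n(1−Σp²)/(n−1), the unbiased probability that two
  individuals drawn without replacement differ in haplotype; its sampling
  variance V = 2/(n(n−1)) · {2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}.
- nucleotide diversity: mean per-site pairwise difference,
  (mean pairwise differences within the pool) / alignment width.

Distances between haplotypes come in two modes: *identity* (0/1 indicator)
and *pairwise_differences* (count of differing profile columns; gap vs base
counts 1 per column, gap vs gap 0). The identity-mode mean pairwise
difference within a pool equals h algebraically; a property test asserts
this to 1e−12.

Nei's distance between pools X and Y is the corrected average pairwise
difference d = π_XY − (π_X + π_Y)/2, with π_XY the mean distance over
cross-pool sample pairs and π_X, π_Y the within-pool means over unordered
pairs. A pool compared against an identical pool is assigned d = 0, the
diagonal convention of within/between distance tables (the literal formula
gives a small negative value, −π_X/n, because the cross term includes
self-pairs).

## AMOVA

Distance-matrix entries are used directly as squared inter-individual
distances — the convention of the classic molecular-variance
implementations — so no re-squaring occurs. With N samples in P
populations:

    SSD_total  = (1/2N) Σ_ordered pairs δ
    SSD_within = Σ_p (1/2N_p) Σ_ordered pairs within p δ
    SSD_among  = SSD_total − SSD_within
    Vb = SSD_within/(N−P),  n′ = (N − Σ N_p²/N)/(P−1)
    Va = (SSD_among/(P−1) − Vb)/n′,  Fst = Va/(Va+Vb)

A negative Va is reported as computed (with a warning) so the
sum-of-squares identity stays exact; Fst may then be negative. The
permutation test reassigns individuals to populations uniformly at random
with sizes fixed and reports p = (1 + #{Fst* ≥ Fst_obs})/(R + 1); R
defaults to 1000 and every run is seeded.

The two distance modes reproduce different published summaries: identity
distances give the two-region decomposition (Fst ≈ 0.475), while
pairwise-difference distances give the among-area Fst within the eastern
region (≈ 0.05); the pipeline runs both with those defaults. Among-area
runs drop any area with fewer than two samples (a single sample would skew
the result) with a warning; the western region then retains only one
usable area and its among-area AMOVA is skipped.

## Median-joining network

Profiles are compared under Hamming distance with "-" as a fifth character
state, all columns equally weighted, ε = 0 by default. Construction
alternates (i) the ε-relaxed minimum spanning network — a link u–v of
length d is kept when d ≤ bottleneck(u,v) + ε, the bottleneck being the
largest step on the minimax MST path, which at ε = 0 yields the union of
all minimum spanning trees — and (ii) insertion of column-wise
majority-consensus medians for triples connected by at least two links,
whenever the median strictly shortens the local three-node subtree.
Unobserved nodes that fall to degree ≤ 1 are pruned. Ties (median state
when all three parents disagree; visit order) are broken lexicographically
on sorted node-name triples, making the output deterministic for a fixed
input ordering. Median vectors are named mv1, mv2, … in creation order.
On the packaged 17-haplotype catalog the network is connected, realises
every brute-force MST edge as a geodesic, and never shortcuts below the
true Hamming distance.

## Synthetic surveys

The generator emulates the survey's sampling design exactly: per-area,
per-haplotype, per-sex counts (default: the packaged 165-sample table, 119
males / 45 females / 1 unknown; the unknown-sex individual is the LV/Z1
cell, as in the survey), alignment width 1882, and one background sequence
per run drawn i.i.d. from the survey's published nucleotide composition
(C 22.11 %, T 22.67 %, A 36.64 %, G 18.58 %). Each sample's sequence is its
haplotype profile written onto the shared background. Because every
downstream statistic depends only on haplotype identities and counts — the
generator fixes both exactly — pipeline results on default synthetic data
equal the published values regardless of seed; only the background draw
varies. A single shared background is a deliberate simplification:
invariant columns cancel in every statistic except the per-site denominator
of nucleotide diversity, which uses the true width.

Optional noise masks background positions as "N" at a per-site rate
(default 0); diagnostic columns stay noise-free unless `noise_diagnostic`
is set, separating exact reproduction from robustness stress-testing. What
passing tests therefore show is that the statistics, calling rules and
network construction are correct on data with the survey's exact
composition; they do not exercise alignment errors, within-haplotype
sequence variation at non-cataloged columns, or real missingness patterns.

## Numerical and design notes

- Coordinates are 1-based alignment columns throughout; the catalog stores
  only polymorphic columns.
- Reported tables round to 4 d.p. (diversity) and 2–3 d.p. (AMOVA display);
  JSON outputs carry full precision.
- The sum-of-squares identity SSD_among + SSD_within = SSD_total is
  enforced to 1e−9; identity-mode AMOVA is cross-checked in tests against
  the closed forms SSD_total = (N² − Σn_h²)/2N and
  SSD_within = Σ_p (N_p² − Σn_{h,p}²)/2N_p.
- Degenerate inputs raise typed errors: gene diversity needs n ≥ 2, AMOVA
  needs ≥ 2 populations and total variance > 0, the network needs ≥ 2
  haplotypes and ε ≥ 0.
- Test and pipeline problem sizes (165 samples, 1000 permutations, width
  1882; 10⁵ columns only for the composition goodness-of-fit check) keep
  the full suite under a few seconds on one CPU.

## Known limitations

- One-level AMOVA only; no hierarchical multi-stratum designs or
  Φ-statistics beyond the single Fst.
- The median-joining implementation targets small haplotype sets (tens of
  nodes); distances are recomputed per round.
- No confidence intervals beyond the variance formulas above; no
  rarefaction or richness estimation; no tree inference or drawing.
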