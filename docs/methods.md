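# Methods

## Scoring model

A site candidate is the peptide window PSP(m, n): the candidate residue
(C or G) with m upstream and n downstream residues, padded with `*` where
the window crosses a terminus. Two scoring primitives are used:

**Peptide similarity.** `S(A, B)` is the fraction of window positions whose
residue pair is a *conserved substitution* — a strictly positive BLOSUM62
entry. It lies in [0, 1], is symmetric, and equals 1 exactly on identical
all-standard peptides. The induced distance is `D = 1/S`, infinite when
`S = 0`. The fraction is taken over the *full* window length, so `*`-padded
positions (never conserved) count against truncated windows; normalising by
non-padded positions only would be the natural alternative, but it makes
similarity incomparable across windows of different effective length.

**Group score.** A query window is scored against a group G of positive
training peptides as the mean over G of the position-weighted sum of
substitution scores (weights `w_i`, matrix `BLOSUM62 + dS`). The mean (as
opposed to the sum) makes scores comparable between groups of different
sizes; it only rescales cutoffs. Internally the group is summarised by a
per-position symbol-frequency profile F, so scoring is the gather of
`(M @ F)` at the query's symbols — scoring cost is independent of group
size, and the leave-one-out score of a member is obtained in closed form by
removing its self-comparison from the group mean (groups of one get `-inf`
and fall back to the other groups' scores).

Conventions: `*` scores 0 against everything, including itself, so terminal
truncation neither rewards nor penalises; the ambiguous residue `X` scores
via the BLOSUM62 X row.

## Grouping

One modification type can be recognised by several enzyme families, so
positives are grouped and each group carries its own weights, matrix and
cutoffs:

- **Myristoylation**: consensus = N-terminal glycine at position 2 of
  `M-G-X-X-X-[ST]`; everything else (including any annotated internal
  glycine) is non-consensus.
- **Farnesylation**: consensus = cysteine 4th from the C-terminus (the CAAX
  position). The "A = aliphatic" constraint is exposed as an optional filter
  (`{A,V,L,I,C,M,F}`) but is off by default: the positional rule routes
  borderline sites to the consensus model rather than silently dropping
  them.
- **Geranylgeranylation**: CAAX as above, plus terminal `CC` / `CXC`
  cysteines as a second consensus class.
- **Palmitoylation**: no published consensus; peptides are clustered by
  k-means (default k = 3, 5 restarts) under `D = 1/S`, with the centroid of
  a cluster being its *medoid* — the member with the highest average
  similarity to the cluster. Assignment ties break toward the lowest
  cluster id, medoid ties toward the lowest peptide index, so clustering is
  deterministic given its seed. Clustering runs on a (10, 10) sub-window of
  the stored (30, 30) context: a short family motif is undetectable in the
  similarity of full 61-mers, where background positions dominate the
  conserved-fraction statistic.

Groups smaller than 3 positives are merged into a non-consensus group
(created on demand) with a warning; a query at prediction time is scored
against all groups of its type and takes the best margin (score minus the
group's stringency cutoff).

## Training pipeline

Four sequential stages, all deterministic given the training seed (per-stage
seeds are spawned from it):

1. **Clustering / motif classification** (above).
2. **Motif length selection (MLS)**: the window (m, n) is chosen from the
   grid {1,3,5,7,10,15,20,25,30}^2 (bounded by the stored +-30 context) by
   maximising pooled leave-one-out sensitivity at 90% specificity with
   baseline weights and matrix; ties prefer the smaller m+n, then smaller m.
3. **Weight training (WT)**: per-group deltas `dw_i` in [-1, 1], applied as
   `w_i = max(0, 1 + dw_i)`.
4. **Matrix mutation (MaM)**: per-group symmetric deltas `dS(a, b)` in
   [-4, 4] over the 210 unordered standard-residue pairs; `*` stays pinned
   at 0 and the X row is not mutated.

The WT/MaM objective is the group's LOO sensitivity at the score cutoff
leaving at most `floor(0.10 * n_neg)` negatives above it (specificity >=
90%), with positives LOO-scored and negatives scored against the full
group. The delta boxes keep scores in a numerically tame range; both are
config-exposed. Training is per group — groups model distinct motifs and
therefore distinct position preferences — with a pooled-objective flag
reserved in the configuration.

Both optimisation stages seed the swarm with the zero-delta point and the
optimizer returns the best-ever evaluated position, so the objective after
WT can never fall below the untrained baseline, nor after MaM below the
post-WT value. A zero-iteration budget is an exact no-op (weights all 1,
BLOSUM62 intact).

## ALC-PSO

Weight training and matrix mutation use particle swarm optimisation with an
aging leader and challengers. Defaults: swarm 20, inertia 0.4, c1 = c2 =
2.0, initial lifespan 60, challenger trial budget 2, velocity clamped to
0.5x the box width per dimension, positions clamped to the box. The swarm
follows the leader rather than the raw global best; the leader is improved
by any better solution found (age retained) and its lifespan is adjusted
each iteration by its leading power (+2 if the best-ever improved, +1 if
any personal best improved, 0 if the iteration maximum rose, else -1, floor
1). When age exceeds lifespan a challenger is generated by redrawing each
dimension with probability 1/d uniformly within bounds (at least one
dimension always changes); it leads for 2 trial iterations and is accepted
iff the swarm improved, otherwise the leader falls back to the best-known
solution with age reset. Runs stop at `max_iterations` (default 100 in the
training configuration, 500 standalone) or after 50 iterations without
best-ever improvement, whichever comes first; both knobs are recorded in
the model file. Given a seed, runs are bit-reproducible.

## Evaluation and calibration

Cutoffs are the minimal observed scores achieving specificity >= 0.95 /
0.90 / 0.85 (high / medium / low) on the negative scores, under the closed
lower bound "call positive iff score >= cutoff"; an unreachable level puts
the cutoff just above the maximal negative score, with a warning. The
stringency levels bracket the 90% training target. Sites are compared
across groups by the margin over each group's medium cutoff; ROC and PR
curves and AUC are computed on these combined scores (AUC equals the
Mann-Whitney probability, ties one half). MCC and precision return 0 when
their denominator vanishes.

k-fold cross-validation (k in {4, 6, 8, 10}) uses stratified seeded folds
(class fold sizes differ by at most 1). By default folds reuse the globally
trained weights and matrices and refit only the group peptide sets and
cutoffs ("fast mode", recorded in the output provenance); `full_refit`
re-runs WT and MaM per fold. Fast mode tracks LOO closely because the
scoring profile, not the optimised deltas, carries most of the signal.

## Crosstalk statistics

- **Co-occurrence**: protein-level 2x2 table (has-A x has-B over all
  library proteins), Pearson chi-square with df = 1 and *no* continuity
  correction (a flag enables Yates); a zero margin reports statistic 0,
  p = 1, flagged degenerate. Pairs where a type is absent are reported as
  not-applicable rather than independent.
- **Proximity**: rows split the candidate residues of A's amino acid into
  A-modified vs not; columns ask for >= 1 B site within the flanking window
  ((5,5), (10,10) or (15,15)); a residue's own position is excluded from
  its window so in-situ overlap does not masquerade as proximity.
  Experimental and predicted annotations are pooled, as the merged-library
  construction implies.
- **In-situ**: population N = all cysteines of library proteins carrying at
  least one lipid annotation (the test is conditional on the curated
  library, not a proteome); K = cysteines with the partner type, n = with
  the prenyl type, k = overlap; p = upper-tail hypergeometric P(X >= k);
  enrichment ratio (k/n)/(K/N).

Significance is `-ln(p)` — the only transform consistent with the
conventional pairing of 2.99 with p = 0.05 and 4.61 with p = 0.01 (note
-ln(0.05) = 2.9957 truncates to 2.99 while -ln(0.01) = 4.6052 rounds to
4.61; tests therefore check one unit in the last printed digit). p-values
at or below the double floor are capped at -ln(5e-324) and flagged.

## Synthetic data

The generator plants, per type, exactly the features the predictor is
meant to learn: the MGXXXS/T consensus (S/T present with probability =
signal strength), CAAX termini with aliphatic A positions at the signal
probability, CC/CXC termini (geranylgeranylation cycles through the three
terminus classes), and three palmitoylation families whose 7-mer consensus
residues are pairwise non-conserved in BLOSUM62, so family structure is
recoverable by clustering. Prenylated termini additionally carry an
upstream polybasic (K/R) stretch, mimicking the membrane-targeting context
of prenylation substrates. Defaults: 60 positive proteins per type, lengths
100–160, uniform residue background (a Swiss-Prot-like composition table is
bundled as an alternative), signal strength 0.8, one annotated site per
protein plus guaranteed decoy candidate residues; under these defaults
every type yields >= 300 negatives. Ground truth is emitted in the site-TSV
dialect of `seqio`, so fixtures double as format tests.

What the generator does **not** emulate: homology between substrates (no
redundancy structure, so identity-reduction hooks are exercised only
syntactically), realistic domain composition or disorder, class imbalance
beyond the configurable ratio, and annotation noise — real negative sets
contain unverified positives. Passing tests therefore demonstrate that the
pipeline recovers planted signal of realistic strength at desk scale, not
field performance on curated data.

The null crosstalk library places sites of each type independently and
uniformly over candidate residues. Its default density (100 proteins of
150–200 residues; 200 palmitoylation/myristoylation and 80 prenylation
sites) was chosen so the expected per-cell counts of the proximity table
are well above the classical chi-square validity threshold; at sparser
densities the asymptotic approximation is conservative and the nominal
type-I error is not attained.

## Problem sizes

Default experiment sizes — 60 positives / >= 300 negatives per type, swarm
20 with 100 optimizer iterations, 200 null libraries for calibration — are
the package's desk-scale study conditions: large enough for stable AUC and
calibration estimates, small enough that the whole pipeline (all four
types) trains in seconds on one CPU.

## Known limitations

- The CAAX rule is positional by default; strict aliphatic filtering is
  opt-in.
- Single-member groups cannot be LOO-scored and fall back to other groups
  (sentinel `-inf` when none exist).
- The chi-square tests are asymptotic; no exact (Fisher) alternative is
  wired in.
- k-fold fast mode shares globally trained deltas across folds and is
  therefore slightly optimistic relative to the full refit protocol.
- No homology reduction is performed internally; callers should pre-cluster
  substrates (e.g. at 40% identity) and pass the retained ids to
  `seqio.filter_proteins`.
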