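# Methods

This note records the models implemented by m6arhythm, the parameters
that matter, the numerical choices taken where the design was open, and
what the synthetic benchmark does and does not show about real data.

## Homology networks

**Ortholog calls.** For every (query, target-species) pair the best hit
is the one with minimal E-value; ties break by maximal bitscore, then
lexicographically smallest subject ID — a deterministic and conventional
chain. An ortholog edge (a, b) exists iff a and b are each other's best
hit (bidirectional best hit). BBH is already maximally selective (one
candidate per species per query), so no E-value cutoff is applied to
ortholog edges.

**Paralog calls.** A within-species edge requires *both* directed hits
to have been reported and the better of the two E-values to pass the
species' cutoff. Requiring reciprocity is a deliberate choice: one-sided
reporting is usually an artifact of asymmetric score thresholds, and the
requirement makes results invariant to which direction a search tool
happened to emit.

**Cutoff selection.** For each species the cutoff is chosen from a grid
as the value maximising the number of paralog networks, counting only
connected components with ≥ 2 members (an edgeless protein is not a
network). Ties select the loosest threshold, which retains the most
sequences. The default grid runs from 1e-3 to 1e-18 in 3-decade steps.
This span is intentional: the scan's job is to find the threshold that
strips spurious "twilight-zone" similarity (which merges unrelated
families at loose cutoffs) while keeping genuine family edges. Scanning
far below the weakest true within-family E-value cannot help — past
that point the only way the network count rises is by *fragmenting*
real families, which is the failure mode the count heuristic cannot
distinguish from signal. Users with stronger or weaker similarity
regimes should move the grid accordingly; `select_cutoff` accepts any
grid.

**Networks and inventory.** Ortholog and paralog edges are merged and
connected components taken (networkx); singletons are excluded.
Components are ordered by (size descending, lexicographically smallest
member) and numbered `NET_1`… from 1 — the numbering is internal and
deterministic, not aligned with any external database's network IDs.
Annotation is transferred per protein from a label table (controlled
vocabulary MTA, MTB, FIP37, VIRILIZER, HAKAI, ALKBH9B, ALKBH10B,
other); members absent from the table are labelled `unknown`, never
fatal. A network enters the writer/eraser inventory iff at least one
member carries a writer/eraser label; a mixed network (e.g. MTA + MTB)
yields one row per (type, gene, species) and appears under a single
network ID. Species tags come from the ID prefix before the first
underscore, with an optional explicit species map. E-values of exactly
0.0 are treated as 1e-180 in log-scale work.

**Redundancy collapse.** Transcript-variant redundancy is reduced by
greedy clustering: sequences sorted by (length desc, ID) join the first
representative with identity ≥ 0.98 over the shorter sequence's aligned
span (edlib infix alignment) and length overlap ≥ 0.5, else open a new
cluster; the longest member represents each cluster. This is a
deliberately simple identity-based stand-in for assembly-level
redundancy checks, adequate because downstream analysis consumes only
membership counts.

## Expression quantification

−ΔCT = CT_RG − CT_GOI per biological sample; technical triplicates are
averaged first, after dropping replicates > 0.5 cycles from their
median (a common qPCR QC rule). Larger −ΔCT means higher relative
abundance. Per-time-point profiles report the mean, the standard error
(sample SD over biological replicates / √n) and n. The formula is
antisymmetric in the two genes and invariant to additive shifts of all
CTs — both are property-tested.

Primer efficiency comes from an ordinary least-squares fit of mean CT on
log₁₀ relative concentration over ≥ 5 distinct dilutions:
E = 10^(−1/slope), reported as (E − 1) × 100 so that perfect doubling
(slope −3.3219 cycles/decade) reads 100%. Non-negative slopes are
flagged invalid. Pearson correlations between genes pair per-sample
−ΔCT values on (species, time, biological replicate) — a full 6 × 3
design pairs N = 18 — with two-sided p from the t distribution on n − 2
df. Acrophases are estimated by the closed-form cosinor regression of
−ΔCT on cos(2πt/24) and sin(2πt/24).

## m⁶A quantification

The ELISA standard curve is fitted through the origin after subtracting
the mean negative-control OD, because the downstream formula uses only
a slope and the NC OD — estimating an intercept would leave it unused.
m⁶A (ng) = (mean sample OD − NC OD)/slope over the technical
replicates, clamped at 0 ng with a `below_background` flag when the
subtracted OD is negative (so full plates always process);
m⁶A% = m⁶A ng / input RNA ng × 100 with 100 ng default input. The
percentage is invariant to rescaling OD units, as long as curve and
samples share a scale.

## Inference

**PERMANOVA.** With distance matrix D, the Gower-centred inner-product
matrix G = J(−D²/2)J (J the centring projector) has trace equal to the
total SS. Each term's SS is tr(P G) with P the projector onto the
centred dummy space of that term; in a balanced crossed design the A, B
and A×B subspaces are mutually orthogonal, so the partition
SS_A + SS_B + SS_AB + SS_res = SS_total holds to machine precision
(asserted at 1e-9 in tests). Pseudo-F = (SS_term/df_term)/(SS_res/df_res).
On univariate Euclidean data this reproduces the classical two-way
ANOVA F exactly — the primary correctness oracle.

p(perm) uses unrestricted permutation of observation labels for all
terms, which is exact for balanced fixed-effects designs under the
global null and differs negligibly from residual-permutation schemes at
these sizes. The convention is p = (b + 1)/(m + 1) with the observed
statistic included. Permuted statistics are evaluated in vectorised
blocks of 1000 permuted G matrices; the "unique perms" column counts
distinct permutation statistic values (rounded at 1e-10), an
approximation to the reporting style of commercial PERMANOVA software.

**Pairwise contrasts.** Each contrast is a one-way two-group PERMANOVA
on the subset, reported as t = √pseudo-F. When the number of group
assignments C(n, n₁) is tractable (always at 3 + 3, where only 10
distinct splits exist) the permutation p is computed by full
enumeration and the result flagged low-resolution; otherwise it is
sampled. Because 10 splits cannot resolve small p-values, a Monte-Carlo
p accompanies every contrast: the null pseudo-F is simulated (10⁴ draws
by default) as (Σλᵢuᵢ/df₁)/(Σλᵢvᵢ/df₂) with λᵢ the eigenvalues of the
subset's centred inner-product matrix and uᵢ ~ χ²(df₁), vᵢ ~ χ²(df₂)
independent. In the univariate case a single eigenvalue survives and
the draw reduces to the exact F(1, n−2) distribution — validated in the
tests against the closed-form F tail.

**ANOVA, SNK, diagnostics.** The balanced two-way ANOVA uses closed-form
sums of squares from marginal and cell means, F against the error mean
square (scipy F distribution); zero within-cell variance is flagged.
SNK orders the cell means and tests ranges with studentized-range
critical values q(α, span, df) stepwise: a sub-range is tested only if
its containing range was significant, and a non-significant span closes
all pairs inside it. Homogeneous groups are the maximal non-significant
spans. Normality and variance homogeneity delegate to scipy's
Shapiro–Wilk and mean-centred Levene tests — the contract is the
reported statistics, not their implementation.

## Synthetic data: what it emulates, and what it does not

**Proteomes.** Each family descends from one random ancestral sequence
(uniform over 20 amino acids, ≥ 30 residues, default 300). Speciation
copies mutate the ancestor at the ortholog rate (default 0.25
substitutions/site), within-species duplicates mutate the species' first
copy at the paralog rate (default 0.10), and transcript variants —
emulating transcriptome-assembly isoform redundancy, pinned by default
to the species with the most copies — diverge < 2% (rate 0.01). Sites
are i.i.d. and substitutions uniform over the 19 alternative residues;
there are no indels, domains or rate heterogeneity. This is adequate
because downstream stages consume E-values, never alignments. The
default family composition plants the full writer/eraser repertoire
across four species (94 proteins), including a six-member FIP37
expansion in one genome and heavy variant redundancy in the
transcriptome-derived species.

**Similarity.** Hits are drawn from an explicit E-value model rather
than an actual search: within-family ordered pairs always reported with
log₁₀E uniform on [−120, −20]; between-family pairs suppressed by
default, or reported with configurable probability on [−8, −3] in
"hard mode". Both directions are drawn independently. The default
supports are disjoint, which is exactly the regime in which the
recovery guarantee (ARI = 1.0) is stated; hard mode exercises the
cutoff scan's actual purpose. Bitscores are a monotone transform of the
E-value, and the remaining outfmt-6 columns are filled consistently but
carry no information.

**Diel CT tables.** CT_GOI(t) = baseline − amplitude·cos(2π(t −
peak)/24) + biological noise; the reference gene is flat at its
baseline. Technical replicates add independent Gaussian noise (default
0.1 cycles); biological noise default 0.3 cycles. Time is decimal hours
since local midnight with no date handling. The default fixture plants
night-peaking (acrophase 0 h) rhythms of amplitude ≈ 1 CT in one
species and afternoon-peaking (17 h) rhythms in the other, with species
baseline offsets of ~3 CT — amplitudes are free parameters chosen to
make the antiphase pattern unambiguous, not fitted to any dataset. The
intraspecific (latitude) comparison in synthetic runs uses shared
nominal clock hours per time level so the two-way design stays
factorial; real sites differ in the clock times of sunrise/sunset,
which this deliberately ignores.

**ELISA plates.** OD = NC + slope·ng + Gaussian noise; standards in
duplicate (≥ 4 points, default 0.05–1 ng at slope 0.5 OD/ng), samples
in two technical replicates at 100 ng input RNA, planted m⁶A around
0.08–0.18% peaking toward the dark period. Quantification is exact at
zero noise, and noisy-plate errors stay within the propagated
3·(σ/slope)/input × 100 percentage-point bound.

Passing the benchmark therefore shows that the *algorithms* are correct
under their stated assumptions — it does not show robustness to indels,
non-uniform mutation, correlated qPCR noise, plate-edge effects, or
E-value models other than the ones simulated.

## Reproducibility and problem sizes

All randomness flows from one seed, fanned out to stage-specific
sub-seeds by a splitmix64 round over seed ⊕ crc32(stage name), so each
stage is independently reproducible; identical config + seed reproduce
identical output checksums and re-running over intact outputs is a
no-op. The bundled evaluation uses the problem sizes of the study
design itself (36- and 24-observation crossed designs, 18-pair
correlations, 94-protein homology runs), 999–9999 permutations, 10⁴
Monte-Carlo draws, 200 replicates for acrophase recovery and 500
simulations for null calibration — sizes at which every check runs in
seconds to a few minutes on one CPU.

## Known limitations

- One reference gene; no multi-reference normalisation (geNorm-class
  methods) and no ΔΔCT calibrator design.
- PERMANOVA is restricted to balanced two-way crossed fixed-effects
  designs and Euclidean distances (optionally on z-scored variables);
  no Type-III/unbalanced handling, random effects, or PERMDISP.
- The Monte-Carlo p is asymptotic; at very small n it inherits the
  usual finite-sample optimism of eigenvalue-based approximations.
- The redundancy collapse is identity-based and ungapped in spirit; it
  is not an assembler.
- Network IDs are deterministic ranks, not stable identifiers across
  different inputs.
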