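# Methods

This note documents the models and conventions implemented in murodiv,
the parameters that matter, and the choices made where the design was
genuinely open.

## Trees, ages, and clades

Trees are rooted; polytomies are first-class throughout, because the
package's comparison targets (supertrees) are mostly unresolved. Node
ages are measured backwards from the present in million years (My):
extant tips sit at age 0 and the root is oldest. A chronogram is
accepted as ultrametric when all root-to-tip path sums agree within a
tolerance, by default `1e-3 × root age` — dated trees exported by dating
software carry rounding, so an exact check would reject real files. A
node's age is the maximum path length to any descendant tip.

Clades are rooted descendant tip sets, not unrooted bipartitions:
statements like "genus X is monophyletic" or "A is sister to B" are
rooted claims, and all concordance metrics inherit that convention.
Numeric internal-node labels in Newick are read as support values
(bootstrap-style, 0–100); non-numeric labels are kept as names. The
writer is deterministic (children ordered by smallest descendant tip
label; floats serialized with `repr`, which round-trips exactly), so
seeded pipelines produce byte-identical files.

## Birth–death simulation

`simulate_bd` is a forward Gillespie simulation of the constant-rate
birth–death process started from the crown split: two lineages at age
`crown_age`, each speciating at rate λ and dying at rate μ (events /
lineage / My), run to the present. Extinct lineages are pruned, each
surviving species is retained independently with probability ρ (the
sampling fraction), and unifurcations left by pruning are suppressed
with branch lengths summed — the result is the reconstructed tree an
empiricist would estimate.

Conditioning: in the default crown mode, draws are rejected until both
crown children leave at least one sampled survivor, so the reconstructed
root age equals `crown_age` exactly. An unconditioned mode supports
calibration checks of the textbook identity `E[N(t)] = 2 e^{(λ−μ)t}`
(extinction counts as zero). A target-tip-count stopping rule is also
provided; it is a simple stop-at-n rule without generalized sampling
correction, so tree-shape statistics conditioned on n are mildly biased
— documented limitation, not used by any core analysis.

Clade rate shifts: a `Shift(age, lambda_mult, mu_mult, anchor)` switches
rates at the given age for a subtree. Anchor `"root:0"`/`"root:1"`
switches the whole crown-child clade — every lineage of that side alive
at the shift time and all descendants — which is the natural reading of
a clade-level shift; anchor `"random"` switches the subtree of one
uniformly chosen lineage, useful for diffuse-shift scenarios. The
ground-truth manifest records, per shift, the sampled extant tips of the
shifted regime, so recovery tests never need simulator internals.

All randomness flows from one `numpy` generator seeded per call; the
same seed reproduces the same Newick string byte for byte.

## LTT and the sliding-window rate

N(t) is the number of reconstructed lineages crossing age t. At a
branching age the post-split count applies (half-open intervals, older
edge exclusive): this makes N right-continuous toward the present and
the windowed statistic exactly additive — summing

    r(m) = log2( N(m − w/2) / N(m + w/2) )

over adjacent non-overlapping windows telescopes to
`log2(N_final / N_initial)` with no double counting. The price is a
boundary artifact visible only on synthetic trees whose splits sit
exactly on window edges (the doubling registers one window early); for
continuous-time trees the event has probability zero.

Defaults: window w = 2 My, so r = 1 means one doubling of diversity per
2 My; evaluation step 0.1 My (smooth curves at negligible cost, coarser
steps used in Monte-Carlo tests for speed); midpoints run from
`root_age − w/2` down to `w/2`. A window as wide as the tree is allowed
(it yields the single full-depth rate); wider is an error. Rates are
computed on the reconstructed, sampled tree only — what an observer
could measure. Thinning tips (ρ < 1) depresses r specifically in the
youngest windows, reproducing the artifactual rate decline near the
present familiar from under-sampled phylogenies; the tests assert this
direction.

## Null envelopes and exceedance

`build_envelope` simulates `reps` constant-rate trees at the observed
crown age, computes each replicate's rate series on the shared midpoint
grid, and takes pointwise quantiles (default 2.5%/97.5%). When no rates
are supplied, λ is solved from the observed richness,
`2ρ e^{(λ−μ)T} = n`, so the simulated curves are comparable in scale to
the data; μ defaults to 0.1/My, a moderate mammalian extinction rate.
Exceedance regions are maximal contiguous runs of midpoints where the
observed rate leaves the band. The comparison is pointwise, not
family-wise: it mirrors the visual grey-curve argument and is documented
as exploratory, not a calibrated global test.

For shift-*recovery* experiments the envelope is built from the true
generating base rates rather than richness-matched ones: a
richness-matched envelope absorbs part of a genuine shift into a higher
constant rate and answers a different question. With clade-level
tripling of λ, detection against the true-rate envelope is essentially
certain; with richness matching it drops to ~85%.

## Fossil calibration parameterization

A calibration is a shifted lognormal prior `age ~ c + LogNormal(0, σ)`
(mean log 0, so the prior median is `c + 1` My). The offset is anchored
at the 5% quantile: `c = min_age − exp(z_{0.05} σ)`, `z_{0.05} ≈
−1.6449`, putting 95% of the prior mass above the oldest secure fossil.
The anchor quantile is a parameter (`q`) because the "95% interval"
phrasing common in dating studies is ambiguous between central-95% and
one-sided conventions; q = 0.05 is the convention that reproduces the
packaged reference table. Twelve of that table's 28 rows reproduce to
±0.001 My; the remainder were evidently constructed row-specifically,
so `fill_offsets` reports per-row residuals instead of forcing them. σ
is always user-supplied, never solved from a maximum age (rows sharing
σ and offset have different maxima, so the maximum demonstrably did not
determine σ). A computed offset below zero warns rather than fails —
nonsensical as an age, but near-zero offsets occur legitimately.

The stratigraphic range extension is the classical distribution-free
estimator: with H fossil horizons uniformly sampled over a true range,
the confidence-C extension of the observed range R is `α R` with
`α = (1−C)^{−1/(H−1)} − 1`; strictly decreasing in H, increasing in C.
Database-computed variants of this index may differ; residuals against
externally computed bounds should be expected.

## Concordance metrics

"Possible nodes" of an n-tip rooted tree is fixed at n − 2, the internal
non-root node count of a fully resolved rooted binary tree; the
denominator is explicit in the report because published comparisons
rarely define it. Clade agreement restricts both trees to their shared
taxa; a test clade then AGREEs if it equals a well-supported reference
clade (support ≥ 70 by default — configurable, since "well-supported"
has no universal cutoff), CONFLICTs if it is incompatible with one
(intersection neither empty nor nested), is UNEVALUABLE if it contains
tips absent from the reference, and is UNDETERMINED otherwise. The
disparate-clade count is computed by descending from the root and
counting maximal nodes whose tip set lies wholly inside the query set —
the minimum monophyletic cover; it equals 1 exactly when the set is
monophyletic, an invariant the tests enforce against brute-force
enumeration (exhaustively on all 3,019 rooted multifurcating topologies
with ≤ 6 tips, and on random 20–30-tip instances; the 7-tip frontier
has 39,208 topologies and adds no logic the 6-tip frontier misses).

Genus defaults to the first underscore- or space-delimited token of a
tip label; any tokens after the second (e.g. geographic identifiers
appended to distinguish populations) are ignored by construction.

## Sequence screening

Pseudogene detection translates the gap-stripped sequence under a
declared NCBI genetic code (vertebrate mitochondrial by default — cytb
is mitochondrial, where AGA/AGG are stops alongside TAA/TAG) and flags
any stop strictly before the final codon. Codons containing N never
count. Frame may be fixed or auto-detected as the forward frame
minimising internal stops; ranking uses frame 0 by default because
curated coding sequences start in frame, and auto-detection would
re-frame around a genuine internal stop. Reverse-complement scanning is
out of scope (GenBank CDS orientation assumed).

Accession ranking is a lexicographic sort over nine criteria in their
conventional listed order (museum-associated lab, peer-reviewed,
vouchered, within known range, longer sequence, no internal stops,
cross-gene concordance, conspecific monophyly, shared voucher). Seven
criteria are curator judgments supplied as flags — the module encodes
the decision procedure, not the curation; length and stop codons are
computed. Full ties are broken by a seeded random draw.

Conspecific monophyly: a species is *mono* if its tips form an exact
clade; otherwise *para* if the foreign tips inside its span form exactly
one nested clade, else *poly*. The para/poly boundary is conventionally
fuzzy; this operationalisation is the one that makes the verdicts a
function of disparate-clade counts.

Cross-gene discordance compares each accession's placement context (the
majority genus/tribe/subfamily among its nearest neighbours — the
smallest enclosing clade with at least 2 other tips, which keeps the
context robust to one stray sequence landing alongside) against the
strict majority across that species' genes. Severity is the highest
rank of disagreement; at or above the removal rank (default subfamily)
the accession is recommended for removal. Ambiguous majorities flag
nothing: with two genes disagreeing, there is no way to tell which is
wrong.

## Synthetic data

Generators are pure functions of (spec, seed) and every fixture ships a
manifest sufficient for recovery testing. The labelled-tree generator
builds genus-clustered pectinate trees and plants monophyly violations
by moving a donor genus's last species next to a recipient genus's last
species; both genera then split into exactly two disparate clades, and
the manifest names them. The sequence generator concatenates random
sense codons of the declared code (no substitution-model realism — the
fixtures test screening logic, not phylogenetic signal), plants internal
stops mid-sequence for pseudogenes, and regrafts selected species into a
foreign subfamily in exactly one gene tree for discordance; graft
destinations avoid victims' genera so each planted anomaly is the only
context disturbance affecting its species. A muroid-flavoured preset
(125 genera × 7 species, six genes with coverage fractions 0.93 / 0.64 /
0.48 / 0.43 / 0.41 / 0.18, ρ = 0.69461, 45.2-My crown) exists for
smoke-testing at realistic scale; it emulates the shape of a real
supermatrix, not its biology.

Because fixtures are clean by construction (exact reading frames, exact
taxon labels, single planted defects), passing recovery tests show the
decision rules are implemented correctly — they do not show robustness
to alignment error, partial sequences, or compound curation problems in
real GenBank data.

## Problem sizes and numerical choices

Monte-Carlo experiment sizes are chosen so the full suite runs in a few
minutes on one CPU: 2,000 replicates per cell for the simulator-mean
grid (3σ Monte-Carlo criterion), 500 trees for the doubling-convention
check (12-My crown depth — deep enough that early-window small-count
bias, the Jensen-gap of log2 at N ≤ 4, contributes < 0.1 to the mean),
200 + 100 trials for envelope calibration and shift recovery with
100-replicate envelopes on a 0.5-My grid. Quantiles use numpy's default
linear interpolation. Exceedance ties (rate exactly on the band) count
as inside. The rejection budget for crown conditioning is 100,000
attempts, after which a diagnostic failure is raised rather than
looping forever on impossible parameters (μ ≥ λ with a deep crown).

## Known limitations

* No γ statistic, episodic (CoMET/TreePar-style) models, or
  compound-Poisson shift inference; the envelope comparison is
  deliberately the simple, transparent alternative.
* Envelope bands are pointwise; runs of exceedance are descriptive, and
  their family-wise error is uncontrolled.
* The tip-count stopping rule lacks GSA correction.
* Chimera breakpoints within a single sequence, reverse-strand frames,
  and alignment construction are out of scope for screening.
* Supertree construction itself (e.g. matrix representation with
  parsimony) is not implemented — only the evaluation of such trees.
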