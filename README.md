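# murodiv

Analytical tools for studying diversification in large time-calibrated
phylogenies, built around the questions raised by kilo-species rodent
trees: did net diversification rates increase through time, how should
fossil calibrations be parameterized, how much do supertrees agree with
well-supported molecular phylogenies, and which public sequences can be
trusted?

The package is aimed at systematists and macroevolution researchers who
work with Newick chronograms, fossil calibration tables, and
GenBank-derived supermatrices.

## What it computes

**Diversification.** For an ultrametric chronogram with node ages in My
before present, the lineage-through-time function N(t) counts branches
crossing age t. The windowed net diversification statistic is

    r(m) = log2( N(m − w/2) / N(m + w/2) ),   w = 2 My by default,

so r = 1 means diversity doubled across the window. Significance is
judged against a null envelope: pointwise quantile bands of r over
simulated constant-rate birth–death trees (Gillespie simulation with
speciation rate λ, extinction rate μ, incomplete sampling fraction ρ,
conditioned on crown survival), with maximal runs of exceedance reported
as candidate rate-shift intervals. The simulator also plants
ground-truth clade rate shifts for method validation.

**Fossil calibrations.** A calibration is a shifted lognormal prior on a
node age, `age ~ c + LogNormal(0, σ)`, with the offset chosen so the 5%
quantile sits at the hard fossil minimum: `c = min_age − exp(−1.6449 σ)`.
The classical distribution-free stratigraphic range extension
`α·R, α = (1−C)^(−1/(H−1)) − 1` is included for building maximum-age
bounds from fossil horizon counts.

**Concordance.** Rooted-clade metrics for comparing a sparsely resolved
tree against a supported reference: resolved fraction (internal non-root
nodes over the n−2 possible), agree/conflict/unevaluable tallies on
shared taxa, genus/tribe/subfamily monophyly reports, and
disparate-clade counts (the minimum number of clades exactly covering a
taxon set; 1 iff monophyletic).

**Sequence screening.** The automatable parts of a GenBank curation
protocol: internal-stop-codon pseudogene detection under the vertebrate
mitochondrial (or any NCBI) genetic code, criterion-based ranking of
candidate accessions per species and gene, conspecific monophyly
classification (mono/para/poly), and cross-gene placement discordance
flags with a removal recommendation at a configurable taxonomic rank.

All of it is exercisable on synthetic data: `murodiv.synthetic_data`
generates birth–death chronograms, genus-labelled trees with planted
monophyly violations, and coding-sequence sets with planted pseudogenes
and misplacements, each with a ground-truth manifest.

## Worked example

Simulate a 16-My crown clade in which one crown child triples its
speciation rate 8 My ago, then test the reconstructed tree against a
constant-rate null envelope:

```python
from murodiv import (BDParams, Shift, simulate_with_shifts,
                     sliding_window_rate, build_envelope,
                     exceedance_regions, offset_for_min_age)

print("offset:", round(offset_for_min_age(5.3, 0.515), 3))

params = BDParams(birth=0.2, death=0.05, crown_age=16.0, seed=42)
tree, truth = simulate_with_shifts(
    params, [Shift(age=8.0, lambda_mult=3.0, anchor="root:0")])
print("tips:", tree.n_tips,
      "| shifted clade:", len(truth["shifts"][0]["tips"]))

env = build_envelope(tree, params=BDParams(birth=0.2, death=0.05,
                                           crown_age=16.0),
                     reps=100, seed=7, step=0.5)
rates = sliding_window_rate(tree, w=2.0, step=0.5)
for region in exceedance_regions(rates, env):
    print(f"{region.direction}: {region.older:.1f} -> "
          f"{region.younger:.1f} My")
```

Output:

```
offset: 4.871
tips: 186 | shifted clade: 179
above: 6.5 -> 1.0 My
```

Reading it: a fossil calibration with minimum age 5.3 My and log-sd
0.515 gets offset 4.871 My (its prior's 5% quantile is exactly 5.3 My).
The simulated tree has 186 sampled extant tips, 179 of them descending
from the shifted crown child. The windowed diversification rate exceeds
the upper 97.5% envelope curve continuously from 6.5 My to 1.0 My —
correctly recovering a rate increase confined to ages younger than the
planted 8-My shift.

The same flows are available from the shell:

```bash
murodiv simulate --lam 0.3 --mu 0.1 --crown-age 15 --reps 100 --seed 1 --out sims/
murodiv slide sims/sim_0000.nwk -w 2 --step 0.1 --out rates.tsv
murodiv envelope sims/sim_0000.nwk --mu 0.1 --reps 100 --seed 7 --out env.tsv
murodiv calibrate table.tsv --out filled.tsv
murodiv monophyly tree.nwk --rank genus --out mono.tsv
murodiv compare supertree.nwk reference.nwk --support 70 --out report.tsv
murodiv screen --fasta seqs.fasta --meta meta.tsv --out screen.tsv
murodiv fixtures sequences --seed 2 --out fixtures/
```

Every output TSV carries a commented header with the package version,
seed, and parameters; directory outputs include a sha256 manifest.

## Layout

| module | contents |
|---|---|
| `murodiv.tree_model` | validated rooted trees/chronograms over dendropy, Newick/NEXUS I/O, MRCA and clade primitives |
| `murodiv.calibration` | lognormal calibration offsets, prior quantiles, stratigraphic range extension, table I/O |
| `murodiv.bd_simulator` | forward birth–death simulation, clade rate shifts, incomplete sampling |
| `murodiv.diversification` | LTT series, sliding-window rates, null envelopes, exceedance regions |
| `murodiv.concordance` | resolved fraction, clade agreement, monophyly and disparate-clade metrics |
| `murodiv.screening` | pseudogene detection, accession ranking, conspecific monophyly, cross-gene discordance |
| `murodiv.synthetic_data` | fixture generators with ground-truth manifests |
| `murodiv.cli` | `murodiv` command-line interface |

See `docs/methods.md` for the models, conventions, and design choices.
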