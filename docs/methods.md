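# Methods

## The generative model

A ground-truth landscape maps a protein genotype to log10 green fluorescence
through a latent **fitness potential**: the sum of per-substitution additive
effects plus optional pairwise epistatic terms. Additive effects are drawn
from a neutral-or-deleterious mixture — with probability `neutral_fraction`
(default 0.35) a Normal(0, 0.02) draw, otherwise −Exponential(`deleterious_scale`,
default 0.8 log10 units). Epistatic terms are placed between random pairs of
*panel* moves (substitutions reachable by a single nucleotide change,
optionally subsampled to emulate mutational hotspots), negative with
probability 0.9 and exponential in magnitude.

The potential is pushed through an abrupt sigmoid threshold,
`F = F_dark + (F_wt − F_dark)·σ(steepness·(potential − midpoint))` with
defaults F_dark = 1.8, F_wt = 4.2, steepness 8, midpoint −1.5, producing the
bimodal fluorescence distribution characteristic of fluorescent-protein
scans: a dark mode and a near-wildtype mode. Substitutions at the three
chromophore sites, and premature stop codons, return `F_dark` outright.

A second transform, `LinearThresholdTransform` (`F = max(F_dark, F_wt +
potential)`), is **additive on the fluorescence scale** and serves as the
null for epistasis statistics: under a saturating sigmoid, additivity in
potential still produces strong apparent epistasis in fluorescence — the
threshold *is* epistasis — so a meaningful additive null requires
fluorescence-scale additivity. Its dark floor is absorbed by the capped
expectation of the epistasis statistic.

Presets: `FLAT_CONFIG` (robust peak: more neutral, weaker effects, no
epistatic terms), `SHARP_CONFIG` (fragile peak: stronger effects, dense
negative epistasis), `ADDITIVE_CONFIG` (the strict null above).

## The simulated experiment

Libraries are generated by i.i.d. per-nucleotide substitution over the coding
sequence; the rate is calibrated by exact per-codon enumeration of mutation
outcomes (`expected_aa_substitutions`) so the mean amino-acid load matches a
target (default ≈ 4 at 235 residues). Each genotype carries a unique 20-nt
primary barcode; secondary barcodes per primary are max(1, Poisson(7)); each
(primary, secondary, sorter) replicate receives Poisson(35) cells. Cells draw
log10 F from Normal(true F, 0.2) — about half a gate width, so sorted
populations span 2–3 gates and the binned CDF fit is well identified — are
affinely miscalibrated per sorter (sorter B: scale 1.03, offset −0.10),
gated on boundaries (2.0, 2.4, …, 4.4), and mis-sorted into an adjacent gate
with probability 0.01. Reads per gate are Poisson(cells × 2); barcode reads
carry i.i.d. substitution errors (0.002/nt) that create the spurious
secondary barcodes the merging rule exists for. Count-control barcodes
contribute exactly 5000 cells per gate per sorter. Known-brightness
spike-ins at levels (2.6, 3.2, 3.8) emulate the wildtype sequences of other
orthologs added to every library; they anchor the cross-machine regression,
which would otherwise be unidentifiable from the single wildtype level.

Coding-region reads cover two gene halves with a 30-nt overlap, split between
strands, with fixed per-half read counts and i.i.d. substitution errors.
Not emulated: indels, PCR chimeras, realistic quality profiles, nucleotide-
biased mutagenesis (a bias matrix hook exists but defaults to uniform).
Passing tests therefore validate the *rules and estimators*, not robustness
to those artifacts.

## Inference choices

* **Gate-distribution fit**: least squares of the 8 cell counts against
  N·ΔΦ over gate bounds, open-ended gates at ±∞; initial μ at the center of
  the fullest gate, initial σ that gate's width; bounds μ ∈ [b₁−2, b₇+2],
  σ ∈ [0.005, 2]; analytic Jacobian. σ collapsing onto a bound flags the fit.
  A genotype whose true level lies below the darkest gate boundary is not
  localizable — a single informative boundary leaves a μ–σ ridge — and is
  treated as *classified dark*, never as an estimate; recovery claims apply
  to the gated range.
* **Calibration**: OLS of sorter-A fluorescence on sorter-B over the known
  anchors; sorter A is the reference frame.
* **Replicate merging**: cell-weighted mean; index of dispersion computed on
  the linear scale (10^μ), where cutoffs of order 500–1000 are meaningful.
* **Epistasis null sd**: the epistasis of a d-mutant compares one observed
  measurement with d single-mutant measurements and a (1−d)-weighted
  wildtype reference. Replicate noise is treated as homoskedastic: the
  replicate variance is pooled across the dataset and each genotype's
  standard error is pooled_sd/√n. Per-genotype variance estimates from ~6
  replicates would have heavy t-tails and under-cover at 3σ.
* **LD50**: per-distance loss fractions (≥15 genotypes per bin, ≥4 bins)
  fitted with L/(1+e^(−k(x−x0))) under bounds L ≤ 1.05, k ≤ 10; LD50 solved
  analytically, defined only when L > 0.5. "Loss of function" is fluorescence
  below the darkest-gate upper boundary; "loss of wildtype level" is leaving
  the ±2 sd band around the wildtype mean.

## Neural networks

No deep-learning framework is used: the networks are small dense models
implemented in numpy with manual backpropagation, Adam (lr 10⁻³, batch 64),
MSE loss, and early stopping (patience 10, best weights restored). Targets
are z-scored internally (scale-only for the leaky-ReLU a-posteriori model,
whose one-sided output activation needs positive targets). The linear model
is the fitness potential; the sigmoid model is warm-started from the trained
linear model with the sigmoid node in its linear regime and an affine output
rescale (fluorescence is not confined to (0,1)). The two-layer family
(linear → dropout → sigmoid → dropout → linear output, dropout 0.1 active at
inference) is selected by random search over widths {1..10, 20, 50, 100,
200}² with 10-epoch trials. For dropout networks the validation loss is
computed **with dropout active** (8-pass mean), mirroring inference-time
behavior; this also steers the search away from very narrow layers whose
MC-dropout predictions are wildly unstable. MC predictions are medians/sds
of 20 stochastic passes. Encoding uses observed states per position
(wildtype state included; `full_alphabet` switch available); stop codons are
a valid state.

## Genetic algorithm

Population 50 wildtype sequences; each generation: shuffle, set half aside
untouched, pair the rest, cross over with probability 0.7 at 0–5 uniform
breakpoints (strict reciprocal exchange), mutate at 0.012 per residue with
moves sampled from the pool (0.6 weight on states absent from natural
homologs; wildtype states revert), trim over-target genotypes by removing a
random mutation per excess event, then merge parents, untouched and
offspring, sort by predicted fluorescence and truncate. The **whole
candidate pool is re-scored every generation**: with stochastic MC-dropout
fitness, cached scores let genotypes with lucky past evaluations survive
indefinitely and the population stagnates below the target distance.
Stopping: once ≥90% of the population is at the target distance (before
that the prediction median is trivially flat), a plateau of the median
(< 0.005 over 5 generations) plus 3 extra generations ends the run.
Replicate runs continue until all pool moves have been sampled (≥10 runs).
Designs are the unique at-target genotypes that survived selection in any
generation; final populations alone converge to a handful of near-identical
optima. Candidate filtering (MC median − sd above the wildtype prediction
under both the optimized and the a-posteriori model) and greedy identity
clustering (threshold 0.999 → 0.80 in steps of 0.002, brightest member per
cluster) follow as separate steps; on a synthetic peak whose truth saturates
at the wildtype level the brighter-than-wildtype rule is intentionally
strict and may pass few candidates.

## Benchmark experiments and problem sizes

The benchmarks module runs each experiment at sizes chosen for a single CPU:
fluorescence recovery over 1000 genotypes with true levels across the gated
range (several hundred cells each); the additive null and LD50 recovery on
full simulated experiments of 2500 genotypes at protein length 60 (the LD50
oracle Monte-Carlo samples 20 000 genotypes from the same mutagenesis
distribution); model ordering and the design contrast on panel-restricted
protein-level libraries (length 80, panel 100 moves, 4000–6000 genotypes,
measurement sd 0.03). The panel restriction emulates mutational hotspots and
keeps per-move genotype counts near the study's regime (tens per move);
with a fully uniform panel at desk-scale library sizes nearly every mutation
would fall below the 10-genotype training filter and the 5-background-pair
pool rule by arithmetic alone.

In the design contrast, the random arm combines individually *neutral*
substitutions — measured single-mutant effect within ±2 wildtype sd, the
same neutrality band used for cross-ortholog comparisons — because
background-pair impacts are uninformative when both genotypes sit at the
dark floor. The flat arm uses the fluorescence-additive transform: under a
saturating sigmoid, "measured neutral" can hide deleterious latent
potential, and the contrast would measure threshold epistasis rather than
interaction epistasis.

## Known limitations

* Dark genotypes are classified, not localized; their fluorescence estimates
  carry a μ–σ ridge artifact of order 0.1 log10 units.
* The consensus caller's 80%-agreement rule is depth-sensitive by
  construction (two coinciding errors among nine reads already reject); it
  rejects conservatively rather than miscalling.
* The GA's advantage on sharp peaks depends on the model having seen enough
  pair combinations; at much sparser pair coverage than the benchmark sizes
  the contrast weakens.
* Cross-ortholog and structural-annotation statistics consume external site
  maps / distance tables; none are computed from structures here.
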