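# Methods

## The model

ChIP-seq samples two pools of chromatin fragments: the **input**, a small
aliquot (volume v_in) removed from the reaction volume V before antibody
is added, and the **IP**, the subset captured by the antibody–bead
particle. For epitope species i with total fragment count n_i^t, the
fraction of its fragments starting in genomic interval x is o_i(x) =
n_i^t(x)/n_i^t. Assuming the antibody is unbiased with respect to genomic
position, the expected number of captured species-i fragments at x is
n_i^b·o_i(x), where n_i^b is that species' total bound count — e.g. 100
bound fragments of a species with 2% of its mass at x contribute 2
fragments there on average. Sequencing histograms are then proportional
to Σ_i n_i^b·o_i(x) (IP) and Σ_i n_i^t(x) (input), and the capture
efficiency on interval x for fragment length L is

    ê(x, L) = α · IP(x, L) / input(x, L)

with a single proportionality constant α that restores all the material
bookkeeping lost between the reaction tube and the sequencer.

### α from bench measurements

Each sample's observed mapped-fragment count R̂ is scaled up by every
known loss: the molar fraction of the library sequenced F_L, PCR
amplification 2^c, the library bead-capture yield ρ, and the mass
fraction of IP material carried into library prep F:

    R = R̂ / (F_L · 2^c · ρ · F).

α is the ratio of the input factors to the IP factors, with the volume
factor v_in/(V − v_in) folded in (we include it in α's definition, but
also report it separately so results can be reconciled against the bare
factor-ratio convention):

    α = (ρ_in/ρ) · (F_L,in/F_L) · (F_in/F) · v_in/(V − v_in).

Because α consumes only dimensionless ratios, manifests carry unit tags
(fmol for molar amounts, ng for masses, µl for volumes) and a ratio
mixing units is rejected rather than converted. When ρ is unmeasured it
defaults to 1 — the no-loss limit — with a logged warning; ρ > 1 is
accepted, since it absorbs global deviations from perfect 2^c
amplification. Reports print α and every factor at 4 significant figures
while keeping full precision internally; manifest write→read→compute
round-trips are bit-identical.

### The binding isotherm

The IP is modeled as competitive equilibrium binding with 1:1
antibody:epitope stoichiometry; the macroscopic binding constant K_B,i
(1/µM) absorbs the unknown polyvalent complexity of the
chromatin–antibody-bead interaction. Mass conservation gives the bound
concentration of species i as S_i^b = S_i^t·y/(1+y), y = AB^f·K_B,i,
where the free-antibody concentration AB^f is the unique root of

    g(a) = a + Σ_i S_i^t·(a·K_i)/(1 + a·K_i) − AB^t

on [0, AB^t]. g is strictly increasing with g(0) < 0 ≤ g(AB^t), so the
solver uses bracketed bisection (relative tolerance 1e−12, chosen for
robustness over speed at these problem sizes) followed by a few clipped
Newton steps that push the conservation residual to machine precision.
Counts and concentrations are linked by n_i^b = (V − v_in)·N_A·S_i^b, but
only fractions ever matter downstream, so the package works in
concentration space and in normalized count space interchangeably.

Two readouts must not be conflated: **capture efficiency**
(100·bound/total for one species — what a spike-in reports about itself)
and **fractional composition** (100·bound_i/Σ_j bound_j — the share of
sequenced fragments each species contributes, which spike-ins cannot
see). Composition percentages sum to exactly 100: the last species is
computed by complement.

### Depletion scans

Scans sweep the target total S1t downward under equal total chromatin and
antibody loading — the conditions under which two ChIP experiments are
comparable on the α scale. Two physical scenarios are provided: in
**case 1** depleted target is replaced by inert chromatin (the inert pool
absorbs the difference; it does not enter g), and in **case 2** it is
converted into the first off-target species, S2t = C − S1t with C = 11 µM
by default (configurable). Default off-target parameters are K = 0.1 and
0.5 1/µM with 0.3 µM totals, antibody at 6 µM, and target K = 11 1/µM —
a 110-fold and 22-fold selective antibody. Spike-in calibrants are
ordinary species tagged `spike` with small totals; the default example
uses 0.01 µM at K = 80 1/µM, an illustrative high-affinity semisynthetic
nucleosome (not asserted against any measured reagent). The scans
reproduce the model's qualitative predictions as strict monotonicities:
as target is depleted, free antibody rises, *every* species' capture
efficiency rises (so spike-in normalizers drift or saturate), target
composition falls and off-target composition rises.

### Tracks

Fragments are binned by start interval x (width chosen by the user) and
length bin (default 10 bp). The zero rule evaluates ê(x, L) to 0 whenever
either sample has no fragments in a bin; bins where the IP has counts but
the input does not are additionally flagged, since they are the symptom
of a too-small interval. The 2D→1D projection is the input-count-weighted
mean of ê(x, L) over L, which preserves per-base units, collapses
algebraically to α·IP(x)/input(x), and reduces to the scalar ratio when L
is constant. Per-fragment units multiply by ⟨L⟩, the mean fragment length
of the IP sample by default (configurable to an input-derived or pooled
value). Single-end data is supported by assigning a user-supplied
constant length.

Interval-width stabilization builds the track at an increasing width grid
(default 1, 2, 5, 10, 20, 50 kb) and compares consecutive widths after
resampling the finer track onto the coarser grid by *unweighted* mean
over data-bearing fine bins — weighting by counts would telescope to an
exact identity, whereas the unweighted mean stays sensitive to the
zero-evaluated bins and ratio scatter that mark an unstable width. The
chosen width is the smallest whose mean absolute relative difference to
the next width is below the tolerance (default 0.05); if none converges,
the largest width is returned with a flag.

Differential (treatment/control) tracks emit bins where either condition
is zero as *missing*, never 0 or ∞, so browsers do not render false
depletion. bedGraph output is 0-based half-open, omits zero/missing bins,
and optionally run-length merges equal-valued runs.

### Spike-in comparison

The HMD-style normalizer is the spike-in IP read count over the spike-in
input read count; the raw ratio track is divided by it and multiplied by
⟨L⟩. The package treats spike-in counting as upstream and consumes the
counts, because the critique it enables is arithmetic: a spike-in scale
is physically meaningful only when the normalizer equals α⁻¹, and the
ratio of normalizers between two conditions can imply a material
difference far from the one the α ratio (which tracks every measured
quantity) reports.

### Overlap statistics

Coverage sets are compared on a common grid of fixed-width bins so that
the hypergeometric urn model is exact: with N bins, |A| and |B| covered,
the expected co-coverage is |A||B|/N, fold enrichment is
observed/expected, and significance is the exact upper tail
P(X ≥ observed). The universe defaults to all bins of the supplied
chromosome sizes and is configurable; the statistic is symmetric in the
two sets.

## Synthetic data

The generator emulates the study conditions end to end: a toy genome
(default 2 chromosomes × 1 Mb at 10 kb intervals — the working resolution
for broad marks, at desk scale), per-species genomic distributions
o_i(x), an equilibrium IP solved from the isotherm, and fragment files
sampled as a multinomial over (species, interval) cells with
probabilities ∝ S_i^t·o_i(x) for the input and ∝ S_i^b·o_i(x) for the
IP. Fragment lengths follow a truncated discrete Gaussian (mean 150 bp,
sd 20, support [50, 500] — a typical mononucleosome-scale library);
starts are uniform within an interval. The default reaction is the
depletion-scan system above (target 10.7 µM, K = 11; off-targets 0.3 µM
at K = 0.1 and 0.5; antibody 6 µM).

Because sampling normalizes within each sample, the true α is fixed by
the depths and the bound/total concentration ratio, α =
(depth_input/depth_IP)·(ΣS^b/ΣS^t); the generator fabricates a manifest
realizing this α purely through the volume factor, so the α module
recovers it exactly. A ledger records seeds, per-species bound counts,
per-bin expected counts, and the exact predicted ê(x), making every
pipeline stage testable without sequencing data. A single seed feeds
deterministic substreams (input and IP), and outputs are byte-identical
across runs.

What the generator does **not** emulate: mappability and GC biases,
duplicate fragments, chromatin-state-dependent fragmentation, antibody
positional bias, cell-to-cell heterogeneity beyond the species mixture,
and sequencing error (fragments are intervals, not reads). Passing
recovery tests therefore demonstrate the correctness of the arithmetic
and the estimator under the model's own assumptions, not robustness to
real-library artifacts.

## Verification scale and expectations

The recovery experiment samples 10⁴ and 10⁵ fragments per sample over 200
intervals (roughly 50 and 500 fragments per interval) — sizes chosen so
the whole suite runs in seconds on a laptop while leaving the shot-noise
scaling visible. The mean absolute error of the recovered ê(x) against
the ledger's prediction falls by more than half from 10⁴ to 10⁵ (the
√depth trend plus the rapidly vanishing zero-rule bias of sparse 2D
cells). The isotherm solver is checked against an independent bisection
oracle (and a 10⁶-point grid bracket on the reference reaction) to 1e−8,
with conservation residuals below 1e−10; the hypergeometric tail is
checked against exhaustive enumeration on universes of ≤ 12 bins.

## Degenerate inputs and tie-breaks

Zero antibody or an all-inert species list yields the trivial solution
(all free) rather than an error; composition is undefined (raises) when
nothing is bound. Empty fragment files produce empty tracks with a
warning. Fragments with end ≤ start are skipped and counted; structurally
malformed lines fail loudly with their line number. Grids for depletion
scans must be strictly monotone, and infeasible points (implied negative
concentrations) name the offending grid value.

## Known limitations

* The 2D→1D projection is one defensible choice among several; at high
  resolution, per-fragment units should use an integral over the length
  distribution rather than a single ⟨L⟩ factor.
* Equilibrium only: no wash kinetics or off-rate modeling; binding
  constants are forward inputs, never fitted.
* The low-material regime (pooling several IPs into one library) is out
  of scope.
* Spike-in read extraction (barcode/foreign-genome alignment) is
  upstream; the spikein module consumes counts.
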