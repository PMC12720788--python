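# Methods

## Exchange model

Each backbone amide follows the linear three-state chain

    closed --k_open--> open --k_int--> exchanged
    open  --k_close--> closed

starting closed. With s = k_open + k_close + k_int and p = k_open·k_int,
the survival probability decays with the two rates r_slow, r_fast
(roots of r² − s·r + p = 0) and the exchanged fraction is

    P(t) = [r_fast(1 − e^(−r_slow t)) − r_slow(1 − e^(−r_fast t))] / (r_fast − r_slow).

This closed form is exact in every regime, including irreversible opening
(k_close = 0) and the degenerate equal-root case (handled by the
1 − (1 + rt)e^(−rt) limit). r_slow is evaluated as p / r_fast to avoid
cancellation, and 1 − e^(−rt) via expm1. In the EX2 limit
(k_int ≪ k_close) r_slow → K_op·k_int with K_op = k_open/k_close; in the
EX1 limit (k_int ≫ k_close) r_slow → k_open. An independent event-driven
Monte-Carlo oracle (alternating exponential dwell times, exchange with
probability k_int/(k_close + k_int) per opening) validates the closed
form in the tests; it shares no code path with it.

Peptide-level envelopes: independent residues give the exact
Poisson-binomial convolution of per-residue outcomes (unimodal, gradually
shifting centroid — the EX2 spectral signature); a correlated-opening
mode drives a residue block with one shared opening clock, producing the
bimodal undeuterated/fully-deuterated mixture typical of EX1. The
bimodality detector (two local maxima separated by a trough deeper than a
noise floor) is a diagnostic convention of this package, not a field
standard.

## Synthetic experiments

`simulate_dataset` turns a `SimulationDesign` into a canonical uptake
table. Expected relative uptake of a peptide is the mean exchange
probability over its observable amides (first two residues and prolines
excluded) scaled by the deuterium fraction of the labelling buffer;
Gaussian noise (sd `noise_sd`, in relative-uptake percent, homoscedastic
across timepoints) is added per record and negative draws are clipped at
zero; exposure-0 records are exactly zero. Condition effects multiply
k_open per residue (k_close fixed), the minimal perturbation consistent
with an EX2 reading where uptake differences reflect opening-equilibrium
differences. Ligand-bearing states with occupancy θ < 1 mix bound and
apo probabilities with weights (θ, 1 − θ). One integer seed drives all
draws.

The reference design (`myoglobin_design`) emulates a 162-residue
myoglobin construct (153-residue globin plus a GSG-His6 tag; the sequence
is a synthetic stand-in) measured as 2 variants × 2 ligand states ×
9 non-overlapping peptides (97% coverage) × 7 exposures
(0, 30, 90, 300, 1800, 3600, 5400 s) × 2 replicates. Per-peptide observed
rates are imposed exactly by inverting r_slow for k_open at k_int = 1 s⁻¹,
k_close = 100 s⁻¹ (EX2 by two orders of magnitude): peptide 56–69 carries
the experimentally reported region rates (0.0052/0.0046 s⁻¹ WT apo/holo,
0.0447/0.0263 s⁻¹ mutant apo/holo), peptides 12–29 and 30–40 are
rigidified in the mutant to −18% and −13% time-averaged ΔHDX over the
four pre-saturation exposures, peptides 41–55, 70–86 and 87–106 are
mildly loosened (below +10% average), and the termini are unchanged.
Holo occupancy is computed from K_D = 11.2 µM, [P]₀ = 100 µM,
[I]₀ = 1188 µM (θ ≈ 0.99). Default replicate noise is 3.1% (1σ), the
experimental variability of a duplicate HDX-MS workflow, and the
deuterium fraction is 0.9 (5 µL protein into 45 µL of 99% D₂O).

What the simulator does not emulate: back-exchange during quench/LC
(a constant loss factor exists but defaults to 1), heteroscedastic or
peptide-length-dependent noise, correlated replicate errors, carryover,
and overlapping-peptide redundancy. Passing tests therefore demonstrate
statistical correctness of the analysis under idealised EX2 exchange with
Gaussian replicate noise, not robustness to every artifact of real data.

## Uptake quantification and table model

Uptake is the centroid-mass difference deuterated − undeuterated.
Negative differences above −0.1 Da are clipped to zero with a warning
(noise); below −0.1 Da they are rejected as data errors. When a table
carries both centroids and an uptake column they must agree within
0.05 Da. Relative uptake divides by the exchangeable-amide count
length − 2 − (prolines beyond position 2); the denominator convention is
overridable per peptide. Exposure-0 rows are forced to zero uptake.
`select_nonoverlapping` solves weighted interval scheduling exactly
(weight = residue count), deterministically, rather than greedily — the
returned subset provably maximises residues covered.

## Differential statistics

The significance cutoff pools replicate variability globally: within
each (peptide, state, exposure) group the replicate variance of relative
uptake is computed, and the pooled σ is the square root of the
df-weighted mean within-group variance over all groups and both
conditions (exposure 0 excluded). A `raw` mode (SD of the flat pooled
value distribution) exists for comparison but mixes between-peptide
spread into the estimate and is not the default. ΔHDX% is the difference
of replicate-mean relative uptakes (B − A, B the perturbed condition);
an entry is significant when |Δ| strictly exceeds multiplier × σ (ties
are not significant; a 1e−12 relative epsilon absorbs floating-point
dust). Directions: positive significant = more flexible, negative = more
rigid. Peptide-level calls require significance at ≥ `min_timepoints`
exposures with direction from the sign of the time-averaged Δ.

Under the null with duplicate measurements the replicate-mean difference
has standard deviation σ, so the per-entry flag rate at the mσ cutoff is
2Φ(−m): ~31.7% at 1σ. The 1σ/any-timepoint convention is therefore a
visualisation threshold, not a multiplicity-controlled test; for
automated peptide classification the recovery analyses use a 2σ cutoff
with ≥ 2 (or ≥ 3, for small pooled-σ cohorts where threshold estimation
noise inflates the null rate) significant timepoints, chosen a priori
from the Gaussian null to keep per-peptide specificity above 95%. No
multiple-testing correction is applied by default, matching the fixed-σ
convention; a Bonferroni-style multiplier can be passed explicitly.

## Kinetic fitting

D(t) = A(1 − e^(−kt)) is fitted by bounded least squares (lmfit) on the
individual replicate points, uniform weights, with
k ∈ [10⁻⁶, 10] s⁻¹ and A ∈ (0, 1.2 × max uptake]; initialisation
A₀ = max uptake, k₀ = ln 2 / (earliest time reaching A₀/2, else the
median non-zero time). Exposure-0 points are exact anchors. A fit is
flagged non-converged when the optimiser fails or a parameter sits on a
bound. Rates are reported in s⁻¹ and min⁻¹ (×60 exactly) and classified
fast (≥ 10 min⁻¹) / intermediate / slow (< 0.05 min⁻¹) — a reporting
convention, configurable, not a literature constant. `kop_from_ex2`
divides k_HDX by a user-supplied k_int and rejects k_HDX > k_int as an
EX2-regime violation. Fitted-rate bias is ≤ 5% (median) for true rates
within ~[0.001, 0.05] s⁻¹ on the 7-exposure schedule; rates far outside
the sampled window are not reliably identifiable and callers should
treat bound-adjacent fits as censored.

## Binding occupancy

The 1:1 quadratic mass balance is evaluated as
[PI] = 2[P]₀[I]₀ / (b + √(b² − 4[P]₀[I]₀)) with b = [P]₀ + [I]₀ + K_D,
algebraically identical to the textbook root but stable when
4[P]₀[I]₀ ≪ b². The inverse (`ligand_for_occupancy`) is the closed form
[I]₀ = θ[P]₀ + θK_D/(1 − θ). Concentrations are unit-agnostic but must
match.

## Problem sizes and determinism

Validation analyses use: a 27-point rate grid with a 10⁵-molecule
stochastic oracle; ≥ 10⁴ null Wood's entries (100 seeded runs of a
20-peptide two-condition design); 200 seeded runs each for parameter
recovery and differential recovery; 25 seeded replicate experiments for
median rate and pooled-σ estimates. Every stochastic component is driven
by explicit integer seeds; identical seeds give bit-identical datasets,
tables and reports.

## Known limitations

Peptide-level EX2 fitting cannot separate k_open from k_close, and a
single exponential under-describes peptides with strongly heterogeneous
per-residue rates (the fitted k then tracks a weighted average; the
reference design avoids this by giving each peptide one rate). Residue
values from `residue_deltas` flat-average overlapping peptides — no
residue-level deconvolution is attempted. Back-exchange correction,
spectral processing (peak picking, deconvolution) and peptide
identification/FDR are out of scope: the pipeline starts at centroid
masses.
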