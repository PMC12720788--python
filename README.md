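# hdxdelta

Differential analysis of peptide-level hydrogen–deuterium exchange mass
spectrometry (HDX-MS), built around the workflow used to compare an
engineered myoglobin variant with its parent protein in the apo and
substrate-analog-bound states.

HDX-MS reports on protein flexibility: backbone amide protons exchange
with solvent deuterons only when transient local unfolding exposes them.
In the Linderstrøm-Lang picture each amide cycles between closed and open
states (rates k_open, k_close) and exchanges from the open state at its
intrinsic rate k_int. In the common EX2 regime (k_int ≪ k_close) the
observed rate collapses to

    k_HDX = K_op · k_int,      K_op = k_open / k_close,

so uptake differences between two protein states report directly on
changes in the opening equilibrium (protection factor = 1/K_op).

The package provides:

- **`hdxdelta.io`** — a validated long-format uptake table (one row per
  peptide × state × exposure × replicate), centroid-difference uptake
  computation, exchangeable-amide counting, non-overlapping peptide
  selection (exact maximum-coverage), and sequence coverage.
- **`hdxdelta.differential`** — Wood's-plot statistics: per-peptide,
  per-timepoint ΔHDX% between two conditions with a global pooled
  replicate σ as significance cutoff, direction calls
  (more flexible / more rigid), and time-averaged effect summaries.
- **`hdxdelta.kinetics`** — one-exponential fits D(t) = A(1 − e^(−kt)),
  rate-regime classification, EX2 inversion to K_op, and fit comparison.
- **`hdxdelta.binding`** — quadratic 1:1 binding occupancy
  θ from (K_D, [P]₀, [I]₀) and saturation planning for labelling buffers.
- **`hdxdelta.simulate`** — a residue-level exchange simulator (exact
  three-state closed form, EX1/EX2 envelope diagnostics, event-driven
  stochastic oracle) that generates full synthetic experiments with known
  ground truth, including a reference myoglobin-like design.
- **`hdxdelta.structure`** — per-residue ΔHDX% written into PDB B-factors
  for structure colouring.
- A `hdxdelta` CLI with `simulate`, `diff`, `fit`, `occupancy` and
  `report` subcommands.

## Worked example

Check that the labelling conditions keep the protein saturated with the
substrate analog (K_D = 11.2 µM, 100 µM protein, 1188 µM ligand):

```text
$ hdxdelta occupancy --kd 11.2 --p0 100 --i0 1188
[PI] = 98.98 uM
theta = 0.9898
ligand excess = 11.88-fold
```

θ ≈ 0.99: ~99% of protein molecules carry ligand during labelling, so
holo-state uptake reflects the bound conformation almost exclusively.

Simulate the reference duplicate experiment and analyse it:

```python
from hdxdelta import (myoglobin_design, simulate_dataset, pooled_sigma,
                      woods_table, mean_delta, fit_uptake_curves, ProteinState)

records, truth = simulate_dataset(myoglobin_design(seed=0))
sigma = pooled_sigma(records)
print(f"pooled sigma = {sigma.sigma_pct:.2f}%")        # 3.08%

table = woods_table(records, ProteinState("wt"), ProteinState("mutant"),
                    sigma, timepoints=[30, 90, 300, 1800])
print(f"peptide 12-29: {mean_delta(table, (12, 29)):+.1f}%")   # -18.3%

fits = fit_uptake_curves(records, peptide=(56, 69))
print(fits[["variant", "ligand", "k_hdx_s", "k_hdx_min", "rate_class"]])
```

The pooled σ (≈3.1%) is the 1σ experimental variability of the duplicate
workflow and sets the Wood's-plot significance cutoff. Peptide 12–29
loses ~18% uptake in the mutant (rigidified), while peptide 56–69
exchanges an order of magnitude faster in the mutant
(k ≈ 0.045 s⁻¹ = 2.7 min⁻¹ vs ≈ 0.0055 s⁻¹ = 0.33 min⁻¹, both
intermediate-regime rates) — the signature of locally increased
flexibility.

The same analysis runs end to end from the shell:

```sh
hdxdelta report --seed 0 --out analysis/
hdxdelta diff --input analysis/uptake.csv --state-a wt:apo --state-b mutant:apo
```

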