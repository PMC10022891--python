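# Methods

## Scope and model chain

`curvsense` treats curvature sensing and membrane binding as one
thermodynamic continuum. The quantity of interest is the relative binding
free energy ΔΔF (kJ mol⁻¹): the difference in a peptide's binding free
energy between a stretched membrane leaflet (which mimics the outside of a
highly curved vesicle, reference radius R_ref = 12.5 nm) and a tensionless
one. Negative ΔΔF means preferential binding to curved membranes. The
package provides three coupled components — a genetic-algorithm (GA)
sequence optimizer, a convolutional ΔΔF regressor, and a two-state
partitioning model that converts ΔΔF into a nonbinder / sensor / binder
classification — plus sequence descriptors and a synthetic-data layer that
makes the whole chain runnable and testable without any molecular dynamics.

## Two-state partitioning model

A peptide occupies one of two states: solvated (s) or membrane-bound (m),
separated by the partitioning free energy ΔF_sm (membrane minus solution).
At equilibrium the membrane-bound probability is

    P_m = 1 / (1 + (N_s/N_m) · exp(ΔF_sm / RT)).

The entropic prefactor counts accessible realizations:
N_s = V / V_p and N_m = A / A_p with membrane area A = ½ c N_A A_lip
(half the lipids face outward). Defaults — 1 L volume, c = 1 mM lipid,
A_lip = 0.64 nm², a 5 nm² / 5 nm³ peptide — give N_s/N_m ≈ 5.2 × 10³, so
the switch midpoint sits at ΔF_sm = −RT ln(N_s/N_m) ≈ −21.2 kJ mol⁻¹:
weak but favorable binding. Note that the ratio is *inversely* proportional
to the peptide volume V_p and proportional to its footprint A_p, both of
which only shift the switch logarithmically.

Sensing free energies map onto partitioning free energies linearly. Two
corrections first make peptides comparable:

- **Length.** ΔΔF grows linearly with length; short peptides are
  extrapolated to the 24-residue reference with the proportional model
  ΔΔF_(L=24) = ΔΔF · 24/L (a line through the origin — the simplest model
  consistent with linearity and with the regressor's label interpolation).
  A user-supplied per-residue slope is accepted for compositions where an
  affine model is known.
- **Charge.** Free energies computed on neutral membranes underestimate
  cationic peptides that target anionic membranes in vivo; the correction
  ΔΔF_adj = ΔΔF_(L=24) + c_z·z uses c_z = −0.93 kJ mol⁻¹ per unit charge
  (reported uncertainty ± 0.89 kJ mol⁻¹; the point estimate is used and the
  uncertainty is not propagated).

The flat-membrane map is the empirical line ΔF_sm(∞) = 3.83·ΔΔF_adj + 12.27
(taken as given constants; the package does not refit it). For a vesicle of
radius R the curvature contribution is modeled as

    ΔF_sm(R) = ΔF_sm(∞) + (R_ref / R) · ΔΔF_adj,

i.e. the full sensing free energy is gained at the reference curvature and
decays as 1/R. This radius dependence is an analytic **reconstruction** —
chosen as the simplest form that (i) reduces to the flat line at R → ∞,
(ii) adds exactly ΔΔF_adj at R = R_ref, and (iii) reproduces the sensing
window boundaries at R = 50 nm (−6.4 and −10.0 kJ mol⁻¹ in ΔΔF_adj; −13.9
and −28.5 kJ mol⁻¹ in ΔF_sm) to printed precision. It is kept in one
function (`thermo.delta_f_radius`) so an alternative derivation can be
swapped in.

Temperature defaults to 298.15 K (RT ≈ 2.479 kJ mol⁻¹). The underlying
free-energy simulations are typically thermostatted at 310 K, but the
printed transition point and window boundaries are mutually consistent only
with RT at 298.15 K, so that is the default; it is a plain parameter.

A peptide is classified at a queried radius (default 50 nm, a typical
vesicle) by the window on P_m: nonbinder below 0.05, sensor in [0.05,
0.95], binder above 0.95. The window probabilities are parameters; the
generous default width absorbs the sensitivity of both the empirical
classifications and the switch position to lipid concentration. Boundaries
are inverted in closed form (`thermo.sensing_window`), and classification
uses the same constants, so window and classifier agree to round-off.

## Genetic algorithm

The GA minimizes scaled fitness c·ΔΔF (more negative = fitter) over
fixed-length sequences. Defaults mirror the production configuration:
population 144, truncation selection of the fittest 36 as parents,
one-point crossover (tails swapped at a shared random split), per-position
mutation with probability 1/L so each child carries on average one
substitution, and L = 24 over a reduced 10-letter alphabet of helix-prone
residues {A, L, M, K, Q, E, W, S, Y, F} (one representative per chemical
subtype; the full 20-letter alphabet and arbitrary letter subsets are
configurable). An applied mutation always draws a *different* residue, so
the expected Hamming distance is exactly L·p_mut — this interpretation
makes the one-mutation-per-child contract hold exactly.

The surface constraint c = ½(1 − cos πd/b) for 0 ≤ d ≤ 2b (else 0) is
evaluated under both membrane conditions — b = 1.90 nm tensionless, 1.79 nm
stretched — and the smaller factor is used, so only candidates stably bound
at the surface under both conditions keep their full score.

Because MD-derived fitness is noisy, two elitism rules stabilize the
search: the generation's best individual is copied forward, and any
individual evaluated more than three times is retained. All carried
individuals are re-evaluated every generation and score the running mean
of their evaluation history, so persistent candidates accumulate sampling.
Implementation choices the production description leaves open, fixed here:
the fitness elite is a single individual; selection ties break by earlier
birth order then lexicographic sequence; offspring are generated pairwise
until the open slots fill (an odd last slot takes the first child only);
rerun elites may also serve as parents when they rank in the top pool; a
failed backend evaluation logs the error and scores 0 — the same value as
any non-surface configuration — rather than aborting the run; there is no
early stopping, only a fixed generation budget.

## Surrogate oracle and synthetic data

The MD stage is abstracted behind a backend interface returning
(ΔΔF, d_tensionless, d_stretched). The bundled surrogate is deliberately
non-physical but preserves the qualitative structure of the problem:

    ΔΔF_toy = −κ Σ_i max(0, H_i) + λ|z|,   clipped to [−40, 0],

with Eisenberg hydrophobicities H_i, κ = 1.5 kJ mol⁻¹ per hydrophobicity
unit and λ = 1 kJ mol⁻¹ per unit |charge| (defaults put labels on the
realistic [−35, 0] kJ mol⁻¹ scale; the clip guards GA runaways). The toy
insertion depth d = 2b(1 − f), with f the hydrophobic residue fraction,
makes the surface window bite: all-polar peptides float (c = 0),
all-hydrophobic ones sink (c = 0), and f = 0.5 is optimal, so the GA must
negotiate the same hydrophobicity-vs-solubility trade-off that shapes real
amphipathic sensors. Synthetic datasets label uniform random sequences
(lengths 7–24 unless stated) with ΔΔF_toy plus Gaussian noise of
sd 0.5 kJ mol⁻¹, chosen to be comparable to typical MD sampling error on
this scale.

What passing surrogate-based tests shows: the optimizer, augmentation,
training loop and classification chain are correct and convergent on a
landscape with the right structure and scale. What it does not show:
anything about real membranes — the surrogate has no notion of lipid
packing, helix geometry, or sequence order (it is composition-additive), so
recovery scores on it do not transfer to experimental accuracy.

## Regressor

Inputs are one-hot encoded over the 20 canonical residues (channels in
alphabetical order, `ACDEFGHIKLMNPQRSTVWY`) and zero-padded at the tail to
24 positions; valid input lengths are 7–24 residues and the model refuses
to extrapolate beyond 24. The architecture is two same-padded 1-D
convolution blocks with ReLU and non-overlapping max pooling, a dense ReLU
layer, and one linear output. The published architecture's hyperparameters
are not public; the defaults here — (64 filters, kernel 5, pool 2) × 2,
dense 128 — were sized on the surrogate recovery task (5,000 labeled
sequences, noise sd 0.5), where they reach held-out R² ≈ 0.94 in about a
minute on one CPU core; halving the widths costs ~0.06 R². All are
overridable through `CNNSpec`.

Training minimizes MSE with Adam (learning rate 3 × 10⁻³, batch 32) on a
75/25 random train/validation split, for at most 100 epochs with early
stopping (patience 30) on validation MSE; the best-validation weights are
restored. Labels are standardized internally and predictions returned in
kJ mol⁻¹. The implementation is plain numpy with hand-written backprop —
at these tensor sizes a framework would add dependencies, not speed — and
is deterministic given the training seed.

Augmentation splits each 24-mer once at a position drawn uniformly from
[7, 17], so both fragments are ≥ 7 residues and sum to 24; fragment labels
are ΔΔF · L/24, the same proportional length model used by the
classification chain, keeping the two length treatments consistent.
Duplicate fragment sequences are discarded (first occurrence wins,
labels not compared), so the augmented set is at most 3n records with no
duplicates. Saved models are a directory holding a JSON spec (including
the encoding conventions, so artifacts are portable) plus an `.npz` weight
archive.

## Descriptors

Net charge counts side chains only — (K + R) − (D + E), histidine neutral
— with the termini treated as a zwitterionic net-zero pair. The
hydrophobicity scale is injectable and defaults to the Eisenberg consensus
scale, the standard choice for hydrophobic-moment analysis. The moment uses
δ = 100° per residue (α-helix; configurable for 3₁₀/π geometry) and is
reported per residue by default so different lengths are comparable.
Correlation of ⟨H⟩ and μ_H with partitioning free energies can be explored
with these utilities, but no quantitative relationship is asserted —
descriptors are provided precisely because they are *insufficient* to
separate sensors from binders.

## Numerical notes

- P_m is evaluated through a logistic form (`scipy.special.expit`), so
  extreme free energies saturate to 0/1 without overflow.
- Window inversion is closed-form; classification boundaries therefore
  agree with `sensing_window` to better than 10⁻⁹ kJ mol⁻¹.
- N_s/N_m uses the unrounded computed ratio (≈ 5.189 × 10³) rather than the
  two-significant-figure 5.2 × 10³; both give the same transition point to
  one decimal.
- Max-pooling ties (equal activations in one window) split the gradient
  evenly; with continuous-valued activations this is a measure-zero event.
- GA selection is made fully deterministic by the birth-order/lexicographic
  tie-break, so runs are exactly reproducible from (config, seed).

## Test problem sizes

Desk-scale defaults keep the full suite fast while exercising every claim:
GA correctness is established against exhaustive enumeration on a 3-letter,
length-5 space (243 sequences, 10 seeds) and convergence on a 48-member
population over 30 generations; regressor recovery trains on 5,000
surrogate-labeled sequences and evaluates on 500 held-out ones. These sizes
are the package's own test conditions, chosen so each property is decidable
well clear of noise.

## Known limitations

- The radius dependence of ΔF_sm is a reconstruction (see above), accurate
  at the calibration points but not derived from membrane elasticity.
- The linear map 3.83/12.27 and c_z are fixed constants estimated
  elsewhere; the package neither refits nor propagates their uncertainty.
- The proportional length model is shared by design between augmentation
  and classification; if the true length dependence has a nonzero
  intercept, both inherit the same bias.
- The regressor assumes helical secondary structure implicitly through its
  training labels; it has no notion of folding propensity.
- The surrogate oracle is composition-additive and order-blind; it cannot
  validate positional effects (e.g. charge placement on one helix face).
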