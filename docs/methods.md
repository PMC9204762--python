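# Methods

## Problem and model

The package estimates metastable-state kinetics of a disordered peptide
from an ensemble of short MD trajectories sampled at a fixed frame
interval (default 250 ps). Dynamics are modelled by a soft-state Markov
(Koopman) description: each frame carries a probability vector
χ(xₜ) over k states rather than a hard cluster label, and the transition
operator K(τ) propagates state expectations over a lag τ. Soft
assignments matter for disordered systems because metastable basins are
shallow and frames near barriers are genuinely ambiguous.

χ is a feed-forward network (self-normalizing SELU units, LeCun-normal
initialization, softmax output) trained by stochastic maximization of
the VAMP-2 score of time-lagged pairs,
R = ‖C₀₀^{−1/2} C₀τ Cττ^{−1/2}‖²_F computed from the second-moment
matrices of (χₜ, χₜ₊τ). The gradients of R with respect to the network
outputs are implemented in closed form (∂R/∂C₀τ = 2C₀₀⁻¹C₀τCττ⁻¹ and the
corresponding terms for C₀₀, Cττ), back-propagated through the softmax
and SELU layers by hand-written reverse mode. This keeps the trainer a
plain NumPy component with no deep-learning framework dependency.

The published protocol this pipeline mirrors parametrizes K and π inside
a constrained network layer; that parametrization is not fully specified
by the available description, so here K is estimated post hoc from the
trained χ by soft transition counts, Cᵢⱼ = Σₜ χᵢ(xₜ)χⱼ(xₜ₊τ), row
normalization, and π as the leading left eigenvector of K. This is the
simplest estimator satisfying the stated contracts (row-stochastic K,
stationary π), and it reduces *exactly* to the classical count MSM for
hard assignments — a property the tests assert at 1e-12. It is a
documented deviation risk: variational constrained estimators can differ
on poorly sampled data.

## Training protocol

Frames are split into a 10% test hold-out and repeated randomized 9:1
train/validation splits (20 by default). A time-lagged pair (t, t+τ)
belongs to a split according to its start frame; pairs never span
trajectory boundaries. For each split three independently initialized
trials are trained with Adam on batches of frame pairs, early-stopped
when the best validation VAMP-2 score improves by less than 1e-3 over
the last five epochs, and the best trial is kept by its test-set VAMP-2
score. Two presets exist:

- `desk` (default): 2×64 network, learning rate 0.02, batches of 2,000
  pairs, no dropout/L2 — sized for laptop-scale synthetic benchmarks;
- `paper`: 2×512 network, learning rate 0.05, β₂ = 0.99, ε = 1e-4,
  L2 1e-7, dropout 0.05, batches of 10,000 pairs, matching the published
  hyperparameters. (Alpha-dropout is approximated by standard inverted
  dropout; with dropout 0.05 the difference is minor.)

For ligand (holo) ensembles, frames with minimum ligand–peptide distance
above 0.5 nm are excluded before splitting. Models trained on the same
data are aligned by minimizing the total RMSD between state-averaged
contact maps over state permutations, ties broken by population.
Multi-model observables report the mean over models with either the
95th-percentile interval of the bootstrap distribution of the mean
(default, 1000 resamples) or its bootstrap SD.

## Validation battery

Implied timescales tᵢ(τ) = −τ/ln|λᵢ| are recomputed on a lag grid
(default {1.25, 2.5, 5, 10, 20} ns at 250 ps spacing) and should be flat
in τ. The Chapman–Kolmogorov test compares K(τ)ⁿ against K(nτ) estimated
directly; since no universal numeric tolerance exists, the pass
criterion is that each predicted entry lies within the 95% bootstrap
band (resampling trajectories, 20 resamples by default) of the direct
estimate. Complex eigenvalues enter timescales through their modulus.
Timescale convergence resamples subsets of trajectories without
replacement and reports the mean and 2.5/97.5 percentiles per count.

## Observables and conventions

- Lifetimes t̄ᵢ = −τ/ln Kᵢᵢ(τ) are *lag-dependent*: at longer lags the
  diagonal includes recrossings, so t̄ᵢ(τ) > t̄ᵢ(dt). Recovery tests
  therefore compare against the analytic value of the same functional at
  the model lag (diag of the matrix power of the generating chain). For
  a 2×2 model the familiar reciprocal relation 1/t = 1/t̄₁ + 1/t̄₂ holds
  only to first order in the exit probabilities; the exact identity is
  λ₂ = K₁₁ + K₂₂ − 1.
- Transition "rates" are reported as Kᵢⱼ(τ)/τ in 1/µs — the simplest
  τ-scaled definition at a fixed-lag model; inverse mean first-passage
  times are available behind a flag (`transition_rates(..., mfpt=True)`).
- Frame weights follow wₜ ∝ Σᵢ πᵢχᵢ(xₜ)/Nᵢ with Nᵢ = Σₜχᵢ(xₜ), the
  unique form that reduces to standard MSM frame reweighting (exactly
  uniform weights when π equals the empirical state frequencies under
  hard assignment).
- Ramachandran entropy: per-residue weighted 2D histogram of (φ, ψ) on
  [−π, π)², default 100 bins *per axis* (the alternative reading, 100
  total cells, is selectable via `per_axis=False`; ensemble comparisons
  are insensitive to the choice). Entropies are in nats.
- χ1 autocorrelation embeds angles as unit vectors,
  ρ(τ) = (⟨uₜ·uₜ₊τ⟩ − |⟨u⟩|²)/(1 − |⟨u⟩|²); a linear autocorrelation on
  raw angle values is available behind a flag since the circular
  convention is not fixed by the source protocol. Constant series define
  ρ = 1 (flagged).
- Contact lifetimes use hard 2×2 transition counts per contact at the
  analysis lag (default 5 ns) with no pseudocounts; contacts that never
  form, never break, or whose dwell falls below the lag resolution are
  flagged instead of smoothed.
- π-stacking: the geometric criterion is ring-centroid distance ≤ 0.55 nm
  by default — a deliberately minimal stand-in, since no published
  criterion is available for the target system; an optional ring-plane
  angle filter (≤ 45°) can be enabled.
- Residues are numbered 1-based in all reports, 0-based internally.
  Angles are radians internally, degrees in CSV exports; distances nm.

## Synthetic benchmark

The generator emulates the structure of the real analysis inputs while
keeping every kinetic quantity analytic: a global discrete-time Markov
chain at dt = 250 ps drives (i) per-state von Mises φ/ψ emissions, (ii)
χ1 rotamer hopping among three symmetric wells with state-dependent hop
rates (discrete relaxation factor 1 − 3p/2 per step for hop probability
p), and (iii) two-state telegraph ligand contacts sampled exactly from
the continuous-time process (stationary occupancy k_on/(k_on+k_off),
mean on-time 1/k_off). Optional 3D coordinates are built from the
dihedrals by internal-coordinate (NeRF) chain construction with ideal
backbone geometry and a CB/CG pseudo side chain placed by χ1, so the
coordinate-level featurizers can be tested by exact round trip.

The default benchmark uses a 2-state chain [[0.99, 0.01], [0.02, 0.98]]
(slowest relaxation 8.2 ns, populations 2/3:1/3), 50 trajectories × 2000
frames — 25 µs of synthetic sampling, roughly 3000 state transitions,
enough to pin the slow timescale to a few percent while keeping the full
test suite under a minute of generator time. Emission concentration
κ = 8 gives clearly separated but overlapping basins. Contact rates
(0.0125, 0.05)/ns give a 20 ns mean contact dwell at 20% occupancy,
matching the order of transient-contact lifetimes the analysis targets.

What the generator does *not* emulate: continuous conformational
heterogeneity within states, correlated emissions across residues,
non-Markovian global dynamics (except the heavy-tailed dwell generator
used adversarially in tests), force-field energetics, and solvent.
Passing recovery tests therefore demonstrates estimator correctness on
exactly-Markov soft-emission data, not that a 2-state model suffices for
any particular real peptide — that judgement is what the validation
battery is for.

## Numerical choices

- VAMP-2 correlation matrices carry a ridge of 1e-8 (1e-10 in scoring);
  rank-deficient cases are regularized and logged.
- Row-stochasticity is enforced to 1e-8 and stationarity of π to 1e-6 at
  model construction; π is refined by power iteration after the
  eigenvector solve.
- All generators and trainers derive their randomness from explicit
  seeds via `numpy.random.SeedSequence` spawning, so every result in the
  test suite and acceptance script is bit-reproducible.
- Degenerate cases: identity operators give infinite timescales
  (flagged); empty states raise naming the state; Kᵢᵢ ≤ 0 raises;
  constant angle series define ρ = 1 (flagged).

## Known limitations

- The Koopman estimator is not variationally constrained during
  training; on data with severe sampling imbalance the post-hoc π can
  differ from a constrained estimate.
- The mean-vector term of the circular autocorrelation uses all frames
  rather than only pair-participating frames; for trajectories much
  longer than the lag the difference is negligible.
- `transition_rates`'s default K/τ definition is a reporting convention,
  not a generator estimate; compare only at equal lags.
- Coordinate-level synthetic ligands are rigid three-atom groups with
  scripted positions — sufficient to exercise distance featurizers, not
  a physical ligand model.
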