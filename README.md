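# softmsm

Soft Markov state model (MSM) / Koopman kinetic analysis for
multi-trajectory molecular ensembles of disordered peptides, with the
transient ligand-contact observables used to characterize *disordered
binding*: a small molecule that never settles into a single bound pose
but modulates the conformational kinetics and entropy of an
intrinsically disordered protein such as Aβ42.

## Who this is for

Researchers analysing large MD trajectory ensembles (hundreds of
trajectories, frames every ~250 ps) of a disordered peptide with or
without a ligand, who want metastable-state kinetics, entropy metrics
and contact lifetimes with honest multi-model error bars — plus a
synthetic-trajectory generator with analytically known kinetics so every
estimator in the chain can be verified by parameter recovery.

## The model

A soft state assignment χ(**x**ₜ) maps each frame's features onto the
probability simplex over *k* metastable states. Here χ is a small
self-normalizing feed-forward network (SELU, softmax output) trained by
maximizing the VAMP-2 score of time-lagged frame pairs (gradients of the
score derived in closed form — no autodiff dependency). From χ the
Koopman (transition) matrix at lag τ is estimated by soft counts,

&nbsp;&nbsp;C(τ)ᵢⱼ = Σₜ χᵢ(**x**ₜ) χⱼ(**x**ₜ₊τ),&nbsp;&nbsp;**K**(τ) = diag(C·1)⁻¹ C,

with equilibrium distribution π the leading left eigenvector of **K**.
Downstream quantities follow the standard MSM relations:

- relaxation timescales tᵢ = −τ / ln|λᵢ(**K**)| (non-unit eigenvalues);
- state lifetimes t̄ᵢ = −τ / ln **K**ᵢᵢ;
- state averages ⟨Aᵢ⟩ = Σₜ χᵢ(**x**ₜ)A(**x**ₜ) / Σₜ χᵢ(**x**ₜ);
- frame weights wₜ ∝ Σᵢ πᵢ χᵢ(**x**ₜ)/Nᵢ (Nᵢ the total soft mass of
  state *i*), giving ensemble averages ⟨A⟩ = Σₜ wₜ A(**x**ₜ);
- Chapman–Kolmogorov validation **K**(τ)ⁿ ≈ **K**(nτ);
- per-contact lifetimes from 2×2 transition matrices of binary
  ligand-contact series, local flexibility from Ramachandran-histogram
  entropies and χ1 circular autocorrelation.

Features include nearest-neighbour heavy-atom inter-residue distances
(780 dimensions for a 42-residue chain at sequence separation ≥ 3),
backbone φ/ψ and side-chain χ1 dihedrals, ligand minimum distances and
ring-centroid π-stacking indicators, all computed through mdtraj.

## Worked example

```python
import numpy as np, softmsm as sm

# a 2-state benchmark with analytically known kinetics
spec = sm.default_benchmark_spec(seed=0)          # 50 traj x 2000 frames, 250 ps
bench = sm.make_benchmark_ensemble(spec)

angles = sm.FeatureSeries(
    [np.concatenate([a, b], axis=1) for a, b in zip(bench.phi.arrays, bench.psi.arrays)],
    list(bench.phi.labels) + list(bench.psi.labels), 250.0, "rad")
feats = sm.circular_embed(angles)

model = sm.train_assignment_model(feats, k=2, lag_frames=20, config="desk", seed=0)
print("slowest timescale:", sm.relaxation_timescales(model.koopman)[0])
print("true timescale:   ", bench.ground_truth.true_timescales_ns[0])
print("populations:      ", sm.state_populations(model.koopman))
```

prints

```
slowest timescale: 8.03580306533788
true timescale:    8.20769877632264
populations:       [0.68629523 0.31370477]
```

i.e. the slowest relaxation time of the hidden two-state exchange
(truth 8.21 ns) is recovered within ~2%, and the stationary populations
within ~3% of the true (2/3, 1/3) split. A full pipeline (20 models over
randomized 9:1 train/validation splits, state alignment by contact-map
RMSD, validation, observables, entropies, contacts) is available as
`softmsm run` or `softmsm.pipeline.run_pipeline`.

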