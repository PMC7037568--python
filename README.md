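# saxshape

Ab initio reconstruction of low-resolution 3D molecular envelopes from 1D
small-angle X-ray scattering (SAXS) profiles, by genetic-algorithm search
in the latent space of a 3D shape auto-encoder.

SAXS measures the orientation-averaged intensity I(q) of particles in
solution — cheap to collect, but a 1D curve hugely under-determines a 3D
shape.  `saxshape` constrains the inverse problem with a learned shape
prior: a convolutional auto-encoder compresses 31³ binary envelopes into
a low-dimensional latent vector *z* (200-d at full configuration), and a
genetic algorithm evolves *z* to minimize the fit quality

    χ² = 1/(N−1) · Σᵢ [ (c·I_model(qᵢ) − I_exp(qᵢ)) / σᵢ ]²,  qᵢ ≤ 0.2 Å⁻¹,

where the scale c is fitted in closed form.  Model profiles are evaluated
through a 3D Zernike expansion, I(q) = (4π)² Σ_lm |Σ_n c_nlm T_nl(q·λ)|²,
whose radial transforms enter only through q·(model radius): shape and
size decouple, so the bounding-sphere radius of the particle can be
co-optimized as one extra gene when it is not known.  An exact Debye-sum
backend serves as the correctness oracle, and reconstructed envelopes are
compared and clustered by volume-overlap correlation after optimal rigid
(and mirror) alignment.

Intended users: structural biologists and methods developers who want a
scriptable, fully synthetic-testable shape-reconstruction pipeline
(DAMMIN/DENSS-class output: dummy-atom PDB or CCP4 maps) built on a
generative shape prior rather than bead packing.

## Worked example

```python
from saxshape import (GAConfig, ShapeSpec, align_cc, build_coder,
                      generate_shape, make_dataset, reconstruct, train)
from saxshape.ga_optimizer import simulate_profile

# 1. train the shape auto-encoder on a synthetic corpus (scaled-down)
dataset = make_dataset(500, seed=42)
coder, prior = train(build_coder(latent_dim=64, seed=42), dataset,
                     epochs=10, batch=8, seed=42)

# 2. simulate a noisy SAXS profile from a dumbbell-shaped particle
truth = generate_shape(ShapeSpec("dumbbell", seed=77))
data = simulate_profile(truth, radius=50.0, noise=0.02, seed=7)

# 3. reconstruct the envelope from the profile alone (radius known)
cfg = GAConfig(population=50, generations=60, seed=3,
               radius_mode="fixed", radius_value=50.0)
result = reconstruct(data, coder, prior, cfg)
print(f"chi = {result.final_chi:.2f}")
print(f"cc vs truth = {align_cc(result.best_grid, truth).cc:.2f}")
```

Output from this exact script:

```
chi = 0.84
cc vs truth = 0.92
```

χ ≈ 1 means the model profile matches the data to within its stated
uncertainties; cc is the volume overlap with the ground-truth shape after
optimal alignment, where 0.70 marks consistent overall shape and 1.0 is
identity.  With `radius_mode="free"` the same call also recovers the
particle radius (51 Å here, true value 50 Å) from the profile alone.

The `examples/` directory has short narrative scripts for each
capability — profile simulation and fitting, training, reconstruction,
and model comparison/clustering.  A thin CLI wraps the same pipeline:

```bash
saxshape simulate --family dumbbell --noise 0.02 --out target.dat
saxshape train --shapes 500 --latent 64 --out model/
saxshape reconstruct --data target.dat --model model/coder.npz \
                     --fit-radius --runs 10 --out recon/
saxshape compare recon/envelope_00.pdb reference.pdb
```

`reconstruct --runs 10` performs ten independent seeded runs and clusters
the resulting envelopes (average linkage, correlation-distance cutoff
0.3) to report reconstruction consistency.

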