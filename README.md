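# mdem

Data-driven rigid-body pair potentials and self-assembly simulation at the
whole-macromolecule scale.

Each molecule is abstracted as a single anisotropic rigid body.  The
interaction between two molecules is a scalar potential over their 6D
relative configuration (position + orientation of B in A's body frame),
learned from a sampling oracle with Universal Kriging, tabulated on 6D
grids, and differentiated numerically into forces and torques.  An
anisotropic Langevin integrator (per-axis friction from parameterised
diffusion coefficients, exact Ornstein-Uhlenbeck propagation per step)
drives assembly simulations with periodic boundaries and Verlet lists.
Postprocessing classifies structured/unstructured contacts, tracks
cluster sizes, transitions, lifetimes and assembly kinetics.

Production molecular-dynamics parameterisation is replaced by synthetic
analytic oracles, so the full method runs at desk scale:

* a 2D benchmark truth field (sequential Gaussian simulation residual,
  distance taper, Gaussian trend over the minimum distance),
* a noisy 6D patchy-site oracle with designed binding wells,
* a 120-pose capsid fixture closed from the published four binding
  transformations.

## Layout

| module            | contents |
|-------------------|----------|
| `mdem.structures` | bead structures, body frames (principal axes), poses, configurations |
| `mdem.descriptors`| minimum distance δm, configuration RMSD δr, collision counts, random placements |
| `mdem.trend_variogram` | density weights, trend fits over δm, sectional residual variograms |
| `mdem.kriging`    | Universal Kriging estimation (SVD-solved constrained system), per-component engines |
| `mdem.sampling`   | oracle contract, initial sampling, variance/extrema-driven refinement loop |
| `mdem.synthetic`  | SGS fields, 2D benchmark, toy patchy oracle, capsid fixture, constants |
| `mdem.field`      | 6D potential grids, empirical binding insertion, collision penalty, forces/torques, binary field format |
| `mdem.dynamics`   | anisotropic Langevin simulator, protocols SP1-SP3, RPY drag utility |
| `mdem.analysis`   | contact classification, cluster statistics, size-class transitions, lifetimes, kinetics fits |
| `mdem.cli`        | `mdem` command line (learn / insert-binding / simulate / analyze / synth / rpy) |

## CLI

```sh
mdem learn --oracle 2d --n-initial 20 --iterations 8 --seed 1 --outdir out/
mdem learn --oracle toy --n-initial 100 --iterations 2 --outdir out/
mdem insert-binding --samples out/samples.csv --outdir out/
mdem simulate --protocol SP3 --field out/field.mdemfld --concentration 50 \
    --box 40 --duration 10 --outdir out/
mdem analyze --trajectory out/trajectory.txt --binding toy --outdir out/
mdem synth capsid --outdir out/     # 120-pose shell + contact metadata
mdem rpy                            # five-sphere drag worked example
```

Every command honours `--seed` and writes a `manifest.json` with output
hashes.

## Units

nm, ns, kJ/mol, amu, rad, K throughout.  Diffusion-coefficient tables in
μm²/s and Mrad²/s are converted on input
(`DiffusionCoefficients.from_table`).
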