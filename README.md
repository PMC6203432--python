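# bordergrid

A spiking-network model of boundary-tethered grid-cell dynamics — border
units, velocity-driven toroidal attractor grid modules, and place units
coupled by competitive Hebbian learning — together with the spatial rate-map
analysis toolbox needed to quantify environmental-deformation effects:
boundary-conditioned rate maps with occupancy-matched subsampling, grid
shift, grid rescaling factors, boundary-tethered rate-map prediction, and
population-vector correlations.

## Layout

| module | contents |
|---|---|
| `bordergrid.arena` | environment geometries (rectangle, right trapezoid, linear track, inserted walls), bounded random-walk and track-lap trajectory generators, most-recent-boundary-contact labelling |
| `bordergrid.border` | 32-unit border layer: the 8-bricks-per-wall partition, feed-forward border input, deformation behaviour of border fields |
| `bordergrid.attractor` | toroidal grid modules: shifted radial inhibition (FFT circular convolution), velocity drive, orientation-biased settling on commensurate torus modes |
| `bordergrid.place` | 64 place units with 500 random grid afferents and uniform recurrent inhibition |
| `bordergrid.engine` | coupled dynamics (stochastic spiking or rate-based), competitive Hebbian learning, familiarization / test-trial protocols with per-pixel grid-state caching |
| `bordergrid.metrics` | rate maps (2.5 cm pixels, masked Gaussian smoothing), auto/cross-correlograms with overlap masks, grid scale, gridness, orientation, field length, inclusion rule |
| `bordergrid.deformation` | boundary rate maps, occupancy-matched grid shift, alignment test, rescaling factors (whole-trial and boundary-conditioned), boundary-tethered map prediction, population-vector correlation |
| `bordergrid.cli` / `config` / `io` / `fixtures` | YAML run configs, HDF5 checkpoints, delimited-text spike/trajectory tables, synthetic fixtures with known ground truth |

## CLI

```sh
bordergrid familiarize --config run.yaml --out familiar.h5 --desk
bordergrid test --checkpoint familiar.h5 --env deformed.yaml --out-prefix def
bordergrid analyze --traj def_traj.csv --spikes def_spikes.csv --env def_env.yaml
bordergrid predict --traj def_traj.csv --familiar-map fam.txt \
    --env-familiar fam.yaml --env-deformed def.yaml
bordergrid fixtures --kind hex_map --out-prefix fx
```

Every command writes a JSON manifest (config digest, seeds, version) next to
its outputs, so runs are bit-reproducible from config + seeds.

An empty/omitted config uses the published constants (five 128² modules,
dt = 3 ms, κ = 500, γ = 0.6, λ = 1e-5, 60-min familiarization, …).  The desk
preset (`--desk`, or `NetworkConfig.desk()`) runs two 96² modules with
rate-based dynamics for CPU-budget work; see `notes` in the docstrings for
which statistics are invariant under that scaling.

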