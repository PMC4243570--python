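# arbordepth

Laminar arbor-density depth profiles of sparsely labeled neurons.

Retinal ganglion cell types stratify their dendrites at characteristic
depths of the inner plexiform layer with submicron precision, so the
one-dimensional *depth profile* of a cell's arbor mass — referenced to the
two starburst amacrine (ChAT) laminae — is a strong cell-type signature.
`arbordepth` implements a fully automated pipeline from two-channel
confocal stacks to such profiles and their statistics:

1. **Volumetric reconstruction.** Either topologically constrained
   inflation of an SWC trace — growing the skeleton into voxels above 60%
   of the stack maximum while flipping only *simple points*, so the result
   is homotopy-equivalent to the trace — or a fully automated path:
   convolutional-network enhancement (weights loadable; a 60%-of-max
   threshold baseline by default) followed by cleanup that keeps the
   largest component, drops small objects, and removes somata
   (morphological opening with a ball the dendrites cannot contain).
2. **Unwarping and registration.** The two starburst laminae are detected
   as height maps, flattened by least-squares conformal maps, registered
   in-plane at their flattest patch, and the mapping is extended to all
   voxels by local polynomials (quadratic in xy, linear in z). Depth is
   normalized per column: On surface → 0 μm, Off surface → 12 μm.
3. **Profiles and statistics.** Warped voxels are gridded onto 0.5 μm
   depth bins with a mass-conserving Kaiser-Bessel kernel and weighted by
   the local volume change. Peak depths (two for bistratified cells, the
   second ≥ 6 μm away), crest factor (peak/RMS), per-type profile SNR,
   chi-square confidence intervals for the peak-depth SD,
   s ∈ CI = [√((n−1)s²/χ²₀.₉₇₅), √((n−1)s²/χ²₀.₀₂₅)], the Brown-Forsythe
   variance-equality test, and an exact small-n right-sided signed-rank
   test.

A seeded phantom generator (`arbordepth.synthdata`) renders the whole
study synthetically — warped laminae, stratified branching arbors with
0.25 μm laminar jitter, somata, distractors, PSF blur and shot noise — so
every stage runs and is tested without external data.

## Worked example

Simulate a W3 phantom (stratifying 5.5 μm above the On surface) and run
the automated path end to end:

```bash
arbordepth run-all --simulate-type W3 --seed 0 --out-dir runs/w3
```

This writes `neuron.tif`, `chat.tif`, the cleaned mask `clean.tif`,
`profile.csv`, `summary.csv` and a `manifest.yaml`, and prints:

```
{"peak1_um": 5.5, "peak2_um": null}
```

i.e. the recovered stratification peak sits at 5.5 μm — the W3 target
depth, within one 0.5 μm bin of this phantom's jittered truth (5.66 μm).
`summary.csv` holds the same peak alongside the crest factor and the
retained voxel count. The same pipeline is available from Python:

```python
from arbordepth.synthdata import PhantomSpec, make_phantom
from arbordepth.pipeline import PipelineConfig, run_pipeline

neuron, chat, truth = make_phantom(PhantomSpec(cell_type="BDa", seed=2))
res = run_pipeline(neuron, chat, PipelineConfig(bistratified=True))
print(res["peaks"])   # two peaks, near 0.3 and 12.3 um
```

Individual stages are exposed as subcommands (`simulate`, `inflate`,
`enhance`, `postprocess`, `flatten`, `profile`, `stats`) reading and
writing TIFF/SWC/CSV, so any step can be rerun in isolation; a flat YAML
config can override every numeric constant of the pipeline.

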