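# jfreduce

A desk-scale, pure-software model of a real-time data-acquisition and
reduction pipeline for kilohertz adaptive-gain pixel-array X-ray detectors,
as used in macromolecular crystallography. It is aimed at detector-software
developers and beamline scientists who want to prototype, test and reason
about every stage of such a pipeline — packet reception and flow control,
raw-to-photon conversion, compression, live feedback analysis and HDF5
writing — without detector hardware: a synthetic detector model stands in
for the instrument, exactly the way production systems are exercised with an
internal packet generator.

## What it models

**Detector model.** An adaptive-gain module of 512 × 1024 pixels digitizes
each pixel into a 16-bit raw word: a 2-bit gain code selecting one of three
amplification stages G0/G1/G2 plus a 14-bit ADC value. A module frame is
exactly 1 MiB and streams as 128 packets of 8 kB (4096 pixels each). The
simulator draws per-pixel ground-truth calibrations (pedestals ~1000–1500
ADC, gains ~41 / ~1.4 / ~0.41 ADC keV⁻¹ for G0/G1/G2), generates dark and
diffraction frames (Poisson background plus Gaussian Bragg spots with a
known ground-truth spot table), and replays frames as seeded packet streams
with optional bounded reordering or drops.

**Calibration and conversion.** Dark runs give per-pixel pedestal means and
RMS (single-pass streaming statistics). Conversion to photon counts is the
standard three-step correction

    photons = (ADC − pedestal_g) / (gain_g · E)

executed entirely in 16-bit fixed point, as a memory-bound hardware pipeline
would: pedestals carry f_p = 2 fractional bits, and the combined coefficient
1/(gain_g · E) is stored as round(2^s_g/(gain_g · E)) with a per-stage binary
scale s_g maximized within 16 bits. Six per-pixel constant planes
(3 pedestals + 3 coefficients) feed the converter. Across 4–20 keV the
fixed-point arithmetic differs from an ideal double-precision conversion by
less than 0.30 photons (measured ~0.11 at seed 1), while rounding the ideal
result to a 16-bit integer already costs 0.25 photons on average — the
arithmetic shortcut is essentially free.

**Dataflow.** A software model of the receiver↔host buffer protocol: the
host posts work requests (WRs) granting 1 MiB slots, the receiver claims one
slot per (module, frame), and finalizes frame N with a work completion (WC)
when any packet of frame N + 2 arrives (tolerating packet reordering) or the
acquisition ends. With no WR available the receiver stalls, buffering up to
4 MiB before dropping packets; every packet is accounted for exactly once.

**Compression.** All codecs bitshuffle the image in blocks of 4096 pixels ×
16 bits (one packet) so that equal-significance bits group into long runs,
then apply LZ4 (`bslz4`), Zstandard (`bszstd`), or a custom run-length
encoder (`bsrle_zstd`) that emits *Zstandard-compliant* frames built only
from RLE blocks (maximal runs of 0x00/0xFF bytes) and raw blocks — no
entropy coding, yet any reference Zstandard decoder reads its output.

**Analysis.** Live-feedback products on an every-Nth subsample of the
stream (defaults: preview at 1 image s⁻¹, analysis at 100 images s⁻¹, i.e.
every 20th frame at 2 kHz): module assembly with optional summation, mean
count, radial integration I(q) within a resolution range, and spot finding —
strong pixels above the local background by 3 local standard deviations
(13 × 13 window, iteratively re-estimated excluding strong pixels),
clustered by 8-connectivity, exported with intensity-weighted centroids and
reciprocal-space vectors s = (u/|u| − ẑ)/λ, |s| = 1/d, for an external
indexer.

**Writer.** Pre-compressed chunks are placed directly into HDF5 datasets
(no recompression) together with frame-number and completeness status
datasets and a minimal NXmx-style master file.

## Worked example

```python
from jfreduce import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_frames=100, codec="bsrle_zstd", seed=1,
                     data_file="scratch/example.h5",
                     master_file="scratch/example_master.h5")
report = run_pipeline(cfg)
```

prints (via `report`):

```
frames_in: 100
frames_complete: 100
frames_incomplete: 0
compression_factor: 5.185528059660158
n_analyzed: 5
spots_per_analyzed_frame: 51.0
mean_count_last: 1.0314006805419922
last_image_ok: True
```

All 100 replayed frames were assembled completely; the custom RLE/Zstandard
codec compressed the synthetic diffraction stream 5.2×; every 20th frame was
analyzed, finding 51 spots per frame (50 injected Bragg spots plus an
occasional noise cluster) on a background of ~1 photon/pixel; and the final
decoded image is bit-identical to the converted preload frame — the
pipeline's end-to-end sanity check.

The same pipeline is scriptable from the shell:

```sh
jfreduce generate diffraction --seed 1 -o frame.bin
jfreduce generate dark --frames 50 --seed 1 -o darks.bin
jfreduce calibrate --darks darks.bin --energy 12.4 --seed 1 -o constants.h5
jfreduce convert --raw frame.bin --constants constants.h5 -o photons.h5
jfreduce run --config run.yaml --report report.json
```

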