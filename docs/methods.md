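# Methods

This note documents the models, numerical choices and limitations behind
`jfreduce`. The package is a software analogue of a hardware-accelerated
detector readout chain; everything below is computed on synthetic data from
the built-in detector model.

## Detector and calibration model

A module is 512 × 1024 pixels; each raw word is 16 bits: the two most
significant bits carry the gain code (00 → stage 0, 01 → stage 1,
11 → stage 2; 10 is invalid and never generated), the lower 14 bits the ADC
value. This layout is a convention of the simulator, centralized in one
encode/decode pair (`detector_model.encode_raw_words` /
`decode_raw_words`); real devices may differ, and nothing downstream
depends on the choice.

Ground-truth calibration defaults (per pixel, Gaussian spreads):

| quantity | G0 | G1 | G2 | unit |
|---|---|---|---|---|
| pedestal mean | 1000 ± 50 | 1200 ± 60 | 1500 ± 75 | ADC |
| gain | 41.0 | 41/29 ≈ 1.41 | 41/99.6 ≈ 0.41 | ADC keV⁻¹ |
| gain spread | 2% (clipped ±3σ) | — | — | relative |
| read noise σ | 10 | 3 | 2 | ADC |

Gain magnitudes and stage ratios follow published characterizations of
adaptive-gain MX detectors. Two deliberate simplifications: all gains are
positive (real stage-1/2 slopes are inverted; the sign is irrelevant to
every algorithm here and keeping it positive simplifies the simulator
contract that gain magnitudes strictly decrease with stage), and gain-stage
switching is a deterministic threshold on deposited energy per pixel
(defaults 300 keV and 9000 keV, comfortably below 14-bit ADC saturation for
the default gains). Readout noise is added before clamping to [0, 16383].

The diffraction-frame generator superposes a flat Poisson background
(default mean 1 photon/pixel) and Gaussian spots (integrated intensity
100–1000 photons, σ = 1.0–1.6 px, ≥12 px apart, evaluated on ±5σ windows)
and Poisson-samples the sum, so total photons are conserved in expectation
and the injected table is exact ground truth for scoring the spot finder.
What the generator does *not* emulate: rotation series (spot shape coupling
to mosaicity and beam divergence), diffuse scatter and ice rings, gain-stage
mixing inside one spot, charge sharing, and module-edge effects. Passing
tests therefore demonstrate algorithmic correctness and the stated
numerical bounds, not photometric performance on real crystals.

## Fixed-point conversion

Per pixel with stage g: photons = (ADC − P_g) / (G_g · E). The fixed-point
pipeline stores P_g with f_p = 2 fractional bits in a 16-bit word
(quantization ≤ 1/8 ADC) and C_g = round(2^{s_g} / (G_g · E)) in 16 bits,
with s_g the largest shift keeping the plane's maximum ≤ 65535 (recorded in
the constants file; typical s ≈ 16–25 over 4–20 keV). The conversion is

    result = round_half_away( ((ADC << f_p) − P_fixed) · C_fixed  >>  (s_g + f_p) )

computed in 64-bit integers (numerator < 2^33, no intermediate overflow),
saturated to ±32767. −32768 is reserved as the bad-pixel sentinel (invalid
gain code, masked pixel, dead calibration) and is never produced by
arithmetic.

Two error figures are kept strictly apart:

* **arithmetic error** — the fixed-point pipeline evaluated *without* the
  final integer rounding versus the ideal double-precision result. It
  bounds the cost of quantized constants and scaled integer multiplies:
  ≤ 1/8 ADC of pedestal quantization plus a ≤ 2⁻¹⁶ relative coefficient
  error times the photon count. Measured maximum over 10⁶ random tuples in
  4–20 keV: ≈ 0.11–0.17 photons depending on seed, below the 0.30-photon
  design bound. This is the bound that would be violated by a bad choice of
  f_p or s_g.
* **output quantization** — rounding any real-valued photon count to a
  16-bit integer costs E|round(x) − x| = 0.25 photons for uniform
  fractional parts, independent of the arithmetic. The error report
  computes it from the same ensemble as a baseline.

Conflating the two would make the arithmetic bound meaningless (the final
rounding alone reaches 0.5 photons on worst-case fractional parts).
Round-half-away-from-zero was chosen for its symmetric error; saturated ADC
values convert normally (a strict mode could flag them, but the default
mirrors a pipeline that treats 16383 like any other reading).

Constants whose quantization fails (coefficient rounding to 0 or
overflowing 16 bits) mask the pixel rather than clamp; more than 1% masked
pixels aborts calibration as unusable.

## Dataflow model

Buffer slots hold exactly one module frame (1 MiB). The N+2 rule is applied
per module: delivery of any packet of frame F finalizes every open frame
≤ F − 2 of that module, so frame-number skips (e.g. a detector restart)
implicitly finalize older frames. Late packets for finalized frames are
counted and dropped. The internal stall buffer holds 4 MiB (512 packets) by
default, configurable; occupancy only grows while the WR queue is empty,
and the first packet that would exceed capacity is dropped, not the oldest.
After end-of-acquisition the receiver is idle: new packets are discarded
and stalled leftovers stay classified as buffered. The conservation
identity packets_in = delivered + dropped + late + discarded + buffered is
asserted continuously in tests.

Bounded reordering is implemented by shuffling disjoint blocks of k + 1
packets, which bounds every packet's displacement by k. The N+2 rule
provably absorbs displacement up to 64 packets (half a frame): a trailing
frame-N packet can land at position 128(N+1) − 1 + k while the earliest
frame-N+2 packet appears at 128(N+2) − k, which cannot cross for
2k < 129. Displacements approaching two full frames *can* produce genuine
late packets, so the no-false-incomplete property is stated and tested at
k = 64.

## Compression

Bitshuffle here is a bit-plane transpose of each 4096-element block: output
plane j holds bit j (LSB first) of every element, packed little-endian.
Blocks are one detector packet (8192 bytes); a trailing partial block is
copied verbatim. The on-disk chunk framing follows the established
HDF5-filter convention (8-byte big-endian total size, 4-byte big-endian
block size, then size-prefixed compressed blocks) for the LZ4 and Zstandard
paths; byte-level LZ4/Zstd coding is delegated to numcodecs.

The custom `bsrle_zstd` encoder writes one standard Zstandard frame per
image chunk: magic, single-segment frame header with 8-byte content size,
no checksum, no dictionary; maximal runs of 0x00 or 0xFF of at least 64
bytes become RLE blocks, everything else raw blocks, both capped at the
format's 128 KiB block limit. The 64-byte minimum reflects the 3-byte block
header overhead (shorter runs are cheaper inside a neighbouring raw block);
both 0x00 and 0xFF runs are encoded since bitshuffled data produces both
(sign/overflow planes). Worst case (incompressible input) grows by the
16-byte frame header plus one 3-byte header per 128 KiB. Conformance is
tested two ways on every payload: the package's own minimal RLE/raw-subset
decoder and the independent `zstandard` (libzstd) implementation must both
reproduce the input bit-exactly.

A structural consequence used as a test invariant: if all pixel values fit
in b bits, at least (16 − b)/16 of each block's output is zero runs.

## Analysis

Geometry conventions: 0-based pixel indices, pixel centres at half-integers,
spot/beam coordinates as (x, y) = (column, row). Radial profiles bin the
scattering-vector magnitude q = 1/d = 2 sin(θ)/λ with 2θ = atan(r/D),
linearly between the requested resolution limits; bins without pixels are
NaN, never zero. Sentinel pixels (gaps, bad pixels) are excluded from every
mean, SD, profile and centroid.

Strong-pixel selection marks pixels above the local mean by snr_min = 3
local population SDs. The local statistics use exact integer summed-area
tables (bit-for-bit reproducible) over a (2w+1)² window with w = 6
(13 × 13), refined iteratively: pixels marked strong are excluded from the
next pass's background statistics, up to 4 passes or convergence. The
refinement exists because a compact Bragg spot occupies a sizeable fraction
of any practical window and would otherwise suppress itself — with a
single-pass 7 × 7 window, recovery of injected spots drops to zero
regardless of intensity, which is why the window default is 13 × 13 rather
than the smaller values sometimes quoted for strong-pixel methods. Strong
pixels cluster by 8-connectivity (4-connectivity by flag); components of at
least min_pix = 3 pixels become spots with intensity-weighted centroids
(weights clipped at zero). At these defaults ≥ 98% of injected spots
(≥ 100 photons on background 1) are recovered with centroid errors well
under 0.5 px; the parameters are configurable and should be retuned for
detectors or sources with very different spot profiles.

Feedback scheduling is deterministic every-Nth selection with
N = round(frame rate / requested rate): at 2 kHz the defaults give stride
2000 for preview (1 s⁻¹) and stride 20 for analysis (100 s⁻¹).

## Pipeline and writer

The end-to-end driver mirrors a production service in process: seeded
sub-generators (via `numpy.random.SeedSequence`) for truth, darks, spots,
stream and drops; darks → pedestals → constants; one preloaded diffraction
frame replayed n_frames times over n_modules; receiver → conversion →
assembly → feedback → compression → direct-chunk HDF5 writing. Distribution
sockets (push-to-writer, publish-for-preview) are reduced to in-process
interfaces; multi-writer round-robin is out of scope. The run ends with a
sanity check that the last assembled image equals the converted preload
bit-for-bit (exact integer equality — any tolerance would mask conversion
or transport bugs), and the report carries the compression factor
(Σ uncompressed / Σ compressed) so codecs can be compared side by side on
the identical stream.

The writer stores chunk payloads exactly as compressed (direct chunk I/O)
with the conventional bitshuffle filter id recorded for the LZ4/Zstd paths
and an id from the HDF5 range reserved for internal use for the custom
codec; reading back uses direct chunk reads plus this package's decoders,
so the files are self-contained within the toolchain. The master file
writes a minimal NXmx-style subset (energy, wavelength, distance, beam
centre, pixel size, module layout) — full NXmx compliance is not claimed.

## Problem sizes

Default study sizes were chosen so every check runs comfortably on a
laptop-class machine: 10⁶ tuples for conversion-error sampling, full
512 × 1024 module frames for packetization/compression/spot finding,
runs of 10–150 frames for pipeline statistics (e.g. the binomial
incomplete-frame check at 1% packet drop), and 1000+ buffers for Zstandard
conformance. All randomness flows from explicit seeds; identical seeds give
bit-identical reports (timing aside).

## Known limitations

* Positive-gain simplification and no gain-stage mixing within a spot.
* No count-rate, charge-sharing or module-edge corrections (out of scope).
* Pedestals are static per run; pedestal tracking during acquisition is not
  modelled.
* The custom compressor never emits entropy-coded blocks, trading ratio for
  determinism and speed — matching its design intent.
* HDF5 files with the custom codec need this package to read; `bslz4`
  interoperability with plugin-registered readers follows the standard
  framing but is not exercised in the test environment.
* Reciprocal-space vectors assume zero goniometer rotation; indexing is
  external.
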