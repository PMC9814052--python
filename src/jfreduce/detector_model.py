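"""Synthetic adaptive-gain detector model.

Generates ground-truth calibration constants, dark and diffraction frames,
encodes them as 16-bit raw words and packetizes module frames the way the
real readout streams them (128 packets of 8 kB per 512 x 1024 module frame).
An internal packet generator replays a preloaded 1 MiB module frame with
incrementing frame numbers, optionally with bounded packet reordering or
seeded packet drops, emulating the in-hardware test-pattern source.

Raw word layout (a configurable convention of this simulator, centralized in
:func:`encode_raw_words` / :func:`decode_raw_words`): the two most significant
bits carry the gain code (``00`` stage 0, ``01`` stage 1, ``11`` stage 2;
``10`` is invalid and never produced), the lower 14 bits the ADC value.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .geometry import DetectorGeometry

ADC_BITS = 14
ADC_MAX = (1 << ADC_BITS) - 1          # 16383
GAIN_SHIFT = ADC_BITS
#: gain stage -> 2-bit gain code
STAGE_TO_CODE = np.array([0, 1, 3], dtype=np.uint16)
#: 2-bit gain code -> gain stage (-1 = invalid code 2)
CODE_TO_STAGE = np.array([0, 1, -1, 2], dtype=np.int8)

PACKET_PIXELS = 4096
PACKET_BYTES = PACKET_PIXELS * 2       # 8192
PACKETS_PER_MODULE = 128

_CAPTURE_HEADER = struct.Struct("<QQQQ")  # module, frame, packet_index, timestamp


class ConfigurationError(ValueError):
    """Invalid simulator configuration (geometry, preload size, ...)."""


# ---------------------------------------------------------------------------
# calibration ground truth
# ---------------------------------------------------------------------------

#: default per-stage calibration distribution, loosely following published
#: adaptive-gain module characterizations: the stage-0 gain is ~41 ADC/keV,
#: stage 1 is ~29x smaller and stage 2 ~100x smaller; pedestals sit in the
#: low ADC range with a few-percent pixel-to-pixel spread.
DEFAULT_PEDESTAL_MEAN = (1000.0, 1200.0, 1500.0)
DEFAULT_PEDESTAL_SPREAD = (50.0, 60.0, 75.0)
DEFAULT_GAIN_MEAN = (41.0, 41.0 / 29.0, 41.0 / 99.6)
DEFAULT_GAIN_SPREAD_FRAC = 0.02
DEFAULT_NOISE_SIGMA = (10.0, 3.0, 2.0)


@dataclass
class CalibrationTruth:
    """Per-pixel ground-truth constants of the simulated detector.

    Arrays have shape ``(3, n_modules, module_rows, module_cols)`` indexed by
    gain stage first.
    """

    pedestal_true: np.ndarray
    gain_true: np.ndarray
    noise_sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.pedestal_true.shape != self.gain_true.shape:
            raise ConfigurationError("pedestal/gain shape mismatch")
        if np.any(self.gain_true <= 0):
            raise ConfigurationError("gain factors must be positive")
        if np.any(np.diff(np.abs(self.gain_true), axis=0) >= 0):
            raise ConfigurationError("gain magnitudes must decrease with stage")
        if np.any((self.pedestal_true < 0) | (self.pedestal_true > ADC_MAX)):
            raise ConfigurationError("pedestal outside ADC range")

    @property
    def n_modules(self) -> int:
        return self.pedestal_true.shape[1]

    def module(self, module_id: int) -> "CalibrationTruth":
        """View of the truth restricted to one module (n_modules = 1)."""
        sl = slice(module_id, module_id + 1)
        return CalibrationTruth(self.pedestal_true[:, sl],
                                self.gain_true[:, sl],
                                self.noise_sigma[:, sl])


def make_calibration_truth(
    geometry: DetectorGeometry,
    seed: int,
    *,
    pedestal_mean: tuple[float, float, float] = DEFAULT_PEDESTAL_MEAN,
    pedestal_spread: tuple[float, float, float] = DEFAULT_PEDESTAL_SPREAD,
    gain_mean: tuple[float, float, float] = DEFAULT_GAIN_MEAN,
    gain_spread_frac: float = DEFAULT_GAIN_SPREAD_FRAC,
    noise_sigma: tuple[float, float, float] = DEFAULT_NOISE_SIGMA,
) -> CalibrationTruth:
    """Draw deterministic per-pixel pedestals, gains and noise scales."""
    rng = np.random.default_rng(seed)
    shape = (geometry.n_modules, geometry.module_rows, geometry.module_cols)
    ped = np.empty((3,) + shape)
    gain = np.empty((3,) + shape)
    sig = np.empty((3,) + shape)
    for g in range(3):
        ped[g] = np.clip(rng.normal(pedestal_mean[g], pedestal_spread[g], shape),
                         0.0, ADC_MAX)
        # clip the multiplicative spread at +-3 sigma so stage ordering is
        # guaranteed for any seed
        spread = np.clip(rng.normal(0.0, gain_spread_frac, shape), -0.06, 0.06)
        gain[g] = gain_mean[g] * (1.0 + spread)
        sig[g] = np.full(shape, noise_sigma[g])
    return CalibrationTruth(ped, gain, sig)


# ---------------------------------------------------------------------------
# raw words and frames
# ---------------------------------------------------------------------------

@dataclass
class RawFrame:
    """One module's raw readout: 16-bit words (gain code + ADC)."""

    module_id: int
    frame_number: int
    timestamp: int
    pixels: np.ndarray  # uint16, (module_rows, module_cols)

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint16:
            raise ConfigurationError("raw pixels must be uint16")

    @property
    def nbytes(self) -> int:
        return self.pixels.size * 2

    def to_bytes(self) -> bytes:
        return self.pixels.astype("<u2", copy=False).tobytes()

    @classmethod
    def from_bytes(cls, data: bytes, shape: tuple[int, int],
                   module_id: int = 0, frame_number: int = 1,
                   timestamp: int = 0) -> "RawFrame":
        pixels = np.frombuffer(data, dtype="<u2").reshape(shape).astype(np.uint16)
        return cls(module_id, frame_number, timestamp, pixels)


def encode_raw_words(stage: np.ndarray, adc: np.ndarray) -> np.ndarray:
    """Pack gain stage (0/1/2) and 14-bit ADC into 16-bit raw words."""
    stage = np.asarray(stage)
    adc = np.asarray(adc)
    if np.any((stage < 0) | (stage > 2)):
        raise ValueError("gain stage must be 0, 1 or 2")
    code = STAGE_TO_CODE[stage]
    words = (code.astype(np.uint16) << GAIN_SHIFT) | (
        adc.astype(np.uint16) & ADC_MAX)
    return words


def decode_raw_words(words: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split raw words into (gain stage, ADC); invalid code 2 maps to stage -1."""
    words = np.asarray(words, dtype=np.uint16)
    stage = CODE_TO_STAGE[words >> GAIN_SHIFT]
    adc = (words & ADC_MAX).astype(np.int32)
    return stage, adc


@dataclass(frozen=True)
class StagePolicy:
    """Deterministic gain-stage selection from deposited energy per pixel.

    ``thresholds_kev = (t01, t12)``: stage 0 below ``t01`` keV, stage 1 in
    ``[t01, t12)``, stage 2 above. Defaults switch comfortably before the
    14-bit ADC would saturate with the default gains.
    """

    thresholds_kev: tuple[float, float] = (300.0, 9000.0)

    def stages(self, energy_kev: np.ndarray) -> np.ndarray:
        t01, t12 = self.thresholds_kev
        if not 0 < t01 < t12:
            raise ConfigurationError("stage thresholds must be increasing")
        e = np.asarray(energy_kev, dtype=np.float64)
        return (e >= t01).astype(np.int8) + (e >= t12).astype(np.int8)


def encode_photons(
    photons: np.ndarray,
    energy_kev: float,
    truth: CalibrationTruth,
    module_id: int = 0,
    policy: StagePolicy = StagePolicy(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inverse of the photon-count conversion: raw words from photon counts.

    ADC = clamp_14(round(pedestal[g] + photons * E * gain[g] + noise)), with
    the gain stage ``g`` chosen by ``policy`` from the deposited energy.
    With ``rng=None`` no readout noise is added.
    """
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    photons = np.asarray(photons, dtype=np.float64)
    deposited = photons * energy_kev
    stage = policy.stages(deposited)
    ped = np.take_along_axis(
        truth.pedestal_true[:, module_id], stage[None], axis=0)[0]
    gain = np.take_along_axis(
        truth.gain_true[:, module_id], stage[None], axis=0)[0]
    adc = ped + deposited * gain
    if rng is not None:
        sig = np.take_along_axis(
            truth.noise_sigma[:, module_id], stage[None], axis=0)[0]
        adc = adc + rng.normal(0.0, 1.0, adc.shape) * sig
    adc = np.clip(np.rint(adc), 0, ADC_MAX).astype(np.uint16)
    return encode_raw_words(stage, adc)


def encode_raw_pixel(photons: float, energy_kev: float, pedestal: float,
                     gain: float, stage: int, noise: float = 0.0) -> int:
    """Scalar raw-word encoder for a single pixel with explicit constants."""
    adc = int(np.clip(np.rint(pedestal + photons * energy_kev * gain + noise),
                      0, ADC_MAX))
    return int(encode_raw_words(np.array(stage), np.array(adc)))


# ---------------------------------------------------------------------------
# frame simulation
# ---------------------------------------------------------------------------

def simulate_dark_frames(
    truth: CalibrationTruth,
    gain_stage: int,
    n_frames: int,
    seed: int,
    module_id: int = 0,
    first_frame_number: int = 1,
) -> list[RawFrame]:
    """Pedestal + Gaussian readout noise only, all pixels at a forced stage."""
    if gain_stage not in (0, 1, 2):
        raise ValueError("gain stage must be 0, 1 or 2")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    ped = truth.pedestal_true[gain_stage, module_id]
    sig = truth.noise_sigma[gain_stage, module_id]
    stage = np.full(ped.shape, gain_stage, dtype=np.int8)
    frames = []
    for i in range(n_frames):
        adc = np.clip(np.rint(ped + rng.normal(0.0, 1.0, ped.shape) * sig),
                      0, ADC_MAX).astype(np.uint16)
        frames.append(RawFrame(module_id, first_frame_number + i, i,
                               encode_raw_words(stage, adc)))
    return frames


@dataclass(frozen=True)
class SpotSpec:
    """One injected Bragg spot: centre (x, y) px, integrated photons, width."""

    x: float
    y: float
    intensity: float
    sigma_px: float = 1.2


def random_spot_table(
    geometry: DetectorGeometry,
    n_spots: int,
    seed: int,
    *,
    intensity_range: tuple[float, float] = (100.0, 1000.0),
    sigma_range: tuple[float, float] = (1.0, 1.6),
    min_separation_px: float = 12.0,
    margin_px: float = 10.0,
) -> list[SpotSpec]:
    """Scatter well-separated spots over one module (rejection sampling)."""
    rng = np.random.default_rng(seed)
    rows, cols = geometry.module_rows, geometry.module_cols
    centers: list[tuple[float, float]] = []
    spots: list[SpotSpec] = []
    attempts = 0
    while len(spots) < n_spots:
        attempts += 1
        if attempts > 200 * n_spots:
            raise ConfigurationError("cannot place spots with this separation")
        x = rng.uniform(margin_px, cols - margin_px)
        y = rng.uniform(margin_px, rows - margin_px)
        if any((x - cx) ** 2 + (y - cy) ** 2 < min_separation_px ** 2
               for cx, cy in centers):
            continue
        centers.append((x, y))
        spots.append(SpotSpec(
            x=x, y=y,
            intensity=float(rng.uniform(*intensity_range)),
            sigma_px=float(rng.uniform(*sigma_range))))
    return spots


def simulate_diffraction_frame(
    truth: CalibrationTruth,
    geometry: DetectorGeometry,
    spots: list[SpotSpec],
    background_mean: float,
    seed: int,
    *,
    energy_kev: float = 12.4,
    module_id: int = 0,
    frame_number: int = 1,
    policy: StagePolicy = StagePolicy(),
    readout_noise: bool = True,
) -> tuple[RawFrame, list[SpotSpec]]:
    """Poisson background plus Gaussian spots, encoded as a raw frame.

    Returns the frame together with the exact injected-spot table so that
    downstream spot-finding can be scored against ground truth.
    """
    rows, cols = geometry.module_rows, geometry.module_cols
    bad = [s for s in spots
           if not (0 <= s.x < cols and 0 <= s.y < rows)]
    if bad:
        raise ValueError(f"spot centres outside module: {bad}")
    if background_mean < 0:
        raise ValueError("background mean must be non-negative")
    rng = np.random.default_rng(seed)
    lam = np.full((rows, cols), float(background_mean))
    rr = np.arange(rows) + 0.5
    cc = np.arange(cols) + 0.5
    for s in spots:
        # evaluate the Gaussian only on a local window; +-5 sigma support
        half = int(np.ceil(5 * s.sigma_px))
        r0 = max(0, int(s.y) - half)
        r1 = min(rows, int(s.y) + half + 1)
        c0 = max(0, int(s.x) - half)
        c1 = min(cols, int(s.x) + half + 1)
        dy = (rr[r0:r1] - s.y) / s.sigma_px
        dx = (cc[c0:c1] - s.x) / s.sigma_px
        g = np.exp(-0.5 * dy[:, None] ** 2) * np.exp(-0.5 * dx[None, :] ** 2)
        g *= s.intensity / (2.0 * np.pi * s.sigma_px ** 2)
        lam[r0:r1, c0:c1] += g
    photons = rng.poisson(lam).astype(np.float64)
    words = encode_photons(photons, energy_kev, truth, module_id, policy,
                           rng if readout_noise else None)
    return RawFrame(module_id, frame_number, 0, words), list(spots)


# ---------------------------------------------------------------------------
# packetization and the internal packet generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorPacket:
    """One 8 kB streaming unit: 4096 pixels of a module frame."""

    module_id: int
    frame_number: int
    packet_index: int
    timestamp: int
    payload: bytes

    def __post_init__(self) -> None:
        if len(self.payload) != PACKET_BYTES:
            raise ConfigurationError(
                f"payload must be {PACKET_BYTES} bytes, got {len(self.payload)}")


def packetize_module_frame(frame: RawFrame) -> list[DetectorPacket]:
    """Split a full module frame into 128 packets of 8192 bytes, pixel order."""
    data = frame.to_bytes()
    if len(data) % PACKET_BYTES:
        raise ConfigurationError("frame size is not a whole number of packets")
    n = len(data) // PACKET_BYTES
    return [
        DetectorPacket(frame.module_id, frame.frame_number, i, frame.timestamp,
                       data[i * PACKET_BYTES:(i + 1) * PACKET_BYTES])
        for i in range(n)
    ]


def reassemble_frame(packets: list[DetectorPacket],
                     shape: tuple[int, int]) -> RawFrame:
    """Inverse of :func:`packetize_module_frame` (packets of one frame)."""
    ordered = sorted(packets, key=lambda p: p.packet_index)
    data = b"".join(p.payload for p in ordered)
    first = ordered[0]
    return RawFrame.from_bytes(data, shape, first.module_id,
                               first.frame_number, first.timestamp)


@dataclass(frozen=True)
class InOrder:
    """Emit packets exactly in generation order."""


@dataclass(frozen=True)
class BoundedReorder:
    """Randomly permute the stream so no packet moves more than ``k`` slots."""

    k: int = 64


@dataclass(frozen=True)
class RandomDrop:
    """Drop each packet independently with probability ``p``."""

    p: float = 0.0


OrderPolicy = InOrder | BoundedReorder | RandomDrop


@dataclass
class GeneratorLog:
    """Accounting of what the internal packet generator emitted."""

    packets_emitted: int = 0
    packets_dropped: int = 0
    dropped: list[tuple[int, int, int]] = field(default_factory=list)


def internal_packet_generator(
    preloaded_frame: RawFrame | bytes,
    n_frames: int,
    n_modules: int = 1,
    order_policy: OrderPolicy = InOrder(),
    seed: int = 0,
    log: GeneratorLog | None = None,
):
    """Replay one preloaded module frame as a packet stream.

    The preload must be exactly one full module frame (1 MiB); the same pixel
    payload is replayed for every module with frame numbers 1..n_frames and a
    monotone tick timestamp, the way the hardware test-pattern source does.
    Yields :class:`DetectorPacket`.
    """
    if isinstance(preloaded_frame, RawFrame):
        data = preloaded_frame.to_bytes()
    else:
        data = bytes(preloaded_frame)
    if len(data) != PACKETS_PER_MODULE * PACKET_BYTES:
        raise ConfigurationError(
            "preloaded frame must be exactly one module frame "
            f"({PACKETS_PER_MODULE * PACKET_BYTES} bytes), got {len(data)}")
    payloads = [data[i * PACKET_BYTES:(i + 1) * PACKET_BYTES]
                for i in range(PACKETS_PER_MODULE)]
    rng = np.random.default_rng(seed)

    def ordered_stream():
        tick = 0
        for f in range(1, n_frames + 1):
            for m in range(n_modules):
                for i in range(PACKETS_PER_MODULE):
                    yield DetectorPacket(m, f, i, tick, payloads[i])
            tick += 1

    if isinstance(order_policy, InOrder):
        yield from ordered_stream()
    elif isinstance(order_policy, RandomDrop):
        for pkt in ordered_stream():
            if order_policy.p > 0 and rng.random() < order_policy.p:
                if log is not None:
                    log.packets_dropped += 1
                    log.dropped.append(
                        (pkt.module_id, pkt.frame_number, pkt.packet_index))
                continue
            if log is not None:
                log.packets_emitted += 1
            yield pkt
    elif isinstance(order_policy, BoundedReorder):
        if order_policy.k < 0:
            raise ConfigurationError("reorder bound must be non-negative")
        # shuffling disjoint blocks of k+1 packets bounds the displacement of
        # every packet by k positions
        block: list[DetectorPacket] = []
        for pkt in ordered_stream():
            block.append(pkt)
            if len(block) == order_policy.k + 1:
                order = rng.permutation(len(block))
                for j in order:
                    yield block[j]
                block = []
        order = rng.permutation(len(block))
        for j in order:
            yield block[j]
    else:  # pragma: no cover - exhaustive match
        raise ConfigurationError(f"unknown order policy {order_policy!r}")
    if log is not None and isinstance(order_policy, (InOrder, BoundedReorder)):
        log.packets_emitted = n_frames * n_modules * PACKETS_PER_MODULE


# ---------------------------------------------------------------------------
# packet capture files
# ---------------------------------------------------------------------------

def save_capture(path, packets) -> int:
    """Write packets to a flat binary capture file; returns the packet count."""
    n = 0
    with open(path, "wb") as fh:
        for p in packets:
            fh.write(_CAPTURE_HEADER.pack(p.module_id, p.frame_number,
                                          p.packet_index, p.timestamp))
            fh.write(p.payload)
            n += 1
    return n


def load_capture(path) -> list[DetectorPacket]:
    """Read a packet capture file written by :func:`save_capture`."""
    packets = []
    with open(path, "rb") as fh:
        while True:
            header = fh.read(_CAPTURE_HEADER.size)
            if not header:
                break
            if len(header) != _CAPTURE_HEADER.size:
                raise ValueError("truncated capture header")
            m, f, i, t = _CAPTURE_HEADER.unpack(header)
            payload = fh.read(PACKET_BYTES)
            if len(payload) != PACKET_BYTES:
                raise ValueError("truncated capture payload")
            packets.append(DetectorPacket(m, f, i, t, payload))
    return packets
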