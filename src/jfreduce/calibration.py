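"""Pedestal calibration and fixed-point conversion constants.

The dark-run calibration computes, per pixel and gain stage, the pedestal
mean and its RMS (population standard deviation of the dark ADC samples)
with a single-pass streaming accumulator, then quantizes pedestals and the
combined gain/energy coefficients into the six 16-bit constant planes the
fixed-point converter consumes:

* ``pedestal_fixed[g]`` — pedestal with ``f_p`` fractional bits (default 2);
* ``coeff_fixed[g]``    — ``round(2**s_g / (gain_g * E))`` with a per-stage
  binary scale ``s_g`` chosen as large as the 16-bit range allows.

Pixels whose constants cannot be represented are masked rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .detector_model import CalibrationTruth, RawFrame, decode_raw_words

COEFF_MAX = np.iinfo(np.uint16).max  # 65535
ENERGY_RANGE_KEV = (4.0, 20.0)
CONSTANTS_FORMAT_VERSION = 1


class CalibrationError(RuntimeError):
    """Raised when a calibration product is unusable."""


# ---------------------------------------------------------------------------
# pedestal accumulation
# ---------------------------------------------------------------------------

@dataclass
class PedestalStage:
    """Per-pixel pedestal statistics for one gain stage."""

    mean: np.ndarray          # float64, ADC
    rms: np.ndarray           # float64, ADC (population SD)
    n_frames_used: np.ndarray  # per-pixel usable sample count
    n_rejected: np.ndarray     # per-pixel samples at an unexpected gain code
    mask: np.ndarray           # True where no usable samples existed


class PedestalAccumulator:
    """Single-pass (Welford) mean/variance accumulator over dark frames.

    Pixels that report a gain code other than the expected stage are excluded
    from the accumulation and counted per pixel.
    """

    def __init__(self, shape: tuple[int, int], gain_stage: int) -> None:
        if gain_stage not in (0, 1, 2):
            raise ValueError("gain stage must be 0, 1 or 2")
        self.gain_stage = gain_stage
        self.n = np.zeros(shape, dtype=np.int64)
        self.mean = np.zeros(shape, dtype=np.float64)
        self.m2 = np.zeros(shape, dtype=np.float64)
        self.n_rejected = np.zeros(shape, dtype=np.int64)

    def add_frame(self, frame: RawFrame | np.ndarray) -> None:
        words = frame.pixels if isinstance(frame, RawFrame) else frame
        stage, adc = decode_raw_words(words)
        ok = stage == self.gain_stage
        self.n_rejected += ~ok
        x = adc.astype(np.float64)
        n_new = self.n + ok
        delta = np.where(ok, x - self.mean, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(n_new > 0, delta / np.maximum(n_new, 1), 0.0)
        self.mean += step
        self.m2 += delta * np.where(ok, x - self.mean, 0.0)
        self.n = n_new

    def result(self) -> PedestalStage:
        empty = self.n == 0
        if np.any(empty):
            import warnings

            warnings.warn(f"{int(empty.sum())} pixels had no usable dark "
                          "samples and were masked", RuntimeWarning)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.where(self.n > 0, self.m2 / np.maximum(self.n, 1), np.nan)
        return PedestalStage(
            mean=np.where(empty, np.nan, self.mean),
            rms=np.sqrt(var),
            n_frames_used=self.n.copy(),
            n_rejected=self.n_rejected.copy(),
            mask=empty,
        )


def compute_pedestal(dark_frames, gain_stage: int) -> PedestalStage:
    """Pedestal mean and RMS for one gain stage from a dark-frame sequence."""
    frames = list(dark_frames)
    if len(frames) < 2:
        raise ValueError("pedestal calibration needs at least two frames")
    first = frames[0]
    shape = (first.pixels if isinstance(first, RawFrame) else first).shape
    acc = PedestalAccumulator(shape, gain_stage)
    for f in frames:
        acc.add_frame(f)
    return acc.result()


@dataclass
class PedestalRecord:
    """All three gain stages' pedestal statistics stacked stage-first."""

    stages: tuple[PedestalStage, PedestalStage, PedestalStage]

    @property
    def mean(self) -> np.ndarray:
        return np.stack([s.mean for s in self.stages])

    @property
    def rms(self) -> np.ndarray:
        return np.stack([s.rms for s in self.stages])

    @property
    def mask(self) -> np.ndarray:
        return np.stack([s.mask for s in self.stages]).any(axis=0)


def pedestal_from_darks(truth, n_frames: int, seed: int,
                        module_id: int = 0) -> PedestalRecord:
    """Convenience: simulate darks at every stage and accumulate pedestals."""
    from .detector_model import simulate_dark_frames

    stages = []
    for g in range(3):
        frames = simulate_dark_frames(truth, g, n_frames, seed + g,
                                      module_id=module_id)
        stages.append(compute_pedestal(frames, g))
    return PedestalRecord(tuple(stages))


# ---------------------------------------------------------------------------
# fixed-point constants
# ---------------------------------------------------------------------------

@dataclass
class ConversionConstants:
    """The six per-pixel 16-bit constant planes plus their scaling metadata."""

    pedestal_fixed: np.ndarray   # uint16, (3, H, W), f_p fractional bits
    coeff_fixed: np.ndarray      # uint16, (3, H, W)
    shifts: tuple[int, int, int]  # per-stage binary scale s_g of the coeff
    f_p: int
    energy_kev: float
    mask: np.ndarray             # bool, (H, W): True = bad pixel
    format_version: int = CONSTANTS_FORMAT_VERSION

    @property
    def planes(self) -> list[np.ndarray]:
        """The per-pixel constant planes consumed by the converter."""
        return [self.pedestal_fixed[g] for g in range(3)] + \
               [self.coeff_fixed[g] for g in range(3)]

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    def pedestal_real(self) -> np.ndarray:
        """Dequantized pedestals in ADC units."""
        return self.pedestal_fixed.astype(np.float64) / (1 << self.f_p)

    def coeff_real(self) -> np.ndarray:
        """Dequantized 1/(gain*E) coefficients, photons per ADC unit."""
        out = self.coeff_fixed.astype(np.float64)
        for g in range(3):
            out[g] /= float(1 << self.shifts[g])
        return out


def build_fixed_point_constants(
    pedestal: PedestalRecord | np.ndarray,
    gains: CalibrationTruth | np.ndarray,
    energy_kev: float,
    *,
    f_p: int = 2,
    max_bad_fraction: float = 0.01,
    module_id: int = 0,
) -> ConversionConstants:
    """Quantize pedestals and gain/energy coefficients into 16-bit planes.

    ``pedestal`` may be a calibration product or a raw (3, H, W) array of
    pedestal means; ``gains`` a detector-model truth or a (3, H, W) array of
    ADC/keV gain factors.
    """
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    lo, hi = ENERGY_RANGE_KEV
    if not lo <= energy_kev <= hi:
        import warnings

        warnings.warn(f"energy {energy_kev} keV outside the supported "
                      f"{lo}-{hi} keV range; precision bounds unverified",
                      RuntimeWarning)
    if isinstance(pedestal, PedestalRecord):
        ped = pedestal.mean
        base_mask = pedestal.mask
    else:
        ped = np.asarray(pedestal, dtype=np.float64)
        base_mask = np.zeros(ped.shape[1:], dtype=bool)
    if isinstance(gains, CalibrationTruth):
        gain = gains.gain_true[:, module_id]
    else:
        gain = np.asarray(gains, dtype=np.float64)
    if ped.shape != gain.shape or ped.shape[0] != 3:
        raise ValueError("pedestal/gain planes must both be (3, H, W)")

    mask = base_mask | np.isnan(ped).any(axis=0) | (gain <= 0).any(axis=0)
    ped_filled = np.where(np.isnan(ped), 0.0, ped)

    ped_fixed = np.rint(ped_filled * (1 << f_p))
    bad_ped = (ped_fixed < 0) | (ped_fixed > np.iinfo(np.uint16).max)
    mask |= bad_ped.any(axis=0)
    ped_fixed = np.clip(ped_fixed, 0, np.iinfo(np.uint16).max).astype(np.uint16)

    coeff_real = np.empty_like(gain)
    with np.errstate(divide="ignore"):
        for g in range(3):
            coeff_real[g] = 1.0 / (gain[g] * energy_kev)
    shifts = []
    coeff_fixed = np.empty(gain.shape, dtype=np.uint16)
    for g in range(3):
        valid = ~mask
        cmax = float(np.nanmax(np.where(valid, coeff_real[g], np.nan)))
        # largest s with round(cmax * 2**s) still representable in 16 bits
        s = int(np.floor(np.log2(COEFF_MAX / cmax)))
        q = np.rint(coeff_real[g] * (1 << s))
        over = q > COEFF_MAX
        if np.any(over & valid):  # rounding pushed the extreme pixel over
            s -= 1
            q = np.rint(coeff_real[g] * (1 << s))
            over = q > COEFF_MAX
        mask |= over | (q < 1)
        coeff_fixed[g] = np.clip(q, 0, COEFF_MAX).astype(np.uint16)
        shifts.append(s)

    bad_frac = float(mask.mean())
    if bad_frac > max_bad_fraction:
        raise CalibrationError(
            f"{bad_frac:.1%} of pixels have unrepresentable constants; "
            "calibration looks unusable")
    return ConversionConstants(
        pedestal_fixed=ped_fixed,
        coeff_fixed=coeff_fixed,
        shifts=(shifts[0], shifts[1], shifts[2]),
        f_p=f_p,
        energy_kev=float(energy_kev),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# constants file I/O
# ---------------------------------------------------------------------------

def save_constants(path, constants: ConversionConstants) -> None:
    """Write the constants file (HDF5, one dataset per plane)."""
    with h5py.File(path, "w") as f:
        for g in range(3):
            f.create_dataset(f"pedestal_g{g}", data=constants.pedestal_fixed[g])
            f.create_dataset(f"coeff_g{g}", data=constants.coeff_fixed[g])
        f.create_dataset("mask", data=constants.mask)
        f.attrs["energy_keV"] = constants.energy_kev
        f.attrs["f_p"] = constants.f_p
        f.attrs["s_g"] = list(constants.shifts)
        f.attrs["format_version"] = constants.format_version


def load_constants(path) -> ConversionConstants:
    with h5py.File(path, "r") as f:
        ped = np.stack([f[f"pedestal_g{g}"][()] for g in range(3)])
        coeff = np.stack([f[f"coeff_g{g}"][()] for g in range(3)])
        shifts = tuple(int(s) for s in f.attrs["s_g"])
        return ConversionConstants(
            pedestal_fixed=ped.astype(np.uint16),
            coeff_fixed=coeff.astype(np.uint16),
            shifts=shifts,  # type: ignore[arg-type]
            f_p=int(f.attrs["f_p"]),
            energy_kev=float(f.attrs["energy_keV"]),
            mask=f["mask"][()].astype(bool),
            format_version=int(f.attrs["format_version"]),
        )
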