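"""Raw-to-photon-count conversion in fixed-point arithmetic.

The production path mirrors what a hardware pipeline does per pixel: decode
the gain code, subtract the quantized pedestal, multiply by the quantized
1/(gain*E) coefficient and rescale with a binary shift, rounding
half-away-from-zero to a signed 16-bit photon count.  A double-precision
reference path and an exact (pre-rounding) fixed-point evaluator allow the
arithmetic error to be separated from the unavoidable output quantization:
the former stays well below 0.30 photons across the 4-20 keV operating
range, while rounding real-valued photon counts to integers contributes an
expected 0.25 photons on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ConversionConstants
from .detector_model import RawFrame, decode_raw_words

#: int16 value reserved for bad/invalid pixels; never produced by arithmetic
SENTINEL = -32768
PHOTON_MIN = -32767
PHOTON_MAX = 32767


class ConversionInputError(ValueError):
    """Frame/constants mismatch."""


@dataclass
class PhotonImage:
    """Converted module frame: signed 16-bit photon counts."""

    module_id: int
    frame_number: int
    pixels: np.ndarray       # int16
    sentinel: int = SENTINEL
    energy_kev: float = 0.0
    constants_version: int = 0

    def valid_mask(self) -> np.ndarray:
        return self.pixels != self.sentinel


def _check_shapes(raw: RawFrame, constants: ConversionConstants) -> None:
    if raw.pixels.shape != constants.pedestal_fixed.shape[1:]:
        raise ConversionInputError(
            f"frame shape {raw.pixels.shape} does not match constants "
            f"{constants.pedestal_fixed.shape[1:]}")
    if constants.pedestal_fixed.shape[0] != 3:
        raise ConversionInputError("constants must carry all three stages")


def _fixed_point_terms(raw, constants):
    """Common integer pipeline: returns (stage, numerator, shift, invalid)."""
    stage, adc = decode_raw_words(raw.pixels)
    invalid = stage < 0
    g = np.where(invalid, 0, stage).astype(np.intp)
    ped = np.take_along_axis(constants.pedestal_fixed.astype(np.int64),
                             g[None], axis=0)[0]
    coeff = np.take_along_axis(constants.coeff_fixed.astype(np.int64),
                               g[None], axis=0)[0]
    shifts = np.asarray(constants.shifts, dtype=np.int64)[g]
    num = ((adc.astype(np.int64) << constants.f_p) - ped) * coeff
    shift = shifts + constants.f_p
    return num, shift, invalid


def convert_frame_fixed_point(raw: RawFrame,
                              constants: ConversionConstants) -> PhotonImage:
    """Integer fixed-point conversion with round-half-away-from-zero.

    Invalid gain codes and masked pixels map to the sentinel; results are
    saturated to +-32767, never wrapped.
    """
    _check_shapes(raw, constants)
    num, shift, invalid = _fixed_point_terms(raw, constants)
    half = np.int64(1) << (shift - 1)
    mag = (np.abs(num) + half) >> shift
    photons = np.sign(num) * mag
    photons = np.clip(photons, PHOTON_MIN, PHOTON_MAX)
    photons = np.where(invalid | constants.mask, SENTINEL, photons)
    return PhotonImage(raw.module_id, raw.frame_number,
                       photons.astype(np.int16),
                       energy_kev=constants.energy_kev,
                       constants_version=constants.format_version)


def convert_frame_fixed_exact(raw: RawFrame,
                              constants: ConversionConstants) -> np.ndarray:
    """Fixed-point pipeline evaluated exactly, without the final rounding.

    Returns float64 ``numerator / 2**shift``; the numerator magnitude stays
    below 2**33 so the division is exact in double precision.  Invalid or
    masked pixels are NaN.  This isolates the error of quantized constants
    and scaled integer arithmetic from the output integer quantization.
    """
    _check_shapes(raw, constants)
    num, shift, invalid = _fixed_point_terms(raw, constants)
    out = num.astype(np.float64) / np.exp2(shift.astype(np.float64))
    out[invalid | constants.mask] = np.nan
    return out


def convert_frame_reference(raw: RawFrame, pedestal_real: np.ndarray,
                            gain_real: np.ndarray,
                            energy_kev: float) -> np.ndarray:
    """Ideal double-precision conversion: (ADC - pedestal) / (gain * E).

    ``pedestal_real`` and ``gain_real`` are (3, H, W) stage-first planes.
    Invalid gain codes are NaN.
    """
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    pedestal_real = np.asarray(pedestal_real, dtype=np.float64)
    gain_real = np.asarray(gain_real, dtype=np.float64)
    if pedestal_real.shape[0] != 3 or gain_real.shape[0] != 3:
        raise ConversionInputError("reference constants must carry 3 stages")
    if raw.pixels.shape != pedestal_real.shape[1:]:
        raise ConversionInputError("frame/constants shape mismatch")
    stage, adc = decode_raw_words(raw.pixels)
    invalid = stage < 0
    g = np.where(invalid, 0, stage).astype(np.intp)
    ped = np.take_along_axis(pedestal_real, g[None], axis=0)[0]
    gain = np.take_along_axis(gain_real, g[None], axis=0)[0]
    out = (adc.astype(np.float64) - ped) / (gain * energy_kev)
    out[invalid] = np.nan
    return out


@dataclass
class ConversionErrorReport:
    """Fixed-point vs double-precision error statistics over an ensemble."""

    max_abs_error: float          # max |fixed_exact - float| (photons)
    mean_abs_error: float         # mean of the same
    max_abs_error_rounded: float  # max |int16 output - float| (photons)
    mean_abs_error_rounded: float
    quantization_baseline: float  # mean |round(x) - x| of the float results
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "max_abs_error", "mean_abs_error", "max_abs_error_rounded",
            "mean_abs_error_rounded", "quantization_baseline", "n")}


def conversion_error_report(raw_frames, constants: ConversionConstants,
                            pedestal_real: np.ndarray, gain_real: np.ndarray,
                            energy_kev: float | None = None
                            ) -> ConversionErrorReport:
    """Compare the fixed-point path with the ideal float path frame by frame.

    The quantization baseline is the mean absolute error of rounding the
    float results themselves to integers - the component of the error that
    no arithmetic can avoid while emitting integer photon counts.
    """
    if energy_kev is None:
        energy_kev = constants.energy_kev
    max_err = 0.0
    sum_err = 0.0
    max_err_r = 0.0
    sum_err_r = 0.0
    sum_q = 0.0
    n = 0
    for raw in raw_frames:
        ref = convert_frame_reference(raw, pedestal_real, gain_real, energy_kev)
        exact = convert_frame_fixed_exact(raw, constants)
        rounded = convert_frame_fixed_point(raw, constants)
        ok = np.isfinite(ref) & np.isfinite(exact) & rounded.valid_mask()
        if not np.any(ok):
            continue
        err = np.abs(exact[ok] - ref[ok])
        err_r = np.abs(rounded.pixels[ok].astype(np.float64) - ref[ok])
        max_err = max(max_err, float(err.max()))
        sum_err += float(err.sum())
        max_err_r = max(max_err_r, float(err_r.max()))
        sum_err_r += float(err_r.sum())
        sum_q += float(np.abs(np.rint(ref[ok]) - ref[ok]).sum())
        n += int(ok.sum())
    if n == 0:
        raise ValueError("no valid pixels to compare")
    return ConversionErrorReport(
        max_abs_error=max_err,
        mean_abs_error=sum_err / n,
        max_abs_error_rounded=max_err_r,
        mean_abs_error_rounded=sum_err_r / n,
        quantization_baseline=sum_q / n,
        n=n,
    )
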