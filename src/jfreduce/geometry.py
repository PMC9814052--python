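"""Detector geometry: module layout, lab-frame pixel positions, resolution.

Conventions (used consistently across the package):

* pixel indices are 0-based; the centre of pixel ``(row, col)`` sits at
  ``(row + 0.5, col + 0.5)`` in pixel units;
* image coordinates are given as ``(x, y) = (col, row)`` pairs where they
  appear in spot tables and beam-centre fields;
* the beam travels along +z; the detector plane is normal to the beam at
  ``detector_distance_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: keV * Angstrom; E [keV] = HC_KEV_A / wavelength [A]
HC_KEV_A = 12.398419843320026

MODULE_ROWS = 512
MODULE_COLS = 1024
MODULE_PIXELS = MODULE_ROWS * MODULE_COLS  # 524288
MODULE_FRAME_BYTES = MODULE_PIXELS * 2     # 1 MiB at 16 bit/pixel


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in Angstrom for an energy in keV."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    return HC_KEV_A / energy_kev


class GeometryError(ValueError):
    """Raised for inconsistent detector geometry configuration."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Multi-module detector layout plus the diffraction geometry.

    ``module_rows``/``module_cols`` default to the full 512 x 1024 module;
    smaller values are permitted for reduced test detectors (the 1 MiB frame
    invariant then no longer applies and is only asserted for full modules).
    """

    n_modules: int = 1
    module_rows: int = MODULE_ROWS
    module_cols: int = MODULE_COLS
    #: (row, col) offset of each module in the assembled image
    module_origins: tuple[tuple[int, int], ...] = ((0, 0),)
    gap_fill: int = -32768
    pixel_size_um: float = 75.0
    detector_distance_mm: float = 100.0
    #: beam centre (x, y) in assembled-image pixels, pixel-centre convention
    beam_center: tuple[float, float] = (512.0, 256.0)
    wavelength_A: float = 1.0

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise GeometryError("need at least one module")
        if self.module_rows < 1 or self.module_cols < 1:
            raise GeometryError("module dimensions must be positive")
        if len(self.module_origins) != self.n_modules:
            raise GeometryError("one origin per module required")
        if self.wavelength_A <= 0 or self.detector_distance_mm <= 0:
            raise GeometryError("wavelength and distance must be positive")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel size must be positive")
        self._check_overlap()

    def _check_overlap(self) -> None:
        boxes = []
        for r0, c0 in self.module_origins:
            box = (r0, c0, r0 + self.module_rows, c0 + self.module_cols)
            for other in boxes:
                if (box[0] < other[2] and other[0] < box[2]
                        and box[1] < other[3] and other[1] < box[3]):
                    raise GeometryError("module footprints overlap")
            boxes.append(box)

    # -- shape helpers ----------------------------------------------------
    @property
    def module_pixels(self) -> int:
        return self.module_rows * self.module_cols

    @property
    def module_frame_bytes(self) -> int:
        return self.module_pixels * 2

    @property
    def assembled_shape(self) -> tuple[int, int]:
        rows = max(r + self.module_rows for r, _ in self.module_origins)
        cols = max(c + self.module_cols for _, c in self.module_origins)
        return rows, cols

    def module_slices(self, module_id: int) -> tuple[slice, slice]:
        r0, c0 = self.module_origins[module_id]
        return (slice(r0, r0 + self.module_rows),
                slice(c0, c0 + self.module_cols))

    def gap_mask(self) -> np.ndarray:
        """Boolean mask of assembled pixels NOT covered by any module."""
        mask = np.ones(self.assembled_shape, dtype=bool)
        for m in range(self.n_modules):
            mask[self.module_slices(m)] = False
        return mask

    # -- diffraction geometry --------------------------------------------
    def pixel_radius_mm(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """In-plane distance from the beam centre, in mm (pixel centres)."""
        bx, by = self.beam_center
        px = self.pixel_size_um * 1e-3
        dx = (np.asarray(cols, dtype=np.float64) + 0.5 - bx) * px
        dy = (np.asarray(rows, dtype=np.float64) + 0.5 - by) * px
        return np.hypot(dx, dy)

    def lab_positions_mm(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Lab-frame pixel-centre positions, shape (..., 3), in mm."""
        bx, by = self.beam_center
        px = self.pixel_size_um * 1e-3
        x = (np.asarray(cols, dtype=np.float64) + 0.5 - bx) * px
        y = (np.asarray(rows, dtype=np.float64) + 0.5 - by) * px
        z = np.full_like(x, self.detector_distance_mm)
        return np.stack([x, y, z], axis=-1)

    def two_theta(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        r = self.pixel_radius_mm(rows, cols)
        return np.arctan2(r, self.detector_distance_mm)

    def d_spacing(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Bragg d-spacing (A) seen by each pixel; inf at the beam centre."""
        tth = self.two_theta(rows, cols)
        s = np.sin(0.5 * tth)
        with np.errstate(divide="ignore"):
            return self.wavelength_A / (2.0 * s)

    def q_map(self) -> np.ndarray:
        """Scattering-vector magnitude q = 1/d (A^-1) for every assembled pixel."""
        rows, cols = np.indices(self.assembled_shape)
        with np.errstate(divide="ignore"):
            return 1.0 / self.d_spacing(rows, cols)

    # -- canned layouts ---------------------------------------------------
    @classmethod
    def single_module(cls, **kwargs) -> "DetectorGeometry":
        kwargs.setdefault("module_origins", ((0, 0),))
        rows = kwargs.get("module_rows", MODULE_ROWS)
        cols = kwargs.get("module_cols", MODULE_COLS)
        kwargs.setdefault("beam_center", (cols / 2.0, rows / 2.0))
        return cls(n_modules=1, **kwargs)

    @classmethod
    def four_megapixel(cls, gap_px: int = 36, **kwargs) -> "DetectorGeometry":
        """Eight modules in a 4 x 2 grid with configurable inter-module gaps."""
        origins = []
        for i in range(4):
            for j in range(2):
                origins.append((i * (MODULE_ROWS + gap_px),
                                j * (MODULE_COLS + gap_px)))
        rows = 4 * MODULE_ROWS + 3 * gap_px
        cols = 2 * MODULE_COLS + gap_px
        kwargs.setdefault("beam_center", (cols / 2.0, rows / 2.0))
        return cls(n_modules=8, module_origins=tuple(origins), **kwargs)
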