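"""Live-feedback image analysis: assembly, statistics and spot finding.

Implements the quick-look computations a beamline runs on a subsample of the
stream: module assembly with optional summation, mean count, azimuthal
(radial) integration within a resolution range, strong-pixel selection with
connected-component clustering into diffraction spots, and conversion of
spot centroids to reciprocal-space vectors for an external indexer.

The spot finder follows the classic two-step scheme: a pixel is "strong"
when its value exceeds the local background mean by ``snr_min`` local
standard deviations (background estimated over a (2w+1)^2 window, sentinel
pixels excluded), and 8-connected components of at least ``min_pix`` strong
pixels become spots with intensity-weighted centroids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .conversion import SENTINEL, PhotonImage
from .geometry import DetectorGeometry

# the background window must comfortably exceed the spot footprint or the
# spot biases its own background estimate; 13x13 covers spots up to ~1.6 px
# sigma (see docs/methods.md)
DEFAULT_WINDOW = 6        # half-width -> 13x13 background window
DEFAULT_SNR_MIN = 3.0
DEFAULT_MIN_PIX = 3
DEFAULT_BG_ITER = 4       # background-refinement passes (1 = single pass)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class AssembledImage:
    """Full-detector image with gap/bad pixels at the sentinel value."""

    pixels: np.ndarray        # int16 (n_summed == 1) or int32
    sentinel: int
    geometry: DetectorGeometry
    n_summed: int = 1
    frame_number: int = 0

    def valid_mask(self) -> np.ndarray:
        return self.pixels != self.sentinel


def assemble_image(module_frames: dict[int, PhotonImage | np.ndarray],
                   geometry: DetectorGeometry,
                   sum_n: int = 1,
                   frames_to_sum: list[dict[int, PhotonImage | np.ndarray]] | None = None,
                   ) -> AssembledImage:
    """Place module frames at their origins; optionally sum several slices.

    ``module_frames`` maps module id to the converted frame for one time
    slice; with ``sum_n > 1`` the additional slices come from
    ``frames_to_sum`` and are accumulated in int32 with saturation.  A
    sentinel in any summand propagates to the output.
    """
    missing = [m for m in range(geometry.n_modules) if m not in module_frames]
    if missing:
        raise ValueError(f"missing module frames: {missing}")
    slices = [module_frames]
    if sum_n > 1:
        if frames_to_sum is None or len(frames_to_sum) != sum_n - 1:
            raise ValueError("sum_n > 1 requires sum_n - 1 extra slices")
        slices += frames_to_sum
    dtype = np.int16 if sum_n == 1 else np.int32
    sentinel = SENTINEL if sum_n == 1 else np.iinfo(np.int32).min
    out = np.full(geometry.assembled_shape, sentinel, dtype=dtype)
    frame_number = 0
    for m in range(geometry.n_modules):
        acc = np.zeros((geometry.module_rows, geometry.module_cols),
                       dtype=np.int64)
        bad = np.zeros(acc.shape, dtype=bool)
        for sl in slices:
            frame = sl[m]
            pix = frame.pixels if isinstance(frame, PhotonImage) else frame
            if pix.shape != acc.shape:
                raise ValueError(f"module {m}: frame shape mismatch")
            bad |= pix == SENTINEL
            acc += pix.astype(np.int64)
            if isinstance(frame, PhotonImage):
                frame_number = frame.frame_number
        lo = np.iinfo(dtype).min + 1
        hi = np.iinfo(dtype).max
        placed = np.clip(acc, lo, hi).astype(dtype)
        placed[bad] = sentinel
        out[geometry.module_slices(m)] = placed
    return AssembledImage(out, int(sentinel), geometry, sum_n, frame_number)


def mean_count(image: AssembledImage | np.ndarray,
               sentinel: int = SENTINEL) -> float:
    """Mean photon count over non-sentinel pixels."""
    if isinstance(image, AssembledImage):
        pix, sentinel = image.pixels, image.sentinel
    else:
        pix = image
    valid = pix != sentinel
    if not np.any(valid):
        return float("nan")
    return float(pix[valid].mean(dtype=np.float64))


# ---------------------------------------------------------------------------
# radial integration
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs scattering vector q = 1/d."""

    q_edges: np.ndarray       # A^-1, n_bins + 1
    intensity: np.ndarray     # mean per bin; NaN where no pixels
    counts: np.ndarray        # pixels per bin
    d_range: tuple[float, float]
    frame_number: int = 0

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    def mean_count(self) -> float:
        """Count-weighted mean over the populated bins."""
        tot = self.counts.sum()
        if tot == 0:
            return float("nan")
        good = self.counts > 0
        return float((self.intensity[good] * self.counts[good]).sum() / tot)

    def to_csv(self) -> str:
        lines = ["q_center_invA,intensity,n_pixels"]
        for q, i, c in zip(self.q_centers, self.intensity, self.counts):
            lines.append(f"{q:.6g},{'' if np.isnan(i) else f'{i:.6g}'},{c}")
        return "\n".join(lines) + "\n"


def radial_profile(image: AssembledImage | np.ndarray,
                   geometry: DetectorGeometry,
                   d_range: tuple[float, float] | None = None,
                   n_bins: int = 100,
                   sentinel: int = SENTINEL) -> RadialProfile:
    """Mean intensity in q bins restricted to a resolution range.

    ``d_range = (d_max, d_min)`` in Angstrom (low to high resolution); by
    default the full detector coverage is integrated.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if isinstance(image, AssembledImage):
        pix, sentinel = image.pixels, image.sentinel
        frame_number = image.frame_number
    else:
        pix, frame_number = image, 0
    if pix.shape != geometry.assembled_shape:
        raise ValueError("image shape does not match geometry")
    q = geometry.q_map()
    valid = pix != sentinel
    q_cov = q[valid] if np.any(valid) else q.ravel()
    q_lo_det, q_hi_det = float(q_cov.min()), float(q_cov.max())
    if d_range is None:
        q_min, q_max = q_lo_det, q_hi_det
        d_range = (1.0 / q_min if q_min > 0 else np.inf, 1.0 / q_max)
    else:
        d_max, d_min = d_range
        if d_max <= d_min:
            raise ValueError("d_range must be (d_max, d_min) with d_max > d_min")
        q_min, q_max = 1.0 / d_max, 1.0 / d_min
        if q_max < q_lo_det or q_min > q_hi_det:
            raise ValueError(
                "requested resolution range is outside detector coverage "
                f"(achievable d: {1.0 / q_hi_det:.3g} to "
                f"{(1.0 / q_lo_det) if q_lo_det > 0 else np.inf:.3g} A)")
    edges = np.linspace(q_min, q_max, n_bins + 1)
    sel = valid & (q >= q_min) & (q <= q_max)
    idx = np.clip(np.digitize(q[sel], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=pix[sel].astype(np.float64),
                       minlength=n_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(edges, intensity, counts, d_range, frame_number)


# ---------------------------------------------------------------------------
# spot finding
# ---------------------------------------------------------------------------

def _window_sum(arr: np.ndarray, w: int) -> np.ndarray:
    """Exact (2w+1)^2 box sums via an integer summed-area table; windows
    are truncated at the image edge."""
    pad = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.int64)
    np.cumsum(arr, axis=0, out=pad[1:, 1:])
    np.cumsum(pad[1:, 1:], axis=1, out=pad[1:, 1:])
    r0 = np.clip(np.arange(arr.shape[0]) - w, 0, None)
    r1 = np.clip(np.arange(arr.shape[0]) + w + 1, None, arr.shape[0])
    c0 = np.clip(np.arange(arr.shape[1]) - w, 0, None)
    c1 = np.clip(np.arange(arr.shape[1]) + w + 1, None, arr.shape[1])
    return (pad[r1][:, c1] - pad[r1][:, c0]
            - pad[r0][:, c1] + pad[r0][:, c0])


def find_strong_pixels(image: np.ndarray, w: int = DEFAULT_WINDOW,
                       snr_min: float = DEFAULT_SNR_MIN,
                       sentinel: int = SENTINEL,
                       n_iter: int = DEFAULT_BG_ITER) -> np.ndarray:
    """Mark pixels above the local background by ``snr_min`` local SDs.

    The background mean and population SD are computed over the (2w+1)^2
    neighbourhood, skipping sentinel pixels.  Because a Bragg spot spans a
    sizeable fraction of a small window and would bias its own background
    estimate, the threshold is refined iteratively: pixels marked strong in
    one pass are excluded from the background statistics of the next, until
    the mask is stable or ``n_iter`` passes were made (``n_iter=1`` gives
    the plain single-pass selection).  Exact integer summed-area tables are
    used throughout, so results are reproducible bit for bit.
    """
    if w < 1:
        raise ValueError("window half-width must be >= 1")
    if n_iter < 1:
        raise ValueError("need at least one pass")
    valid = image != sentinel
    vimg = np.where(valid, image, 0).astype(np.int64)
    strong = np.zeros(image.shape, dtype=bool)
    for _ in range(n_iter):
        bg = valid & ~strong
        n = _window_sum(bg.astype(np.int64), w)
        s1 = _window_sum(np.where(bg, vimg, 0), w)
        s2 = _window_sum(np.where(bg, vimg * vimg, 0), w)
        nf = n.astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / nf
            var = s2 / nf - mean ** 2
        sd = np.sqrt(np.clip(var, 0.0, None))
        new = valid & (n > 0) & (image > mean + snr_min * sd)
        if np.array_equal(new, strong):
            break
        strong = new
    return strong


@dataclass
class Spot:
    """One diffraction spot: centroid, intensity and reciprocal position."""

    x: float                  # centroid column (pixel-centre convention)
    y: float                  # centroid row
    intensity: float          # summed photon counts
    n_pixels: int
    s: tuple[float, float, float] | None = None  # reciprocal vector, A^-1
    d: float | None = None    # resolution, A
    frame_number: int = 0

    def to_dict(self) -> dict:
        rec = {"x": self.x, "y": self.y, "intensity": self.intensity,
               "n_pixels": self.n_pixels, "frame_number": self.frame_number}
        if self.s is not None:
            rec.update(sx=self.s[0], sy=self.s[1], sz=self.s[2], d=self.d)
        return rec


@dataclass
class SpotList:
    spots: list[Spot] = field(default_factory=list)
    frame_number: int = 0

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(s.to_dict()) for s in self.spots) + (
            "\n" if self.spots else "")

    def to_tsv(self) -> str:
        header = "x\ty\tintensity\tn_pixels\tsx\tsy\tsz\td\tframe_number"
        rows = [header]
        for s in self.spots:
            sx, sy, sz = s.s if s.s is not None else ("", "", "")
            d = s.d if s.d is not None else ""
            rows.append("\t".join(str(v) for v in (
                s.x, s.y, s.intensity, s.n_pixels, sx, sy, sz, d,
                s.frame_number)))
        return "\n".join(rows) + "\n"


_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def cluster_spots(mask: np.ndarray, image: np.ndarray,
                  min_pix: int = DEFAULT_MIN_PIX,
                  connectivity: int = 8,
                  frame_number: int = 0) -> SpotList:
    """Group strong pixels into spots via connected components.

    Centroids are intensity weighted (negative values clipped to zero for
    the weighting) and reported in the pixel-centre convention.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(
        mask, structure=_STRUCT_8 if connectivity == 8 else _STRUCT_4)
    if n == 0:
        return SpotList([], frame_number)
    flat = labels.ravel()
    sel = flat > 0
    lab = flat[sel]
    vals = image.ravel()[sel].astype(np.float64)
    rows, cols = np.divmod(np.nonzero(sel)[0], image.shape[1])
    sizes = np.bincount(lab, minlength=n + 1)
    inten = np.bincount(lab, weights=vals, minlength=n + 1)
    wpos = np.clip(vals, 0.0, None)
    wsum = np.bincount(lab, weights=wpos, minlength=n + 1)
    wx = np.bincount(lab, weights=wpos * (cols + 0.5), minlength=n + 1)
    wy = np.bincount(lab, weights=wpos * (rows + 0.5), minlength=n + 1)
    # fall back to unweighted centroids where all weights vanish
    cx = np.bincount(lab, weights=cols + 0.5, minlength=n + 1)
    cy = np.bincount(lab, weights=rows + 0.5, minlength=n + 1)
    spots = []
    for k in range(1, n + 1):
        if sizes[k] < min_pix:
            continue
        if wsum[k] > 0:
            x, y = wx[k] / wsum[k], wy[k] / wsum[k]
        else:
            x, y = cx[k] / sizes[k], cy[k] / sizes[k]
        spots.append(Spot(float(x), float(y), float(inten[k]),
                          int(sizes[k]), frame_number=frame_number))
    return SpotList(spots, frame_number)


def find_spots(image: AssembledImage | np.ndarray,
               geometry: DetectorGeometry | None = None,
               w: int = DEFAULT_WINDOW, snr_min: float = DEFAULT_SNR_MIN,
               min_pix: int = DEFAULT_MIN_PIX,
               sentinel: int = SENTINEL,
               frame_number: int = 0) -> SpotList:
    """Strong-pixel selection + clustering (+ reciprocal vectors if geometry)."""
    if isinstance(image, AssembledImage):
        pix, sentinel = image.pixels, image.sentinel
        frame_number = image.frame_number
        geometry = geometry or image.geometry
    else:
        pix = image
    mask = find_strong_pixels(pix, w=w, snr_min=snr_min, sentinel=sentinel)
    spots = cluster_spots(mask, pix, min_pix=min_pix,
                          frame_number=frame_number)
    if geometry is not None:
        spots = spots_to_reciprocal(spots, geometry)
    return spots


def spots_to_reciprocal(spots: SpotList,
                        geometry: DetectorGeometry) -> SpotList:
    """Attach s = (u/|u| - z_hat)/lambda to every spot; |s| = 2 sin(theta)/lambda = 1/d.

    A spot exactly at the beam centre has s = 0 and undefined d (flagged with
    ``d = inf``).
    """
    lam = geometry.wavelength_A
    out = []
    for s in spots:
        u = geometry.lab_positions_mm(np.array(s.y - 0.5),
                                      np.array(s.x - 0.5))
        u = np.asarray(u, dtype=np.float64)
        norm = float(np.linalg.norm(u))
        vec = (u / norm - np.array([0.0, 0.0, 1.0])) / lam
        mag = float(np.linalg.norm(vec))
        d = (1.0 / mag) if mag > 0 else float("inf")
        out.append(Spot(s.x, s.y, s.intensity, s.n_pixels,
                        (float(vec[0]), float(vec[1]), float(vec[2])),
                        d, s.frame_number))
    return SpotList(out, spots.frame_number)


# ---------------------------------------------------------------------------
# feedback scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeedbackPlan:
    """Deterministic every-Nth subsampling of the frame stream."""

    preview_stride: int
    analysis_stride: int

    def preview_frames(self, frame_numbers) -> list[int]:
        return [f for f in frame_numbers if (f - 1) % self.preview_stride == 0]

    def analysis_frames(self, frame_numbers) -> list[int]:
        return [f for f in frame_numbers if (f - 1) % self.analysis_stride == 0]


def _stride(frame_rate: float, rate: float) -> int:
    if rate <= 0 or frame_rate <= 0:
        raise ValueError("rates must be positive")
    if rate > frame_rate:
        import warnings

        warnings.warn("requested rate exceeds the frame rate; analysing "
                      "every frame", RuntimeWarning)
        return 1
    return max(1, round(frame_rate / rate))


def schedule_feedback(frame_rate: float, preview_rate: float = 1.0,
                      analysis_rate: float = 100.0) -> FeedbackPlan:
    """Strides achieving the requested preview/analysis rates.

    At a 2 kHz frame rate with the default 100 images/s analysis rate every
    20th frame is analysed; the 1 image/s preview takes every 2000th.
    """
    return FeedbackPlan(_stride(frame_rate, preview_rate),
                        _stride(frame_rate, analysis_rate))
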