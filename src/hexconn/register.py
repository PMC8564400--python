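"""Pattern-lattice recovery from raster images.

Two stages, mirroring standard practice for periodic micropattern arrays:

1. **Rotation** — the hexagonal array is periodic, so the 2D power spectrum
   shows first-order peaks on a 60°-symmetric star.  The angle of the
   strongest non-DC peaks, folded into [−30°, +30°), is the array rotation
   relative to the canonical flat-top orientation.
2. **Detection** — zero-normalized cross-correlation between the derotated
   image and a synthesized single-hexagon template; correlation maxima
   (score ≥ threshold, separated by ≥ 0.8 × lattice spacing) are pattern
   centers, refined to sub-pixel precision by a quadratic fit and indexed
   by least-squares alignment to the model lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon
from skimage.feature import match_template, peak_local_max

from .geometry import (
    SQRT3,
    LatticeSpec,
    PatternIndex,
    _axial_round,
    hexagon_vertices,
)


class NoLatticeError(RuntimeError):
    """The image shows no detectable periodic structure."""


class InsufficientDetectionsError(RuntimeError):
    """Fewer pattern candidates than needed to fit the lattice."""


@dataclass
class RegistrationResult:
    rotation_deg: float
    detected_centers: list  # (x_px, y_px, score), scores descending
    index_map: dict  # (x_px, y_px) → PatternIndex
    px_per_um: float
    origin_offset_px: tuple = (0.0, 0.0)


def _fold_60(angle_deg: float) -> float:
    """Fold an angle into [−30°, +30°) using the lattice's 60° symmetry."""
    return (angle_deg + 30.0) % 60.0 - 30.0


def _subpixel_peak(power: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Quadratic 3-point refinement of a peak location, per axis."""

    def refine(vm: float, v0: float, vp: float) -> float:
        denom = vm - 2.0 * v0 + vp
        if denom == 0:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dr = dc = 0.0
    if 0 < r < power.shape[0] - 1:
        dr = refine(power[r - 1, c], power[r, c], power[r + 1, c])
    if 0 < c < power.shape[1] - 1:
        dc = refine(power[r, c - 1], power[r, c], power[r, c + 1])
    return r + dr, c + dc


def estimate_rotation(pattern_image: np.ndarray, min_peak_ratio: float = 20.0) -> float:
    """Array rotation in degrees, in [−30°, +30°), from the FFT power spectrum.

    Positive angles are counter-clockwise as displayed.  Raises
    :class:`NoLatticeError` when the spectrum has no dominant non-DC peak
    (flat or pure-noise input).
    """
    img = np.asarray(pattern_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("pattern_image must be 2D")
    if img.std() == 0:
        raise NoLatticeError("image is flat")
    win = np.outer(np.hanning(img.shape[0]), np.hanning(img.shape[1]))
    spec = np.fft.fftshift(np.abs(np.fft.fft2((img - img.mean()) * win)) ** 2)
    cy, cx = np.array(spec.shape) // 2

    yy, xx = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    rad = np.hypot(yy - cy, xx - cx)
    dc_mask = rad < max(3.0, 0.01 * min(spec.shape))
    work = spec.copy()
    work[dc_mask] = 0.0

    peak = np.unravel_index(int(np.argmax(work)), work.shape)
    peak_val = work[peak]
    background = float(np.median(work[~dc_mask]))
    if background <= 0 or peak_val / background < min_peak_ratio:
        raise NoLatticeError("no dominant spectral peak")

    # gather all first-order peaks in the radial band of the strongest one
    k0 = rad[peak]
    band = (~dc_mask) & (rad > 0.85 * k0) & (rad < 1.15 * k0)
    cand = peak_local_max(
        np.where(band, work, 0.0), min_distance=3, threshold_abs=0.2 * peak_val
    )

    angles = []
    weights = []
    for r, c in cand:
        rr, cc = _subpixel_peak(work, int(r), int(c))
        # ky measured upward so CCW display rotation gives positive angles
        ang = math.degrees(math.atan2(-(rr - cy), cc - cx))
        angles.append(_fold_60(ang))
        weights.append(work[int(r), int(c)])
    ref = angles[int(np.argmax(weights))]
    rel = [_fold_60(a - ref) for a in angles]
    return _fold_60(ref + float(np.average(rel, weights=weights)))


def hexagon_template(spec: LatticeSpec, px_per_um: float) -> np.ndarray:
    """Filled flat-top hexagon at image scale, with half-gap background."""
    pad = max(2.0, 0.5 * spec.gap_D * px_per_um)
    half = spec.edge_length_L * px_per_um + pad
    size = int(math.ceil(2 * half)) | 1  # odd size, exact center pixel
    c = size // 2
    verts = hexagon_vertices((0.0, 0.0), spec.edge_length_L * px_per_um)
    rr, cc = polygon(c - verts[:, 1], c + verts[:, 0], shape=(size, size))
    tpl = np.zeros((size, size), dtype=float)
    tpl[rr, cc] = 1.0
    return tpl


def detect_patterns(
    pattern_image: np.ndarray,
    spec: LatticeSpec,
    px_per_um: float,
    score_min: float = 0.5,
) -> RegistrationResult:
    """Locate and index pattern centers in a derotated image.

    Centers are correlation maxima of the hexagon template; indexing aligns
    the detected set to the model lattice over a translational offset,
    choosing the lattice shift that maximizes overlap with the in-bounds
    index set.
    """
    img = np.asarray(pattern_image, dtype=float)
    tpl = hexagon_template(spec, px_per_um)
    if min(img.shape) < min(tpl.shape):
        raise InsufficientDetectionsError("image smaller than the template")
    corr = match_template(img, tpl, pad_input=True)

    spacing_px = spec.spacing * px_per_um
    peaks = peak_local_max(
        corr,
        min_distance=max(1, int(0.8 * spacing_px)),
        threshold_abs=score_min,
        exclude_border=False,
    )
    if len(peaks) < 4:
        raise InsufficientDetectionsError(
            f"only {len(peaks)} correlation peaks ≥ {score_min}"
        )

    centers = []
    for r, c in peaks:
        rr, cc = _subpixel_peak(corr, int(r), int(c))
        centers.append((float(cc), float(rr), float(corr[int(r), int(c)])))
    centers.sort(key=lambda t: -t[2])

    index_map, offset = _index_centers(centers, spec, px_per_um, img.shape[0])
    return RegistrationResult(
        rotation_deg=0.0,
        detected_centers=centers,
        index_map=index_map,
        px_per_um=px_per_um,
        origin_offset_px=offset,
    )


def _index_centers(centers, spec: LatticeSpec, px_per_um: float, img_height: int):
    """Assign axial indices to detected centers (px → μm with +y up)."""
    pts = np.array([(x / px_per_um, (img_height - 1 - y) / px_per_um) for x, y, _ in centers])
    size = spec._cell_size
    anchor = pts[np.argmin(pts[:, 0] + pts[:, 1])]

    # two rounding passes: the second uses the refined translation
    t = anchor.copy()
    for _ in range(2):
        rel = pts - t
        ax = []
        for x, y in rel:
            qf = (2.0 / 3.0) * x / size
            rf = (-x / 3.0 + SQRT3 / 3.0 * y) / size
            ax.append(_axial_round(qf, rf))
        model = np.array(
            [(1.5 * size * a.q, SQRT3 * size * (a.r + a.q / 2.0)) for a in ax]
        )
        t = (pts - model).mean(axis=0)

    in_bounds = {PatternIndex(i.q, i.r) for i in spec.all_indices()}
    det = [PatternIndex(a.q, a.r) for a in ax]
    qs_d, rs_d = [a.q for a in det], [a.r for a in det]
    qs_b, rs_b = [i.q for i in in_bounds], [i.r for i in in_bounds]
    best, best_shift = -1, (0, 0)
    for dq in range(min(qs_b) - max(qs_d), max(qs_b) - min(qs_d) + 1):
        for dr in range(min(rs_b) - max(rs_d), max(rs_b) - min(rs_d) + 1):
            hit = sum(1 for a in det if PatternIndex(a.q + dq, a.r + dr) in in_bounds)
            if hit > best:
                best, best_shift = hit, (dq, dr)
    dq, dr = best_shift
    index_map = {
        (x, y): PatternIndex(a.q + dq, a.r + dr)
        for (x, y, _), a in zip(centers, det)
    }
    return index_map, (float(t[0]), float(t[1]))


def register_image(
    pattern_image: np.ndarray,
    spec: LatticeSpec,
    px_per_um: float,
    score_min: float = 0.5,
) -> RegistrationResult:
    """Full registration: estimate rotation, derotate, then detect and index."""
    from scipy import ndimage

    angle = estimate_rotation(pattern_image)
    img = np.asarray(pattern_image, dtype=float)
    if abs(angle) > 1e-6:
        img = ndimage.rotate(img, -angle, reshape=True, order=1, prefilter=False)
    result = detect_patterns(img, spec, px_per_um, score_min=score_min)
    result.rotation_deg = angle
    return result
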