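"""Raster rendering of simulated circuits.

Produces the multi-channel images the registration stage consumes: channel
0 holds the filled hexagon patterns (the micropattern fluorescence
channel), channels 1..n_colors hold per-cell color intensity painted over
the soma disc, the dendrite-occupied patterns and thin axon traces.
Purely a fixture generator — optics (PSF, bleed-through, vignetting) are
not modeled beyond optional additive Gaussian noise.

Pixel convention: row 0 is the top of the image and μm +y points up, so
``row = (y_max + margin − y) · px_per_um``.  ``rotation_deg`` is the
counter-clockwise rotation of the lattice as seen in the displayed image.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage.draw import disk, line, polygon

from .geometry import LatticeSpec, hex_center, hexagon_vertices


def _transform(spec: LatticeSpec, px_per_um: float, margin_um: float):
    verts = []
    for idx in spec.all_indices():
        verts.append(hexagon_vertices(hex_center(spec, idx), spec.edge_length_L, spec.rotation))
    allv = np.vstack(verts)
    xmin, ymin = allv.min(axis=0)
    xmax, ymax = allv.max(axis=0)
    width = int(math.ceil((xmax - xmin + 2 * margin_um) * px_per_um))
    height = int(math.ceil((ymax - ymin + 2 * margin_um) * px_per_um))

    def to_px(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(pts)
        cols = (pts[:, 0] - xmin + margin_um) * px_per_um
        rows = (ymax + margin_um - pts[:, 1]) * px_per_um
        return rows, cols

    return to_px, height, width


def render_image(
    spec: LatticeSpec,
    annotation,
    px_per_um: float = 0.5,
    noise_sd: float = 0.0,
    rotation_deg: float = 0.0,
    seed: int = 0,
    n_colors: int | None = None,
    soma_radius_um: float = 7.5,
    margin_um: float | None = None,
) -> np.ndarray:
    """Render a circuit to a (1 + n_colors, H, W) float32 stack in [0, 1]."""
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    if margin_um is None:
        margin_um = 0.75 * spec.spacing
    cells = getattr(annotation, "cells", ()) if annotation is not None else ()
    if n_colors is None:
        n_colors = len(cells[0].color) if cells else 3

    to_px, h, w = _transform(spec, px_per_um, margin_um)
    img = np.zeros((1 + n_colors, h, w), dtype=np.float32)

    for idx in spec.all_indices():
        verts = hexagon_vertices(hex_center(spec, idx), spec.edge_length_L, spec.rotation)
        rr, cc = to_px(verts)
        pr, pc = polygon(rr, cc, shape=(h, w))
        img[0, pr, pc] = 1.0

    for cell in cells:
        color = np.asarray(cell.color, dtype=np.float32)
        sr, sc = to_px(np.array([cell.soma_point]))
        soma_r, soma_c = float(sr[0]), float(sc[0])
        pr, pc = disk((soma_r, soma_c), max(1.0, soma_radius_um * px_per_um), shape=(h, w))
        for ch in range(n_colors):
            img[1 + ch, pr, pc] = np.maximum(img[1 + ch, pr, pc], color[ch])
        for pat in cell.dendrite_patterns:
            verts = hexagon_vertices(hex_center(spec, pat), spec.edge_length_L, spec.rotation)
            rr, cc = to_px(verts)
            pr, pc = polygon(rr, cc, shape=(h, w))
            for ch in range(n_colors):
                img[1 + ch, pr, pc] = np.maximum(img[1 + ch, pr, pc], 0.55 * color[ch])
        for pat in cell.axon_patterns:
            tr, tc = to_px(np.array([hex_center(spec, pat)]))
            pr, pc = line(
                int(round(soma_r)), int(round(soma_c)),
                int(round(float(tr[0]))), int(round(float(tc[0]))),
            )
            keep = (pr >= 0) & (pr < h) & (pc >= 0) & (pc < w)
            for ch in range(n_colors):
                img[1 + ch, pr[keep], pc[keep]] = np.maximum(
                    img[1 + ch, pr[keep], pc[keep]], 0.8 * color[ch]
                )

    if rotation_deg != 0.0:
        # positive angle = CCW in the y-up μm frame, matching LatticeSpec.rotation
        img = np.stack(
            [
                ndimage.rotate(ch, rotation_deg, reshape=True, order=1, prefilter=False)
                for ch in img
            ]
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.5)
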