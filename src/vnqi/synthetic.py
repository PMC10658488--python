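"""Procedural generation of vasculogenesis-like binary vessel masks.

Real vascularized-chip cohorts vary in endothelial seeding density, matrix
stiffness, growth-factor supplementation and cell source; each of those
wet-lab determinants maps here onto one generator knob so that cohorts and
parameter sweeps can be produced synthetically:

================  =============================================
wet-lab factor    generator knob
================  =============================================
cell density      ``n_seed_points``
matrix stiffness  ``dropout_frac`` (and diameter)
growth factors    ``connect_prob``
perfusion access  ``spanning_bias`` (segments reaching the two
                  lateral media boundaries)
================  =============================================

A mask is built by scattering seed points, joining them with a k-nearest-
neighbour proximity graph (k = 3, which yields branchpoints and loops like
vasculogenic networks), thinning edges with ``connect_prob``, deleting a
``dropout_frac`` fraction of the surviving segments, and rasterising each
remaining segment as a hard-binary capsule stroke whose diameter is drawn
from a truncated normal. No anti-aliasing is applied anywhere: metrics
downstream assume a strictly binary raster.

Everything is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "GeneratorConfig",
    "VesselMask",
    "generate_mask",
    "generate_cohort",
    "DEFAULT_JITTER",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters controlling one synthetic vessel-network mask.

    Defaults give a 256 x 256 raster at 4 um/pixel, i.e. a ~1 x 1 mm field
    of view, the scale at which such networks are usually imaged.

    Parameters
    ----------
    image_shape:
        (rows, cols) of the raster.
    pixel_pitch:
        Physical size of one pixel, in micrometres.
    n_seed_points:
        Number of scattered seed points (endothelial-density analogue).
    connect_prob:
        Probability of keeping each proximity-graph edge, in [0, 1].
    diameter_mean, diameter_sd:
        Normal distribution of per-segment stroke diameters, in um,
        truncated below at one pixel.
    spanning_bias:
        Number of anchor points placed on each lateral (left/right) image
        boundary and connected to the nearest interior seed point; controls
        how strongly the network spans between the two media channels.
    dropout_frac:
        Fraction of kept segments deleted afterwards, in [0, 1).
    rng_seed:
        Seed for the generator's private random stream.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_pitch: float = 4.0
    n_seed_points: int = 80
    connect_prob: float = 0.9
    diameter_mean: float = 16.0
    diameter_sd: float = 4.0
    spanning_bias: float = 2.0
    dropout_frac: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.connect_prob <= 1.0):
            raise ValueError(f"connect_prob must be in [0, 1], got {self.connect_prob}")
        if not (0.0 <= self.dropout_frac < 1.0):
            raise ValueError(f"dropout_frac must be in [0, 1), got {self.dropout_frac}")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if self.n_seed_points < 0:
            raise ValueError("n_seed_points must be >= 0")
        if self.spanning_bias < 0:
            raise ValueError("spanning_bias must be >= 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass
class VesselMask:
    """A binary 2D raster of vessel lumen (1) vs tissue (0) pixels."""

    pixels: np.ndarray
    pixel_pitch: float
    provenance: str | GeneratorConfig | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask not binary")
        self.pixels = self.pixels.astype(bool)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def coverage(self) -> float:
        """Vessel area fraction in [0, 1]."""
        return float(self.pixels.mean())


def _capsule_stroke(mask: np.ndarray, p: np.ndarray, q: np.ndarray, radius: float) -> None:
    """Rasterize the set of pixels within `radius` of segment p-q (in-place)."""
    r0 = int(np.floor(min(p[0], q[0]) - radius))
    r1 = int(np.ceil(max(p[0], q[0]) + radius)) + 1
    c0 = int(np.floor(min(p[1], q[1]) - radius))
    c1 = int(np.ceil(max(p[1], q[1]) + radius)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, mask.shape[0]), min(c1, mask.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d = q - p
    L2 = float(d @ d)
    if L2 == 0.0:
        dist2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
    else:
        t = ((rr - p[0]) * d[0] + (cc - p[1]) * d[1]) / L2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (rr - (p[0] + t * d[0])) ** 2 + (cc - (p[1] + t * d[1])) ** 2
    mask[r0:r1, c0:c1] |= dist2 <= radius * radius


def _proximity_edges(points: np.ndarray, k: int = 3) -> list[tuple[int, int]]:
    """Undirected k-nearest-neighbour edges over point indices."""
    n = len(points)
    if n < 2:
        return []
    tree = cKDTree(points)
    kq = min(k + 1, n)
    _, idx = tree.query(points, k=kq)
    edges = set()
    for i in range(n):
        for j in np.atleast_1d(idx[i])[1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.add((a, b))
    return sorted(edges)


def generate_mask(config: GeneratorConfig) -> VesselMask:
    """Generate one binary vessel-network mask from a configuration.

    Deterministic: the same config (including ``rng_seed``) always yields a
    bit-identical raster. ``n_seed_points = 0`` yields a valid all-zero mask.
    """
    rng = np.random.default_rng(config.rng_seed)
    shape = tuple(config.image_shape)
    pixels = np.zeros(shape, dtype=bool)

    n = config.n_seed_points
    if n == 0:
        return VesselMask(pixels, config.pixel_pitch, provenance=config)

    pts = rng.uniform(low=(0, 0), high=(shape[0] - 1, shape[1] - 1), size=(n, 2))

    # Boundary anchors pull the network out to the lateral media channels.
    n_anchor = int(round(config.spanning_bias))
    anchor_edges: list[tuple[int, int]] = []
    if n_anchor > 0 and n >= 1:
        rows_l = rng.uniform(0, shape[0] - 1, size=n_anchor)
        rows_r = rng.uniform(0, shape[0] - 1, size=n_anchor)
        anchors = np.concatenate(
            [
                np.column_stack([rows_l, np.zeros(n_anchor)]),
                np.column_stack([rows_r, np.full(n_anchor, shape[1] - 1)]),
            ]
        )
        tree = cKDTree(pts)
        _, nearest = tree.query(anchors, k=1)
        base = len(pts)
        pts = np.vstack([pts, anchors])
        anchor_edges = [(int(nearest[i]), base + i) for i in range(len(anchors))]

    edges = _proximity_edges(pts[:n], k=3)
    keep = rng.uniform(size=len(edges)) < config.connect_prob
    kept = [e for e, k_ in zip(edges, keep) if k_] + anchor_edges

    if kept and config.dropout_frac > 0:
        n_drop = int(np.floor(config.dropout_frac * len(kept)))
        if n_drop > 0:
            drop_idx = set(rng.choice(len(kept), size=n_drop, replace=False).tolist())
            kept = [e for i, e in enumerate(kept) if i not in drop_idx]

    diam_px = config.diameter_mean / config.pixel_pitch
    sd_px = config.diameter_sd / config.pixel_pitch
    for a, b in kept:
        d = max(rng.normal(diam_px, sd_px), 1.0)
        _capsule_stroke(pixels, pts[a], pts[b], radius=d / 2.0)

    return VesselMask(pixels, config.pixel_pitch, provenance=config)


#: Default per-field uniform jitter ranges used by :func:`generate_cohort`.
#: Spans sparse, barely connected networks through dense spanning ones, so a
#: default cohort covers roughly the 5-40% vessel-coverage band seen across
#: diverse vasculogenesis conditions.
DEFAULT_JITTER: dict[str, tuple[float, float]] = {
    "n_seed_points": (5, 400),
    "connect_prob": (0.35, 1.0),
    "diameter_mean": (8.0, 34.0),
    "diameter_sd": (2.0, 6.0),
    "spanning_bias": (0.0, 4.0),
    "dropout_frac": (0.0, 0.55),
}

_INT_FIELDS = {"n_seed_points"}


def generate_cohort(
    base: GeneratorConfig,
    n: int,
    jitter_spec: Mapping[str, tuple[float, float]] | None = None,
    master_seed: int = 0,
) -> tuple[list[VesselMask], pd.DataFrame]:
    """Generate ``n`` masks whose configs are jittered around ``base``.

    Each mask's config fields listed in ``jitter_spec`` are drawn uniformly
    from the given (low, high) ranges using a stream seeded by
    ``master_seed``; per-mask raster seeds are drawn from the same stream.
    Pass ``jitter_spec={}`` for a single-condition cohort. Returns the masks
    plus a provenance table with one row per mask (sampled config + seed).
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if jitter_spec is None:
        jitter_spec = DEFAULT_JITTER
    bad = set(jitter_spec) - {f.name for f in dataclasses.fields(GeneratorConfig)}
    if bad:
        raise ValueError(f"unknown config fields in jitter_spec: {sorted(bad)}")

    rng = np.random.default_rng(master_seed)
    masks: list[VesselMask] = []
    rows: list[dict] = []
    for i in range(n):
        overrides: dict[str, float | int] = {}
        for name, (lo, hi) in jitter_spec.items():
            val = rng.uniform(lo, hi)
            if name in _INT_FIELDS:
                val = int(round(val))
            overrides[name] = val
        overrides["rng_seed"] = int(rng.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(base, **overrides)
        masks.append(generate_mask(cfg))
        row = {"sample_id": f"mask_{i:04d}"}
        row.update(dataclasses.asdict(cfg))
        row["image_shape"] = f"{cfg.image_shape[0]}x{cfg.image_shape[1]}"
        rows.append(row)
    return masks, pd.DataFrame(rows)
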