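"""Seeded synthetic micrographs of rod-shaped striated cardiomyocytes.

Healthy isolated adult cardiomyocytes are elongated, nearly rectangular cells
with rounded ends and a periodic striation (the sarcomere pattern, ~1.8 µm).
This module renders fields of such cells — plus the disqualified classes a
real preparation contains (touching/overlaying pairs, rounded cells and small
fragments) — with exact ground truth, so every downstream stage (segmentation,
shape measurement, qualification, sarcomere period, 3D volume) can be tested
against a known answer.

Geometry model
--------------
An intact rod is drawn as a *capsule* (stadium): a rectangle of length
``L - W`` and width ``W`` capped by two semicircles of diameter ``W``.  The
capsule has closed-form area ``W (L - W) + pi W^2 / 4`` and its maximum /
minimum caliper (Feret) diameters are exactly ``L`` and ``W``, which makes it
the natural oracle shape for the measurement stages.  Striation is a
multiplicative intensity modulation ``1 + a cos(2 pi u / s)`` along the cell
axis coordinate ``u`` with period ``s`` (the sarcomere length).

Population model
----------------
Per-group length/width (and sarcomere-period, volume) distributions default to
the hypertrophy-study group statistics bundled in :data:`GROUP_PARAMS`
(control, angiotensin-II, isoproterenol, aged).  Lengths and widths are drawn
from truncated normals (width >= 5 µm, length >= width).  Class composition is
allocated by the largest-remainder rule so realized counts are exact (a
multinomial mode exists behind a flag).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .image import CalibratedImage, write_stack, write_tiff

CELL_CLASSES = ("intact_rod", "touching_pair", "rounded", "fragment")

#: Default field geometry: 1024 x 1024 px at 0.65 µm/px (a desk-scale
#: stand-in for full-frame ~2k x 2k sCMOS acquisitions).
DEFAULT_FIELD_PX = (1024, 1024)
DEFAULT_PIXEL_UM = 0.65

#: Per-group morphometric population parameters, (mean, sd) in physical units.
#: Groups: untreated control, angiotensin-II infusion ("ang"), isoproterenol
#: infusion ("iso") and aged animals ("old").
GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "length_um": (139.42, 33.06),
        "width_um": (28.78, 7.93),
        "sarcomere_period_um": (1.801, 0.034),
        "volume_um3": (35368.88, 19283.4),
    },
    "ang": {
        "length_um": (154.09, 37.52),
        "width_um": (31.44, 8.29),
        "sarcomere_period_um": (1.829, 0.045),
        "volume_um3": (56919.39, 28243.97),
    },
    "iso": {
        "length_um": (146.12, 34.29),
        "width_um": (31.15, 8.96),
        "sarcomere_period_um": (1.797, 0.083),
        "volume_um3": (48895.67, 21910.03),
    },
    "old": {
        "length_um": (147.24, 36.2),
        "width_um": (34.48, 10.44),
        "sarcomere_period_um": (1.794, 0.031),
        "volume_um3": (51928.17, 29308.98),
    },
}


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth description of one synthetic object.

    ``length_um >= width_um`` for rods; rounded cells have ``length == width``;
    a ``touching_pair`` is a single truth object drawn as two overlapping
    capsules (the partner geometry lives in the ``pair_*`` fields).
    """

    cell_class: str
    length_um: float
    width_um: float
    orientation_deg: float = 0.0
    center_um: tuple[float, float] = (0.0, 0.0)  # (x, y)
    intensity: float = 0.8
    sarcomere_period_um: float | None = None
    # touching-pair partner geometry
    pair_length_um: float | None = None
    pair_width_um: float | None = None
    pair_overlap_um: float = 3.0
    pair_shift_frac: float = 0.3
    # z-extent of the 3D solid as a fraction of the width
    depth_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("length and width must be positive")
        if self.cell_class == "intact_rod" and self.length_um < self.width_um:
            raise ValueError("intact_rod requires length_um >= width_um")
        if self.cell_class == "rounded" and self.length_um != self.width_um:
            raise ValueError("rounded requires length_um == width_um")
        if not 0 < self.intensity <= 1:
            raise ValueError("intensity must be in (0, 1]")


@dataclass
class SyntheticScene:
    """Rendered image (and/or z-stack) paired with its ground truth.

    ``label_map`` value ``i`` marks pixels owned by ``truth[i - 1]`` (0 is
    background; overlap ties go to the lower index)."""

    image: CalibratedImage
    truth: list[CellSpec]
    label_map: np.ndarray | None = None
    stack: np.ndarray | None = None          # (z, y, x)
    voxel_um: tuple[float, float, float] | None = None  # (x, y, z)
    seed: int = 0
    clipped: list[bool] = field(default_factory=list)
    truth_volumes_um3: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# analytic geometry

def capsule_area(length_um: float, width_um: float) -> float:
    """Closed-form area of a capsule: W(L - W) + pi W^2 / 4."""
    L, W = length_um, width_um
    return W * (L - W) + np.pi * W * W / 4.0


def capsule_spheroid_volume(length_um: float, width_um: float,
                            depth_ratio: float) -> float:
    """Volume of the 3D rod solid.

    Cross-sections perpendicular to the cell axis are ellipses with in-plane
    semi-axis ``W/2`` and z semi-axis ``D/2`` where ``D = depth_ratio * W``;
    the ends are half-spheroids.  V = pi/4 W D (L - W) + pi/6 W^2 D.
    """
    L, W = length_um, width_um
    D = depth_ratio * W
    return np.pi / 4.0 * W * D * (L - W) + np.pi / 6.0 * W * W * D


def calibrated_depth_ratio(params: dict[str, tuple[float, float]]) -> float:
    """Depth ratio that makes the expected 3D solid volume of a group's
    length/width distribution match the group's target mean volume.

    Uses normal moments (truncation is negligible at these parameters):
    E[V] = ratio * (pi/4 (E[W^2] E[L] - E[W^3]) + pi/6 E[W^3]).
    """
    muL, _ = params["length_um"]
    muW, sdW = params["width_um"]
    v_target = params["volume_um3"][0]
    ew2 = muW ** 2 + sdW ** 2
    ew3 = muW ** 3 + 3 * muW * sdW ** 2
    ev_unit = np.pi / 4.0 * (ew2 * muL - ew3) + np.pi / 6.0 * ew3
    return float(v_target / ev_unit)


# ---------------------------------------------------------------------------
# population sampling

def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Allocate exactly ``n`` items to classes by the largest-remainder rule.

    Realized counts are the rounded expectations (ties broken by class order),
    so the composition of a sampled population is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {total}, expected 1")
    classes = [c for c in CELL_CLASSES if c in proportions]
    if set(proportions) - set(classes):
        raise ValueError(f"unknown classes: {set(proportions) - set(classes)}")
    quotas = np.array([n * proportions[c] for c in classes])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # stable sort: largest fractional part first, class order breaks ties
    order = sorted(range(len(classes)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return {c: int(k) for c, k in zip(classes, counts)}


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lower, size: int) -> np.ndarray:
    """Draw from N(mean, sd) truncated below at ``lower`` (scalar or array)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (size,))
    if sd == 0:
        return np.maximum(np.full(size, float(mean)), lower)
    a = ndtr((lower - mean) / sd)
    a = np.minimum(a, 1.0 - 1e-12)
    u = a + (1.0 - a) * rng.random(size)
    return mean + sd * ndtri(u)


#: Non-rod class geometry (means/sds in µm): swollen rounded cells and small
#: fragments of broken cells.  Chosen so rounded cells have rod-like areas at
#: aspect ratio ~1 and fragments stay well under 2000 µm² (four times the
#: default minimum segmentation gate).
ROUNDED_DIAMETER_UM = (60.0, 10.0)
FRAGMENT_LENGTH_UM = (35.0, 10.0)
FRAGMENT_WIDTH_UM = (18.0, 5.0)


def sample_population(group_params: dict[str, tuple[float, float]] | str | None = None,
                      n_cells: int = 100,
                      class_proportions: dict[str, float] | None = None,
                      seed: int = 0,
                      multinomial: bool = False) -> list[CellSpec]:
    """Sample a population of :class:`CellSpec` (centers left at the origin;
    use :func:`place_population` to lay them out in fields).

    Parameters
    ----------
    group_params : dict or str
        Map ``feature -> (mean, sd)`` with at least ``length_um`` and
        ``width_um``; or one of the group names in :data:`GROUP_PARAMS`.
        Defaults to the control group.
    class_proportions : dict
        ``class -> fraction`` summing to 1.  Default: 97% intact rods and
        3% rounded cells, the composition of a good fixative-dissociation
        preparation.
    multinomial : bool
        If True, class counts are a multinomial draw instead of the exact
        largest-remainder allocation.
    """
    if group_params is None:
        group_params = "control"
    if isinstance(group_params, str):
        group_params = GROUP_PARAMS[group_params]
    for feat, (m, s) in group_params.items():
        if m < 0:
            raise ValueError(f"negative mean for {feat}")
    if class_proportions is None:
        class_proportions = {"intact_rod": 0.97, "rounded": 0.03}

    if multinomial:
        total = sum(class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        rng0 = np.random.default_rng(seed)
        classes = [c for c in CELL_CLASSES if c in class_proportions]
        draws = rng0.multinomial(n_cells, [class_proportions[c] for c in classes])
        counts = dict(zip(classes, (int(d) for d in draws)))
    else:
        counts = largest_remainder_counts(n_cells, class_proportions)

    rng = np.random.default_rng(seed)
    muL, sdL = group_params["length_um"]
    muW, sdW = group_params["width_um"]
    muS, sdS = group_params.get("sarcomere_period_um", (1.801, 0.034))
    if "volume_um3" in group_params:
        depth_ratio = calibrated_depth_ratio(group_params)
    else:
        depth_ratio = 0.5

    specs: list[CellSpec] = []
    for cls in CELL_CLASSES:
        k = counts.get(cls, 0)
        if k == 0:
            continue
        if cls in ("intact_rod", "touching_pair"):
            W = _truncnorm(rng, muW, sdW, 5.0, k)
            L = _truncnorm(rng, muL, sdL, np.maximum(W, 5.0), k)
            S = _truncnorm(rng, muS, sdS, 0.5, k)
        elif cls == "rounded":
            d = _truncnorm(rng, *ROUNDED_DIAMETER_UM, 20.0, k)
            W = L = d
            S = np.full(k, np.nan)
        else:  # fragment
            L = _truncnorm(rng, *FRAGMENT_LENGTH_UM, 10.0, k)
            W = np.minimum(_truncnorm(rng, *FRAGMENT_WIDTH_UM, 5.0, k), L)
            S = _truncnorm(rng, muS, sdS, 0.5, k)
        theta = rng.uniform(0.0, 180.0, k)
        inten = rng.uniform(0.65, 0.95, k)
        if cls == "touching_pair":
            W2 = _truncnorm(rng, muW, sdW, 5.0, k)
            L2 = _truncnorm(rng, muL, sdL, np.maximum(W2, 5.0), k)
            overlap = rng.uniform(2.0, 8.0, k) * DEFAULT_PIXEL_UM
            shift = rng.uniform(0.15, 0.45, k)
        for i in range(k):
            extra = {}
            if cls == "touching_pair":
                extra = dict(pair_length_um=float(L2[i]),
                             pair_width_um=float(W2[i]),
                             pair_overlap_um=float(overlap[i]),
                             pair_shift_frac=float(shift[i]))
            specs.append(CellSpec(
                cell_class=cls,
                length_um=float(L[i]),
                width_um=float(W[i]),
                orientation_deg=float(theta[i]),
                intensity=float(inten[i]),
                sarcomere_period_um=None if np.isnan(S[i]) else float(S[i]),
                depth_ratio=depth_ratio,
                **extra,
            ))
    return specs


# ---------------------------------------------------------------------------
# 2D rendering

def _capsule_segments(spec: CellSpec) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
    """Decompose a spec into drawn capsules: (endpoint0, endpoint1, width,
    striation period or nan), endpoints in µm (x, y)."""
    th = np.deg2rad(spec.orientation_deg)
    u = np.array([np.cos(th), np.sin(th)])
    n = np.array([-np.sin(th), np.cos(th)])
    c = np.asarray(spec.center_um, dtype=float)
    per = spec.sarcomere_period_um or np.nan

    def caps(center, L, W, period):
        half = max(L - W, 0.0) / 2.0
        return (center - half * u, center + half * u, W, period)

    segs = [caps(c, spec.length_um, spec.width_um,
                 np.nan if spec.cell_class == "rounded" else per)]
    if spec.cell_class == "touching_pair":
        L2 = spec.pair_length_um or spec.length_um
        W2 = spec.pair_width_um or spec.width_um
        d = (spec.width_um + W2) / 2.0 - spec.pair_overlap_um
        c2 = c + d * n + spec.pair_shift_frac * spec.length_um * u
        segs.append(caps(c2, L2, W2, per))
    return segs


def _draw_capsule(xx, yy, p0, p1, width, period, intensity, amp):
    """Return (mask, value) of one capsule over pixel-center coordinate grids
    xx, yy (µm)."""
    d = p1 - p0
    seg_len2 = float(d @ d)
    px = xx - p0[0]
    py = yy - p0[1]
    if seg_len2 > 0:
        t = np.clip((px * d[0] + py * d[1]) / seg_len2, 0.0, 1.0)
    else:
        t = 0.0
    cx = px - t * d[0]
    cy = py - t * d[1]
    dist2 = cx * cx + cy * cy
    mask = dist2 <= (width / 2.0) ** 2
    value = np.full(xx.shape, float(intensity), dtype=np.float32)
    if np.isfinite(period) and period > 0:
        seg_len = np.sqrt(seg_len2)
        mid = (p0 + p1) / 2.0
        if seg_len > 0:
            uhat = d / seg_len
        else:
            uhat = np.array([1.0, 0.0])
        ucoord = (xx - mid[0]) * uhat[0] + (yy - mid[1]) * uhat[1]
        value = value * (1.0 + amp * np.cos(2.0 * np.pi * ucoord / period))
    return mask, value.astype(np.float32)


def render_scene(field_size_px: tuple[int, int] = DEFAULT_FIELD_PX,
                 pixel_size_um: float = DEFAULT_PIXEL_UM,
                 specs: list[CellSpec] | None = None,
                 noise_sd: float = 0.05,
                 seed: int = 0,
                 striation_amp: float = 0.4) -> SyntheticScene:
    """Render a 2D field of view.

    Pixels inside a cell take value ``intensity * (1 + amp cos(2 pi u / s))``
    (striated classes) on a zero background; additive Gaussian noise with
    standard deviation ``noise_sd`` is applied last.  ``label_map`` records
    per-pixel ownership with overlap ties resolved to the lower spec index.
    Identical (specs, seed) input renders bit-identically.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    h, w = int(field_size_px[0]), int(field_size_px[1])
    if h < 64 or w < 64:
        raise ValueError("field must be at least 64 x 64 px")
    specs = list(specs or [])

    image = np.zeros((h, w), dtype=np.float32)
    label_map = np.zeros((h, w), dtype=np.int32)
    clipped: list[bool] = []
    p = pixel_size_um

    for idx, spec in enumerate(specs):
        segs = _capsule_segments(spec)
        xs = [e[k][0] for e in segs for k in (0, 1)]
        ys = [e[k][1] for e in segs for k in (0, 1)]
        wmax = max(e[2] for e in segs)
        pad = wmax / 2.0 + 2 * p
        c0 = int(np.floor((min(xs) - pad) / p))
        c1 = int(np.ceil((max(xs) + pad) / p)) + 1
        r0 = int(np.floor((min(ys) - pad) / p))
        r1 = int(np.ceil((max(ys) + pad) / p)) + 1
        was_clipped = c0 < 0 or r0 < 0 or c1 > w or r1 > h
        c0, c1 = max(c0, 0), min(c1, w)
        r0, r1 = max(r0, 0), min(r1, h)
        if c1 <= c0 or r1 <= r0:
            clipped.append(True)
            continue
        cols = (np.arange(c0, c1) + 0.5) * p
        rows = (np.arange(r0, r1) + 0.5) * p
        xx, yy = np.meshgrid(cols, rows)
        mask = np.zeros(xx.shape, dtype=bool)
        value = np.zeros(xx.shape, dtype=np.float32)
        for p0, p1, width, period in segs:
            m, v = _draw_capsule(xx, yy, p0, p1, width, period,
                                 spec.intensity, striation_amp)
            value = np.where(m, np.maximum(value, v), value)
            mask |= m
        sub_img = image[r0:r1, c0:c1]
        sub_lab = label_map[r0:r1, c0:c1]
        np.maximum(sub_img, np.where(mask, value, 0.0), out=sub_img)
        sub_lab[mask & (sub_lab == 0)] = idx + 1
        border = (mask[0].any() or mask[-1].any()
                  or mask[:, 0].any() or mask[:, -1].any())
        clipped.append(bool(was_clipped and border))

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, image.shape).astype(np.float32)

    return SyntheticScene(
        image=CalibratedImage(image, pixel_size_um, "synthetic-morphology"),
        truth=specs, label_map=label_map, seed=seed, clipped=clipped)


# ---------------------------------------------------------------------------
# placement

def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D segments."""
    def pt_seg(p, s0, s1):
        d = s1 - s0
        L2 = float(d @ d)
        if L2 == 0:
            return float(np.hypot(*(p - s0)))
        t = np.clip(float((p - s0) @ d) / L2, 0.0, 1.0)
        return float(np.hypot(*(p - (s0 + t * d))))

    # segments intersect?
    def ccw(p, q, r):
        return (r[1] - p[1]) * (q[0] - p[0]) > (q[1] - p[1]) * (r[0] - p[0])

    if (ccw(a0, b0, b1) != ccw(a1, b0, b1)
            and ccw(a0, a1, b0) != ccw(a0, a1, b1)):
        return 0.0
    return min(pt_seg(a0, b0, b1), pt_seg(a1, b0, b1),
               pt_seg(b0, a0, a1), pt_seg(b1, a0, a1))


def place_population(specs: list[CellSpec],
                     field_size_px: tuple[int, int] = DEFAULT_FIELD_PX,
                     pixel_size_um: float = DEFAULT_PIXEL_UM,
                     cells_per_field: int = 18,
                     seed: int = 0,
                     gap_um: float = 3.0,
                     max_attempts: int = 300) -> list[list[CellSpec]]:
    """Scatter specs into as many fields of view as needed, without overlap.

    Cells are placed by seeded rejection sampling with an exact
    capsule-to-capsule clearance test; a cell that cannot be placed in the
    current field spills into the next one.  Cells are kept fully inside the
    field so none is edge-clipped.
    """
    h_um = field_size_px[0] * pixel_size_um
    w_um = field_size_px[1] * pixel_size_um
    rng = np.random.default_rng(seed)
    remaining = list(specs)
    fields: list[list[CellSpec]] = []
    while remaining:
        placed: list[CellSpec] = []
        geoms: list[tuple[np.ndarray, np.ndarray, float]] = []
        spill: list[CellSpec] = []
        for spec in remaining:
            if len(placed) >= cells_per_field:
                spill.append(spec)
                continue
            ext = spec.length_um / 2.0 + spec.width_um / 2.0 + gap_um
            if spec.cell_class == "touching_pair":
                ext += spec.length_um / 2.0  # partner offset margin
            if 2 * ext >= min(h_um, w_um):
                raise ValueError("cell larger than the field of view")
            ok = False
            for _ in range(max_attempts):
                cx = rng.uniform(ext, w_um - ext)
                cy = rng.uniform(ext, h_um - ext)
                cand = replace(spec, center_um=(cx, cy))
                segs = [(s[0], s[1], s[2]) for s in _capsule_segments(cand)]
                clear = True
                for p0, p1, width in segs:
                    for q0, q1, width2 in geoms:
                        if (_segment_distance(p0, p1, q0, q1)
                                < (width + width2) / 2.0 + gap_um):
                            clear = False
                            break
                    if not clear:
                        break
                if clear:
                    placed.append(cand)
                    geoms.extend(segs)
                    ok = True
                    break
            if not ok:
                spill.append(spec)
        if not placed:
            # pathological congestion: force the first spec at field center
            spec = spill.pop(0)
            placed.append(replace(spec, center_um=(w_um / 2.0, h_um / 2.0)))
        fields.append(placed)
        remaining = spill
    return fields


# ---------------------------------------------------------------------------
# 3D rendering

def render_stack(spec: CellSpec,
                 voxel_um: tuple[float, float, float] = (0.5, 0.5, 1.0),
                 depth_slices: int | None = None,
                 seed: int = 0,
                 depth_ratio: float | None = None,
                 noise_sd: float = 0.0) -> SyntheticScene:
    """Render one cell as a 3D solid in a small z-stack.

    The solid has the capsule footprint in-plane and elliptical cross-sections
    in z with depth ``D = depth_ratio * W`` (default taken from the spec);
    its analytic volume is recorded in ``truth_volumes_um3``.

    ``voxel_um`` is ordered (x, y, z); the returned ``stack`` array is
    (z, y, x).
    """
    vx, vy, vz = voxel_um
    if min(vx, vy, vz) <= 0:
        raise ValueError("voxel dimensions must be positive")
    if depth_slices is not None and depth_slices < 3:
        raise ValueError("depth_slices must be >= 3")
    ratio = spec.depth_ratio if depth_ratio is None else depth_ratio
    L, W = spec.length_um, spec.width_um
    D = ratio * W

    nx = int(np.ceil((L + W) / vx)) + 4
    ny = int(np.ceil((L + W) / vy)) + 4
    nz = depth_slices or max(int(np.ceil(D / vz)) + 4, 3)
    cx, cy, cz = nx * vx / 2.0, ny * vy / 2.0, nz * vz / 2.0

    th = np.deg2rad(spec.orientation_deg)
    u = np.array([np.cos(th), np.sin(th)])
    half = max(L - W, 0.0) / 2.0
    p0 = np.array([cx, cy]) - half * u
    p1 = np.array([cx, cy]) + half * u

    xs = (np.arange(nx) + 0.5) * vx
    ys = (np.arange(ny) + 0.5) * vy
    zs = (np.arange(nz) + 0.5) * vz
    xx, yy = np.meshgrid(xs, ys)
    d = p1 - p0
    L2 = float(d @ d)
    px = xx - p0[0]
    py = yy - p0[1]
    t = np.clip((px * d[0] + py * d[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    rho2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
    rad2 = (W / 2.0) ** 2
    inside = rho2 <= rad2
    hmax = np.where(inside, (D / 2.0) * np.sqrt(np.clip(1.0 - rho2 / rad2, 0.0, 1.0)), -1.0)
    stack = (np.abs(zs[:, None, None] - cz) <= hmax[None, :, :])
    stack = stack.astype(np.float32) * spec.intensity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, stack.shape).astype(np.float32)

    proj = CalibratedImage(stack.max(axis=0), vx, "synthetic-projection")
    vol = capsule_spheroid_volume(L, W, ratio)
    return SyntheticScene(image=proj, truth=[spec], stack=stack,
                          voxel_um=(vx, vy, vz), seed=seed,
                          truth_volumes_um3=[vol])


def render_cuboid_stack(extent_vox: tuple[int, int, int] = (20, 10, 5),
                        voxel_um: tuple[float, float, float] = (0.5, 0.5, 1.0),
                        pad_vox: int = 2,
                        value: float = 1.0) -> SyntheticScene:
    """Debug solid: an axis-aligned cuboid of ``extent_vox`` (x, y, z) voxels.

    Its analytic volume, ``nx ny nz * vx vy vz``, is exact under voxel
    counting, which makes it the reference fixture for volume measurement.
    """
    nx, ny, nz = extent_vox
    vx, vy, vz = voxel_um
    if min(vx, vy, vz) <= 0:
        raise ValueError("voxel dimensions must be positive")
    stack = np.zeros((nz + 2 * pad_vox, ny + 2 * pad_vox, nx + 2 * pad_vox),
                     dtype=np.float32)
    stack[pad_vox:pad_vox + nz, pad_vox:pad_vox + ny, pad_vox:pad_vox + nx] = value
    vol = nx * ny * nz * vx * vy * vz
    spec = CellSpec("intact_rod", length_um=nx * vx, width_um=min(nx, ny) * min(vx, vy))
    proj = CalibratedImage(stack.max(axis=0), vx, "synthetic-cuboid")
    return SyntheticScene(image=proj, truth=[spec], stack=stack,
                          voxel_um=(vx, vy, vz), truth_volumes_um3=[vol])


# ---------------------------------------------------------------------------
# scene export

def truth_table(scene: SyntheticScene) -> pd.DataFrame:
    """One row per ground-truth object."""
    rows = []
    for i, s in enumerate(scene.truth):
        rows.append({
            "label": i + 1,
            "cell_class": s.cell_class,
            "length_um": s.length_um,
            "width_um": s.width_um,
            "orientation_deg": s.orientation_deg,
            "center_x_um": s.center_um[0],
            "center_y_um": s.center_um[1],
            "intensity": s.intensity,
            "sarcomere_period_um": s.sarcomere_period_um,
            "clipped": scene.clipped[i] if i < len(scene.clipped) else False,
        })
    return pd.DataFrame(rows)


def write_scene(scene: SyntheticScene, out_dir, prefix: str = "scene") -> None:
    """Write image (TIFF), label map (16-bit TIFF), truth CSV and a JSON spec."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tiff(out / f"{prefix}_image.tif", scene.image)
    if scene.label_map is not None:
        lab = CalibratedImage(scene.label_map.astype(np.uint16),
                              scene.image.pixel_size_um, "labels")
        write_tiff(out / f"{prefix}_labels.tif", lab)
    if scene.stack is not None and scene.voxel_um is not None:
        write_stack(out / f"{prefix}_stack.tif", scene.stack, scene.voxel_um)
    truth_table(scene).to_csv(out / f"{prefix}_truth.csv", index=False)
    spec_json = {
        "seed": scene.seed,
        "pixel_size_um": scene.image.pixel_size_um,
        "field_size_px": list(scene.image.shape),
        "truth": [dataclasses.asdict(s) for s in scene.truth],
    }
    (out / f"{prefix}_spec.json").write_text(
        json.dumps(spec_json, indent=2, sort_keys=True))
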