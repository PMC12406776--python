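"""Synthetic two-channel astrocyte images with complete ground truth.

Generates a branched astrocyte-like cell — a wide soma disk with levels of
radiating processes whose width decreases with hierarchy depth — places
elliptical mitochondria on chosen branches, and renders both channels as
constant-intensity rasters with optional additive pseudo-normal noise.
Because the generator knows every branch polyline, width, intended
hierarchy type and mitochondrion placement, every pipeline stage can be
verified against ground truth without any external data.

The default geometry emulates a cultured astrocyte imaged at roughly
0.2-0.3 µm/px: a ~24 px soma, 4-5 primary processes of ~9 px width,
secondary processes of ~5 px, and fine distal processes rendered 1-2 px
wide, on a 512x512 16-bit canvas.  Mitochondria are small ellipses
(4-16 px) elongated along their host branch and clipped to the cell body,
mirroring organelles confined to the cytoplasm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .hierarchy import BranchType
from .image import Image2D

__all__ = [
    "ArborSpec",
    "GTBranch",
    "GTMito",
    "GroundTruth",
    "generate_arbor",
    "place_mitochondria",
    "render_image",
    "rasterize",
    "branch_type_agreement",
]

_S8 = np.ones((3, 3), dtype=bool)

# background 100 emulates a camera offset: the stress noise level
# (sd = contrast/5 = 28) then stays clear of the zero-clip
DEFAULT_INTENSITIES = {"background": 100.0, "cell": 240.0, "mito": 240.0}
DEFAULT_MITO_SIZE_RANGES = {
    BranchType.SOMA_PRIMARY: (10, 20),
    BranchType.SECONDARY: (8, 16),
    BranchType.FINE: (5, 9),
    BranchType.TERMINAL: (5, 8),
}


@dataclass(frozen=True)
class ArborSpec:
    """Parameters of a random arbor; widths strictly decrease with level."""

    canvas: tuple = (512, 512)
    soma_radius: float = 12.0
    n_levels: int = 3
    # children per level; minimum 2 below the top so every level transition
    # sits at a branchpoint (the hierarchy is branchpoint-delimited)
    branch_counts: tuple = ((4, 5), (2, 2), (2, 2))
    length_ranges: tuple = ((55.0, 80.0), (40.0, 60.0), (25.0, 40.0))
    widths: tuple = (9.0, 5.0, 2.0)
    tortuosity: float = 12.0  # max bend per step, degrees
    step: float = 3.0
    fine_width: float = 3.0  # at or below this width, a branch is intended FINE
    tip_length: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels >= 1 required")
        for name in ("branch_counts", "length_ranges", "widths"):
            if len(getattr(self, name)) != self.n_levels:
                raise ValueError(f"{name} must have one entry per level")
        if any(w2 >= w1 for w1, w2 in zip(self.widths, self.widths[1:])):
            raise ValueError("widths must strictly decrease with level")
        if self.soma_radius <= 0 or self.step <= 0 or self.widths[-1] <= 0:
            raise ValueError("soma_radius, step and widths must be positive")
        if any(lo <= 0 or hi < lo for lo, hi in self.length_ranges):
            raise ValueError("length ranges must be positive")
        if any(lo < 0 or hi < lo for lo, hi in self.branch_counts):
            raise ValueError("branch count ranges must be non-negative")


@dataclass
class GTBranch:
    id: int
    level: int  # 0 = primary
    parent: int  # parent branch id, -1 for soma
    poly: np.ndarray  # (n, 2) float vertices as (row, col)
    width: float
    intended_type: BranchType
    is_leaf: bool = False
    tip_length: int = 5

    def point_at(self, frac: float) -> tuple[np.ndarray, float]:
        """Point at a fraction of arc length and the local heading (rad)."""
        seg = np.diff(self.poly, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        target = frac * cum[-1]
        i = min(int(np.searchsorted(cum, target, side="right")) - 1, len(seg) - 1)
        local = (target - cum[i]) / seglen[i] if seglen[i] else 0.0
        pt = self.poly[i] + local * seg[i]
        heading = math.atan2(seg[i, 0], seg[i, 1])
        return pt, heading

    @property
    def arclength(self) -> float:
        seg = np.diff(self.poly, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


@dataclass
class GTMito:
    id: int
    center: tuple  # (row, col)
    axes: tuple  # (semi-major, semi-minor)
    angle: float  # orientation of the major axis, rad
    host_branch: int  # branch id, -1 for soma
    intended_type: BranchType
    rows: np.ndarray = None
    cols: np.ndarray = None
    size: int = 0  # realized pixel count after clipping to the cell


@dataclass
class GroundTruth:
    spec: ArborSpec
    soma_center: tuple
    soma_radius: float
    branches: list
    mitos: list = field(default_factory=list)
    noise_sd: float = 0.0
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    _rasters: dict = field(default_factory=dict, repr=False)

    def intended_counts(self) -> dict:
        """Branch counts per intended type (tips counted per leaf)."""
        counts = {t: 0 for t in BranchType}
        counts[BranchType.SOMA_PRIMARY] = 1
        for b in self.branches:
            counts[b.intended_type] += 1
            if b.is_leaf:
                counts[BranchType.TERMINAL] += 1
        return counts

    def mito_counts(self) -> dict:
        counts = {t: 0 for t in BranchType}
        for mt in self.mitos:
            counts[mt.intended_type] += 1
        return counts


def _grow_polyline(rng, start, heading, length, step, tortuosity_rad):
    pts = [np.asarray(start, dtype=float)]
    n = max(int(round(length / step)), 2)
    h = heading
    for _ in range(n):
        h += rng.uniform(-tortuosity_rad, tortuosity_rad)
        pts.append(pts[-1] + step * np.array([math.sin(h), math.cos(h)]))
    return np.array(pts), h


def generate_arbor(spec: ArborSpec) -> GroundTruth:
    """Seeded random arbor: soma disk plus levels of radiating branches.

    Children attach at the distal endpoint of their parent with diverging
    headings, so each ground-truth branch maps to exactly one skeleton
    branch between consecutive branchpoints.  Raises if any branch would
    leave the canvas.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    center = np.array([h / 2.0, w / 2.0])
    tort = math.radians(spec.tortuosity)
    branches: list[GTBranch] = []
    # occupancy raster (1-px moat) for collision avoidance: branches from
    # different subtrees must never touch, or spurious junctions would
    # corrupt the ground-truth topology
    occupied = np.zeros((h, w), dtype=bool)
    halos: dict[int, np.ndarray] = {}  # per-branch dilated ribbon
    grid_r, grid_c = np.mgrid[0:h, 0:w]
    soma_mask = (grid_r - h / 2.0) ** 2 + (grid_c - w / 2.0) ** 2 <= spec.soma_radius**2
    soma_halo = ndi.binary_dilation(soma_mask, structure=_S8)

    def in_bounds(poly, width):
        margin = width / 2.0 + 2.0
        return (
            poly[:, 0].min() >= margin
            and poly[:, 1].min() >= margin
            and poly[:, 0].max() <= h - 1 - margin
            and poly[:, 1].max() <= w - 1 - margin
        )

    def intended(level, width):
        if level == 0:
            return BranchType.SOMA_PRIMARY
        if level >= 2 or width <= spec.fine_width:
            return BranchType.FINE
        return BranchType.SECONDARY

    def spawn(level, start, heading, parent_id, parent_width):
        lo, hi = spec.length_ranges[level]
        width = spec.widths[level]
        allowed_r = width / 2.0 + parent_width / 2.0 + 4.0
        parent_halo = soma_halo if parent_id < 0 else halos[parent_id]
        rib = None
        for attempt in range(60):
            length = rng.uniform(lo, hi)
            jitter = rng.uniform(-0.1, 0.1) * attempt
            poly, final_h = _grow_polyline(rng, start, heading + jitter, length, spec.step, tort)
            if not in_bounds(poly, width):
                continue
            rib = _ribbon(poly, width, (h, w))
            near_start = (grid_r - start[0]) ** 2 + (grid_c - start[1]) ** 2 <= allowed_r**2
            # may touch only the parent (or soma), and only at the attachment
            if (rib & occupied & ~parent_halo).any() or (rib & parent_halo & ~near_start).any():
                rib = None
                continue
            break
        if rib is None:
            raise ValueError("arbor exceeds canvas")
        halo = ndi.binary_dilation(rib, structure=_S8)
        occupied[halo] = True
        b = GTBranch(
            id=len(branches),
            level=level,
            parent=parent_id,
            poly=poly,
            width=width,
            intended_type=intended(level, width),
            tip_length=spec.tip_length,
        )
        branches.append(b)
        halos[b.id] = halo
        if level + 1 < spec.n_levels:
            clo, chi = spec.branch_counts[level + 1]
            k = int(rng.integers(clo, chi + 1))
            if k == 0:
                b.is_leaf = True
                return
            offs = np.linspace(-0.9, 0.9, k) if k > 1 else np.array([0.0])
            for off in offs:
                child_h = final_h + off + rng.uniform(-0.12, 0.12)
                spawn(level + 1, poly[-1], child_h, b.id, width)
        else:
            b.is_leaf = True

    nlo, nhi = spec.branch_counts[0]
    last_err = None
    for _restart in range(20):  # a blocked subtree restarts the whole arbor
        branches.clear()
        halos.clear()
        occupied[:] = False
        occupied |= soma_halo  # nothing but a primary may touch the soma
        try:
            n0 = int(rng.integers(nlo, nhi + 1))
            base = rng.uniform(0, 2 * math.pi)
            spacing = 2 * math.pi / max(n0, 1)
            for i in range(n0):
                ang = base + i * spacing + rng.uniform(-0.2, 0.2) * spacing
                start = center + (spec.soma_radius - 1.0) * np.array([math.sin(ang), math.cos(ang)])
                spawn(0, start, ang, -1, 2.0 * spec.soma_radius)
            break
        except ValueError as exc:
            last_err = exc
    else:
        raise ValueError("arbor exceeds canvas") from last_err

    return GroundTruth(spec=spec, soma_center=tuple(center), soma_radius=spec.soma_radius, branches=branches)


def _polyline_pixels(poly: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray]:
    """1-px raster of a polyline, thickened to 4-connectivity.

    Diagonal steps get a connector pixel so that even 1-px-wide branches
    form a single 4-connected component, like real ribbons wider than the
    pixel grid.
    """
    rs, cs = [], []
    v = np.round(poly).astype(int)
    for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        diag = np.flatnonzero((np.diff(rr) != 0) & (np.diff(cc) != 0))
        if diag.size:
            # insert a connector pixel in path order at each diagonal step
            rr = np.insert(rr, diag + 1, rr[diag])
            cc = np.insert(cc, diag + 1, cc[diag + 1])
        rs.append(rr)
        cs.append(cc)
    rr = np.clip(np.concatenate(rs), 0, shape[0] - 1)
    cc = np.clip(np.concatenate(cs), 0, shape[1] - 1)
    # dedupe while preserving order along the path
    flat = rr * shape[1] + cc
    _, first = np.unique(flat, return_index=True)
    keep = np.sort(first)
    return rr[keep], cc[keep]


def _ribbon(poly: np.ndarray, width: float, shape) -> np.ndarray:
    """Pixels within (strictly) width/2 of the polyline raster."""
    rr, cc = _polyline_pixels(poly, shape)
    pad = int(math.ceil(width / 2.0)) + 2
    r0 = max(int(rr.min()) - pad, 0)
    r1 = min(int(rr.max()) + pad + 1, shape[0])
    c0 = max(int(cc.min()) - pad, 0)
    c1 = min(int(cc.max()) + pad + 1, shape[1])
    crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    crop[rr - r0, cc - c0] = True
    if width > 2.0:
        d = ndi.distance_transform_edt(~crop)
        crop = d < width / 2.0
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = crop
    return out


def rasterize(gt: GroundTruth) -> dict:
    """Ground-truth rasters: cell mask, per-branch ribbons, type labels.

    The branch-type label raster paints the soma first, then branches from
    coarse to fine (deeper levels on top where ribbons overlap at
    junctions), then the TERMINAL tip ribbon of every leaf.
    """
    if "cell" in gt._rasters:
        return gt._rasters
    h, w = gt.spec.canvas
    rr, cc = np.mgrid[0:h, 0:w]
    soma = (rr - gt.soma_center[0]) ** 2 + (cc - gt.soma_center[1]) ** 2 <= gt.soma_radius**2
    cell = soma.copy()
    type_map = np.zeros((h, w), dtype=np.uint8)
    branch_ribbons = {}
    for b in sorted(gt.branches, key=lambda b: b.level):
        rib = _ribbon(b.poly, b.width, (h, w))
        branch_ribbons[b.id] = rib
        cell |= rib
    type_map[soma] = int(BranchType.SOMA_PRIMARY)
    for b in sorted(gt.branches, key=lambda b: b.level):
        type_map[branch_ribbons[b.id] & ~soma] = int(b.intended_type)
    for b in gt.branches:
        if not b.is_leaf:
            continue
        L = b.arclength
        frac = max(1.0 - b.tip_length / L, 0.0)
        n = len(b.poly)
        i0 = min(int(frac * (n - 1)), n - 2)
        tip_rib = _ribbon(b.poly[i0:], b.width, (h, w))
        type_map[tip_rib & ~soma] = int(BranchType.TERMINAL)
    gt._rasters.update(cell=cell, type_map=type_map, branch_ribbons=branch_ribbons, soma=soma)
    return gt._rasters


def place_mitochondria(
    gt: GroundTruth,
    counts: dict,
    size_ranges: dict | None = None,
    seed: int = 0,
    max_tries: int = 200,
    min_size: int = 5,
) -> GroundTruth:
    """Place non-overlapping elliptical mitochondria on host branches.

    ``counts`` maps BranchType -> number of mitochondria.  Centers sit on
    the host branch centerline: mid-branch (30-70% of arc length) for
    SECONDARY/FINE hosts, half a tip length from the leaf end for TERMINAL,
    inside the soma disk for SOMA_PRIMARY.  Ellipses are elongated along
    the local branch direction and clipped to the cell raster; the realized
    (clipped) pixel set defines the ground-truth size.  Placements keep a
    1-px gap so detections cannot merge.  Raises after bounded retries if a
    request cannot be packed.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(DEFAULT_MITO_SIZE_RANGES)
    if size_ranges:
        sizes.update(size_ranges)
    rasters = rasterize(gt)
    cell = rasters["cell"]
    h, w = cell.shape
    occupied = np.zeros_like(cell)
    mitos = list(gt.mitos)

    def hosts_for(btype):
        if btype == BranchType.TERMINAL:
            return [b for b in gt.branches if b.is_leaf]
        if btype == BranchType.SOMA_PRIMARY:
            return [None]
        return [b for b in gt.branches if b.intended_type == btype]

    def ellipse_pixels(center, a, bb, ang):
        pad = int(math.ceil(a)) + 1
        r0 = max(int(center[0]) - pad, 0)
        r1 = min(int(center[0]) + pad + 1, h)
        c0 = max(int(center[1]) - pad, 0)
        c1 = min(int(center[1]) + pad + 1, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dy = rr - center[0]
        dx = cc - center[1]
        u = dy * math.sin(ang) + dx * math.cos(ang)
        v = -dy * math.cos(ang) + dx * math.sin(ang)
        inside = (u / a) ** 2 + (v / max(bb, 0.5)) ** 2 <= 1.0
        return rr[inside], cc[inside]

    for btype in (BranchType.SOMA_PRIMARY, BranchType.SECONDARY, BranchType.FINE, BranchType.TERMINAL):
        want = int(counts.get(btype, 0))
        if want == 0:
            continue
        hlist = hosts_for(btype)
        if not hlist:
            raise ValueError(f"no host branches for {btype.name}")
        lo, hi = sizes[btype]
        for _i in range(want):
            placed = False
            for _try in range(max_tries):
                host = hlist[int(rng.integers(len(hlist)))]
                target = rng.uniform(lo, hi)
                if host is None:
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = rng.uniform(0, gt.soma_radius * 0.55)
                    center = (
                        gt.soma_center[0] + rad * math.sin(ang),
                        gt.soma_center[1] + rad * math.cos(ang),
                    )
                    heading = rng.uniform(0, math.pi)
                    bmin = 1.5
                    host_id = -1
                elif btype == BranchType.TERMINAL:
                    L = host.arclength
                    frac = max(1.0 - (host.tip_length / 2.0) / L, 0.0)
                    pt, heading = host.point_at(frac)
                    center = tuple(pt)
                    bmin = max(min(host.width / 2.0, 1.5), 0.8)
                    host_id = host.id
                else:
                    # keep a clear margin from the terminal-tip compartment:
                    # the tip zone spans the tip length plus the few pixels
                    # the thinned skeleton retracts from the ribbon end
                    L = host.arclength
                    hi_frac = max(0.35, min(0.70, 1.0 - (host.tip_length + 7.0) / L))
                    pt, heading = host.point_at(rng.uniform(0.30, hi_frac))
                    center = tuple(pt)
                    bmin = max(min(host.width / 2.0, 2.0), 0.8)
                    host_id = host.id
                a = max(target / (math.pi * bmin), 1.5)
                rr, cc = ellipse_pixels(center, a, bmin, heading)
                if rr.size == 0:
                    continue
                keep = cell[rr, cc]
                rr, cc = rr[keep], cc[keep]
                if rr.size < min_size:
                    continue
                # the clipped organelle must stay one 4-connected piece
                r0, c0 = int(rr.min()), int(cc.min())
                blob = np.zeros((int(rr.max()) - r0 + 1, int(cc.max()) - c0 + 1), dtype=bool)
                blob[rr - r0, cc - c0] = True
                _lab, ncomp = ndi.label(blob)
                if ncomp != 1:
                    continue
                # require a 1-px moat around existing mitochondria
                moat = ndi.binary_dilation(occupied, structure=_S8)
                if moat[rr, cc].any():
                    continue
                m = GTMito(
                    id=len(mitos),
                    center=center,
                    axes=(a, bmin),
                    angle=heading,
                    host_branch=host_id,
                    intended_type=btype,
                    rows=rr,
                    cols=cc,
                    size=int(rr.size),
                )
                mitos.append(m)
                occupied[rr, cc] = True
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place a {btype.name} mitochondrion after {max_tries} tries")
    return replace(gt, mitos=mitos, _rasters=gt._rasters)


def render_image(gt: GroundTruth, intensities: dict | None = None, noise_sd: float | None = None, seed: int = 0):
    """Render the two channels plus ground-truth label rasters.

    Returns ``(cell_img, mito_img, labels)`` where labels holds the exact
    cell mask, the intended branch-type map and the mito instance map.
    Noise is additive pseudo-normal with the given sd (clipped at zero),
    seeded and reproducible.
    """
    inten = dict(gt.intensities)
    if intensities:
        inten.update(intensities)
    sd = gt.noise_sd if noise_sd is None else float(noise_sd)
    rasters = rasterize(gt)
    cell_mask = rasters["cell"]
    h, w = cell_mask.shape

    cell = np.full((h, w), inten["background"], dtype=float)
    cell[cell_mask] = inten["cell"]
    mito = np.full((h, w), inten["background"], dtype=float)
    mito_labels = np.zeros((h, w), dtype=np.int32)
    for mt in gt.mitos:
        mito[mt.rows, mt.cols] = inten["mito"]
        mito_labels[mt.rows, mt.cols] = mt.id + 1

    if sd > 0:
        rng = np.random.default_rng(seed)
        cell = cell + rng.normal(0.0, sd, size=cell.shape)
        mito = mito + rng.normal(0.0, sd, size=mito.shape)
    cell = np.clip(cell, 0, None)
    mito = np.clip(mito, 0, None)
    labels = {
        "cell_mask": cell_mask,
        "branch_type": rasters["type_map"],
        "mito": mito_labels,
    }
    return Image2D(cell), Image2D(mito), labels


def branch_type_agreement(gt: GroundTruth, type_map: np.ndarray) -> float:
    """Fraction of ground-truth branch units whose type is recovered.

    A unit is a branch body (centerline raster, minus the tip for leaves)
    or a leaf tip; it agrees when the majority pipeline type over its
    centerline pixels (where the pipeline assigned any type) equals the
    intended type.
    """
    shape = type_map.shape
    units = []
    for b in gt.branches:
        rr, cc = _polyline_pixels(b.poly, shape)  # ordered along the path
        if b.is_leaf and rr.size > b.tip_length:
            cut = rr.size - b.tip_length
            units.append((int(b.intended_type), rr[:cut], cc[:cut]))
            units.append((int(BranchType.TERMINAL), rr[cut:], cc[cut:]))
        elif b.is_leaf:
            units.append((int(BranchType.TERMINAL), rr, cc))
        else:
            units.append((int(b.intended_type), rr, cc))
    agree = 0
    for want, rr, cc in units:
        codes = type_map[rr, cc]
        codes = codes[codes > 0]
        if codes.size == 0:
            continue
        got = np.bincount(codes, minlength=5)[1:].argmax() + 1
        if got == want:
            agree += 1
    return agree / len(units) if units else 1.0
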