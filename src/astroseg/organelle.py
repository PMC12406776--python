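"""Mitochondria: detection inside a cell mask, branch-type binning, stats.

Mitochondria are detected in the organelle channel with the same
locally-significant-region detector used for the cell, restricted to the
cell mask.  Each mitochondrion is then binned into the branch type that
holds the plurality of its pixels (ties resolved toward the finer type),
and per-type counts and mean sizes are reported.  Measurements from the
soma and primary branches are excluded from the reported statistics —
mitochondria form a dense network there that cannot be resolved into
discrete organelles — but they are still counted in ``excluded_mito_count``
so the bookkeeping is conservative: reported + excluded = detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import NoiseEstimate, detect_regions, estimate_noise
from .hierarchy import BranchType, TypedArbor
from .image import as_image
from .linkage import CellMask

__all__ = [
    "Mitochondrion",
    "CellProfile",
    "EXCLUDED_SOMA_PRIMARY",
    "detect_mitochondria",
    "assign_mitochondria",
    "mito_stats",
]

EXCLUDED_SOMA_PRIMARY = "EXCLUDED_SOMA_PRIMARY"
REPORTED_TYPES = (BranchType.SECONDARY, BranchType.FINE, BranchType.TERMINAL)


@dataclass
class Mitochondrion:
    id: int
    rows: np.ndarray
    cols: np.ndarray
    size: int  # area in px
    mean_intensity: float
    zscore: float
    pixel_size: float = 1.0
    assigned_type: object = None  # BranchType or EXCLUDED_SOMA_PRIMARY

    @property
    def pixels(self):
        return self.rows, self.cols

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    @property
    def size_um2(self) -> float:
        return self.size * self.pixel_size**2

    @property
    def excluded(self) -> bool:
        return self.assigned_type == EXCLUDED_SOMA_PRIMARY


def detect_mitochondria(
    mito_img,
    mask,
    alpha: float = 1e-3,
    min_area: int = 5,
    max_area: int = 400,
    *,
    ring_width: int = 2,
    connectivity: int = 1,
    noise: NoiseEstimate | None = None,
) -> list[Mitochondrion]:
    """Detect mitochondria in the organelle channel within a cell mask.

    Pixels outside the mask are suppressed to the background median before
    detection (noise is estimated on the unsuppressed image), and the
    resulting regions are clipped back to the mask.
    """
    im = as_image(mito_img)
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if m.shape != im.shape:
        raise ValueError("mito image and cell mask shapes differ")
    a = im.pixels.astype(float)
    if noise is None:
        noise = estimate_noise(im)
    outside = ~m
    bg = float(np.median(a[outside])) if outside.any() else float(np.median(a))
    work = a.copy()
    work[outside] = bg
    frags = detect_regions(
        work,
        alpha=alpha,
        min_area=min_area,
        max_area=max_area,
        noise=noise,
        ring_width=ring_width,
        connectivity=connectivity,
    )
    mitos = []
    for f in frags:
        keep = m[f.rows, f.cols]
        rr, cc = f.rows[keep], f.cols[keep]
        if rr.size < min_area:
            continue
        mitos.append(
            Mitochondrion(
                id=len(mitos),
                rows=rr,
                cols=cc,
                size=int(rr.size),
                mean_intensity=float(a[rr, cc].mean()),
                zscore=f.zscore,
                pixel_size=im.pixel_size,
            )
        )
    return mitos


def assign_mitochondria(mitos, arbor: TypedArbor) -> list:
    """Bin each mitochondrion into the branch type holding the plurality of
    its pixels; ties break toward the finer type.  Soma/primary assignments
    are marked excluded."""
    tm = arbor.type_map
    out = []
    for mt in mitos:
        codes = tm[mt.rows, mt.cols]
        if (codes == 0).any():
            raise ValueError("mitochondrion outside cell")
        counts = np.bincount(codes, minlength=5)
        best = max(
            (t for t in BranchType),
            key=lambda t: (counts[int(t)], int(t)),  # plurality, then finer
        )
        mt.assigned_type = EXCLUDED_SOMA_PRIMARY if best == BranchType.SOMA_PRIMARY else best
        out.append(mt)
    return out


@dataclass
class CellProfile:
    """Per-cell output: branch counts, mito counts and mean sizes per type.

    Mitochondrial statistics are reported only for SECONDARY, FINE and
    TERMINAL; soma/primary mitochondria appear only in
    ``excluded_mito_count``.  Mean size is NaN where a type has no
    mitochondria.
    """

    cell_id: int
    branch_count: dict
    mito_count: dict
    mito_mean_size: dict
    excluded_mito_count: int
    total_mito_count: int


def mito_stats(assigned, cell_id: int = 0, branch_count: dict | None = None) -> CellProfile:
    """Summarize assigned mitochondria into a CellProfile."""
    counts = {t: 0 for t in REPORTED_TYPES}
    sizes = {t: [] for t in REPORTED_TYPES}
    excluded = 0
    for mt in assigned:
        if mt.assigned_type == EXCLUDED_SOMA_PRIMARY:
            excluded += 1
        else:
            counts[mt.assigned_type] += 1
            sizes[mt.assigned_type].append(mt.size)
    mean_size = {t: (float(np.mean(sizes[t])) if sizes[t] else math.nan) for t in REPORTED_TYPES}
    return CellProfile(
        cell_id=cell_id,
        branch_count=dict(branch_count or {}),
        mito_count=counts,
        mito_mean_size=mean_size,
        excluded_mito_count=excluded,
        total_mito_count=len(assigned),
    )
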