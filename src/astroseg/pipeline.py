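"""End-to-end pipeline: detect -> link -> hierarchy -> mitochondria -> stats.

Runs the full branched-cell analysis on a two-channel image and emits the
standard artifact files: fragment/edge/branch/mito/profile CSV tables and
label TIFFs.  All stages are deterministic given the configuration, so two
runs with the same inputs produce bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as asio
from .config import PipelineConfig
from .detect import detect_regions, estimate_noise
from .hierarchy import (
    BranchType,
    HierarchyParams,
    branch_counts,
    build_branch_graph,
    classify_branches,
    skeletonize_mask,
)
from .image import as_image
from .linkage import assemble_cells, build_fragment_graph, link_fragments
from .organelle import assign_mitochondria, detect_mitochondria, mito_stats

__all__ = ["PipelineResult", "run_pipeline", "NO_CELL_STATUS"]

log = logging.getLogger("astroseg")

NO_CELL_STATUS = "no significant cell region"

FRAGMENT_COLUMNS = ["id", "area_px", "mean_intensity", "zscore", "centroid_row", "centroid_col"]
EDGE_COLUMNS = ["frag_a", "frag_b", "weight", "in_tree", "kept_after_cut"]
BRANCH_COLUMNS = ["cell_id", "branch_id", "segment_id", "type", "length_px", "mean_width_px", "is_counted"]
MITO_COLUMNS = [
    "mito_id",
    "cell_id",
    "size_px",
    "size_um2",
    "centroid_row",
    "centroid_col",
    "assigned_type",
    "excluded_flag",
]
PROFILE_COLUMNS = [
    "cell_id",
    "branch_count_soma_primary",
    "branch_count_secondary",
    "branch_count_fine",
    "branch_count_terminal",
    "mito_count_secondary",
    "mito_count_fine",
    "mito_count_terminal",
    "mito_mean_size_secondary",
    "mito_mean_size_fine",
    "mito_mean_size_terminal",
    "excluded_mito_count",
    "total_mito_count",
]


@dataclass
class PipelineResult:
    status: str
    profiles: list
    cells: list = field(default_factory=list)
    arbors: list = field(default_factory=list)
    mitos: list = field(default_factory=list)  # list (per cell) of assigned mitochondria
    fragments: list = field(default_factory=list)
    tables: dict = field(default_factory=dict)


def _profile_row(profile):
    bc = profile.branch_count
    return {
        "cell_id": profile.cell_id,
        "branch_count_soma_primary": bc.get(BranchType.SOMA_PRIMARY, 0),
        "branch_count_secondary": bc.get(BranchType.SECONDARY, 0),
        "branch_count_fine": bc.get(BranchType.FINE, 0),
        "branch_count_terminal": bc.get(BranchType.TERMINAL, 0),
        "mito_count_secondary": profile.mito_count[BranchType.SECONDARY],
        "mito_count_fine": profile.mito_count[BranchType.FINE],
        "mito_count_terminal": profile.mito_count[BranchType.TERMINAL],
        "mito_mean_size_secondary": profile.mito_mean_size[BranchType.SECONDARY],
        "mito_mean_size_fine": profile.mito_mean_size[BranchType.FINE],
        "mito_mean_size_terminal": profile.mito_mean_size[BranchType.TERMINAL],
        "excluded_mito_count": profile.excluded_mito_count,
        "total_mito_count": profile.total_mito_count,
    }


def run_pipeline(cfg: PipelineConfig, cell_img, mito_img, out_dir=None) -> PipelineResult:
    """Run the full analysis on one two-channel field of view.

    Returns a PipelineResult with one CellProfile per detected cell
    (largest first).  If no significant cell region is found the status is
    ``NO_CELL_STATUS`` and all tables are header-only.
    """
    cell = as_image(cell_img, pixel_size=cfg.pixel_size)
    mito = as_image(mito_img, pixel_size=cfg.pixel_size)
    if cell.shape != mito.shape:
        raise ValueError("cell and mito images must have the same shape")

    t0 = time.perf_counter()
    noise = estimate_noise(cell)
    log.info("noise: sigma=%.3f", noise.sigma)

    # a cell should not fill the field of view; unlimited max_area would let
    # a noise-background mega-component win selection on noisy images
    max_area_cell = cfg.max_area_cell if cfg.max_area_cell > 0 else cell.pixels.size // 4
    fragments = detect_regions(
        cell,
        alpha=cfg.alpha_cell,
        min_area=cfg.min_area_cell,
        max_area=max_area_cell,
        noise=noise,
        ring_width=cfg.ring_width,
        connectivity=cfg.connectivity,
    )
    log.info("detect: %d cell fragments (alpha=%g, min_area=%d)", len(fragments), cfg.alpha_cell, cfg.min_area_cell)

    tables = {}
    frag_rows = [
        {
            "id": f.id,
            "area_px": f.area,
            "mean_intensity": f.mean_intensity,
            "zscore": f.zscore,
            "centroid_row": f.centroid[0],
            "centroid_col": f.centroid[1],
        }
        for f in fragments
    ]
    tables["fragments"] = pd.DataFrame(frag_rows, columns=FRAGMENT_COLUMNS)

    if not fragments:
        for name, cols in (
            ("edges", EDGE_COLUMNS),
            ("branches", BRANCH_COLUMNS),
            ("mitochondria", MITO_COLUMNS),
            ("profiles", PROFILE_COLUMNS),
        ):
            tables[name] = pd.DataFrame(columns=cols)
        result = PipelineResult(status=NO_CELL_STATUS, profiles=[], tables=tables)
        if out_dir is not None:
            _write_outputs(cfg, result, cell.shape, out_dir)
        return result

    envelope = cfg.envelope if cfg.envelope > 0 else None
    graph = build_fragment_graph(cell, fragments, envelope=envelope)
    tree = link_fragments(graph)
    min_link = cfg.min_link_weight if cfg.min_link_weight >= 0 else None
    cells = assemble_cells(cell, fragments, tree, min_link_weight=min_link)
    log.info("linkage: %d fragments -> %d cell masks", len(fragments), len(cells))

    in_tree = {(u, v) for u, v, _w, _p in tree.edges}
    if min_link is None and fragments:
        tot = sum(f.area for f in fragments)
        min_link = 0.5 * sum(f.mean_intensity * f.area for f in fragments) / tot
    edge_rows = []
    for u, v, data in sorted(graph.edges(data=True)):
        uu, vv = (u, v) if u <= v else (v, u)
        w = float(data.get("weight", 0.0))
        edge_rows.append(
            {
                "frag_a": uu,
                "frag_b": vv,
                "weight": w,
                "in_tree": (uu, vv) in in_tree,
                "kept_after_cut": (uu, vv) in in_tree and w >= min_link,
            }
        )
    tables["edges"] = pd.DataFrame(edge_rows, columns=EDGE_COLUMNS)

    hp = HierarchyParams(
        theta_soma=cfg.theta_soma,
        theta_primary=cfg.theta_primary,
        theta_fine=cfg.theta_fine,
        l_tip=cfg.l_tip,
        spur_len=cfg.spur_len,
    )

    if cfg.mask_fill_sigma > 0:
        cells = [_complete_mask(cell.pixels, cm, noise.sigma, cfg.mask_fill_sigma) for cm in cells]

    profiles, arbors, all_assigned = [], [], []
    branch_rows, mito_rows = [], []
    kept_cells = []
    mito_id = 0
    for cid, cm in enumerate(cells):
        if cm.area < 9:
            continue
        kept_cells.append((cid, cm))
        skel = skeletonize_mask(cm)
        bg = build_branch_graph(skel, spur_len=cfg.spur_len)
        arbor = classify_branches(bg, hp)
        bc = branch_counts(arbor)
        mitos = detect_mitochondria(
            mito,
            cm,
            alpha=cfg.alpha_mito,
            min_area=cfg.min_area_mito,
            max_area=cfg.max_area_mito,
            ring_width=cfg.ring_width,
            connectivity=cfg.connectivity,
        )
        assigned = assign_mitochondria(mitos, arbor)
        profile = mito_stats(assigned, cell_id=cid, branch_count=bc)
        log.info(
            "cell %d: area=%d, branches=%s, mitochondria=%d (%d excluded)",
            cid,
            cm.area,
            {t.name: bc[t] for t in BranchType},
            profile.total_mito_count,
            profile.excluded_mito_count,
        )
        profiles.append(profile)
        arbors.append(arbor)
        all_assigned.append(assigned)
        for s in arbor.segments:
            branch_rows.append(
                {
                    "cell_id": cid,
                    "branch_id": s.branch_id,
                    "segment_id": s.id,
                    "type": s.type.name,
                    "length_px": len(s.pixels),
                    "mean_width_px": s.mean_width,
                    "is_counted": s.counted,
                }
            )
        for mt in assigned:
            mito_rows.append(
                {
                    "mito_id": mito_id,
                    "cell_id": cid,
                    "size_px": mt.size,
                    "size_um2": mt.size * cfg.pixel_size**2,
                    "centroid_row": mt.centroid[0],
                    "centroid_col": mt.centroid[1],
                    "assigned_type": mt.assigned_type if isinstance(mt.assigned_type, str) else mt.assigned_type.name,
                    "excluded_flag": mt.excluded,
                }
            )
            mito_id += 1

    tables["branches"] = pd.DataFrame(branch_rows, columns=BRANCH_COLUMNS)
    tables["mitochondria"] = pd.DataFrame(mito_rows, columns=MITO_COLUMNS)
    tables["profiles"] = pd.DataFrame([_profile_row(p) for p in profiles], columns=PROFILE_COLUMNS)

    status = "ok" if profiles else NO_CELL_STATUS
    result = PipelineResult(
        status=status,
        profiles=profiles,
        cells=[cm for _cid, cm in kept_cells],
        arbors=arbors,
        mitos=all_assigned,
        fragments=fragments,
        tables=tables,
    )
    log.info("pipeline finished in %.2f s (status: %s)", time.perf_counter() - t0, status)
    if out_dir is not None:
        _write_outputs(cfg, result, cell.shape, out_dir)
    return result


def _complete_mask(pixels, cm, sigma, k):
    """Hysteresis completion of a cell mask.

    The significance-optimal threshold can drop the dimmest distal pixels of
    thin processes; grow the mask with 8-connected pixels strictly above
    background median + k*sigma that touch it, which recovers those pixels
    at a permissive but still above-background level.
    """
    from scipy import ndimage as ndi

    from .linkage import CellMask

    bg = float(np.median(pixels[~cm.mask])) if (~cm.mask).any() else float(np.median(pixels))
    grow = (pixels > bg + k * sigma) | cm.mask
    lab, _n = ndi.label(grow, structure=np.ones((3, 3), bool))
    keep = np.unique(lab[cm.mask])
    keep = keep[keep > 0]
    newmask = np.isin(lab, keep)
    return CellMask(mask=newmask, member_ids=cm.member_ids)


def _write_outputs(cfg: PipelineConfig, result: PipelineResult, shape, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name, df in result.tables.items():
        asio.write_table(os.path.join(out_dir, f"{name}.csv"), df)
    cell_labels = np.zeros(shape, dtype=np.uint16)
    type_labels = np.zeros(shape, dtype=np.uint16)
    for k, (cm, arbor) in enumerate(zip(result.cells, result.arbors), start=1):
        cell_labels[cm.mask] = k
        type_labels[cm.mask] = arbor.type_map[cm.mask]
    asio.write_label_tiff(os.path.join(out_dir, "cell_labels.tif"), cell_labels)
    asio.write_label_tiff(os.path.join(out_dir, "branch_type_labels.tif"), type_labels)
    cfg.to_file(os.path.join(out_dir, "config.txt"))
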