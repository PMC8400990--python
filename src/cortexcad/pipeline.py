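"""End-to-end feature extraction for one subject.

Glues the stages together: mask the scan, pick the isovalue, reconstruct
the cortical surface, estimate per-vertex curvature descriptors, label
vertices with the atlas, reconstruct each region separately for its
volume, and aggregate to the subject's regions × 5 feature row.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import region_table as rt
from . import shape_features as sf
from . import surface_recon as sr
from .volume_io import LabelVolume, VolumeGrid, apply_brain_mask

logger = logging.getLogger(__name__)


def extract_subject_features(
    scan: VolumeGrid,
    mask: VolumeGrid | None,
    atlas: LabelVolume,
    n_bins: int = 64,
    rings: int = 2,
    alpha: float | None = None,
):
    """Compute one subject's per-region 5-feature row.

    Returns (row, missing_mask, mesh, vertex_labels, alpha); the row is
    ordered by the atlas region-table ids with the fixed feature order
    (gaussian, mean, sharpness, curvedness, volume).
    """
    vol = apply_brain_mask(scan, mask) if mask is not None else scan
    if alpha is None:
        alpha = sr.select_isovalue(vol, n_bins=n_bins)
    mesh = sr.marching_cubes(vol, alpha)
    shapes = sf.compute_vertex_shapes(mesh, rings=rings)
    vlabels = rt.label_vertices(mesh, atlas)
    regions = atlas.region_ids
    volumes = {r: rt.region_surface_volume(vol, atlas, r, alpha) for r in regions}
    row, miss = rt.aggregate_region_features(shapes, vlabels, volumes, regions)
    return row, miss, mesh, vlabels, float(alpha)


def features_to_frame(row: np.ndarray, regions: list[int]) -> pd.DataFrame:
    return pd.DataFrame(row, index=pd.Index(regions, name="region_id"),
                        columns=list(rt.FEATURE_NAMES))
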