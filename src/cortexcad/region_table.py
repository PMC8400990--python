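"""Region-wise feature tables.

Mesh vertices are labeled with atlas regions, the per-vertex shape
descriptors are aggregated to one value per region, the region volume
is appended, and every feature column is min–max normalized to [0,1]
with training-set statistics that are frozen and replayed on test
subjects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .shape_features import VertexShape
from .surface_recon import TriMesh, component_volumes, marching_cubes
from .volume_io import LabelVolume, VolumeGrid

logger = logging.getLogger(__name__)

#: fixed feature order of the per-region 5-vector
FEATURE_NAMES = ("gaussian", "mean", "sharpness", "curvedness", "volume")

#: regions with fewer labeled vertices than this are flagged missing
MIN_VERTICES_PER_REGION = 10


@dataclass
class RegionFeatureTable:
    """subjects × regions × 5 feature array with explicit missingness.

    Features follow the fixed order ``FEATURE_NAMES`` (four aggregated
    curvature descriptors plus the region volume in mm³); missing
    (subject, region) cells hold NaN and are flagged in ``missing``,
    never silently zero.  ``normalized`` records whether entries have
    been mapped to [0,1].
    """

    subjects: list[str]
    regions: list[int]
    features: np.ndarray  # (n_subjects, n_regions, 5)
    missing: np.ndarray = field(default=None)  # (n_subjects, n_regions) bool
    normalized: bool = False
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        expect = (len(self.subjects), len(self.regions), len(self.feature_names))
        if self.features.shape != expect:
            raise ValueError(f"feature array shape {self.features.shape} != {expect}")
        if self.missing is None:
            self.missing = np.isnan(self.features).any(axis=2)
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def copy(self) -> "RegionFeatureTable":
        return RegionFeatureTable(
            list(self.subjects), list(self.regions), self.features.copy(),
            self.missing.copy(), self.normalized, self.feature_names,
        )

    def subset(self, idx) -> "RegionFeatureTable":
        idx = np.asarray(idx)
        return RegionFeatureTable(
            [self.subjects[i] for i in idx], list(self.regions),
            self.features[idx], self.missing[idx], self.normalized,
            self.feature_names,
        )

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.subjects):
            for j, r in enumerate(self.regions):
                for k, f in enumerate(self.feature_names):
                    rows.append((s, r, f, self.features[i, j, k]))
        return pd.DataFrame(rows, columns=["subject_id", "region_id", "feature_name", "value"])

    def to_wide(self) -> pd.DataFrame:
        cols = {}
        for j, r in enumerate(self.regions):
            for k, f in enumerate(self.feature_names):
                cols[f"r{r}_{f}"] = self.features[:, j, k]
        return pd.DataFrame(cols, index=pd.Index(self.subjects, name="subject_id"))

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "RegionFeatureTable":
        subjects = list(pd.unique(df["subject_id"]))
        regions = sorted(pd.unique(df["region_id"]))
        names = tuple(FEATURE_NAMES)
        arr = np.full((len(subjects), len(regions), len(names)), np.nan)
        sidx = {s: i for i, s in enumerate(subjects)}
        ridx = {r: j for j, r in enumerate(regions)}
        fidx = {f: k for k, f in enumerate(names)}
        for row in df.itertuples(index=False):
            arr[sidx[row.subject_id], ridx[row.region_id], fidx[row.feature_name]] = row.value
        return cls(subjects, [int(r) for r in regions], arr)


# ---------------------------------------------------------------------------
# vertex labeling

def _dilated_labels(atlas: LabelVolume, radius_voxels: float) -> np.ndarray:
    """Fill background voxels from their nearest labeled voxel within a radius."""
    lab = atlas.labels
    if radius_voxels <= 0 or not (lab == 0).any() or not (lab != 0).any():
        return lab
    dist, (ii, jj, kk) = ndimage.distance_transform_edt(lab == 0, return_indices=True)
    filled = lab[ii, jj, kk]
    out = lab.copy()
    grow = (lab == 0) & (dist <= radius_voxels)
    out[grow] = filled[grow]
    return out


def label_vertices(mesh: TriMesh, atlas: LabelVolume,
                   dilate_voxels: float = np.sqrt(3.0)) -> np.ndarray:
    """Atlas region id for every mesh vertex.

    Each vertex takes the label of the atlas voxel containing its world
    coordinate (floor of the inverse-affine index).  Because isosurface
    vertices sit between tissue and background voxels, the lookup uses
    the atlas after a 1-voxel nearest-nonzero dilation so boundary
    vertices inherit the adjacent region; vertices outside the field of
    view (or still on background) get 0 and are counted in the log.
    """
    lab = _dilated_labels(atlas, dilate_voxels)
    grid = VolumeGrid(np.zeros((2, 2, 2)), atlas.affine)
    idx = np.floor(grid.world_to_voxel(mesh.vertices)).astype(np.int64)
    shape = np.array(lab.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(mesh.n_vertices, dtype=np.int64)
    ii = idx[inside]
    out[inside] = lab[ii[:, 0], ii[:, 1], ii[:, 2]]
    n_bg = int((out == 0).sum())
    if n_bg:
        logger.info("%d of %d vertices labeled background/outside FOV",
                    n_bg, mesh.n_vertices)
    return out


def region_surface_volume(vol: VolumeGrid, atlas: LabelVolume,
                          region: int, alpha: float) -> float:
    """Enclosed volume (mm³) of one region's separately reconstructed surface.

    The scan is masked to the region's voxels, marching cubes extracts
    the region surface at ``alpha``, and the closed components' signed
    volumes are summed.  An empty region returns NaN (flagged missing),
    never 0.
    """
    if region not in atlas.region_table:
        raise KeyError(f"region {region} not in atlas region table")
    sel = atlas.labels == region
    if not sel.any():
        logger.warning("region %d has no voxels; volume flagged missing", region)
        return float("nan")
    masked = np.where(sel, vol.data, 0.0)
    if not (masked.min() < alpha < masked.max()):
        logger.warning("region %d has no crossing at isovalue %g; flagged missing",
                       region, alpha)
        return float("nan")
    mesh = marching_cubes(VolumeGrid(masked, vol.affine, vol.spacing), alpha)
    vols = component_volumes(mesh)
    if not vols:
        return float("nan")
    return float(np.sum(vols))


def aggregate_region_features(
    shapes: VertexShape,
    vertex_labels: np.ndarray,
    region_volumes: dict[int, float],
    regions: list[int] | None = None,
    statistic: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's (n_regions × 5) feature row.

    Per region: the chosen statistic (mean by default, median optional)
    of the labeled vertices' four descriptors, plus the region volume.
    Regions with fewer than ``MIN_VERTICES_PER_REGION`` labeled vertices
    are flagged missing.  Returns (row, missing_mask).
    """
    vertex_labels = np.asarray(vertex_labels)
    if regions is None:
        regions = sorted(region_volumes)
    if not (vertex_labels > 0).any():
        raise ValueError("no labeled vertices at all")
    agg = np.nanmean if statistic == "mean" else np.nanmedian
    desc = shapes.descriptor_matrix()
    row = np.full((len(regions), 5), np.nan)
    miss = np.ones(len(regions), dtype=bool)
    for j, r in enumerate(regions):
        sel = (vertex_labels == r) & ~np.isnan(desc).any(axis=1)
        if sel.sum() < MIN_VERTICES_PER_REGION:
            continue
        vol = region_volumes.get(r, float("nan"))
        if np.isnan(vol):
            continue
        row[j, :4] = agg(desc[sel], axis=0)
        row[j, 4] = vol
        miss[j] = False
    return row, miss


# ---------------------------------------------------------------------------
# normalization (min–max to [0,1], training statistics frozen)

@dataclass
class NormStats:
    """Per (region, feature) training min/max used by min–max scaling."""

    mins: np.ndarray  # (n_regions, 5)
    maxs: np.ndarray
    regions: list[int]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "regions": self.regions,
            "feature_names": list(self.feature_names),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormStats":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["mins"]), np.array(d["maxs"]),
                   d["regions"], tuple(d["feature_names"]))


def normalize_features(
    table: RegionFeatureTable, stats: NormStats | None = None
) -> tuple[RegionFeatureTable, NormStats]:
    """Min–max scale every (region, feature) column to [0,1].

    normFeat = (oldFeat − min) / (max − min), with min/max taken over
    the training subjects.  Passing precomputed ``stats`` replays the
    frozen training statistics on test subjects, clipping to [0,1].
    Constant columns (max = min) are set to 0.5 with a warning — they
    carry no information.
    """
    if stats is None:
        if table.n_subjects < 2:
            raise ValueError("need at least 2 subjects to fit normalization")
        with np.errstate(all="ignore"):
            mins = np.nanmin(table.features, axis=0)
            maxs = np.nanmax(table.features, axis=0)
        stats = NormStats(mins, maxs, list(table.regions))
    if stats.regions != list(table.regions):
        raise ValueError("normalization stats were fitted on different regions")
    span = stats.maxs - stats.mins
    degenerate = ~(span > 0)
    if degenerate.any() and np.isfinite(stats.mins[degenerate]).any():
        logger.warning("%d constant feature column(s) set to 0.5",
                       int(degenerate.sum()))
    with np.errstate(all="ignore"):
        out = (table.features - stats.mins) / np.where(degenerate, 1.0, span)
    out = np.where(degenerate & ~np.isnan(table.features), 0.5, out)
    out = np.clip(out, 0.0, 1.0)
    norm = RegionFeatureTable(
        list(table.subjects), list(table.regions), out,
        table.missing.copy(), True, table.feature_names,
    )
    return norm, stats


def impute_missing(
    table: RegionFeatureTable, column_means: np.ndarray | None = None
) -> tuple[RegionFeatureTable, np.ndarray]:
    """Fill missing cells with the (training) column mean, flagged in logs.

    Returns the imputed table and the column means used, so test-time
    imputation can replay training-set means.
    """
    if column_means is None:
        with np.errstate(all="ignore"):
            column_means = np.nanmean(table.features, axis=0)
    filled = table.features.copy()
    nanmask = np.isnan(filled)
    if nanmask.any():
        logger.info("imputing %d missing feature cells with column means",
                    int(nanmask.sum()))
        filled[nanmask] = np.broadcast_to(column_means, filled.shape)[nanmask]
    out = RegionFeatureTable(
        list(table.subjects), list(table.regions), filled,
        np.zeros_like(table.missing), table.normalized, table.feature_names,
    )
    return out, column_means
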