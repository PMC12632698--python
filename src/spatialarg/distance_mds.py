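"""Genealogical distances and "toy" coordinates via classical MDS.

The pairwise genealogical distance between two samples is the expected
tree-path length between them, averaged over the genome: in each
marginal tree the path through their most recent common ancestor has
length 2 * TMRCA (for contemporaneous samples), and trees contribute in
proportion to the genomic span they cover. Classical (Torgerson) MDS of
this matrix gives deterministic 2D coordinates whose Euclidean geometry
approximates the genealogical one — useful demo coordinates when no
real sampling locations exist.
"""

from __future__ import annotations

import dataclasses
from typing import List, Tuple

import numpy as np

from .errors import StructuralError, ValidationError
from .model import CRS_CUSTOM, LocationTable, SpatialARG
from .ts_io import detect_crs


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric matrix of genealogical distances (generations)."""

    sample_ids: List[int]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        k = len(self.sample_ids)
        if self.D.shape != (k, k):
            raise ValidationError("distance matrix shape does not match sample count")
        if not np.allclose(self.D, self.D.T):
            raise ValidationError("distance matrix must be symmetric")
        if (self.D < 0).any() or np.diagonal(self.D).any():
            raise ValidationError("distances must be nonnegative with zero diagonal")


def genealogical_distance_matrix(
    arg: SpatialARG, span_weighted: bool = True
) -> DistanceMatrix:
    """D[i,j] = sum over marginal trees of weight * 2 * TMRCA(i, j).

    With ``span_weighted`` (default) the weight is span / sequence
    length; otherwise each tree counts equally. Samples without a common
    ancestor in some tree are an error naming the tree's interval.
    """
    samples = [int(s) for s in arg.samples]
    k = len(samples)
    if k < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    D = np.zeros((k, k))
    L = arg.sequence_length
    times = arg.node_times
    n_trees = arg.ts.num_trees
    for tree in arg.ts.trees():
        left, right = tree.interval
        w = (right - left) / L if span_weighted else 1.0 / n_trees
        for a in range(k):
            for b in range(a + 1, k):
                mrca = tree.mrca(samples[a], samples[b])
                if mrca == -1:
                    raise StructuralError(
                        f"samples {samples[a]} and {samples[b]} share no "
                        f"ancestor in tree [{left:g}, {right:g})"
                    )
                D[a, b] += w * 2.0 * times[mrca]
    D = D + D.T
    return DistanceMatrix(samples, D)


def classical_mds(dm: DistanceMatrix, dims: int = 2) -> LocationTable:
    """Torgerson double-centering MDS.

    B = -1/2 J D^2 J; coordinates come from the top ``dims`` eigenpairs
    with negative eigenvalues clamped to zero. Output is centered at the
    origin; each axis's sign is fixed so its first nonzero coordinate is
    positive, making the embedding fully deterministic.
    """
    k = len(dm.sample_ids)
    if k < 2:
        raise ValidationError("classical MDS needs at least 2 points")
    D2 = dm.D**2
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:dims]
    lam = np.clip(eigvals[order], 0.0, None)
    X = eigvecs[:, order] * np.sqrt(lam)
    for d in range(X.shape[1]):
        col = X[:, d]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            X[:, d] = -col
    coords = {
        u: (float(X[i, 0]), float(X[i, 1]) if dims > 1 else 0.0)
        for i, u in enumerate(dm.sample_ids)
    }
    return LocationTable(coords, crs=CRS_CUSTOM)


def fit_to_extent(
    table: LocationTable, bbox: Tuple[float, float, float, float]
) -> LocationTable:
    """Map the point cloud into ``bbox`` with one isotropic scale.

    The cloud's bounding square is scaled and translated to fit centered
    in the box, preserving the aspect ratio (and hence all inter-point
    distance ratios). A degenerate cloud collapses to the box center.
    """
    if len(table) == 0:
        raise ValidationError("cannot fit an empty location table")
    xmin, ymin, xmax, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValidationError(f"degenerate bounding box {bbox}")
    pts = np.array([xy for _, xy in table.items()], dtype=float)
    ids = [u for u, _ in table.items()]
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    side = float(max(hi[0] - lo[0], hi[1] - lo[1]))
    center_box = np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])
    if side == 0.0:
        out = np.tile(center_box, (len(pts), 1))
    else:
        scale = min(xmax - xmin, ymax - ymin) / side
        center_cloud = (lo + hi) / 2.0
        out = (pts - center_cloud) * scale + center_box
    coords = {u: (float(p[0]), float(p[1])) for u, p in zip(ids, out)}
    return LocationTable(coords, crs=detect_crs(LocationTable(coords, crs=CRS_CUSTOM)))
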