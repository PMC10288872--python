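"""Connectivity-based parcellation of the midsagittal CC section.

Pipeline: select plane-crossing streamlines, keep those connecting
homologous (same-label, opposite-hemisphere) cortical parcels, build
per-parcel fiber-density maps restricted to the section, then assign one
of seven labels per section voxel by a regularized majority vote (self
weight 1/2, each of the eight in-plane neighbours 1/12) and fill the
zero-density remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import PipelineError, ValidationError
from .formats_io import (
    LabeledMesh,
    N_PARCELS,
    PARCEL_NAMES,
    Tractogram,
    Volume3D,
)
from .section import PlaneSpec, SectionGrid, _component_labels


class ParcelLabel(IntEnum):
    """The seven parcels in fixed anterior->posterior order."""

    FRONTOPOLAR = 1
    ANTERIOR_PREFRONTAL = 2
    POSTERIOR_PREFRONTAL = 3
    PRECENTRAL = 4
    POSTCENTRAL = 5
    PARIETAL = 6
    OCCIPITAL = 7

    @property
    def parcel_name(self) -> str:
        return PARCEL_NAMES[self.value - 1]


@dataclass
class VoteConfig:
    """Regularized-vote kernel: self 1/2, each 8-neighbour 1/12."""

    self_weight: float = 0.5
    neighbor_weight: float = 1.0 / 12.0

    def __post_init__(self):
        if self.self_weight <= 0 or self.neighbor_weight <= 0:
            raise ValidationError("vote weights must be > 0")


@dataclass
class SelectedStreamlines:
    """Plane-crossing streamlines with their in-grid crossing voxels."""

    indices: np.ndarray                 # into the source tractogram
    crossing_voxels: list[np.ndarray]   # distinct grid positions per streamline


@dataclass
class LabeledBundle:
    label: int
    streamline_indices: np.ndarray
    weights: np.ndarray
    crossing_voxels: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.streamline_indices)


@dataclass
class LabelMap:
    """One parcel label per section voxel plus a voted/filled provenance flag."""

    labels: np.ndarray     # (N,) ints in 0..7; 0 = unassigned
    filled: np.ndarray     # (N,) bool, True where the label came from fill_gaps

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.filled = np.asarray(self.filled, dtype=bool)
        if self.labels.shape != self.filled.shape:
            raise ValidationError("labels and filled flags must align")


@dataclass
class SubjectMorphometry:
    """Per-subject area metrics: CcPS (mm^2), CxPS and TCxS (cm^2), %CxPS."""

    ccps_mm2: dict[str, float]
    cc_total_mm2: float
    cxps_cm2: dict[str, float] | None = None
    tcxs_cm2: float | None = None

    @property
    def pct_cxps(self) -> dict[str, float] | None:
        if self.cxps_cm2 is None or not self.tcxs_cm2:
            return None
        return {k: 100.0 * v / self.tcxs_cm2 for k, v in self.cxps_cm2.items()}


# ---------------------------------------------------------------------------
# Streamline selection
# ---------------------------------------------------------------------------

def select_cc_streamlines(tract: Tractogram, grid: SectionGrid
                          ) -> SelectedStreamlines:
    """Retain streamlines whose plane crossing falls inside the section.

    A crossing is a consecutive point pair changing sign of signed plane
    distance (points exactly on the plane count as the positive side);
    the linearly interpolated crossing point must land in a grid voxel.
    All in-grid crossing voxels of a streamline are recorded, each at
    most once.
    """
    plane = grid.plane
    kept, voxels = [], []
    for s_idx, pts in enumerate(tract.streamlines):
        d = plane.signed_distance(pts)
        side = d >= 0
        flips = np.nonzero(side[1:] != side[:-1])[0]
        if flips.size == 0:
            continue
        t = d[flips] / (d[flips] - d[flips + 1])
        crossings = pts[flips] + t[:, None] * (pts[flips + 1] - pts[flips])
        pos = grid.locate(crossings)
        pos = np.unique(pos[pos >= 0])
        if pos.size:
            kept.append(s_idx)
            voxels.append(pos)
    return SelectedStreamlines(indices=np.asarray(kept, dtype=int),
                               crossing_voxels=voxels)


# ---------------------------------------------------------------------------
# Endpoint -> cortical parcel mapping
# ---------------------------------------------------------------------------

class CortexLookup:
    """Maps a world point to a cortical parcel label.

    Backed by either a 7-label volume (containing voxel, else nearest
    labeled voxel centre within ``radius``) or a labeled mesh (nearest
    labeled vertex within ``radius``).
    """

    def __init__(self, cortex: Volume3D | LabeledMesh):
        self._volume = None
        if isinstance(cortex, Volume3D):
            self._volume = cortex
            idx = np.argwhere(cortex.data > 0)
            if idx.size == 0:
                raise ValidationError("cortex label volume has no labeled voxels")
            self._labels = cortex.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(int)
            self._points = cortex.voxel_to_world(idx)
        elif isinstance(cortex, LabeledMesh):
            m = cortex.vertex_labels > 0
            if not m.any():
                raise ValidationError("mesh has no labeled vertices")
            self._labels = cortex.vertex_labels[m].astype(int)
            self._points = cortex.vertices[m]
        else:
            raise ValidationError(f"unsupported cortex type: {type(cortex)!r}")
        self._tree = cKDTree(self._points)

    def lookup(self, point: np.ndarray, radius: float) -> int:
        """Parcel label 1..7 at a point, or 0 if none within reach."""
        if radius < 0:
            raise ValidationError("radius must be >= 0")
        point = np.asarray(point, dtype=float).reshape(3)
        if self._volume is not None:
            ijk = np.round(self._volume.world_to_voxel(point)[0]).astype(int)
            if np.all(ijk >= 0) and np.all(ijk < self._volume.data.shape):
                lab = int(self._volume.data[tuple(ijk)])
                if lab > 0:
                    return lab
        dist, nearest = self._tree.query(point)
        if dist <= radius:
            return int(self._labels[nearest])
        return 0


def endpoint_parcel(point: np.ndarray, cortex: CortexLookup, plane: PlaneSpec,
                    radius: float = 3.0) -> tuple[int, int]:
    """(parcel label or 0, hemisphere) of one streamline endpoint.

    Hemisphere is the sign of the signed plane distance (-1 left,
    +1 right, 0 exactly on the plane -> undefined).
    """
    label = cortex.lookup(point, radius)
    d = float(plane.signed_distance(np.asarray(point, dtype=float))[0])
    hemi = 0 if d == 0 else (1 if d > 0 else -1)
    return label, hemi


# ---------------------------------------------------------------------------
# Homologous bundle construction
# ---------------------------------------------------------------------------

def build_bundles(tract: Tractogram, selected: SelectedStreamlines,
                  cortex: CortexLookup, plane: PlaneSpec,
                  radius: float = 3.0
                  ) -> tuple[dict[int, LabeledBundle], dict[str, int]]:
    """Assign selected streamlines to the seven homologous bundles.

    A streamline joins bundle l iff its endpoints lie in opposite
    hemispheres and both map to parcel l.  Everything else is discarded
    and tallied by reason in the QC dict.
    """
    weights = tract.effective_weights()
    members: dict[int, list[int]] = {l: [] for l in range(1, N_PARCELS + 1)}
    voxels: dict[int, list[np.ndarray]] = {l: [] for l in range(1, N_PARCELS + 1)}
    qc = {"homotopic": 0, "heterotopic": 0, "unlabeled_endpoint": 0,
          "same_hemisphere": 0, "on_plane_endpoint": 0}
    for k, s_idx in enumerate(selected.indices):
        pts = tract.streamlines[s_idx]
        la, ha = endpoint_parcel(pts[0], cortex, plane, radius)
        lb, hb = endpoint_parcel(pts[-1], cortex, plane, radius)
        if ha == 0 or hb == 0:
            qc["on_plane_endpoint"] += 1
            continue
        if la == 0 or lb == 0:
            qc["unlabeled_endpoint"] += 1
            continue
        if ha == hb:
            qc["same_hemisphere"] += 1
            continue
        if la != lb:
            qc["heterotopic"] += 1
            continue
        qc["homotopic"] += 1
        members[la].append(int(s_idx))
        voxels[la].append(selected.crossing_voxels[k])
    bundles = {
        l: LabeledBundle(
            label=l,
            streamline_indices=np.asarray(members[l], dtype=int),
            weights=weights[members[l]] if members[l] else np.zeros(0),
            crossing_voxels=voxels[l],
        )
        for l in range(1, N_PARCELS + 1)
    }
    return bundles, qc


# ---------------------------------------------------------------------------
# Density maps and the regularized vote
# ---------------------------------------------------------------------------

def density_maps(bundles: dict[int, LabeledBundle], grid: SectionGrid
                 ) -> np.ndarray:
    """Per-parcel fiber density over the section: shape (7, n_voxels).

    d_l(v) = sum of streamline weights of bundle l over streamlines that
    cross voxel v; each streamline contributes at most once per voxel.
    """
    d = np.zeros((N_PARCELS, len(grid)))
    for l, bundle in bundles.items():
        for w, vox in zip(bundle.weights, bundle.crossing_voxels):
            d[l - 1, vox] += w
    return d


def regularized_vote(d: np.ndarray, grid: SectionGrid,
                     cfg: VoteConfig | None = None) -> LabelMap:
    """Per-voxel argmax of kernel-smoothed densities.

    score_l(v) = self_weight * d_l(v)
               + neighbor_weight * sum of d_l over in-grid 8-neighbours.
    Ties break toward the label with the larger whole-section bundle
    mass, then the lower label index.  All-zero voxels stay unassigned
    (label 0) for :func:`fill_gaps`.
    """
    cfg = cfg or VoteConfig()
    d = np.asarray(d, dtype=float)
    if d.shape != (N_PARCELS, len(grid)):
        raise ValidationError(f"density maps must have shape (7, {len(grid)})")
    if np.any(d < 0):
        raise ValidationError("densities must be >= 0")
    if not np.any(d > 0):
        raise PipelineError("regularized_vote", "no callosal fibers")

    neigh_sum = np.zeros_like(d)
    for v in range(len(grid)):
        nb = grid.neighbors8(v)
        if nb:
            neigh_sum[:, v] = d[:, nb].sum(axis=1)
    scores = cfg.self_weight * d + cfg.neighbor_weight * neigh_sum

    # Tie priority: larger total bundle mass first, then lower label index.
    mass = d.sum(axis=1)
    priority = sorted(range(N_PARCELS), key=lambda l: (-mass[l], l))
    labels = np.zeros(len(grid), dtype=int)
    best = np.zeros(len(grid))
    for l in priority:
        better = scores[l] > best
        labels[better] = l + 1
        best[better] = scores[l][better]
    labels[best <= 0] = 0
    return LabelMap(labels=labels, filled=np.zeros(len(grid), dtype=bool))


def fill_gaps(partial: LabelMap, grid: SectionGrid) -> LabelMap:
    """Totalise a partial label map.

    Unassigned voxels iteratively take the modal label of their assigned
    8-neighbours (ties -> lower label index; synchronous updates) until
    stable; any voxels still unassigned (isolated islands) take the
    label of the nearest assigned voxel (Euclidean in-plane distance,
    ties -> lower label index).
    """
    labels = partial.labels.copy()
    if not np.any(labels > 0):
        raise ValidationError("fill_gaps needs at least one assigned voxel")
    filled = partial.filled.copy()

    while True:
        todo = np.nonzero(labels == 0)[0]
        if todo.size == 0:
            break
        new = {}
        for v in todo:
            counts = np.zeros(N_PARCELS + 1, dtype=int)
            for nb in grid.neighbors8(v):
                if labels[nb] > 0:
                    counts[labels[nb]] += 1
            if counts.sum():
                new[v] = int(np.argmax(counts))  # lower index wins ties
        if not new:
            break
        for v, l in new.items():
            labels[v] = l
            filled[v] = True

    todo = np.nonzero(labels == 0)[0]
    if todo.size:
        assigned = np.nonzero(labels > 0)[0]
        tree = cKDTree(grid.centers[assigned])
        k = min(len(assigned), 9)
        dist, idx = tree.query(grid.centers[todo], k=k)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        for r, v in enumerate(todo):
            near = idx[r][dist[r] <= dist[r, 0] + 1e-9]
            labels[v] = int(labels[assigned[near]].min())
            filled[v] = True
    return LabelMap(labels=labels, filled=filled)


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def parcel_areas(label_map: LabelMap, grid: SectionGrid) -> SubjectMorphometry:
    """CcPS per parcel (mm^2) and the exact total; absent labels report 0."""
    if np.any(label_map.labels <= 0):
        raise ValidationError("parcel_areas requires a total label map")
    ccps = {}
    for l, name in enumerate(PARCEL_NAMES, start=1):
        ccps[name] = float((label_map.labels == l).sum() * grid.voxel_area)
    return SubjectMorphometry(ccps_mm2=ccps,
                              cc_total_mm2=float(sum(ccps.values())))


def cortical_areas(mesh: LabeledMesh) -> tuple[dict[str, float], float, int]:
    """CxPS per parcel and TCxS, in cm^2.

    Each triangle contributes one third of its area to each vertex's
    label; label-0 (unlabeled) area is excluded from both CxPS and TCxS.
    Returns (cxps_cm2, tcxs_cm2, n_degenerate_triangles).
    """
    v = mesh.vertices
    t = mesh.triangles
    per_label_mm2 = np.zeros(N_PARCELS + 1)
    degenerate = 0
    if len(t):
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        degenerate = int((areas == 0).sum())
        share = areas / 3.0
        for corner in range(3):
            np.add.at(per_label_mm2, mesh.vertex_labels[t[:, corner]], share)
    cxps = {name: float(per_label_mm2[l] / 100.0)
            for l, name in enumerate(PARCEL_NAMES, start=1)}
    tcxs = float(sum(cxps.values()))
    return cxps, tcxs, degenerate


# ---------------------------------------------------------------------------
# Geometric (Witelson-style) baseline
# ---------------------------------------------------------------------------

#: Arbitrary default anterior->posterior cut fractions for the geometric
#: baseline (six cuts -> seven bins); configurable, for comparison only.
DEFAULT_GEOMETRIC_FRACTIONS = (1.0 / 6, 1.0 / 3, 1.0 / 2, 2.0 / 3, 4.0 / 5, 9.0 / 10)


def witelson_baseline(grid: SectionGrid,
                      fractions: tuple[float, ...] = DEFAULT_GEOMETRIC_FRACTIONS
                      ) -> LabelMap:
    """Bin voxels by anterior-posterior position at fixed cut fractions.

    Fraction 0 is the anterior end of the section.  Cuts must be
    strictly increasing within (0, 1); k cuts produce k+1 parcels
    labeled 1..k+1 anterior->posterior.
    """
    fr = tuple(float(x) for x in fractions)
    if any(not (0.0 < x < 1.0) for x in fr) or any(
        b <= a for a, b in zip(fr, fr[1:])
    ):
        raise ValidationError("fractions must be strictly increasing in (0,1)")
    ap = grid.ap
    a_max, a_min = ap.max(), ap.min()  # anterior = larger +y
    extent = a_max - a_min
    # Position measured from the anterior end, as a fraction of AP extent.
    rel = (a_max - ap) / extent if extent > 0 else np.zeros_like(ap)
    cuts = np.asarray(fr)
    labels = 1 + np.searchsorted(cuts, rel, side="left")
    return LabelMap(labels=labels.astype(int),
                    filled=np.zeros(len(grid), dtype=bool))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

#: Parcel area fractions outside this band trigger a QC warning.
DEFAULT_FRACTION_BAND = (0.05, 0.35)


def qc_report(label_map: LabelMap, grid: SectionGrid,
              fraction_band: tuple[float, float] = DEFAULT_FRACTION_BAND) -> dict:
    """Per-label component counts, area fractions and warnings."""
    if np.any(label_map.labels <= 0):
        raise ValidationError("qc_report requires a total label map")
    report = {"labels": {}, "warnings": [],
              "filled_fraction": float(label_map.filled.mean()),
              "total_area_mm2": grid.area}
    lo, hi = fraction_band
    for l, name in enumerate(PARCEL_NAMES, start=1):
        mask = label_map.labels == l
        n_comp = 0
        if mask.any():
            sub = SectionGrid(
                ij=grid.ij[mask], centers=grid.centers[mask],
                voxel_area=grid.voxel_area, plane=grid.plane,
                affine_os=grid.affine_os, inplane_axes=grid.inplane_axes,
                slab_axis=grid.slab_axis,
                slab_half_thickness=grid.slab_half_thickness,
            )
            n_comp = int(_component_labels(sub)[0].max())
        frac = float(mask.mean())
        report["labels"][name] = {
            "components": n_comp,
            "area_mm2": float(mask.sum() * grid.voxel_area),
            "area_fraction": frac,
        }
        if n_comp > 1:
            report["warnings"].append(f"{name}: {n_comp} disconnected components")
        if mask.any() and not (lo <= frac <= hi):
            report["warnings"].append(
                f"{name}: area fraction {frac:.3f} outside [{lo}, {hi}]"
            )
    return report


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ParcellationResult:
    grid: SectionGrid
    label_map: LabelMap
    morphometry: SubjectMorphometry
    qc: dict
    densities: np.ndarray
    bundle_sizes: dict[str, int] = field(default_factory=dict)


def run_parcellation(tract: Tractogram, grid: SectionGrid,
                     cortex: CortexLookup, radius: float = 3.0,
                     vote: VoteConfig | None = None) -> ParcellationResult:
    """Selection -> bundles -> densities -> vote -> fill -> areas -> QC."""
    selected = select_cc_streamlines(tract, grid)
    bundles, qc_sel = build_bundles(tract, selected, cortex, grid.plane, radius)
    d = density_maps(bundles, grid)
    voted = regularized_vote(d, grid, vote)
    total = fill_gaps(voted, grid)
    morpho = parcel_areas(total, grid)
    qc = qc_report(total, grid)
    qc["streamline_selection"] = qc_sel
    sizes = {PARCEL_NAMES[l - 1]: len(b) for l, b in bundles.items()}
    return ParcellationResult(grid=grid, label_map=total, morphometry=morpho,
                              qc=qc, densities=d, bundle_sizes=sizes)


def paint_label_volume(label_map: LabelMap, grid: SectionGrid,
                       shape_native: tuple[int, int, int], oversample: int
                       ) -> Volume3D:
    """Paint section labels 1..7 into the oversampled volume for export."""
    shape = tuple(int(s) * oversample for s in shape_native)
    data = np.zeros(shape, dtype=np.int16)
    inv = np.linalg.inv(grid.affine_os)
    vox = np.round(grid.centers @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    data[vox[ok, 0], vox[ok, 1], vox[ok, 2]] = label_map.labels[ok]
    return Volume3D(data=data, affine=grid.affine_os)
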