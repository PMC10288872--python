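"""Midsagittal section extraction.

The section is the one-voxel-thick intersection of the white-matter mask
with the midsagittal plane, represented on an oversampled grid (default
factor 2, i.e. 1 mm native -> 0.5 mm in-plane voxels).  In-plane voxels
carry 2D indices for 8-neighbourhood operations; anterior-posterior
position is the world +y coordinate (RAS convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PipelineError, ValidationError
from .formats_io import Volume3D

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class PlaneSpec:
    """An oriented plane: origin point and unit normal, in world mm.

    The left hemisphere is the negative signed side (RAS: normal +x).
    """

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            raise ValidationError("plane normal must be nonzero")
        self.normal = normal / norm

    @classmethod
    def from_string(cls, text: str) -> "PlaneSpec":
        """Parse the CLI shorthand ``x=<mm>``."""
        text = text.strip().lower().replace(" ", "")
        if not text.startswith("x="):
            raise ValidationError(f"unsupported plane shorthand: {text!r}")
        x0 = float(text[2:])
        return cls(origin=np.array([x0, 0.0, 0.0]), normal=np.array([1.0, 0.0, 0.0]))

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneSpec":
        return cls(origin=np.asarray(d["origin"]), normal=np.asarray(d["normal"]))

    @classmethod
    def from_cli(cls, text: str) -> "PlaneSpec":
        """Parse either the ``x=<mm>`` shorthand or a JSON object/file."""
        text = text.strip()
        if text.lower().lstrip().startswith("x="):
            return cls.from_string(text)
        if text.startswith("{"):
            return cls.from_dict(json.loads(text))
        p = Path(text)
        if p.exists():
            return cls.from_dict(json.loads(p.read_text()))
        raise ValidationError(f"cannot interpret plane spec: {text!r}")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.normal


@dataclass
class SectionGrid:
    """The in-plane voxels of the midsagittal CC section.

    Attributes
    ----------
    ij
        (N, 2) integer in-plane indices on the oversampled lattice.
    centers
        (N, 3) world-mm centres of the section voxels.
    voxel_area
        In-plane area of one oversampled voxel, mm^2.
    plane, affine_os
        The defining plane and the oversampled voxel->world affine.
    inplane_axes, slab_axis
        Which oversampled index axes run in-plane / across the slab.
    """

    ij: np.ndarray
    centers: np.ndarray
    voxel_area: float
    plane: PlaneSpec
    affine_os: np.ndarray
    inplane_axes: tuple[int, int]
    slab_axis: int
    slab_half_thickness: float
    _ij_to_pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ij = np.asarray(self.ij, dtype=int).reshape(-1, 2)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if len(self.ij) != len(self.centers):
            raise ValidationError("ij and centers must align")
        if self.voxel_area <= 0:
            raise ValidationError("voxel_area must be > 0")
        keys = [tuple(p) for p in self.ij]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate in-plane voxel indices")
        self._ij_to_pos = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.ij)

    @property
    def area(self) -> float:
        """Total section area in mm^2."""
        return len(self) * self.voxel_area

    @property
    def ap(self) -> np.ndarray:
        """Anterior-posterior coordinate of each voxel centre (world +y)."""
        return self.centers[:, 1]

    def index_of(self, ij: tuple[int, int]) -> int:
        return self._ij_to_pos.get(tuple(ij), -1)

    def neighbors8(self, pos: int) -> list[int]:
        """Positions of the in-plane 8-neighbours present in the grid."""
        i, j = self.ij[pos]
        out = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                q = self._ij_to_pos.get((i + di, j + dj))
                if q is not None:
                    out.append(q)
        return out

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Grid position of each world point's in-plane voxel, or -1.

        Points are binned by the half-open oversampled voxel boxes along
        the two in-plane axes; the slab axis is ignored (any point on
        the plane lies inside the slab by construction).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine_os)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        ij = np.floor(vox[:, self.inplane_axes] + 0.5).astype(int)
        return np.array(
            [self._ij_to_pos.get((a, b), -1) for a, b in ij], dtype=int
        )


def _oversampled_affine(affine: np.ndarray, factor: int) -> np.ndarray:
    """Affine of the grid obtained by subdividing each voxel f times per axis.

    Oversampled voxel m (per axis) has centre at native voxel coordinate
    (m + 0.5)/f - 0.5, so subvoxels tile the native voxel boxes exactly.
    """
    out = affine.copy()
    out[:3, :3] = affine[:3, :3] / factor
    shift = affine[:3, :3] @ (np.full(3, 0.5) / factor - 0.5)
    out[:3, 3] = affine[:3, 3] + shift
    return out


def extract_section(wm_mask: Volume3D, plane: PlaneSpec, oversample: int = 2
                    ) -> SectionGrid:
    """Intersect a binary WM mask with the midsagittal plane.

    The grid contains exactly the oversampled voxels whose centres lie
    inside the mask and within half an oversampled voxel of the plane
    (half-open slab [-h/2, h/2), so a plane on a voxel boundary still
    yields a one-voxel-thick section).
    """
    if oversample < 1:
        raise ValidationError("oversample factor must be >= 1")
    if not np.all(np.isin(np.unique(wm_mask.data), (0, 1))):
        raise ValidationError("WM mask must be binary")
    f = int(oversample)
    affine_os = _oversampled_affine(wm_mask.affine, f)

    # Slab axis: oversampled index axis most parallel to the plane normal.
    dirs = affine_os[:3, :3] / np.linalg.norm(affine_os[:3, :3], axis=0)
    slab_axis = int(np.argmax(np.abs(plane.normal @ dirs)))
    inplane_axes = tuple(a for a in range(3) if a != slab_axis)
    os_sizes = np.linalg.norm(affine_os[:3, :3], axis=0)
    half = 0.5 * os_sizes[slab_axis]

    # Candidate native voxels: in-mask and within half a native diagonal.
    native = np.argwhere(wm_mask.data > 0)
    if native.size == 0:
        raise PipelineError("extract_section", "no callosal section found")
    centers = wm_mask.voxel_to_world(native)
    diag = 0.5 * np.linalg.norm(wm_mask.affine[:3, :3] @ np.ones(3))
    near = np.abs(plane.signed_distance(centers)) <= diag + half
    native = native[near]
    if native.size == 0:
        raise PipelineError("extract_section", "no callosal section found")

    # Expand each candidate into its f^3 subvoxels and apply the centre tests.
    sub = np.stack(np.meshgrid(*([np.arange(f)] * 3), indexing="ij"), -1).reshape(-1, 3)
    os_idx = (native[:, None, :] * f + sub[None, :, :]).reshape(-1, 3)
    os_centers = os_idx @ affine_os[:3, :3].T + affine_os[:3, 3]
    d = plane.signed_distance(os_centers)
    inslab = (d >= -half) & (d < half)
    os_idx, os_centers = os_idx[inslab], os_centers[inslab]
    if os_idx.size == 0:
        raise PipelineError("extract_section", "no callosal section found")

    ij = os_idx[:, inplane_axes]
    # An oblique plane can put two slab voxels on one in-plane index; keep
    # the one closest to the plane (deterministic).
    dist = np.abs(plane.signed_distance(os_centers))
    order = np.lexsort((dist, ij[:, 1], ij[:, 0]))
    ij_o = ij[order]
    first = np.ones(len(ij_o), dtype=bool)
    first[1:] = np.any(ij_o[1:] != ij_o[:-1], axis=1)
    sel = order[first]
    sel.sort()

    voxel_area = float(os_sizes[inplane_axes[0]] * os_sizes[inplane_axes[1]])
    return SectionGrid(
        ij=ij[np.isin(np.arange(len(ij)), sel)],
        centers=os_centers[np.isin(np.arange(len(ij)), sel)],
        voxel_area=voxel_area,
        plane=plane,
        affine_os=affine_os,
        inplane_axes=inplane_axes,
        slab_axis=slab_axis,
        slab_half_thickness=half,
    )


def _component_labels(grid: SectionGrid) -> tuple[np.ndarray, int]:
    """8-connected component id per grid voxel, via a dense raster."""
    ij = grid.ij
    lo = ij.min(axis=0)
    shape = ij.max(axis=0) - lo + 1
    raster = np.zeros(shape, dtype=bool)
    raster[ij[:, 0] - lo[0], ij[:, 1] - lo[1]] = True
    labeled, n = ndimage.label(raster, structure=_EIGHT_CONN)
    return labeled[ij[:, 0] - lo[0], ij[:, 1] - lo[1]], n


def clean_section(grid: SectionGrid) -> tuple[SectionGrid, int]:
    """Keep the largest 8-connected component of the section.

    Ties go to the component with the more anterior centroid, then the
    larger anterior-posterior extent.  Returns (grid, removed count).
    """
    if len(grid) == 0:
        raise ValidationError("empty section grid")
    comp, n = _component_labels(grid)
    if n <= 1:
        return grid, 0
    best, best_key = None, None
    for c in range(1, n + 1):
        m = comp == c
        ap = grid.ap[m]
        key = (int(m.sum()), float(ap.mean()), float(ap.max() - ap.min()))
        if best_key is None or key > best_key:
            best, best_key = m, key
    removed = int(len(grid) - best.sum())
    out = SectionGrid(
        ij=grid.ij[best],
        centers=grid.centers[best],
        voxel_area=grid.voxel_area,
        plane=grid.plane,
        affine_os=grid.affine_os,
        inplane_axes=grid.inplane_axes,
        slab_axis=grid.slab_axis,
        slab_half_thickness=grid.slab_half_thickness,
    )
    return out, removed


def section_from_mask(cc_mask: Volume3D, plane: PlaneSpec, oversample: int = 2
                      ) -> SectionGrid:
    """Build the grid from a ready-made CC section mask (bypasses WM logic)."""
    return extract_section(cc_mask, plane, oversample)
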