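"""Readers and writers for every on-disk format the pipeline touches.

All geometry is exchanged in world RAS millimetres.  Streamline files
(TCK/TRK) are loaded through :mod:`nibabel.streamlines`, which converts
TRK voxel-space coordinates to RAS mm using the file header.  Meshes use
a small documented ASCII format (see :func:`read_mesh`), cohort tables a
documented CSV schema (see :data:`COHORT_COLUMNS`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: Fixed anterior->posterior order of the seven parcels.
PARCEL_NAMES = (
    "frontopolar",
    "anterior_prefrontal",
    "posterior_prefrontal",
    "precentral",
    "postcentral",
    "parietal",
    "occipital",
)
N_PARCELS = 7

#: Recognised cohort groups.
GROUPS = ("control", "FAS", "NS-FASD")

#: Surfaces carried per subject: total CC plus the seven parcels.
SURFACES = ("total",) + PARCEL_NAMES


def parcel_index(name: str) -> int:
    """1-based label code of a parcel name."""
    return PARCEL_NAMES.index(name) + 1


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class Volume3D:
    """A 3D scalar array with a voxel-index -> world-mm affine.

    Voxel indexing is 0-based; voxel (i,j,k) occupies the half-open box
    centred on ``affine @ (i,j,k,1)``.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each index axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (no rounding)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def read_volume(path: str | Path, kind: str = "scalar") -> Volume3D:
    """Load a NIfTI volume without any resampling.

    Parameters
    ----------
    path
        NIfTI-1 file (.nii or .nii.gz).
    kind
        "scalar" (no value checks), "mask" (values must be 0/1 and
        finite) or "labels" (integer codes 0..7).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.squeeze(data)
    vol = Volume3D(data=data, affine=np.asarray(img.affine))
    if kind in ("mask", "labels"):
        if not np.all(np.isfinite(vol.data)):
            raise ValidationError(f"{path}: non-finite values in a {kind} volume")
        vals = np.unique(vol.data)
        if kind == "mask" and not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"{path}: mask values outside {{0,1}}: {vals[:10]}")
        if kind == "labels":
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError(f"{path}: non-integer label codes")
            bad = vals[(vals < 0) | (vals > N_PARCELS)]
            if bad.size:
                raise ValidationError(
                    f"{path}: label codes outside 0..{N_PARCELS}: {bad[:10]}"
                )
            vol = Volume3D(vol.data.astype(np.int16), vol.affine)
        else:
            vol = Volume3D(vol.data.astype(np.uint8), vol.affine)
    return vol


def write_volume(vol: Volume3D, path: str | Path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# Tractograms
# ---------------------------------------------------------------------------

@dataclass
class Tractogram:
    """Ordered 3D polylines in world mm with optional per-streamline weights."""

    streamlines: list[np.ndarray]
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValidationError(
                    "every streamline must be an (n>=2, 3) point array"
                )
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.streamlines):
                raise ValidationError(
                    f"{len(self.weights)} weights for "
                    f"{len(self.streamlines)} streamlines"
                )
            if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
                raise ValidationError("weights must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.streamlines)

    def effective_weights(self) -> np.ndarray:
        """Weights, defaulting to 1 for unweighted tractograms."""
        if self.weights is None:
            return np.ones(len(self.streamlines))
        return self.weights


def read_weights(path: str | Path) -> np.ndarray:
    """Whitespace/newline-separated ASCII floats, one weight per streamline."""
    text = Path(path).read_text().split()
    try:
        w = np.array([float(tok) for tok in text], dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric token in weights file {path}") from exc
    return w


def write_weights(weights: Sequence[float], path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{w:.10g}" for w in weights) + "\n")


def read_tractogram(path: str | Path, weights_path: str | Path | None = None
                    ) -> Tractogram:
    """Load a TCK or TRK file into world-mm streamlines.

    Single-point streamlines are dropped (with a logged count); the
    matching weights are dropped with them.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read {path} as TCK/TRK: {exc}") from exc
    raw = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]

    weights = None
    if weights_path is not None:
        weights = read_weights(weights_path)
        if len(weights) != len(raw):
            raise ValidationError(
                f"weight count {len(weights)} != streamline count {len(raw)}"
            )

    keep = [i for i, s in enumerate(raw) if len(s) >= 2]
    dropped = len(raw) - len(keep)
    if dropped:
        log.warning("dropped %d single-point streamline(s) from %s", dropped, path)
    streamlines = [raw[i] for i in keep]
    if weights is not None:
        weights = weights[keep]
    return Tractogram(streamlines=streamlines, weights=weights)


def write_tractogram(tract: Tractogram, path: str | Path,
                     weights_path: str | Path | None = None) -> None:
    """Write streamlines as TCK (native RAS mm) and optionally the weights."""
    t = nib.streamlines.Tractogram(tract.streamlines, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(t, str(path))
    if weights_path is not None:
        if tract.weights is None:
            raise ValidationError("tractogram has no weights to write")
        write_weights(tract.weights, weights_path)


# ---------------------------------------------------------------------------
# Labeled surface meshes
# ---------------------------------------------------------------------------

@dataclass
class LabeledMesh:
    """Triangle mesh in mm with one parcel label and hemisphere tag per vertex.

    Hemisphere tags: -1 left, +1 right, 0 unknown.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_labels: np.ndarray
    vertex_hemis: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=int)
        if self.vertex_hemis is None:
            self.vertex_hemis = np.zeros(len(self.vertices), dtype=int)
        self.vertex_hemis = np.asarray(self.vertex_hemis, dtype=int)
        n = len(self.vertices)
        if len(self.vertex_labels) != n or len(self.vertex_hemis) != n:
            raise ValidationError("per-vertex arrays must match vertex count")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise ValidationError("triangle vertex index out of range")
        if np.any((self.vertex_labels < 0) | (self.vertex_labels > N_PARCELS)):
            raise ValidationError(f"vertex labels must lie in 0..{N_PARCELS}")


MESH_MAGIC = "# ccmesh 1"


def read_mesh(path: str | Path) -> LabeledMesh:
    """Read the package's ASCII mesh format.

    Layout::

        # ccmesh 1
        <n_vertices> <n_triangles>
        x y z label hemi     (n_vertices lines)
        i j k                (n_triangles lines, 0-based indices)
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != MESH_MAGIC:
        raise FormatError(f"{path}: missing '{MESH_MAGIC}' header")
    try:
        nv, nt = (int(tok) for tok in lines[1].split())
        vrows = [lines[2 + i].split() for i in range(nv)]
        trows = [lines[2 + nv + i].split() for i in range(nt)]
        vertices = np.array([[float(r[0]), float(r[1]), float(r[2])] for r in vrows])
        labels = np.array([int(r[3]) for r in vrows])
        hemis = np.array([int(r[4]) for r in vrows])
        triangles = np.array([[int(t) for t in r] for r in trows], dtype=int)
        if nt == 0:
            triangles = np.zeros((0, 3), dtype=int)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed mesh file: {exc}") from exc
    return LabeledMesh(vertices, triangles, labels, hemis)


def write_mesh(mesh: LabeledMesh, path: str | Path) -> None:
    out = [MESH_MAGIC, f"{len(mesh.vertices)} {len(mesh.triangles)}"]
    for v, l, h in zip(mesh.vertices, mesh.vertex_labels, mesh.vertex_hemis):
        out.append(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g} {l} {h}")
    for t in mesh.triangles:
        out.append(f"{t[0]} {t[1]} {t[2]}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

#: Mandatory cohort CSV columns, in canonical order.
COHORT_COLUMNS = (
    ["subject_id", "group", "sex", "age_years", "tcxs_cm2"]
    + [f"cxps_{n}_cm2" for n in PARCEL_NAMES]
    + [f"ccps_{n}_mm2" for n in PARCEL_NAMES]
    + ["cc_total_mm2"]
)

AGE_PLAUSIBLE = (6.0, 25.0)


def ccps_column(surface: str) -> str:
    return "cc_total_mm2" if surface == "total" else f"ccps_{surface}_mm2"


def cxps_column(surface: str) -> str:
    if surface == "total":
        raise ValidationError("no CxPS column for the total surface; use tcxs_cm2")
    return f"cxps_{surface}_cm2"


def _coerce_sex(col: pd.Series) -> pd.Series:
    """Accept M/F (case-insensitive) or 0/1; return 0 female / 1 male."""
    mapping = {"m": 1, "male": 1, "f": 0, "female": 0, "0": 0, "1": 1, 0: 0, 1: 1}
    out = col.map(lambda v: mapping.get(str(v).strip().lower(), None))
    if out.isna().any():
        bad = col[out.isna()].unique()
        raise ValidationError(f"unrecognised sex codes: {bad}")
    return out.astype(int)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise an in-memory cohort table."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        log.warning("ignoring unknown cohort columns: %s", extra)
    df = df[list(COHORT_COLUMNS)].copy()
    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown group values: {sorted(bad_groups)}")
    df["sex"] = _coerce_sex(df["sex"])
    numeric = [c for c in COHORT_COLUMNS if c not in ("subject_id", "group", "sex")]
    for c in numeric:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"non-numeric values in column {c}")
        df[c] = vals.astype(float)
    if (df["age_years"] <= 0).any():
        raise ValidationError("age_years must be > 0")
    lo, hi = AGE_PLAUSIBLE
    n_out = int(((df["age_years"] < lo) | (df["age_years"] > hi)).sum())
    if n_out:
        log.warning("%d subject(s) outside the plausible %g-%g y age range",
                    n_out, lo, hi)
    pos = ["tcxs_cm2"] + [f"cxps_{n}_cm2" for n in PARCEL_NAMES]
    for c in pos:
        if (df[c] <= 0).any():
            raise ValidationError(f"column {c} must be > 0")
    # CcPS may be 0 (partial agenesis) but never negative.
    for c in [f"ccps_{n}_mm2" for n in PARCEL_NAMES] + ["cc_total_mm2"]:
        if (df[c] < 0).any():
            raise ValidationError(f"column {c} must be >= 0")
    return df.reset_index(drop=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read cohort CSV {path}: {exc}") from exc
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df).to_csv(path, index=False)
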