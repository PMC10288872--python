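"""Seeded synthetic data: a geometric brain phantom and simulated cohorts.

The phantom is a flat-strip brain: a white-matter block with a callosal
bridge at the midplane, two lateral cortical ribbons carrying the seven
labels in anterior->posterior bands, and a tractogram of homotopic
streamlines (plus configurable heterotopic and stray fibers).  Band
membership of every section voxel is known exactly, so each pipeline
stage can be scored against ground truth.  Cohorts are drawn from the
same linear models the statistics layer fits.

All randomness flows from the single seed in each spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats_io import (
    COHORT_COLUMNS,
    LabeledMesh,
    N_PARCELS,
    PARCEL_NAMES,
    Tractogram,
    Volume3D,
    write_mesh,
    write_tractogram,
    write_volume,
)
from .section import PlaneSpec, SectionGrid

#: Default anterior->posterior target band fractions (arbitrary, sum 1).
DEFAULT_BAND_FRACTIONS = (0.12, 0.14, 0.16, 0.18, 0.14, 0.13, 0.13)


def _integer_widths(fractions: tuple[float, ...], total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` rows to the bands."""
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (N_PARCELS,) or np.any(fr <= 0):
        raise ValidationError("band_fractions must be 7 positive values")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValidationError("band_fractions must sum to 1")
    raw = fr * total
    widths = np.floor(raw).astype(int)
    remainder = raw - widths
    for i in np.argsort(-remainder, kind="stable")[: total - widths.sum()]:
        widths[i] += 1
    if np.any(widths < 1):
        raise ValidationError("band too small for the requested fractions")
    return widths


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and content of the strip phantom."""

    shape: tuple[int, int, int] = (33, 80, 24)
    voxel_size: float = 1.0
    plane_x: int | None = None            # native column index; default centre
    footprint: tuple[int, int, int, int] = (15, 50, 7, 10)  # y0, ny, z0, nz
    band_fractions: tuple[float, ...] = DEFAULT_BAND_FRACTIONS
    fibers_per_voxel: int = 2
    heterotopic_fraction: float = 0.05
    stray_fraction: float = 0.05
    agenesis: frozenset[int] = frozenset()
    oversample: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.fibers_per_voxel < 0:
            raise ValidationError("fibers_per_voxel must be >= 0")
        bad = set(self.agenesis) - set(range(1, N_PARCELS + 1))
        if bad:
            raise ValidationError(f"agenesis labels must be in 1..7, got {bad}")


@dataclass
class Phantom:
    """Generated phantom data plus exact ground truth."""

    spec: PhantomSpec
    wm_mask: Volume3D
    cortex_labels: Volume3D
    mesh: LabeledMesh
    tractogram: Tractogram
    plane: PlaneSpec
    ground_truth: dict

    def truth_labels(self, grid: SectionGrid) -> np.ndarray:
        """Ground-truth band label of each section-grid voxel."""
        inv = np.linalg.inv(self.wm_mask.affine)
        native_y = np.round(
            grid.centers @ inv[:3, :3].T + inv[:3, 3]
        )[:, 1].astype(int)
        starts = np.asarray(self.ground_truth["band_start_y"])
        ends = np.asarray(self.ground_truth["band_end_y"])
        labels = np.zeros(len(grid), dtype=int)
        for l in range(1, N_PARCELS + 1):
            inband = (native_y >= starts[l - 1]) & (native_y < ends[l - 1])
            labels[inband] = l
        return labels

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all phantom files; returns the path of each artefact."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "wm_mask": out / "wm_mask.nii",
            "cortex_labels": out / "cortex_labels.nii",
            "tractogram": out / "tractogram.tck",
            "weights": out / "weights.txt",
            "mesh": out / "cortex_mesh.txt",
            "ground_truth": out / "ground_truth.json",
            "plane": out / "plane.json",
        }
        write_volume(self.wm_mask, paths["wm_mask"])
        write_volume(self.cortex_labels, paths["cortex_labels"])
        write_tractogram(self.tractogram, paths["tractogram"], paths["weights"])
        write_mesh(self.mesh, paths["mesh"])
        paths["ground_truth"].write_text(json.dumps(self.ground_truth, indent=1))
        paths["plane"].write_text(json.dumps(
            {"origin": list(self.plane.origin), "normal": list(self.plane.normal)}
        ))
        return paths


def _band_table(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(start_y, end_y) native index ranges per band, anterior (high y) first."""
    y0, ny, _, _ = spec.footprint
    widths = _integer_widths(spec.band_fractions, ny)
    ends = y0 + ny - np.concatenate(([0], np.cumsum(widths)[:-1]))
    starts = ends - widths
    return starts, ends


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the deterministic strip phantom for one spec/seed."""
    rng = np.random.default_rng(spec.seed)
    nx, nyv, nzv = spec.shape
    y0, ny, z0, nz = spec.footprint
    if y0 + ny > nyv or z0 + nz > nzv:
        raise ValidationError("footprint exceeds the grid shape")
    x0 = spec.plane_x if spec.plane_x is not None else nx // 2
    if not 2 <= x0 <= nx - 3:
        raise ValidationError("plane column too close to the grid edge")
    vs = float(spec.voxel_size)
    affine = np.diag([vs, vs, vs, 1.0])
    plane = PlaneSpec(origin=np.array([x0 * vs, 0.0, 0.0]),
                      normal=np.array([1.0, 0.0, 0.0]))

    # --- volumes -----------------------------------------------------------
    wm = np.zeros(spec.shape, dtype=np.uint8)
    fy = slice(y0, y0 + ny)
    fz = slice(z0, z0 + nz)
    wm[max(x0 - 1, 0):x0 + 2, fy, fz] = 1                      # callosal bridge
    wing_y = slice(max(y0 - 5, 0), min(y0 + ny + 5, nyv))
    wing_z = slice(max(z0 - 3, 0), min(z0 + nz + 3, nzv))
    xl_in, xl_out = max(x0 - 12, 0), x0 - 2                     # lateral wings
    xr_in, xr_out = x0 + 3, min(x0 + 13, nx)
    wm[xl_in:xl_out, wing_y, wing_z] = 1
    wm[xr_in:xr_out, wing_y, wing_z] = 1

    starts, ends = _band_table(spec)
    cortex = np.zeros(spec.shape, dtype=np.int16)
    cxl = max(x0 - 10, 1)
    cxr = min(x0 + 10, nx - 2)
    for l in range(1, N_PARCELS + 1):
        band_y = slice(int(starts[l - 1]), int(ends[l - 1]))
        cortex[cxl - 1:cxl + 1, band_y, fz] = l
        cortex[cxr:cxr + 2, band_y, fz] = l

    # --- streamlines -------------------------------------------------------
    f = spec.oversample
    # Oversampled in-plane voxel centres, native index units.
    sub = (np.arange(f) + 0.5) / f - 0.5
    ys = (np.arange(y0, y0 + ny)[:, None] + sub[None, :]).ravel()
    zs = (np.arange(z0, z0 + nz)[:, None] + sub[None, :]).ravel()

    def polyline(y_left, y_right, z, x_left=cxl, x_right=cxr):
        pts = np.array([
            [x_left, y_left, z],
            [x0 - 3.0, y_left, z],
            [x0 + 3.0, y_right, z],
            [x_right, y_right, z],
        ]) * vs
        if rng.random() < 0.5:
            pts = pts[::-1]
        return pts

    def band_of(y):
        for l in range(1, N_PARCELS + 1):
            if starts[l - 1] <= y < ends[l - 1]:
                return l
        return 0

    def band_ys_of(l):
        """Oversampled y centres whose parent native voxel is in band l."""
        parent = np.round(ys).astype(int)
        return ys[(parent >= starts[l - 1]) & (parent < ends[l - 1])]

    streamlines: list[np.ndarray] = []
    bundle_counts = {name: 0 for name in PARCEL_NAMES}
    for l in range(1, N_PARCELS + 1):
        if l in spec.agenesis:
            continue
        band_ys = band_ys_of(l)
        if band_ys.size == 0 and spec.fibers_per_voxel > 0:
            raise ValidationError(f"band {l} too small for requested counts")
        for y in band_ys:
            for z in zs:
                for _ in range(spec.fibers_per_voxel):
                    streamlines.append(polyline(y, y, z))
                    bundle_counts[PARCEL_NAMES[l - 1]] += 1
    n_homotopic = len(streamlines)

    live = [l for l in range(1, N_PARCELS + 1) if l not in spec.agenesis]
    n_het = int(round(spec.heterotopic_fraction * n_homotopic)) \
        if len(live) >= 2 else 0
    for _ in range(n_het):
        la, lb = rng.choice(live, size=2, replace=False)
        ya = rng.choice(band_ys_of(la))
        yb = rng.choice(band_ys_of(lb))
        streamlines.append(polyline(ya, yb, rng.choice(zs)))

    n_stray = int(round(spec.stray_fraction * n_homotopic))
    for k in range(n_stray):
        y = rng.choice(ys)
        kind = k % 3
        if kind == 0:      # crosses the plane below the section footprint
            streamlines.append(polyline(y, y, z0 - 3.0))
        elif kind == 1:    # never crosses the plane
            pts = np.array([[cxl, y, z0 + 1.0],
                            [x0 - 3.0, y, z0 + 1.0],
                            [cxl, y, z0 + 2.0]]) * vs
            streamlines.append(pts)
        else:              # crosses twice, returns to the same hemisphere
            z = rng.choice(zs)
            pts = np.array([[cxl, y, z],
                            [x0 + 3.0, y, z],
                            [cxl, min(y + 1.0, y0 + ny - 1.0), z]]) * vs
            streamlines.append(pts)

    weights = rng.uniform(0.5, 1.5, size=len(streamlines))
    tract = Tractogram(streamlines=streamlines, weights=weights)

    # --- cortical ribbon mesh ---------------------------------------------
    verts, labels, hemis = [], [], []
    for hemi, x_mesh in ((-1, (cxl - 1.5)), (1, (cxr + 1.5))):
        for jy in range(ny + 1):
            for jz in range(nz + 1):
                y = y0 - 0.5 + jy
                verts.append([x_mesh * vs, y * vs, (z0 - 0.5 + jz) * vs])
                labels.append(band_of(min(y0 + jy, y0 + ny - 1)))
                hemis.append(hemi)
    tris = []
    row = nz + 1
    for h in range(2):
        base = h * (ny + 1) * (nz + 1)
        for jy in range(ny):
            for jz in range(nz):
                a = base + jy * row + jz
                b, c, d = a + row, a + row + 1, a + 1
                tris.append([a, b, c])
                tris.append([a, c, d])
    mesh = LabeledMesh(np.array(verts), np.array(tris), np.array(labels),
                       np.array(hemis))

    widths = (ends - starts).astype(int)
    ground_truth = {
        "seed": spec.seed,
        "plane_x_mm": x0 * vs,
        "wm_voxel_count": int(wm.sum()),
        "section_voxel_count": int(ny * nz * f * f),
        "band_start_y": [int(s) for s in starts],
        "band_end_y": [int(e) for e in ends],
        "band_fractions_realized": [float(w) / ny for w in widths],
        "band_fractions_target": list(spec.band_fractions),
        "bundle_counts": bundle_counts,
        "n_homotopic": n_homotopic,
        "n_heterotopic": n_het,
        "n_stray": n_stray,
        "agenesis": sorted(spec.agenesis),
        "oversample": f,
    }
    return Phantom(spec=spec, wm_mask=Volume3D(wm, affine),
                   cortex_labels=Volume3D(cortex, affine), mesh=mesh,
                   tractogram=tract, plane=plane, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceParams:
    """True generating coefficients for one callosal parcel (mm^2 scale)."""

    b0: float
    b_sex: float
    b_age: float
    b_tcxs: float
    delta: float = 0.0        # additive group effect (DIAG = 1)
    sigma: float = 10.0       # residual SD

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


def default_surface_params() -> dict[str, SurfaceParams]:
    """Arbitrary but realistic per-parcel generating coefficients."""
    out = {}
    for name, frac in zip(PARCEL_NAMES, DEFAULT_BAND_FRACTIONS):
        out[name] = SurfaceParams(
            b0=150.0 * frac, b_sex=25.0 * frac, b_age=4.0 * frac,
            b_tcxs=0.25 * frac, delta=0.0, sigma=12.0,
        )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generating model.

    All defaults except the 6-25 y age range are arbitrary and
    configurable.  ``cc_total_mm2`` is the sum of the seven generated
    parcels, so its implied true coefficients are the parcel sums.
    """

    group_sizes: tuple[tuple[str, int], ...] = (
        ("control", 50), ("FAS", 30), ("NS-FASD", 20))
    sex_ratio: float = 0.5
    age_range: tuple[float, float] = (6.0, 25.0)
    tcxs_mean: float = 1600.0
    tcxs_sd: float = 150.0
    surface_params: tuple[tuple[str, SurfaceParams], ...] = dc_field(
        default_factory=lambda: tuple(default_surface_params().items()))
    cx_share_sd: float = 1.0              # per-subject noise on %CxPS shares
    cx_delta_pct: tuple[tuple[str, float], ...] = ()   # group shift per parcel
    seed: int = 0

    def __post_init__(self):
        for _, n in self.group_sizes:
            if n < 2:
                raise ValidationError("group sizes must be >= 2")

    @property
    def params(self) -> dict[str, SurfaceParams]:
        return dict(self.surface_params)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table from the generating model."""
    rng = np.random.default_rng(spec.seed)
    params = spec.params
    missing = set(PARCEL_NAMES) - set(params)
    if missing:
        raise ValidationError(f"surface_params missing parcels: {missing}")
    groups = [g for g, n in spec.group_sizes for _ in range(n)]
    n = len(groups)
    diag = np.array([0 if g == "control" else 1 for g in groups], dtype=float)
    sex = (rng.random(n) < spec.sex_ratio).astype(int)
    age = rng.uniform(*spec.age_range, size=n)
    tcxs = np.maximum(rng.normal(spec.tcxs_mean, spec.tcxs_sd, size=n), 100.0)

    ccps = {}
    for name in PARCEL_NAMES:
        sp = params[name]
        mu = (sp.b0 + sp.b_sex * sex + sp.b_age * age + sp.b_tcxs * tcxs
              + sp.delta * diag)
        ccps[name] = np.maximum(mu + rng.normal(0.0, sp.sigma, size=n), 0.0)

    delta_pct = dict(spec.cx_delta_pct)
    base_shares = 100.0 * np.asarray(DEFAULT_BAND_FRACTIONS)
    shares = np.empty((n, N_PARCELS))
    for j, name in enumerate(PARCEL_NAMES):
        shares[:, j] = (base_shares[j]
                        + rng.normal(0.0, spec.cx_share_sd, size=n)
                        + delta_pct.get(name, 0.0) * diag)
    shares = np.maximum(shares, 0.1)
    shares *= 100.0 / shares.sum(axis=1, keepdims=True)

    data = {
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "group": groups,
        "sex": ["M" if s else "F" for s in sex],
        "age_years": age,
        "tcxs_cm2": tcxs,
    }
    for j, name in enumerate(PARCEL_NAMES):
        data[f"cxps_{name}_cm2"] = shares[:, j] / 100.0 * tcxs
    for name in PARCEL_NAMES:
        data[f"ccps_{name}_mm2"] = ccps[name]
    data["cc_total_mm2"] = np.sum([ccps[name] for name in PARCEL_NAMES], axis=0)
    from .formats_io import validate_cohort

    return validate_cohort(pd.DataFrame(data, columns=list(COHORT_COLUMNS)))
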