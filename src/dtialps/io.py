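"""Readers, writers and configuration for the DTI-ALPS pipeline.

All imaging flows through three small containers: :class:`VolumeGrid` (the
voxel lattice and its voxel->world affine), :class:`GradientScheme` (the
diffusion-encoding table in the FSL bval/bvec dialect) and
:class:`DWIVolume` (the 4D signal plus both). Clinical data live in a plain
long-format :class:`pandas.DataFrame` validated by :func:`validate_cohort`.

Convention: atlas ROI coordinates are 0-based voxel indices on the 1-mm
JHU-ICBM template grid (182 x 218 x 182); this package equates that grid's
world coordinates with its voxel indices in mm (identity affine), and every
synthetic grid's affine is expressed in the same frame, so printed atlas
coordinates apply verbatim.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, SchemaError, ValidationError

log = logging.getLogger("dtialps")

GROUPS = ("HC", "PD_good", "PD_poor")

#: Columns every cohort table must carry; cognitive-test columns are optional.
COHORT_REQUIRED = (
    "subject_id",
    "group",
    "age",
    "sex",
    "session",
    "time_from_baseline",
)


@dataclass(frozen=True)
class VolumeGrid:
    """A regular voxel lattice with a voxel->world affine (mm)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValidationError(f"grid shape must be three positive ints, got {shape}")
        if any(v <= 0 for v in voxel):
            raise ValidationError(f"voxel sizes must be positive, got {voxel}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")

    def world_to_voxel(self, world_xyz: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to (fractional) voxel indices."""
        w = np.atleast_2d(np.asarray(world_xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        v = (inv[:3, :3] @ w.T).T + inv[:3, 3]
        return v[0] if np.ndim(world_xyz) == 1 else v

    def voxel_to_world(self, voxel_ijk: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(voxel_ijk, dtype=float))
        w = (self.affine[:3, :3] @ v.T).T + self.affine[:3, 3]
        return w[0] if np.ndim(voxel_ijk) == 1 else w


def _identity_affine(voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    aff[:3, 3] = origin
    return aff


#: The 1-mm JHU-ICBM template lattice on which atlas ROI centers are printed.
JHU_GRID = VolumeGrid(
    shape=(182, 218, 182),
    voxel_size=(1.0, 1.0, 1.0),
    affine=_identity_affine(),
)


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    Zero-b entries may carry an arbitrary (zero) direction. Validation
    requires at least one b=0 volume and at least six unique, pairwise
    non-collinear non-zero directions so the tensor is identifiable.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size) and bvecs.shape[0] == 3 and bvals.size != 3:
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise FormatError(
                f"bvecs shape {bvecs.shape} incompatible with {bvals.size} b-values"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        self._validate()

    def _validate(self) -> None:
        if np.any(self.bvals < 0):
            raise ValidationError("negative b-value")
        nz = self.bvals > 0
        if not np.any(~nz):
            raise ValidationError("gradient scheme has no b=0 volume")
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        bad = np.abs(norms - 1.0) > 1e-4
        if np.any(bad):
            raise ValidationError(
                f"{int(bad.sum())} diffusion-weighted direction(s) not unit norm "
                f"(worst |norm-1| = {np.abs(norms - 1).max():.3g})"
            )
        if self.n_unique_directions < 6:
            raise ValidationError(
                "tensor not identifiable: fewer than 6 unique non-collinear "
                f"non-zero directions ({self.n_unique_directions})"
            )

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def n_unique_directions(self) -> int:
        """Unique non-zero directions up to sign (antipodal pairs collapse)."""
        dirs = self.bvecs[self.bvals > 0]
        if dirs.size == 0:
            return 0
        kept: list[np.ndarray] = []
        for d in dirs:
            if not any(abs(abs(float(d @ k)) - 1.0) < 1e-6 for k in kept):
                kept.append(d)
        return len(kept)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


@dataclass(frozen=True)
class DWIVolume:
    """A 4D diffusion-weighted signal with its grid and gradient table."""

    data: np.ndarray
    grid: VolumeGrid
    gradients: GradientScheme

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise FormatError(f"DWI data must be 4D, got {data.ndim}D")
        if data.shape[:3] != self.grid.shape:
            raise FormatError(
                f"data spatial shape {data.shape[:3]} != grid shape {self.grid.shape}"
            )
        if data.shape[3] != self.gradients.n_volumes:
            raise FormatError(
                f"image has {data.shape[3]} volumes but gradient table lists "
                f"{self.gradients.n_volumes}"
            )
        if np.any(data < 0):
            raise ValidationError("negative diffusion signal")


# ---------------------------------------------------------------------------
# file I/O


def read_gradients(bval_path, bvec_path) -> GradientScheme:
    """Parse FSL-dialect bval (one row) / bvec (three rows) text files.

    Directions within 1e-2 of unit norm are renormalized; anything farther
    off raises ``ValidationError``.
    """
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[0] == 3 and bvecs.shape[1] == 3:
        # ambiguous 3x3: FSL convention is three rows = x,y,z components
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise FormatError(
            f"bvec table shape {bvecs.shape} incompatible with {bvals.size} b-values"
        )
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    off = np.abs(norms - 1.0)
    if np.any(off > 1e-2):
        raise ValidationError(
            f"non-renormalizable gradient direction (|norm-1| up to {off.max():.3g})"
        )
    fixed = bvecs.copy()
    fixed[nz] = bvecs[nz] / norms[:, None]
    return GradientScheme(bvals=bvals, bvecs=fixed)


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4D NIfTI-1 diffusion series with its gradient table."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    gradients = read_gradients(bval_path, bvec_path)
    if data.shape[3] != gradients.n_volumes:
        raise FormatError(
            f"{image_path}: image has {data.shape[3]} volumes but gradient "
            f"table lists {gradients.n_volumes}"
        )
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(shape=data.shape[:3], voxel_size=zooms, affine=img.affine)
    data = np.clip(data, 0.0, None)  # magnitude data; tiny negative interp artefacts
    return DWIVolume(data=data, grid=grid, gradients=gradients)


def write_dwi(dwi: DWIVolume, image_path, bval_path=None, bvec_path=None) -> None:
    img = nib.Nifti1Image(dwi.data.astype(np.float32), dwi.grid.affine)
    img.header.set_zooms(dwi.grid.voxel_size + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None:
        np.savetxt(bval_path, dwi.gradients.bvals[None, :], fmt="%.6g")
    if bvec_path is not None:
        np.savetxt(bvec_path, dwi.gradients.bvecs.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# cohort tables


@dataclass
class CohortReadReport:
    n_rows: int
    n_missing_cells: int
    missing_by_column: dict[str, int]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check cohort invariants; returns the (typed) table.

    Invariants: (subject_id, session) unique; group constant within subject
    and drawn from {HC, PD_good, PD_poor}; time_from_baseline 0 at session 1;
    ALPS values positive where present.
    """
    missing = [c for c in COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing required column(s): {missing}")
    t = table.copy()
    t["session"] = t["session"].astype(int)
    if t.duplicated(["subject_id", "session"]).any():
        raise ValidationError("duplicate (subject_id, session) rows")
    bad_group = set(t["group"].dropna()) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"unknown group label(s): {sorted(bad_group)}")
    if (t.groupby("subject_id")["group"].nunique() > 1).any():
        raise ValidationError("group label varies within a subject")
    base = t.loc[t["session"] == 1, "time_from_baseline"]
    if not np.allclose(base.fillna(0.0), 0.0):
        raise ValidationError("time_from_baseline must be 0 at session 1")
    for col in ("alps_left", "alps_right", "alps_mean"):
        if col in t.columns and (t[col].dropna() <= 0).any():
            raise ValidationError(f"non-positive value in {col}")
    return t


def read_cohort(
    csv_path, schema: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, CohortReadReport]:
    """Read a clinical CSV into a validated cohort table.

    ``schema`` maps canonical column names to the CSV's column names.
    Unparseable numeric cells become NaN and are counted in the report.
    """
    raw = pd.read_csv(csv_path, dtype=str).rename(
        columns={v: k for k, v in (schema or {}).items()}
    )
    missing = [c for c in COHORT_REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"{csv_path}: missing required column(s): {missing}")
    numeric = [
        c
        for c in raw.columns
        if c not in ("subject_id", "group", "sex")
    ]
    t = raw.copy()
    missing_by_col: dict[str, int] = {}
    for c in numeric:
        parsed = pd.to_numeric(t[c], errors="coerce")
        n_bad = int((parsed.isna() & t[c].notna() & (t[c].str.strip() != "")).sum())
        n_blank = int((t[c].isna() | (t[c].str.strip() == "")).sum())
        if n_bad + n_blank:
            missing_by_col[c] = n_bad + n_blank
        t[c] = parsed
    t = validate_cohort(t)
    report = CohortReadReport(
        n_rows=len(t),
        n_missing_cells=int(sum(missing_by_col.values())),
        missing_by_column=missing_by_col,
    )
    return t, report


def write_cohort(table: pd.DataFrame, csv_path) -> None:
    table.to_csv(csv_path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated run configuration with documented defaults.

    ROI centers are 0-based voxel indices on the 1-mm JHU template grid;
    ``radius_mm`` is the sphere radius (5-mm spheres read as diameter).
    """

    roi_radius_mm: float = 2.5
    roi_centers: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {
            "projection_left": (116, 110, 99),
            "projection_right": (64, 110, 99),
            "association_left": (128, 110, 99),
            "association_right": (51, 110, 99),
        }
    )
    covariates: tuple[str, ...] = ("age", "sex")
    n_boot: int = 5000
    seed: int = 0
    output_dir: str = "alps_run"

    def validate(self) -> "RunConfig":
        if self.roi_radius_mm <= 0:
            raise ValidationError(f"roi_radius_mm must be > 0, got {self.roi_radius_mm}")
        if self.n_boot < 0:
            raise ValidationError(f"n_boot must be >= 0, got {self.n_boot}")
        if not (0 <= int(self.seed) < 2**31):
            raise ValidationError("seed must be in [0, 2^31)")
        for name, c in self.roi_centers.items():
            if len(c) != 3:
                raise ValidationError(f"ROI center {name} must be a triple")
        return self


def load_config(path=None, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration, filling defaults for absent keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "roi_centers" in data:
        data["roi_centers"] = {
            k: tuple(int(x) for x in v) for k, v in data["roi_centers"].items()
        }
    cfg = RunConfig(**data)
    return cfg.validate()


def setup_logging(logfile=None, level=logging.INFO) -> logging.Logger:
    """Plain-text log with timestamps; echoes to file when given."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    log.setLevel(level)
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)
    return log
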