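"""The DTI-ALPS index: atlas sphere ROIs and the diffusivity-ratio score.

At the level of the body of the lateral ventricle, perivascular fluid moves
predominantly along the medullary veins, i.e. the x (right-left) axis.
Projection fibers (superior corona radiata) run rostro-caudally (y) and
association fibers (superior longitudinal fasciculus) antero-posteriorly
(z), both orthogonal to the perivascular direction. The index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

therefore isolates the diffusion component along the perivascular axis from
the fiber components. It is computed per hemisphere from 5-mm spheres at
fixed JHU-atlas coordinates and averaged bilaterally; lower values are read
as poorer glymphatic clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ExtractionError, GeometryError
from .io import JHU_GRID, VolumeGrid
from .tensor import DiffusionTensorField, axis_diffusivities, fit_dti

HEMISPHERES = ("left", "right")
ROI_NAMES = ("projection", "association")


@dataclass(frozen=True)
class ROISpec:
    """A spherical ROI centered on a JHU-template voxel coordinate.

    ``center_voxel`` is a 0-based voxel index on the 1-mm JHU grid (which
    this package equates with world mm; see :mod:`dtialps.io`).
    ``radius_mm`` defaults to 2.5 (5-mm spheres read as diameter).
    """

    name: str
    hemisphere: str
    center_voxel: tuple[int, int, int]
    radius_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"ROI name must be one of {ROI_NAMES}, got {self.name!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        if self.radius_mm <= 0:
            raise GeometryError(f"radius_mm must be > 0, got {self.radius_mm}")
        object.__setattr__(
            self, "center_voxel", tuple(int(c) for c in self.center_voxel)
        )


def default_rois(radius_mm: float = 2.5, centers: Mapping | None = None) -> list[ROISpec]:
    """The four study ROIs: SCR (projection) and SLF (association), both sides."""
    c = {
        "projection_left": (116, 110, 99),
        "projection_right": (64, 110, 99),
        "association_left": (128, 110, 99),
        "association_right": (51, 110, 99),
    }
    if centers:
        c.update({k: tuple(v) for k, v in centers.items()})
    return [
        ROISpec("projection", "left", c["projection_left"], radius_mm),
        ROISpec("projection", "right", c["projection_right"], radius_mm),
        ROISpec("association", "left", c["association_left"], radius_mm),
        ROISpec("association", "right", c["association_right"], radius_mm),
    ]


def make_sphere_mask(
    center_voxel: Sequence[float], radius_mm: float, grid: VolumeGrid
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius_mm`` of the center.

    ``center_voxel`` is a (possibly fractional) voxel index on ``grid``;
    distances are measured in mm via the grid's voxel sizes. The nearest
    voxel to the center is always included.
    """
    center = np.asarray(center_voxel, dtype=float)
    if np.any(center < -0.5) or np.any(center > np.asarray(grid.shape) - 0.5):
        raise GeometryError(
            f"sphere center {tuple(np.round(center, 2))} outside grid {grid.shape}"
        )
    vs = np.asarray(grid.voxel_size)
    # bounding box to avoid full-grid broadcasting on large templates
    lo = np.maximum(np.floor(center - radius_mm / vs - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius_mm / vs + 1).astype(int), np.asarray(grid.shape) - 1)
    mask = np.zeros(grid.shape, dtype=bool)
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
    )
    d2 = (
        ((ii - center[0]) * vs[0]) ** 2
        + ((jj - center[1]) * vs[1]) ** 2
        + ((kk - center[2]) * vs[2]) ** 2
    )
    sub = d2 <= radius_mm**2
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = sub
    if not mask.any():
        nearest = tuple(int(np.clip(round(c), 0, s - 1)) for c, s in zip(center, grid.shape))
        mask[nearest] = True
    return mask


def roi_mask(roi: ROISpec, grid: VolumeGrid) -> np.ndarray:
    """Resolve an atlas-coordinate ROI onto an arbitrary grid.

    The JHU voxel index is mapped to world mm through the template affine,
    then into ``grid`` voxel coordinates.
    """
    world = JHU_GRID.voxel_to_world(np.asarray(roi.center_voxel, dtype=float))
    center = grid.world_to_voxel(world)
    return make_sphere_mask(center, roi.radius_mm, grid)


@dataclass(frozen=True)
class AxisDiffusivities:
    """The four diffusivities the ALPS formula consumes, for one hemisphere."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float

    @property
    def alps(self) -> float:
        denom = (self.dyy_proj + self.dzz_assoc) / 2.0
        if denom <= 0:
            raise ComputationError(
                f"non-positive ALPS denominator {denom:.3g} mm^2/s"
            )
        return ((self.dxx_proj + self.dxx_assoc) / 2.0) / denom


@dataclass
class ALPSResult:
    """Per-hemisphere and bilateral ALPS with audit diffusivities."""

    alps_left: float
    alps_right: float
    diffusivities: dict[str, AxisDiffusivities]
    voxel_counts: dict[str, int] = dc_field(default_factory=dict)
    n_clamped: int = 0

    @property
    def alps_mean(self) -> float:
        return (self.alps_left + self.alps_right) / 2.0

    def as_dict(self) -> dict:
        out = {
            "alps_left": self.alps_left,
            "alps_right": self.alps_right,
            "alps_mean": self.alps_mean,
            "voxel_counts": dict(self.voxel_counts),
            "n_clamped": self.n_clamped,
        }
        for hemi, d in self.diffusivities.items():
            out[f"diffusivities_{hemi}"] = {
                "dxx_proj": d.dxx_proj,
                "dxx_assoc": d.dxx_assoc,
                "dyy_proj": d.dyy_proj,
                "dzz_assoc": d.dzz_assoc,
            }
        return out


def compute_alps(
    field: DiffusionTensorField, rois: Sequence[ROISpec] | None = None
) -> ALPSResult:
    """Compute left, right and bilateral-mean ALPS from a tensor field.

    ``rois`` must contain a projection and an association sphere per
    hemisphere (defaults to the study coordinates). A non-positive
    denominator raises :class:`ComputationError` rather than returning NaN.
    """
    rois = list(rois) if rois is not None else default_rois()
    by_key = {(r.name, r.hemisphere): r for r in rois}
    needed = [(n, h) for h in HEMISPHERES for n in ROI_NAMES]
    missing = [k for k in needed if k not in by_key]
    if missing:
        raise ExtractionError(f"missing ROI spec(s): {missing}")

    diffs: dict[str, AxisDiffusivities] = {}
    counts: dict[str, int] = {}
    for hemi in HEMISPHERES:
        proj = by_key[("projection", hemi)]
        assoc = by_key[("association", hemi)]
        pm = roi_mask(proj, field.grid) & field.mask
        am = roi_mask(assoc, field.grid) & field.mask
        if not pm.any():
            raise ExtractionError(f"ROI projection_{hemi} intersects no valid voxels")
        if not am.any():
            raise ExtractionError(f"ROI association_{hemi} intersects no valid voxels")
        dxx_p, dyy_p, _ = axis_diffusivities(field, pm)
        dxx_a, _, dzz_a = axis_diffusivities(field, am)
        diffs[hemi] = AxisDiffusivities(
            dxx_proj=dxx_p, dxx_assoc=dxx_a, dyy_proj=dyy_p, dzz_assoc=dzz_a
        )
        counts[f"projection_{hemi}"] = int(pm.sum())
        counts[f"association_{hemi}"] = int(am.sum())

    return ALPSResult(
        alps_left=diffs["left"].alps,
        alps_right=diffs["right"].alps,
        diffusivities=diffs,
        voxel_counts=counts,
        n_clamped=field.n_clamped,
    )


def batch_alps(
    records: Iterable[Mapping],
    rois: Sequence[ROISpec] | None = None,
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Score a batch of subject-sessions; per-subject failures are collected.

    Each record needs ``subject_id``, ``session`` and either ``dwi`` (an
    in-memory :class:`~dtialps.io.DWIVolume`) or the path triple
    ``image``/``bval``/``bvec``. Returns (table, failures); failures carry
    the record identifiers and the error message, and never abort the batch.
    """
    from .io import read_dwi  # local to keep module import light

    rows: list[dict] = []
    failures: list[dict] = []
    for rec in records:
        sid = rec.get("subject_id", "?")
        ses = rec.get("session", 1)
        try:
            dwi = rec.get("dwi")
            if dwi is None:
                dwi = read_dwi(rec["image"], rec["bval"], rec["bvec"])
            field = fit_dti(dwi, mask=mask)
            res = compute_alps(field, rois)
            row = {
                "subject_id": sid,
                "session": ses,
                "alps_left": res.alps_left,
                "alps_right": res.alps_right,
                "alps_mean": res.alps_mean,
                "n_clamped": res.n_clamped,
            }
            row.update({f"n_vox_{k}": v for k, v in res.voxel_counts.items()})
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 — per-subject failures are data
            failures.append({"subject_id": sid, "session": ses, "error": str(exc)})
    return pd.DataFrame(rows), failures
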