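"""Per-voxel diffusion tensor estimation.

The signal model is the monoexponential tensor model
``S = S0 * exp(-b * g^T D g)``. With d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) the
exponent is linear in d, so the fit is ordinary least squares on
``log(S0 / S)`` against design rows
``(b gx^2, b gy^2, b gz^2, 2b gx gy, 2b gx gz, 2b gy gz)``.

Diffusivity "along an axis" means the corresponding diagonal tensor element
(Dxx etc.), matching the ALPS formula's symbols directly — not a projection
of the eigen-decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ExtractionError, ValidationError
from .io import DWIVolume, GradientScheme, VolumeGrid

#: storage order of the six unique tensor components
TENSOR_COMPONENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


def design_matrix(gradients: GradientScheme) -> np.ndarray:
    """(n_volumes, 6) design B with rows b*(gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz)."""
    b = gradients.bvals
    g = gradients.bvecs
    return np.column_stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ]
    )


@dataclass
class DiffusionTensorField:
    """Six unique tensor components per voxel on a grid, plus a validity mask.

    ``components`` has shape grid.shape + (6,) in :data:`TENSOR_COMPONENTS`
    order, units mm^2/s. ``clamped`` marks voxels whose unclamped fit had a
    negative diagonal element (clamped to 0 and kept valid).
    """

    components: np.ndarray
    grid: VolumeGrid
    mask: np.ndarray
    clamped: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != self.grid.shape + (6,):
            raise ValidationError(
                f"components shape {self.components.shape} != grid {self.grid.shape} + (6,)"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.clamped is None:
            self.clamped = np.zeros(self.grid.shape, dtype=bool)
        if not np.all(np.isfinite(self.components[self.mask])):
            raise ValidationError("non-finite tensor components inside the mask")

    @property
    def n_clamped(self) -> int:
        return int(self.clamped.sum())

    def diagonal(self) -> np.ndarray:
        """(..., 3) view of (Dxx, Dyy, Dzz)."""
        return self.components[..., :3]

    def scaled(self, k: float) -> "DiffusionTensorField":
        return DiffusionTensorField(
            components=self.components * k,
            grid=self.grid,
            mask=self.mask.copy(),
            clamped=self.clamped.copy(),
        )


def fit_dti(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    signal_floor_frac: float = 1e-6,
) -> DiffusionTensorField:
    """Ordinary-least-squares tensor fit on log-attenuation.

    S0 is the mean of the b=0 volumes per voxel. Signals <= 0 are clamped to
    ``signal_floor_frac * S0`` before the log. Voxels with all-zero signal
    (or zero S0) are masked out rather than failing. Negative fitted
    diagonal elements are clamped to 0 and flagged in ``clamped``.
    """
    scheme = dwi.gradients
    B = design_matrix(scheme)
    dwb = B[scheme.bvals > 0]
    if np.linalg.matrix_rank(dwb) < 6:
        raise ValidationError(
            "degenerate gradient scheme: design matrix rank "
            f"{np.linalg.matrix_rank(dwb)} < 6 (collinear directions)"
        )
    shape = dwi.grid.shape
    data = dwi.data.reshape(-1, scheme.n_volumes)
    s0 = data[:, scheme.b0_mask].mean(axis=1)

    fit_mask = s0 > 0
    if mask is not None:
        fit_mask &= np.asarray(mask, dtype=bool).reshape(-1)

    idx = np.flatnonzero(fit_mask)
    comps = np.zeros((data.shape[0], 6))
    clamped = np.zeros(data.shape[0], dtype=bool)
    if idx.size:
        s = data[idx]
        floor = signal_floor_frac * s0[idx, None]
        s = np.maximum(s, floor)
        y = np.log(s0[idx, None] / s)  # (n_vox, n_vol)
        pinv = np.linalg.pinv(B)  # (6, n_vol)
        d = y @ pinv.T  # (n_vox, 6)
        neg = d[:, :3] < 0
        clamped[idx] = neg.any(axis=1)
        d[:, :3] = np.maximum(d[:, :3], 0.0)
        comps[idx] = d

    return DiffusionTensorField(
        components=comps.reshape(shape + (6,)),
        grid=dwi.grid,
        mask=fit_mask.reshape(shape),
        clamped=clamped.reshape(shape),
    )


def axis_diffusivities(field: DiffusionTensorField, roi) -> tuple[float, float, float]:
    """Mean (Dxx, Dyy, Dzz) over masked-in voxels of an ROI.

    ``roi`` is either a boolean mask on the field's grid or an
    :class:`~dtialps.alps.ROISpec` (resolved against the grid via the atlas
    convention).
    """
    if hasattr(roi, "center_voxel"):
        from .alps import roi_mask  # late import; alps builds on this module

        name = f"{roi.name}_{roi.hemisphere}"
        mask = roi_mask(roi, field.grid)
    else:
        name = "mask"
        mask = np.asarray(roi, dtype=bool)
    mask = mask & field.mask
    if not mask.any():
        raise ExtractionError(f"ROI {name} intersects no valid voxels")
    diag = field.diagonal()[mask]
    dxx, dyy, dzz = diag.mean(axis=0)
    return float(dxx), float(dyy), float(dzz)
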