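"""Synthetic cohorts and diffusion phantoms with known ground truth.

Two generators make the pipeline fully testable without any download:

* :func:`simulate_cohort` draws a three-group cohort (28 healthy controls,
  67 PD good-outcome, 31 PD poor-outcome) whose bilateral ALPS
  distributions, left-right coupling, ALPS-cognition partial correlation
  and group-specific longitudinal decline equal configured targets
  (defaults are the study-condition values).
* :func:`simulate_tensor_field` / :func:`simulate_dwi` embed prescribed
  axis diffusivities inside the four atlas spheres of a template-space
  phantom and synthesize the diffusion-weighted signal
  ``S = S0 exp(-b g^T D g)`` with optional Rician or Gaussian noise, so the
  analytic ALPS of the embedded truth is recoverable end to end.

Calibration notes
-----------------
Left and right ALPS are built from a shared per-subject latent: the
bilateral mean is drawn at the group mean/SD and a left-right difference is
added with variance set by a within-group Pearson coupling rho_w. Because
the three group means differ, mixing the groups adds shared variance that
raises the whole-cohort correlation above rho_w; rho_w is therefore solved
numerically (Gauss-Hermite integration of the bivariate-normal grade
correlation ``(6/pi) asin(rho/2)`` over the three-component mixture, with
the standard finite-n expectation correction) so that the *expected sample
Spearman over the full cohort* equals the requested value.

The composite cognitive score is linear in the baseline ALPS residual
(after age and sex), with the coupling coefficient mapped from the target
partial Spearman through ``2 sin(pi rho_s / 6)``; group differences in
cognition therefore arise only through the groups' ALPS differences.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._directions import DIRECTIONS_30
from .alps import ROISpec, AxisDiffusivities, default_rois, roi_mask
from .clinical import COMPOSITE_TESTS, DEFAULT_CONTROL_STATS
from .errors import GeometryError, ValidationError
from .io import DWIVolume, GradientScheme, JHU_GRID, VolumeGrid, validate_cohort
from .tensor import DiffusionTensorField, design_matrix

GROUP_ORDER = ("HC", "PD_good", "PD_poor")


# ---------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class CohortSimParams:
    """Study-condition parameters of the synthetic cohort.

    ALPS means/SDs, group sizes, the interhemispheric Spearman target, the
    ALPS-cognition partial correlations and the poor-group extra decline per
    session are the study's printed values; age and sex compositions follow
    the baseline demographics table.
    """

    n_per_group: Mapping[str, int] = dc_field(
        default_factory=lambda: {"HC": 28, "PD_good": 67, "PD_poor": 31}
    )
    alps_mean_per_group: Mapping[str, float] = dc_field(
        default_factory=lambda: {"HC": 1.18, "PD_good": 1.19, "PD_poor": 1.08}
    )
    alps_sd_per_group: Mapping[str, float] = dc_field(
        default_factory=lambda: {"HC": 0.20, "PD_good": 0.16, "PD_poor": 0.16}
    )
    lr_correlation: float = 0.819  # full-cohort Spearman target
    cognition_partial_rho: float = 0.226  # baseline, PD pool, given age+sex
    cognition_partial_rho_session3: float = 0.25  # baseline ALPS vs session-3 cognition
    group_time_beta: float = -0.057  # extra PD_poor ALPS change per session
    base_slope: float = 0.0  # per-session ALPS drift shared by all groups
    session_noise_sd: float = 0.05  # repeat-measurement noise on bilateral ALPS
    age_mean_sd: Mapping[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {
            "HC": (65.7, 9.1),
            "PD_good": (62.4, 7.0),
            "PD_poor": (68.5, 8.5),
        }
    )
    sex_counts_fm: Mapping[str, tuple[int, int]] = dc_field(
        default_factory=lambda: {
            "HC": (15, 13),
            "PD_good": (38, 29),
            "PD_poor": (8, 23),
        }
    )
    cognition_sd: float = 0.7  # SD of the composite score
    cognition_age_coef: float = -0.02  # z-units per year (centered)
    cognition_sex_coef: float = 0.1  # z-units, M vs F
    n_sessions: int = 2
    alps_floor: float = 0.01
    seed: int = 0

    def validate(self) -> "CohortSimParams":
        for g in GROUP_ORDER:
            if self.n_per_group[g] < 2:
                raise ValidationError(f"n_per_group[{g}] must be >= 2")
            if self.alps_sd_per_group[g] <= 0:
                raise ValidationError(f"alps_sd_per_group[{g}] must be > 0")
        for r in (
            self.lr_correlation,
            self.cognition_partial_rho,
            self.cognition_partial_rho_session3,
        ):
            if not abs(r) < 1:
                raise ValidationError(f"|correlation| must be < 1, got {r}")
        if not 1 <= self.n_sessions <= 3:
            raise ValidationError("n_sessions must be 1, 2 or 3")
        return self

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group[g] for g in GROUP_ORDER)


def _grade_rho(rho_spearman: float) -> float:
    """Bivariate-normal Pearson giving the requested Spearman (grade relation)."""
    return 2.0 * np.sin(np.pi * rho_spearman / 6.0)


@functools.lru_cache(maxsize=32)
def _hermgauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()  # probabilists' nodes, weights summing to 1


def _mixture_expected_spearman(
    rho_w: float,
    weights: np.ndarray,
    means: np.ndarray,
    group_sds: np.ndarray,
    n_sample: int,
    n_nodes: int = 48,
) -> float:
    """Expected sample Spearman of (left, right) over the group mixture.

    Within group g, (L, R) is bivariate normal with mean mu_g, marginal SD
    sigma_g * sqrt(2/(1+rho_w)) (so the bilateral mean has SD sigma_g) and
    correlation rho_w. The population grade correlation is
    12 E[F(L) F(R)] - 3 with F the mixture marginal CDF; the finite-n
    expectation uses the standard ((n-2) rho_S + (6/pi) asin rho_P)/(n+1)
    correction with the mixture's Pearson rho_P.
    """
    sd_lr = group_sds * np.sqrt(2.0 / (1.0 + rho_w))
    x, wq = _hermgauss(n_nodes)
    u = x[:, None]
    v = x[None, :]
    w2 = wq[:, None] * wq[None, :]

    def mixture_cdf(vals: np.ndarray) -> np.ndarray:
        out = np.zeros_like(vals)
        for wg, mg, sg in zip(weights, means, sd_lr):
            out += wg * stats.norm.cdf((vals - mg) / sg)
        return out

    e_ff = 0.0
    for wg, mg, sg in zip(weights, means, sd_lr):
        left = mg + sg * u
        right = mg + sg * (rho_w * u + np.sqrt(1.0 - rho_w**2) * v)
        e_ff += wg * float(np.sum(w2 * mixture_cdf(left) * mixture_cdf(right)))
    rho_s_pop = 12.0 * e_ff - 3.0

    mu_bar = float(weights @ means)
    cov = float(weights @ (rho_w * sd_lr**2 + (means - mu_bar) ** 2))
    var = float(weights @ (sd_lr**2 + (means - mu_bar) ** 2))
    rho_p = np.clip(cov / var, -1.0, 1.0)
    n = n_sample
    return ((n - 2) * rho_s_pop + (6.0 / np.pi) * np.arcsin(rho_p)) / (n + 1)


@functools.lru_cache(maxsize=64)
def _calibrate_lr_pearson(
    target_spearman: float,
    group_tuple: tuple[tuple[int, float, float], ...],
) -> float:
    """Within-group Pearson coupling whose expected full-cohort sample
    Spearman equals ``target_spearman``."""
    ns = np.array([g[0] for g in group_tuple], dtype=float)
    means = np.array([g[1] for g in group_tuple])
    sds = np.array([g[2] for g in group_tuple])
    n = int(ns.sum())
    weights = ns / n

    def f(rho: float) -> float:
        return (
            _mixture_expected_spearman(rho, weights, means, sds, n) - target_spearman
        )

    lo, hi = -0.999, 0.9999995
    if f(hi) < 0:  # target beyond what the mixture can reach; saturate
        return hi
    if f(lo) > 0:
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _residualize(y: np.ndarray, design_cols: Sequence[np.ndarray]) -> np.ndarray:
    X = np.column_stack([np.ones_like(y), *design_cols])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _cognition_for_pool(
    rng: np.random.Generator,
    alps0: np.ndarray,
    age: np.ndarray,
    sexnum: np.ndarray,
    rho_targets: Mapping[int, float],
    sessions: Sequence[int],
    params: CohortSimParams,
    intercept: float,
) -> dict[int, np.ndarray]:
    """Composite scores per session, coupled to the baseline ALPS residual."""
    r = _residualize(alps0, [age, sexnum])
    sd = r.std(ddof=0)
    z_r = r / sd if sd > 0 else np.zeros_like(r)
    nuisance = (
        params.cognition_age_coef * (age - age.mean())
        + params.cognition_sex_coef * (sexnum - sexnum.mean())
    )
    out: dict[int, np.ndarray] = {}
    for s in sessions:
        rho_p = _grade_rho(rho_targets[s])
        eps = rng.standard_normal(alps0.size)
        out[s] = intercept + nuisance + params.cognition_sd * (
            rho_p * z_r + np.sqrt(1.0 - rho_p**2) * eps
        )
    return out


def _raw_test_scores(
    rng: np.random.Generator, composite: np.ndarray
) -> dict[str, np.ndarray]:
    """Six raw test scores whose control-referenced z-scores average back to
    ``composite`` exactly (component scatter is centered per subject)."""
    n = composite.size
    tests = list(COMPOSITE_TESTS)
    eta = rng.normal(0.0, 0.4, size=(n, len(tests)))
    eta -= eta.mean(axis=1, keepdims=True)
    out: dict[str, np.ndarray] = {}
    for j, t in enumerate(tests):
        mean, sd = DEFAULT_CONTROL_STATS[t]
        z = composite + eta[:, j]
        out[t] = mean + COMPOSITE_TESTS[t] * sd * z
    return out


def simulate_cohort(
    params: CohortSimParams | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw one long-format synthetic cohort.

    One row per subject-session with group, age, sex, left/right/bilateral
    ALPS, the composite cognitive score and the six raw battery tests it is
    built from. ``seed`` overrides ``params.seed``.
    """
    params = (params or CohortSimParams()).validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    group_tuple = tuple(
        (
            int(params.n_per_group[g]),
            float(params.alps_mean_per_group[g]),
            float(params.alps_sd_per_group[g]),
        )
        for g in GROUP_ORDER
    )
    rho_w = _calibrate_lr_pearson(float(params.lr_correlation), group_tuple)

    sessions = list(range(1, params.n_sessions + 1))
    rho_targets = {
        1: params.cognition_partial_rho,
        2: (params.cognition_partial_rho + params.cognition_partial_rho_session3) / 2,
        3: params.cognition_partial_rho_session3,
    }

    per_group: dict[str, dict] = {}
    counter = 0
    for g in GROUP_ORDER:
        n = params.n_per_group[g]
        mu, sd = params.alps_mean_per_group[g], params.alps_sd_per_group[g]
        amu, asd = params.age_mean_sd[g]
        n_f, n_m = params.sex_counts_fm[g]
        if n_f + n_m != n:
            raise ValidationError(f"sex counts for {g} must sum to n_per_group")
        age = np.clip(rng.normal(amu, asd, n), 35.0, 95.0)
        sex = np.array(["F"] * n_f + ["M"] * n_m)
        rng.shuffle(sex)
        m0 = rng.normal(mu, sd, n)
        sd_d = 2.0 * sd * np.sqrt(max(1.0 - rho_w, 0.0) / (1.0 + rho_w))
        d = rng.normal(0.0, sd_d, n)
        slope = params.base_slope + (
            params.group_time_beta if g == "PD_poor" else 0.0
        )
        ids = [f"{g}{counter + i:03d}" for i in range(n)]
        counter += n
        per_group[g] = dict(ids=ids, age=age, sex=sex, m0=m0, d=d, slope=slope)

    # cognition: couple to baseline ALPS residual within the PD pool (the
    # pool the correlation analyses run on) and, separately, within HC
    pd_alps0 = np.concatenate([per_group[g]["m0"] for g in ("PD_good", "PD_poor")])
    pd_age = np.concatenate([per_group[g]["age"] for g in ("PD_good", "PD_poor")])
    pd_sex = np.concatenate(
        [(per_group[g]["sex"] == "M").astype(float) for g in ("PD_good", "PD_poor")]
    )
    pd_cog = _cognition_for_pool(
        rng, pd_alps0, pd_age, pd_sex, rho_targets, sessions, params, intercept=-0.3
    )
    hc = per_group["HC"]
    hc_cog = _cognition_for_pool(
        rng,
        hc["m0"],
        hc["age"],
        (hc["sex"] == "M").astype(float),
        rho_targets,
        sessions,
        params,
        intercept=0.07,
    )
    n_good = params.n_per_group["PD_good"]
    cog = {
        "HC": hc_cog,
        "PD_good": {s: pd_cog[s][:n_good] for s in sessions},
        "PD_poor": {s: pd_cog[s][n_good:] for s in sessions},
    }

    rows: list[dict] = []
    for g in GROUP_ORDER:
        info = per_group[g]
        n = params.n_per_group[g]
        for s in sessions:
            t = s - 1
            noise = (
                rng.normal(0.0, params.session_noise_sd, n) if t > 0 else np.zeros(n)
            )
            m_t = info["m0"] + info["slope"] * t + noise
            left = np.maximum(m_t + info["d"] / 2.0, params.alps_floor)
            right = np.maximum(m_t - info["d"] / 2.0, params.alps_floor)
            composite = cog[g][s]
            raw = _raw_test_scores(rng, composite)
            for i in range(n):
                row = {
                    "subject_id": info["ids"][i],
                    "group": g,
                    "age": float(info["age"][i]),
                    "sex": str(info["sex"][i]),
                    "session": s,
                    "time_from_baseline": 1.5 * t,
                    "alps_left": float(left[i]),
                    "alps_right": float(right[i]),
                    "alps_mean": float((left[i] + right[i]) / 2.0),
                    "composite_cognition": float(composite[i]),
                }
                row.update({k: float(v[i]) for k, v in raw.items()})
                rows.append(row)

    return validate_cohort(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# diffusion phantom


def default_gradient_scheme(n_b0: int = 6, bval: float = 1000.0) -> GradientScheme:
    """6 x b=0 plus 30 electrostatically spread directions at b=1000 s/mm^2."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(DIRECTIONS_30), bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), DIRECTIONS_30])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def default_phantom_grid() -> VolumeGrid:
    """Cropped 2-mm template grid (96 x 110 x 96) covering the JHU extent."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag([2.0, 2.0, 2.0])
    return VolumeGrid(shape=(96, 110, 96), voxel_size=(2.0, 2.0, 2.0), affine=aff)


def minimal_roi_grid(
    rois: Sequence[ROISpec] | None = None,
    margin_mm: float = 3.0,
    voxel_mm: float = 2.0,
) -> VolumeGrid:
    """Smallest grid bracketing the ROI spheres plus a margin.

    ALPS only reads the four spheres, so phantoms on this grid score
    identically (up to noise realization) to full-template phantoms at a
    fraction of the cost; used for large simulation batteries.
    """
    rois = list(rois) if rois is not None else default_rois()
    centers = JHU_GRID.voxel_to_world(
        np.array([r.center_voxel for r in rois], dtype=float)
    )
    pad = max(r.radius_mm for r in rois) + margin_mm
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    shape = tuple(int(np.ceil((h - l) / voxel_mm)) + 1 for l, h in zip(lo, hi))
    aff = np.eye(4)
    aff[:3, :3] = np.diag([voxel_mm] * 3)
    aff[:3, 3] = lo
    return VolumeGrid(shape=shape, voxel_size=(voxel_mm,) * 3, affine=aff)


def truth_for_alps(
    alps_left: float,
    alps_right: float,
    dyy_proj: float = 0.8e-3,
    dzz_assoc: float = 0.7e-3,
) -> dict[str, AxisDiffusivities]:
    """Axis diffusivities whose analytic ALPS equals the requested values.

    The fiber-axis diffusivities are held fixed and the perivascular-axis
    diffusivity is scaled: Dxx = alps * (Dyy_proj + Dzz_assoc) / 2.
    """
    denom = (dyy_proj + dzz_assoc) / 2.0
    out = {}
    for hemi, a in (("left", alps_left), ("right", alps_right)):
        if a <= 0:
            raise ValidationError(f"ALPS truth must be positive, got {a}")
        out[hemi] = AxisDiffusivities(
            dxx_proj=a * denom,
            dxx_assoc=a * denom,
            dyy_proj=dyy_proj,
            dzz_assoc=dzz_assoc,
        )
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """A template-space phantom with ROI-embedded ground truth.

    Background voxels are isotropic at ``background_diffusivity``;
    projection spheres carry diag(Dxx_proj, Dyy_proj, background) and
    association spheres diag(Dxx_assoc, background, Dzz_assoc), so the
    analytic ALPS of the truth is mean(Dxx)/mean(Dyy_proj, Dzz_assoc).
    """

    roi_truth: Mapping[str, AxisDiffusivities]
    grid: VolumeGrid = dc_field(default_factory=default_phantom_grid)
    rois: tuple[ROISpec, ...] = dc_field(
        default_factory=lambda: tuple(default_rois())
    )
    background_diffusivity: float = 0.8e-3
    s0: float = 1000.0
    snr: float = 30.0
    noise_model: str = "rician"

    def validate(self) -> "PhantomSpec":
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and not self.snr > 0:
            raise ValidationError("snr must be > 0 unless noise_model is 'none'")
        vals = [self.background_diffusivity]
        for hemi in ("left", "right"):
            t = self.roi_truth[hemi]
            vals += [t.dxx_proj, t.dxx_assoc, t.dyy_proj, t.dzz_assoc]
        if not all(0 < v < 4e-3 for v in vals):
            raise ValidationError("diffusivities must lie in (0, 4e-3) mm^2/s")
        return self

    @property
    def analytic_alps(self) -> dict[str, float]:
        return {h: self.roi_truth[h].alps for h in ("left", "right")}


def _check_sphere_fits(roi: ROISpec, grid: VolumeGrid) -> None:
    world = JHU_GRID.voxel_to_world(np.asarray(roi.center_voxel, dtype=float))
    c = grid.world_to_voxel(world)
    vs = np.asarray(grid.voxel_size)
    lo_ok = np.all(c - roi.radius_mm / vs >= -0.5)
    hi_ok = np.all(c + roi.radius_mm / vs <= np.asarray(grid.shape) - 0.5)
    if not (lo_ok and hi_ok):
        raise GeometryError(
            f"ROI {roi.name}_{roi.hemisphere} (radius {roi.radius_mm} mm) does "
            f"not fit inside grid {grid.shape}"
        )


def simulate_tensor_field(spec: PhantomSpec) -> DiffusionTensorField:
    """Axis-aligned diagonal tensor field realizing the phantom geometry."""
    spec.validate()
    grid = spec.grid
    bg = spec.background_diffusivity
    comps = np.zeros(grid.shape + (6,))
    comps[..., 0] = comps[..., 1] = comps[..., 2] = bg
    for roi in spec.rois:
        _check_sphere_fits(roi, grid)
        mask = roi_mask(roi, grid)
        t = spec.roi_truth[roi.hemisphere]
        if roi.name == "projection":
            comps[mask, 0] = t.dxx_proj
            comps[mask, 1] = t.dyy_proj
            comps[mask, 2] = bg
        else:
            comps[mask, 0] = t.dxx_assoc
            comps[mask, 1] = bg
            comps[mask, 2] = t.dzz_assoc
    return DiffusionTensorField(
        components=comps, grid=grid, mask=np.ones(grid.shape, dtype=bool)
    )


def simulate_dwi(
    field: DiffusionTensorField,
    gradients: GradientScheme | None = None,
    s0: float = 1000.0,
    snr: float = 30.0,
    noise_model: str = "rician",
    seed: int = 0,
) -> DWIVolume:
    """Monoexponential tensor signal with optional noise.

    Rician noise is the magnitude of a complex Gaussian perturbation with
    sigma = s0 / snr (the floor-biased regime of magnitude MRI); Gaussian
    noise is additive real noise clipped at zero. Deterministic given seed.
    """
    gradients = gradients or default_gradient_scheme()
    B = design_matrix(gradients)
    exponent = field.components.reshape(-1, 6) @ B.T  # (n_vox, n_vol)
    signal = s0 * np.exp(-exponent)
    if noise_model != "none":
        sigma = s0 / snr
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            n1 = rng.normal(0.0, sigma, signal.shape)
            n2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        elif noise_model == "gaussian":
            signal = np.clip(signal + rng.normal(0.0, sigma, signal.shape), 0.0, None)
        else:
            raise ValidationError(f"unknown noise model {noise_model!r}")
    data = signal.reshape(field.grid.shape + (gradients.n_volumes,))
    return DWIVolume(data=data, grid=field.grid, gradients=gradients)


def phantom_for_alps(
    alps_left: float, alps_right: float, **spec_kwargs
) -> PhantomSpec:
    """Convenience: a validated phantom embedding the given hemispheric ALPS."""
    truth = truth_for_alps(alps_left, alps_right)
    return PhantomSpec(roi_truth=truth, **spec_kwargs).validate()
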