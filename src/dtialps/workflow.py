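"""End-to-end drivers: cohort-scale imaging, the analysis battery, full runs.

:class:`PhantomPipeline` amortizes everything that is constant across
subjects (sphere masks, the gradient design and its pseudoinverse) so that
whole cohorts — and multi-seed simulation batteries — can be pushed through
the signal-synthesis -> tensor-fit -> ROI -> index chain quickly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .alps import ROISpec, compute_alps, default_rois
from .errors import ComputationError
from .io import GradientScheme, RunConfig, VolumeGrid, log, write_cohort
from .synthetic import (
    CohortSimParams,
    default_gradient_scheme,
    minimal_roi_grid,
    phantom_for_alps,
    simulate_cohort,
    simulate_dwi,
    simulate_tensor_field,
)
from .tensor import fit_dti


@dataclass
class PhantomPipeline:
    """Reusable synthetic DWI -> fit -> ALPS chain on a fixed grid/scheme."""

    grid: VolumeGrid | None = None
    gradients: GradientScheme | None = None
    rois: Sequence[ROISpec] | None = None
    s0: float = 1000.0
    snr: float = 30.0
    noise_model: str = "rician"

    def __post_init__(self) -> None:
        self.rois = list(self.rois) if self.rois is not None else default_rois()
        if self.grid is None:
            self.grid = minimal_roi_grid(self.rois)
        if self.gradients is None:
            self.gradients = default_gradient_scheme()

    def measure(self, alps_left: float, alps_right: float, seed: int) -> dict:
        """One subject: embed truth, synthesize signal, fit, score."""
        spec = phantom_for_alps(
            alps_left,
            alps_right,
            grid=self.grid,
            rois=tuple(self.rois),
            s0=self.s0,
            snr=self.snr,
            noise_model=self.noise_model,
        )
        field = simulate_tensor_field(spec)
        dwi = simulate_dwi(
            field,
            self.gradients,
            s0=self.s0,
            snr=self.snr,
            noise_model=self.noise_model,
            seed=seed,
        )
        fitted = fit_dti(dwi)
        res = compute_alps(fitted, self.rois)
        return {
            "alps_left": res.alps_left,
            "alps_right": res.alps_right,
            "alps_mean": res.alps_mean,
            "n_clamped": res.n_clamped,
        }


def measure_cohort_alps(
    cohort: pd.DataFrame,
    pipeline: PhantomPipeline | None = None,
    sessions: Sequence[int] = (1,),
    seed: int = 0,
) -> pd.DataFrame:
    """Re-measure each subject-session's ALPS through the imaging chain.

    The cohort's simulated ``alps_left/right`` are embedded as phantom
    ground truth; returned rows carry ``measured_alps_*`` columns alongside
    the originals. Per-row noise seeds derive deterministically from
    ``seed`` and the row's position.
    """
    pipe = pipeline or PhantomPipeline()
    rows = cohort[cohort["session"].isin(sessions)].reset_index(drop=True).copy()
    measured = {"measured_alps_left": [], "measured_alps_right": [], "measured_alps_mean": []}
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = ss.generate_state(len(rows)) % (2**31)
    for i, row in rows.iterrows():
        out = pipe.measure(row["alps_left"], row["alps_right"], int(child_seeds[i]))
        measured["measured_alps_left"].append(out["alps_left"])
        measured["measured_alps_right"].append(out["alps_right"])
        measured["measured_alps_mean"].append(out["alps_mean"])
    for k, v in measured.items():
        rows[k] = v
    return rows


# ---------------------------------------------------------------------------
# cohort-level analysis battery


def analyze_cohort(
    cohort: pd.DataFrame,
    alps_col: str = "alps_mean",
    covariates: Sequence[str] = ("age", "sex"),
    seed: int = 0,
    n_boot: int = 5000,
) -> dict:
    """The study's statistics on one cohort table.

    Baseline group comparison of ALPS; interhemispheric Spearman; partial
    Spearman of baseline ALPS with cognition at baseline and (when present)
    at session 3, within the PD pool, given age and sex; the group-by-time
    mixed model; and a mediation of the poor-outcome indicator's effect on
    cognition through ALPS. Returns a JSON-serializable dict.
    """
    base = cohort[cohort["session"] == 1]
    pdpool = base[base["group"].isin(["PD_good", "PD_poor"])]
    out: dict = {"n_baseline": int(len(base)), "n_pd_baseline": int(len(pdpool))}

    cmp_res = st.compare_groups(base[alps_col], base["group"])
    out["group_comparison"] = {
        "test": cmp_res.test_name,
        "statistic": cmp_res.statistic,
        "pvalue": cmp_res.pvalue,
        "posthoc": cmp_res.posthoc.to_dict(orient="records"),
    }
    out["group_means"] = {
        g: {
            "mean": float(d[alps_col].mean()),
            "sd": float(d[alps_col].std(ddof=1)),
            "n": int(len(d)),
        }
        for g, d in base.groupby("group")
    }

    lr = st.partial_spearman(base["alps_left"], base["alps_right"])
    out["interhemispheric_spearman"] = {"rho": lr.rho, "pvalue": lr.pvalue, "n": lr.n_used}

    cov = pd.DataFrame(
        {
            "age": pdpool["age"].to_numpy(dtype=float),
            "sex": st._sex_numeric(pdpool["sex"]),
        }
    )
    pc = st.partial_spearman(
        pdpool[alps_col], pdpool["composite_cognition"], cov, covariate_names=tuple(covariates)
    )
    out["alps_cognition_baseline"] = {"rho": pc.rho, "pvalue": pc.pvalue, "n": pc.n_used}

    if (cohort["session"] == 3).any():
        s3 = cohort[(cohort["session"] == 3)][["subject_id", "composite_cognition"]]
        merged = pdpool.merge(s3, on="subject_id", suffixes=("", "_s3")).dropna(
            subset=[alps_col, "composite_cognition_s3"]
        )
        cov3 = pd.DataFrame(
            {
                "age": merged["age"].to_numpy(dtype=float),
                "sex": st._sex_numeric(merged["sex"]),
            }
        )
        pc3 = st.partial_spearman(
            merged[alps_col],
            merged["composite_cognition_s3"],
            cov3,
            covariate_names=tuple(covariates),
        )
        out["alps_cognition_session3"] = {
            "rho": pc3.rho,
            "pvalue": pc3.pvalue,
            "n": pc3.n_used,
        }

    if cohort["session"].nunique() >= 2:
        lm = st.fit_group_time_model(cohort, outcome=alps_col, covariates=covariates)
        out["group_time_model"] = {
            "interaction_beta": lm.interaction_beta,
            "interaction_p": lm.interaction_p,
            "n_subjects": lm.n_subjects,
            "n_observations": lm.n_observations,
            "converged": lm.converged,
            "coefficients": {
                term: {
                    "estimate": float(r["estimate"]),
                    "se": float(r["se"]),
                    "pvalue": float(r["pvalue"]),
                }
                for term, r in lm.coefficients.iterrows()
            },
        }

    med_base = base.dropna(subset=[alps_col, "composite_cognition"])
    poor = (med_base["group"] == "PD_poor").astype(float)
    med_cov = np.column_stack(
        [med_base["age"].to_numpy(dtype=float), st._sex_numeric(med_base["sex"])]
    )
    try:
        med = st.mediation(
            poor,
            med_base[alps_col],
            med_base["composite_cognition"],
            med_cov,
            n_boot=n_boot,
            seed=seed,
        )
        out["mediation_poor_alps_cognition"] = {
            "total": med.total,
            "direct": med.direct,
            "indirect": med.indirect,
            "ci_total": med.ci_total,
            "ci_direct": med.ci_direct,
            "ci_indirect": med.ci_indirect,
            "n": med.n_used,
            "n_boot": med.n_boot,
        }
    except (ComputationError, Exception) as exc:  # pragma: no cover - defensive
        out["mediation_poor_alps_cognition"] = {"error": str(exc)}
    return out


# ---------------------------------------------------------------------------
# full workflow


def config_hash(cfg: RunConfig, extra: Mapping | None = None) -> str:
    payload = {**asdict(cfg), **(extra or {})}
    payload.pop("output_dir", None)  # where a run lands must not change its identity
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_full_workflow(
    cfg: RunConfig,
    sim_params: CohortSimParams | None = None,
    imaging_sessions: Sequence[int] = (1,),
    out_dir: str | Path | None = None,
) -> dict:
    """simulate -> compute -> score -> analyze, with artifacts on disk.

    Writes the cohort CSV (simulated plus imaging-measured ALPS), the
    per-subject ALPS JSON, the statistics JSON and a log, all stamped with
    the config hash and seed. Deterministic stages are bit-identical under
    rerun with the same config.
    """
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = sim_params or CohortSimParams(seed=cfg.seed)
    stamp = {"config_hash": config_hash(cfg, asdict(params)), "seed": cfg.seed}
    log.info("full run start: %s", stamp)

    cohort = simulate_cohort(params)
    rois = default_rois(cfg.roi_radius_mm, cfg.roi_centers)
    pipe = PhantomPipeline(rois=rois)
    measured = measure_cohort_alps(
        cohort, pipe, sessions=imaging_sessions, seed=cfg.seed
    )
    merged = cohort.merge(
        measured[
            ["subject_id", "session", "measured_alps_left", "measured_alps_right", "measured_alps_mean"]
        ],
        on=["subject_id", "session"],
        how="left",
    )
    write_cohort(merged, out / "cohort.csv")

    per_subject = {
        f"{r.subject_id}_s{r.session}": {
            "alps_left": r.measured_alps_left,
            "alps_right": r.measured_alps_right,
            "alps_mean": r.measured_alps_mean,
        }
        for r in measured.itertuples()
    }
    (out / "alps_per_subject.json").write_text(
        json.dumps({**stamp, "subjects": per_subject}, indent=2)
    )

    results = analyze_cohort(cohort, seed=cfg.seed, n_boot=cfg.n_boot)
    results.update(stamp)
    (out / "statistics.json").write_text(json.dumps(results, indent=2))
    log.info("full run done in %.1fs -> %s", time.time() - t0, out)
    return results
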