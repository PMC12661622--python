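"""Multi-seed parameter-recovery studies.

These drivers re-estimate the quantities the synthetic generator embeds —
group ALPS means through the full imaging chain, the interhemispheric
Spearman, the ALPS-cognition partial correlations, the group-by-time
interaction — by repeated simulation, and report seed-level distributions
so callers can form Monte-Carlo standard errors. They are what the
calibration checks and the reproduction script run.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as st
from .synthetic import CohortSimParams, simulate_cohort
from .workflow import PhantomPipeline, measure_cohort_alps


def derive_seeds(base_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """n child seeds (< 2^31) from one base seed; ``stream`` separates
    independent uses of the same base."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(stream,))
    return ss.generate_state(n) % (2**31)


def group_mean_recovery_imaging(
    n_seeds: int = 200,
    base_seed: int = 0,
    params: CohortSimParams | None = None,
    pipeline: PhantomPipeline | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-seed group means of bilateral ALPS measured through the
    synthetic-DWI -> tensor-fit -> ROI -> index chain at baseline.

    Returns {"measured": df, "truth": df} with one row per seed and one
    column per group.
    """
    params = params or CohortSimParams()
    pipe = pipeline or PhantomPipeline()
    seeds = derive_seeds(base_seed, n_seeds, stream=1)
    measured_rows, truth_rows = [], []
    for i, s in enumerate(seeds):
        cohort = simulate_cohort(params, seed=int(s))
        meas = measure_cohort_alps(cohort, pipe, sessions=(1,), seed=int(seeds[i]))
        measured_rows.append(meas.groupby("group")["measured_alps_mean"].mean())
        truth_rows.append(meas.groupby("group")["alps_mean"].mean())
    return {
        "measured": pd.DataFrame(measured_rows).reset_index(drop=True),
        "truth": pd.DataFrame(truth_rows).reset_index(drop=True),
    }


def correlation_recovery(
    n_seeds: int = 200,
    base_seed: int = 0,
    params: CohortSimParams | None = None,
) -> pd.DataFrame:
    """Per-seed interhemispheric Spearman (full cohort, baseline) and PD-pool
    partial Spearman of bilateral ALPS with the composite score given age
    and sex (statistics-only path, no imaging)."""
    params = params or CohortSimParams()
    rows = []
    for s in derive_seeds(base_seed, n_seeds, stream=2):
        cohort = simulate_cohort(params, seed=int(s))
        base = cohort[cohort.session == 1]
        lr = sps.spearmanr(base.alps_left, base.alps_right).statistic
        pdpool = base[base.group.isin(["PD_good", "PD_poor"])]
        cov = np.column_stack(
            [pdpool.age.to_numpy(float), (pdpool.sex == "M").to_numpy(float)]
        )
        pc = st.partial_spearman(pdpool.alps_mean, pdpool.composite_cognition, cov)
        rows.append({"lr_spearman": float(lr), "partial_rho_baseline": pc.rho})
    return pd.DataFrame(rows)


def session3_recovery(
    n_seeds: int = 200,
    base_seed: int = 0,
    params: CohortSimParams | None = None,
) -> pd.DataFrame:
    """Per-seed partial Spearman of baseline bilateral ALPS with session-3
    composite cognition in the PD pool, given age and sex."""
    params = params or CohortSimParams(n_sessions=3)
    if params.n_sessions < 3:
        params = dataclasses.replace(params, n_sessions=3)
    rows = []
    for s in derive_seeds(base_seed, n_seeds, stream=3):
        cohort = simulate_cohort(params, seed=int(s))
        base = cohort[cohort.session == 1]
        pdpool = base[base.group.isin(["PD_good", "PD_poor"])]
        s3 = cohort[cohort.session == 3][["subject_id", "composite_cognition"]]
        merged = pdpool.merge(s3, on="subject_id", suffixes=("", "_s3"))
        cov = np.column_stack(
            [merged.age.to_numpy(float), (merged.sex == "M").to_numpy(float)]
        )
        pc = st.partial_spearman(
            merged.alps_mean, merged.composite_cognition_s3, cov
        )
        rows.append({"partial_rho_session3": pc.rho})
    return pd.DataFrame(rows)


def interaction_recovery(
    n_seeds: int = 200,
    base_seed: int = 0,
    params: CohortSimParams | None = None,
) -> pd.DataFrame:
    """Per-seed poor-group-by-time coefficient from the mixed model on
    two-session cohorts."""
    params = params or CohortSimParams()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in derive_seeds(base_seed, n_seeds, stream=4):
            cohort = simulate_cohort(params, seed=int(s))
            lm = st.fit_group_time_model(cohort)
            rows.append({"interaction_beta": lm.interaction_beta})
    return pd.DataFrame(rows)


def type1_error_rate(
    n_sims: int = 1000,
    base_seed: int = 0,
    n_per_group: Sequence[int] = (28, 67, 31),
    alpha: float = 0.05,
) -> float:
    """Rejection rate of :func:`dtialps.stats.compare_groups` at ``alpha``
    when all groups share one normal distribution."""
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in derive_seeds(base_seed, n_sims, stream=5):
            rng = np.random.default_rng(int(s))
            values = rng.normal(1.15, 0.17, sum(n_per_group))
            labels = np.repeat([f"g{i}" for i in range(len(n_per_group))], n_per_group)
            res = st.compare_groups(values, labels)
            rejections += res.pvalue < alpha
    return rejections / n_sims


def mc_se(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    return float(v.std(ddof=1) / np.sqrt(v.size))
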