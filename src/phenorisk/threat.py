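"""Emerging-threat response: temporal-cutoff retraining and composite score.

When a novel threat emerges, the record matrix is truncated at a calendar
cutoff (nothing dated after it enters training or inference), the risk
network is retrained, and the risk states of clinically related endpoints
(pneumonia-like, sepsis-like, all-cause death) are combined into an
unweighted composite severity score.  "Unweighted" is realised as the mean
of per-component z-scores: raw log partial hazards live on incomparable
scales across endpoints, so each component is standardised over the scored
population before equal weighting (a raw mean is available via
``standardize=False``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import Cohort, RecordMatrix, ablate_recent
from .cph import DegenerateCovariateError, build_covariates, fit_cph
from .metrics import assign_percentiles, harrell_c, kaplan_meier
from .nn import ModelConfig, MultitaskCoxPHResults, train_risk_model

__all__ = [
    "CompositeSpec",
    "temporal_cutoff_inputs",
    "temporal_cutoff_retrain",
    "composite_score",
    "evaluate_threat_score",
]


@dataclass
class CompositeSpec:
    """Which endpoint risk states enter the composite, and how.

    ``components`` are endpoint ids (by convention the pneumonia-like,
    sepsis-like and all-cause-death endpoints); ``standardize`` controls the
    per-component z-scoring before the unweighted mean.
    """

    components: list[str]
    standardize: bool = True

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("composite needs at least one component endpoint")


def temporal_cutoff_inputs(
    matrix: RecordMatrix, cohort: Cohort, cutoff_date
) -> RecordMatrix:
    """Drop every record dated after the calendar cutoff.

    Record calendar date = recruitment date - timestamp (timestamps are years
    before recruitment), so for each individual the records kept are those
    with timestamp >= (recruitment - cutoff) in years; for cutoffs after
    recruitment nothing is dropped for that individual.
    """
    if matrix.timestamps is None:
        raise ValueError("temporal cutoff requires record timestamps")
    cutoff = np.datetime64(cutoff_date, "D")
    gap_days = (cohort.recruitment_date - cutoff).astype("timedelta64[D]").astype(float)
    window_years = np.maximum(gap_days / 365.25, 0.0)
    out = ablate_recent(matrix, window_years)
    if out.X.nnz == 0:
        raise ValueError(f"cutoff {cutoff} predates every record; nothing to train on")
    return out


def temporal_cutoff_retrain(
    matrix: RecordMatrix,
    cohort: Cohort,
    times: np.ndarray,
    events: np.ndarray,
    cutoff_date,
    model_config: ModelConfig,
    val_fraction: float = 0.1,
) -> tuple[MultitaskCoxPHResults, RecordMatrix]:
    """Retrain the risk network on the cutoff-truncated record matrix.

    Training keeps time zero unchanged; the threat's outcome window begins
    after the cutoff and is evaluated separately.  Returns the fitted results
    and the truncated matrix (for cutoff-consistent inference).
    """
    truncated = temporal_cutoff_inputs(matrix, cohort, cutoff_date)
    X = truncated.toarray()
    rng = np.random.default_rng([model_config.seed, 29])
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    va, tr = perm[:n_val], perm[n_val:]
    res, _ = train_risk_model(
        model_config,
        (X[tr], times[tr], events[tr]),
        (X[va], times[va], events[va]),
    )
    return res, truncated


def composite_score(
    risk_states: np.ndarray, endpoint_ids: Sequence[str], spec: CompositeSpec
) -> np.ndarray:
    """Unweighted composite severity score over the component risk states.

    score_i = mean_j z_ij with z the per-component standardisation over the
    scored individuals; invariant to positive affine rescaling of any
    component and symmetric under component permutation.
    """
    ids = [str(e) for e in endpoint_ids]
    cols = []
    for comp in spec.components:
        if comp not in ids:
            raise KeyError(f"component endpoint {comp!r} absent from risk states")
        cols.append(ids.index(comp))
    Z = np.asarray(risk_states, dtype=float)[:, cols]
    if spec.standardize:
        sd = Z.std(axis=0)
        if np.any(sd == 0):
            bad = [spec.components[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance component(s): {bad}")
        Z = (Z - Z.mean(axis=0)) / sd
    return Z.mean(axis=1)


def evaluate_threat_score(
    score: np.ndarray,
    age: np.ndarray,
    outcome_times: np.ndarray,
    outcome_events: np.ndarray,
    sex: np.ndarray | None = None,
    horizon: float | None = None,
    seed: int = 0,
) -> dict:
    """Discrimination of age alone versus age + composite score, plus KM strata.

    Fits Cox models on age and on age + score, compares truncated C-indices,
    and returns Kaplan-Meier cumulative event curves for the top 5%, median
    5% (percentiles 48-52) and bottom 5% strata of each ranking.
    """
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    t = np.asarray(outcome_times, dtype=float)
    e = np.asarray(outcome_events, dtype=bool)
    sexv = np.asarray(sex) if sex is not None else np.array(["female"] * len(age))

    df_age, cs_age = build_covariates(age, sexv)
    df_age = df_age[["age"]]
    fit_age = fit_cph(df_age, t, e)
    lp_age = fit_age.linear_predictor(df_age)

    df_full = df_age.copy()
    df_full["threat_score"] = score
    try:
        fit_full = fit_cph(df_full, t, e)
        lp_full = fit_full.linear_predictor(df_full)
    except DegenerateCovariateError:
        # score carries no information beyond age (e.g. identical ranking)
        lp_full = lp_age

    c_age = harrell_c(lp_age, t, e, horizon)
    c_full = harrell_c(lp_full, t, e, horizon)

    strata = {}
    for name, ranking in (("age", lp_age), ("age_plus_score", lp_full)):
        bins = assign_percentiles(ranking)
        lab = np.where(
            bins >= 96, "top5", np.where((bins >= 48) & (bins <= 52), "median5", "")
        )
        lab = np.where(bins <= 5, "bottom5", lab)
        keep = lab != ""
        strata[name] = kaplan_meier(t[keep], e[keep], lab[keep])

    return {
        "c_age": c_age,
        "c_age_plus_score": c_full,
        "delta_c": c_full - c_age,
        "km_strata": strata,
    }
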