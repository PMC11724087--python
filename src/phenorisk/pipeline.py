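"""End-to-end orchestration: simulate -> cv-train -> predict -> cph -> evaluate.

A run is fully reconstructable from its config and global seed.  The global
seed fans out to per-stage seeds via CRC-32 of the stage name, so stages can
be rerun independently while staying deterministic.  Each run writes its
artifacts (cohort files, fold plan, risk states, Cox fit summaries,
evaluation tables, a Markdown report and a provenance JSON) into one
directory and reads nothing outside it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cd
from . import simulate as sim
from .cph import build_covariates, fit_cph
from .cv import make_fold_plan, run_nested_cv
from .metrics import (
    EndpointEval,
    assign_percentiles,
    bootstrap_delta_c,
    harrell_c,
    incident_event_ratio,
    summarize_phenome,
)
from .nn import ModelConfig
from .shapley import aggregate_attributions, shapley_sampling
from .threat import CompositeSpec, composite_score, evaluate_threat_score

logger = logging.getLogger("phenorisk")

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed + CRC32(stage)) mod 2^31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    min_carriers: int = 50
    min_incident: int = 100
    horizon: float = 10.0
    n_boot: int = 100  # fast mode; 1000 for confirmatory runs
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "phenorisk_run"
    run_threat: bool = False
    threat_components: list = field(default_factory=list)
    threat_cutoff: str = "2008-12-31"
    run_attributions: bool = False
    attribution_endpoint: str | None = None
    attribution_samples: int = 16
    attribution_individuals: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("sim", {}).items()
        }
        sim_cfg = sim.SimConfig(**sim_raw)
        model_cfg = ModelConfig(**raw.pop("model", {}))
        return cls(sim=sim_cfg, model=model_cfg, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _timed(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.1fs", name, dt)
            else:
                logger.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic-cohort analysis; returns the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"seed": config.seed, "stages": {}}

    # ----- simulate ---------------------------------------------------------
    with _timed("simulate"):
        sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        cohort, vocab, matrix, events, truth = sim.generate_cohort(sim_cfg)
        matrix, vocab = cd.filter_concepts(matrix, vocab, config.min_carriers)
        pct = 100.0 * config.min_carriers / cohort.n
        logger.info(
            "rarity filter: min %d carriers (%.3f%% of %d); %d concepts kept",
            config.min_carriers, pct, cohort.n, vocab.n,
        )
        catalog = cd.filter_endpoints(
            events, config.min_incident,
            dict(zip(events.endpoint_id, truth.sex_specificity)),
        )
        cd.write_cohort(out / "cohort", cohort, vocab, matrix, events)
        provenance["stages"]["simulate"] = {
            "n": cohort.n, "n_concepts": int(vocab.n),
            "n_endpoints": int(catalog.n), "seed": sim_cfg.seed,
        }

    times, ev = events.time, events.event

    # ----- cv-train + predict ----------------------------------------------
    with _timed("cv_train"):
        plan = make_fold_plan(cohort, seed=stage_seed(config.seed, "cv"))
        plan.to_frame().to_csv(out / "fold_plan.tsv", sep="\t", index=False)
        model_cfg = dataclasses.replace(config.model, seed=stage_seed(config.seed, "train"))
        risk, fold_results, fold_src = run_nested_cv(
            plan, model_cfg, matrix.X, times, ev, events.prior_event
        )
        rs = pd.DataFrame(risk, columns=list(events.endpoint_id))
        rs.insert(0, "individual_id", cohort.individual_id)
        rs.insert(1, "source_fold", fold_src)
        rs.to_csv(out / "risk_states.tsv", sep="\t", index=False, float_format="%.6f")
        provenance["stages"]["cv_train"] = {"n_folds": len(plan.folds), "seed": model_cfg.seed}

    # ----- cph + evaluate ---------------------------------------------------
    with _timed("evaluate"):
        eval_seed = stage_seed(config.seed, "evaluate")
        fits_rows, evals = [], []
        kept = [str(e) for e in catalog.endpoint_id]
        for eid in kept:
            j = events.index_of(eid)
            mask = cd.eligibility_mask(events, cohort, eid, catalog)
            t_j, e_j = times[mask, j], ev[mask, j]
            if e_j.sum() < 2:
                continue
            df_base, cs_base = build_covariates(
                cohort.age_at_recruitment[mask], cohort.sex[mask]
            )
            df_full, cs_full = build_covariates(
                cohort.age_at_recruitment[mask], cohort.sex[mask], risk[mask, j]
            )
            spec_j = str(catalog.sex_specificity[catalog.index_of(eid)])
            if spec_j != "both":  # single-sex eligible set: sex is constant
                for df_, cs_ in ((df_base, cs_base), (df_full, cs_full)):
                    df_.drop(columns="sex_male", inplace=True)
                    cs_.columns.remove("sex_male")
            lp = {}
            for name, df, cs in (("AgeSex", df_base, cs_base),
                                 ("AgeSexRiskState", df_full, cs_full)):
                cs.fit(df)
                Xc = cs.transform(df)
                fit = fit_cph(Xc, t_j, e_j)
                lp[name] = fit.linear_predictor(Xc)
                for cov in fit.beta.index:
                    fits_rows.append(
                        {"endpoint_id": eid, "covariate_set": name, "covariate": cov,
                         "beta": fit.beta[cov], "se": fit.se[cov], "n": fit.n,
                         "events": fit.n_events, "converged": fit.converged,
                         "step_size": fit.step_size}
                    )
            delta, ci, sig = bootstrap_delta_c(
                lp["AgeSexRiskState"], lp["AgeSex"], t_j, e_j,
                n_boot=config.n_boot, alpha=config.alpha, m_tests=len(kept),
                horizon=config.horizon, seed=eval_seed + j,
            )
            bins = assign_percentiles(risk[:, j], mask)
            ratio = incident_event_ratio(ev[:, j] & ~events.prior_event[:, j], bins)
            tvm = incident_event_ratio(
                ev[:, j] & ~events.prior_event[:, j], bins,
                top_band=(91, 100), bottom_band=(41, 60),
            )
            evals.append(
                EndpointEval(
                    endpoint_id=eid,
                    c_baseline=harrell_c(lp["AgeSex"], t_j, e_j, config.horizon),
                    c_full=harrell_c(lp["AgeSexRiskState"], t_j, e_j, config.horizon),
                    delta_c=delta, ci_lower=ci[0], ci_upper=ci[1], significant=sig,
                    decile_ratio=ratio.ratio, top_vs_median_ratio=tvm.ratio,
                    n_eligible=int(mask.sum()), n_events=int(e_j.sum()),
                )
            )
        pd.DataFrame(fits_rows).to_csv(out / "cph_fits.tsv", sep="\t", index=False,
                                       float_format="%.6f")
        eval_df = pd.DataFrame([dataclasses.asdict(e) for e in evals])
        eval_df.to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format="%.6f")
        summary = summarize_phenome(eval_df)
        provenance["stages"]["evaluate"] = {"seed": eval_seed, **summary}

    # ----- optional stages --------------------------------------------------
    if config.run_threat:
        with _timed("threat_score"):
            comps = config.threat_components or kept[-3:]
            spec = CompositeSpec(components=list(comps))
            score = composite_score(risk, events.endpoint_id, spec)
            comp_idx = [events.index_of(c) for c in comps]
            t_thr, e_thr = sim.generate_threat_outcome(
                truth, comp_idx, seed=stage_seed(config.seed, "threat")
            )
            threat = evaluate_threat_score(
                score, cohort.age_at_recruitment, t_thr, e_thr, cohort.sex
            )
            provenance["stages"]["threat_score"] = {
                "components": list(comps),
                "c_age": threat["c_age"],
                "c_age_plus_score": threat["c_age_plus_score"],
            }

    if config.run_attributions:
        with _timed("attribute"):
            eid = config.attribution_endpoint or kept[0]
            j = events.index_of(eid)
            a_seed = stage_seed(config.seed, "attribute")
            rng = np.random.default_rng([a_seed, 37])
            Xd = matrix.toarray().astype(float)
            bg = Xd[rng.choice(Xd.shape[0], size=min(100, Xd.shape[0]), replace=False)]
            net = fold_results[0].network
            sel = rng.choice(Xd.shape[0], size=min(config.attribution_individuals,
                                                   Xd.shape[0]), replace=False)
            attrs = np.stack(
                [
                    shapley_sampling(net.predict, Xd[i], bg, j,
                                     n_samples=config.attribution_samples,
                                     seed=a_seed + int(i))[0]
                    for i in sel
                ]
            )
            agg = aggregate_attributions(attrs, vocab.concept_id)
            agg.top_k(10).assign(endpoint_id=eid).to_csv(
                out / "attributions.tsv", sep="\t", index=False, float_format="%.6f"
            )
            provenance["stages"]["attribute"] = {"endpoint": eid, "n_individuals": len(sel)}

    # ----- report + provenance ---------------------------------------------
    report = [
        "# Phenome-wide risk run report",
        "",
        f"- individuals: {cohort.n}; concepts (post-filter): {vocab.n}; "
        f"endpoints (post-filter): {len(kept)}",
        f"- significant discrimination improvements (age+sex+risk state vs age+sex): "
        f"{summary['n_significant']}/{summary['n_endpoints']} "
        f"({summary['pct_significant']}%)",
        f"- delta C quartiles (significant endpoints): "
        f"Q25 {summary['delta_c_quartiles']['q25']:.3f}, "
        f"Q50 {summary['delta_c_quartiles']['q50']:.3f}, "
        f"Q75 {summary['delta_c_quartiles']['q75']:.3f}",
        "",
        "## Top/bottom decile incident-event ratios",
        "",
        "```",
        eval_df[["endpoint_id", "decile_ratio", "top_vs_median_ratio", "n_events"]]
        .round(2)
        .to_string(index=False),
        "```",
    ]
    (out / "report.md").write_text("\n".join(report))
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=float)
    return out
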