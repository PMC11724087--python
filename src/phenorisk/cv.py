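"""Leave-one-center-out nested validation and frozen external transfer.

Each recruitment center serves once as a fully held-out test partition; the
remaining centers are pooled and a random 10% becomes the validation set for
checkpoint selection.  Out-of-fold risk states are aggregated so that every
individual's prediction comes from the single model that never saw their
center.  External transfer freezes the fold models and averages their
predictions on the new cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import Cohort
from .nn import (
    ModelConfig,
    MultitaskCoxPHResults,
    RiskNetwork,
    train_risk_model,
)

__all__ = ["Fold", "FoldPlan", "make_fold_plan", "run_nested_cv", "external_transfer",
           "align_external_records"]


@dataclass
class Fold:
    test_center: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class FoldPlan:
    folds: list[Fold]
    seed: int
    n_individuals: int

    def validate(self) -> None:
        all_test: list[np.ndarray] = []
        for f in self.folds:
            tr, va, te = set(f.train_idx), set(f.val_idx), set(f.test_idx)
            if te & (tr | va):
                raise ValueError(f"fold {f.test_center}: test leaks into train/val")
            if tr & va:
                raise ValueError(f"fold {f.test_center}: train/val overlap")
            all_test.append(f.test_idx)
        cat = np.concatenate(all_test)
        if len(cat) != self.n_individuals or len(np.unique(cat)) != self.n_individuals:
            raise ValueError("test sets must partition the cohort exactly")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for name, idx in (("train", f.train_idx), ("val", f.val_idx), ("test", f.test_idx)):
                rows.append(
                    pd.DataFrame(
                        {"fold_center": f.test_center, "role": name, "individual_index": idx}
                    )
                )
        return pd.concat(rows, ignore_index=True)


def make_fold_plan(cohort: Cohort, val_fraction: float = 0.1, seed: int = 0) -> FoldPlan:
    """One fold per center: that center is the test set; 10% of the rest
    (simple random, seeded) validates checkpoint selection."""
    centers = np.unique(cohort.center_id)
    if len(centers) < 2:
        raise ValueError("spatial validation needs at least two centers")
    present = set(centers.tolist())
    for c in range(1, cohort.n_centers + 1):
        if c not in present:
            raise ValueError(f"center {c} has zero individuals")
    folds = []
    for k, c in enumerate(sorted(centers.tolist())):
        test_idx = np.flatnonzero(cohort.center_id == c)
        rest = np.flatnonzero(cohort.center_id != c)
        rng = np.random.default_rng([seed, 19, k])
        perm = rng.permutation(rest)
        n_val = int(round(val_fraction * len(rest)))
        n_val = max(1, min(n_val, len(rest) - 1))
        folds.append(
            Fold(
                test_center=int(c),
                train_idx=np.sort(perm[n_val:]),
                val_idx=np.sort(perm[:n_val]),
                test_idx=test_idx,
            )
        )
    plan = FoldPlan(folds=folds, seed=seed, n_individuals=cohort.n)
    plan.validate()
    return plan


def run_nested_cv(
    plan: FoldPlan,
    model_config: ModelConfig,
    records,
    times: np.ndarray,
    events: np.ndarray,
    prior_events: np.ndarray | None = None,
    verbose: bool = False,
) -> tuple[np.ndarray, list[MultitaskCoxPHResults], np.ndarray]:
    """Train one model per fold; aggregate out-of-fold risk states.

    Returns (risk_states (n x J), fold results, provenance) where
    ``provenance[i]`` is the test-fold center whose model scored individual i
    (exactly one source fold per individual).
    """
    plan.validate()
    X = records.toarray() if hasattr(records, "toarray") else np.asarray(records)
    X = np.asarray(X, dtype=np.float64)
    n, J = times.shape
    risk = np.full((n, J), np.nan)
    provenance = np.full(n, -1, dtype=int)
    results: list[MultitaskCoxPHResults] = []
    for k, fold in enumerate(plan.folds):
        import dataclasses

        cfg = dataclasses.replace(model_config, seed=model_config.seed + k)
        tr, va, te = fold.train_idx, fold.val_idx, fold.test_idx
        try:
            res, _ = train_risk_model(
                cfg,
                (X[tr], times[tr], events[tr],
                 None if prior_events is None else prior_events[tr]),
                (X[va], times[va], events[va],
                 None if prior_events is None else prior_events[va]),
            )
        except Exception as exc:
            raise RuntimeError(f"training failed in fold center={fold.test_center}") from exc
        if verbose:
            print(f"fold center={fold.test_center}: "
                  f"best val loss {res.history['best_val_loss']:.4f}")
        risk[te] = res.predict(X[te])
        provenance[te] = fold.test_center
        results.append(res)
    if np.any(provenance < 0) or np.any(~np.isfinite(risk)):
        raise RuntimeError("aggregation left uncovered individuals")
    return risk, results, provenance


def align_external_records(
    X_ext, ext_concepts: Sequence[str], train_concepts: Sequence[str]
):
    """Reorder external record columns to the training vocabulary.

    Concepts missing externally become zero columns (frozen-model contract);
    external-only concepts are dropped.
    """
    train_concepts = [str(c) for c in train_concepts]
    pos = {str(c): i for i, c in enumerate(ext_concepts)}
    X = X_ext.tocsc() if sp.issparse(X_ext) else np.asarray(X_ext)
    n = X.shape[0]
    cols = []
    zero = sp.csc_matrix((n, 1), dtype=np.int8) if sp.issparse(X_ext) else np.zeros((n, 1))
    for c in train_concepts:
        if c in pos:
            cols.append(X[:, [pos[c]]] if sp.issparse(X_ext) else X[:, [pos[c]]])
        else:
            cols.append(zero)
    if sp.issparse(X_ext):
        return sp.hstack(cols, format="csr")
    return np.concatenate(cols, axis=1)


def external_transfer(
    fold_results: Sequence[MultitaskCoxPHResults | RiskNetwork],
    records_ext,
    ext_concepts: Sequence[str] | None = None,
    train_concepts: Sequence[str] | None = None,
) -> np.ndarray:
    """Frozen-model transfer: mean of the fold models' risk states.

    With a single fold model the mean equals that model's prediction.  The
    downstream Cox fits are applied frozen elsewhere; only the age+sex
    baseline is refit on the external cohort.
    """
    if len(fold_results) == 0:
        raise ValueError("no fold models given")
    X = records_ext
    if ext_concepts is not None and train_concepts is not None:
        X = align_external_records(X, ext_concepts, train_concepts)
    preds = None
    for res in fold_results:
        net = res.network if isinstance(res, MultitaskCoxPHResults) else res
        p = net.predict(X)
        preds = p if preds is None else preds + p
    return preds / len(fold_results)
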