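"""Sampling-based Shapley attribution of record contributions to risk states.

Which recorded concepts drive an individual's risk state for an endpoint?
The permutation-sampling estimator of Castro et al. / Strumbelj & Kononenko:
for each sampled (permutation, background row) pair, a feature's marginal
contribution is the model-output change when that feature switches from the
background value to the individual's value, given the features preceding it
in the permutation already carry the individual's values.  Averaging over
samples converges to the exact Shapley value of the value function
v(S) = E_z[model(x_S, z_{S-bar})].

Local attributions average over selected individuals (importance for those
affected); global attributions sum (importance for population ranking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AttributionResult", "shapley_sampling", "aggregate_attributions"]


@dataclass
class AttributionResult:
    """Aggregated per-concept attributions for one endpoint."""

    concept_ids: np.ndarray
    local: np.ndarray  # mean over selected individuals
    global_: np.ndarray  # sum over selected individuals
    n_individuals: int

    def top_k(self, k: int = 5) -> pd.DataFrame:
        """Top-k table by local attribution, ties broken by concept id."""
        df = pd.DataFrame(
            {"concept_id": self.concept_ids, "local": self.local, "global": self.global_}
        )
        df = df.sort_values(["local", "concept_id"], ascending=[False, True],
                            kind="stable").head(k)
        return df.reset_index(drop=True)


def shapley_sampling(
    predict_fn,
    x: np.ndarray,
    background: np.ndarray,
    endpoint: int,
    n_samples: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature Shapley attribution of ``predict_fn(x)[endpoint]``.

    Parameters
    ----------
    predict_fn : maps an (m, C) matrix to (m, J) scores (deterministic).
    x : (C,) record vector to explain.
    background : (B, C) reference records; each sample draws one row.
    n_samples : permutation samples; the Monte-Carlo SE shrinks as 1/sqrt(n).

    Returns (attributions, mc_standard_errors), both (C,).  For a linear
    model with weights w the estimator is exact for any sample count:
    attribution_f = w_f (x_f - mean background_f) in expectation, and each
    sampled contribution of feature f is w_f (x_f - z_f).
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] < 1:
        raise ValueError("background must be non-empty")
    if background.shape[1] != x.shape[0]:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[0]} features, "
            f"background has {background.shape[1]}"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    C = x.shape[0]
    rng = np.random.default_rng([seed, 31])
    contribs = np.empty((n_samples, C))
    for s in range(n_samples):
        perm = rng.permutation(C)
        z = background[rng.integers(0, background.shape[0])]
        # build the C+1 prefix states in one batch: row p has the first p
        # permuted features from x, the rest from z
        batch = np.tile(z, (C + 1, 1))
        for p, f in enumerate(perm):
            batch[p + 1 :, f] = x[f]
        vals = np.asarray(predict_fn(batch))[:, endpoint]
        contribs[s, perm] = np.diff(vals)
    attr = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_samples) if n_samples > 1 else np.zeros(C)
    return attr, se


def aggregate_attributions(
    attributions: np.ndarray,
    concept_ids: np.ndarray,
    selection_mask: np.ndarray | None = None,
) -> AttributionResult:
    """Local (mean) and global (sum) aggregation over selected individuals.

    ``attributions`` is (n_individuals, n_concepts); the selection typically
    keeps individuals without a prior event of the endpoint.
    """
    A = np.atleast_2d(np.asarray(attributions, dtype=float))
    mask = (
        np.ones(A.shape[0], dtype=bool)
        if selection_mask is None
        else np.asarray(selection_mask, dtype=bool)
    )
    if mask.sum() == 0:
        raise ValueError("attribution selection is empty")
    sel = A[mask]
    return AttributionResult(
        concept_ids=np.asarray(concept_ids, dtype=object),
        local=sel.mean(axis=0),
        global_=sel.sum(axis=0),
        n_individuals=int(mask.sum()),
    )
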