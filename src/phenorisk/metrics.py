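"""Stratification and discrimination metrics for phenome-wide evaluation.

Percentile stratification of risk states, top/bottom-decile incident-event
ratios, a 10-year truncated Harrell's C-index, paired-bootstrap model
comparison with Bonferroni-adjusted percentile intervals, Kaplan-Meier
cumulative event curves (Greenwood CIs via lifelines), and phenome-wide
summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "EndpointEval",
    "RatioResult",
    "assign_percentiles",
    "incident_event_ratio",
    "harrell_c",
    "bootstrap_delta_c",
    "kaplan_meier",
    "summarize_phenome",
]


@dataclass
class EndpointEval:
    """Per-endpoint discrimination summary used by summarize_phenome."""

    endpoint_id: str
    c_baseline: float
    c_full: float
    delta_c: float
    ci_lower: float
    ci_upper: float
    significant: bool
    decile_ratio: float = np.nan
    top_vs_median_ratio: float = np.nan
    n_eligible: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        for c in (self.c_baseline, self.c_full):
            if np.isfinite(c) and not 0 <= c <= 1:
                raise ValueError("C-index must lie in [0, 1]")
        if np.isfinite(self.ci_lower) and not (
            self.ci_lower <= self.delta_c <= self.ci_upper
        ):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class RatioResult:
    ratio: float
    events_top: int
    n_top: int
    events_bottom: int
    n_bottom: int

    def __float__(self) -> float:
        return self.ratio


def assign_percentiles(scores: np.ndarray, eligible_mask: np.ndarray | None = None,
                       n_bins: int = 100) -> np.ndarray:
    """Percentile bins 1..100 by ordinal rank with a stable tie-break.

    Ties are broken by stable input order (sparse inputs produce heavy score
    ties; a deterministic break keeps runs reproducible).  Bin sizes differ
    by at most one; ineligible individuals get bin 0.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    mask = np.ones(n, dtype=bool) if eligible_mask is None else np.asarray(eligible_mask, bool)
    idx = np.flatnonzero(mask)
    m = idx.size
    if m < n_bins:
        raise ValueError(f"need at least {n_bins} eligible individuals, got {m}")
    order = idx[np.argsort(scores[idx], kind="stable")]
    # sizes: first (m % n_bins) bins get one extra
    base, extra = divmod(m, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:extra] += 1
    bins = np.zeros(n, dtype=int)
    bins[order] = np.repeat(np.arange(1, n_bins + 1), sizes)
    return bins


def incident_event_ratio(
    events: np.ndarray,
    bins: np.ndarray,
    top_band: tuple[int, int] = (91, 100),
    bottom_band: tuple[int, int] = (1, 10),
) -> RatioResult:
    """Ratio of incident event rates between two percentile bands.

    ratio = (events_top/n_top) / (events_bottom/n_bottom); with equal band
    sizes this reduces to the event-count ratio.  Zero events in the bottom
    band yield +inf with the counts preserved for annotation.
    """
    events = np.asarray(events, dtype=bool)
    bins = np.asarray(bins, dtype=int)
    top = (bins >= top_band[0]) & (bins <= top_band[1])
    bot = (bins >= bottom_band[0]) & (bins <= bottom_band[1])
    if top.sum() == 0 or bot.sum() == 0:
        raise ValueError("both percentile bands must be non-empty")
    e_top, n_top = int(events[top].sum()), int(top.sum())
    e_bot, n_bot = int(events[bot].sum()), int(bot.sum())
    if e_bot == 0:
        return RatioResult(np.inf, e_top, n_top, e_bot, n_bot)
    return RatioResult((e_top / n_top) / (e_bot / n_bot), e_top, n_top, e_bot, n_bot)


def _truncate(times: np.ndarray, events: np.ndarray, horizon: float):
    """Clip follow-up at the horizon; events after it become censored there."""
    t = np.minimum(times, horizon)
    e = events & (times <= horizon)
    return t, e


def harrell_c(scores: np.ndarray, times: np.ndarray, events: np.ndarray,
              horizon: float | None = 10.0) -> float:
    """Harrell's C-index truncated at ``horizon`` years.

    A pair is comparable when the shorter time is an event and the times
    differ; score ties count one half.  Truncation controls right-censoring:
    events beyond the horizon are treated as censored at the horizon.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if horizon is not None:
        times, events = _truncate(times, events, horizon)
    ev = np.flatnonzero(events)
    if ev.size == 0:
        raise ValueError("no events before the horizon")
    concordant = 0.0
    comparable = 0
    # loop over events, vectorised over the later-time comparison set
    for i in ev:
        later = times > times[i]
        m = int(later.sum())
        if m == 0:
            continue
        comparable += m
        diff = scores[i] - scores[later]
        concordant += np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable


def bootstrap_delta_c(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    m_tests: int = 1,
    horizon: float | None = 10.0,
    seed: int = 0,
) -> tuple[float, tuple[float, float], bool]:
    """Paired-bootstrap comparison of two models' truncated C-indices.

    Individuals are resampled jointly for both score vectors; the percentile
    CI is taken at Bonferroni-adjusted level 1 - alpha/m_tests and the models
    are called different when it excludes zero.  Returns
    (delta_c = C_a - C_b, (lo, hi), significant).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired comparison requires identical individuals")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if horizon is not None:
        times, events = _truncate(times, events, horizon)
    point = harrell_c(scores_a, times, events, None) - harrell_c(scores_b, times, events, None)
    if np.array_equal(scores_a, scores_b):
        return 0.0, (0.0, 0.0), False
    rng = np.random.default_rng([seed, 23])
    n = len(times)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if not events[idx].any():
            deltas[b] = 0.0
            continue
        deltas[b] = harrell_c(scores_a[idx], times[idx], events[idx], None) - harrell_c(
            scores_b[idx], times[idx], events[idx], None
        )
    level = alpha / m_tests
    lo, hi = np.quantile(deltas, [level / 2, 1 - level / 2])
    significant = bool(lo > 0 or hi < 0)
    return float(point), (float(lo), float(hi)), significant


def kaplan_meier(
    times: np.ndarray, events: np.ndarray, group_labels: np.ndarray
) -> dict[str, pd.DataFrame]:
    """Product-limit cumulative event curves per group with Greenwood 95% CIs.

    Returns, per group label, a frame with columns time, cum_event_rate
    (1 - S(t)), ci_lower, ci_upper.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group_labels = np.asarray(group_labels)
    if times.size == 0:
        raise ValueError("no observations to estimate survival from")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(group_labels):
        m = group_labels == g
        if m.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        out[str(g)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "cum_event_rate": 1.0 - surv.to_numpy(),
                "ci_lower": 1.0 - ci.iloc[:, 1].to_numpy(),
                "ci_upper": 1.0 - ci.iloc[:, 0].to_numpy(),
            }
        )
    return out


def summarize_phenome(evals: list[EndpointEval] | pd.DataFrame) -> dict:
    """Phenome-wide summary: counts/percentages significant, delta-C quartiles.

    Percentages are reported to one decimal (e.g. 1546 of 1741 -> 88.8).
    """
    if isinstance(evals, pd.DataFrame):
        df = evals
    else:
        df = pd.DataFrame(
            {
                "endpoint_id": [e.endpoint_id for e in evals],
                "delta_c": [e.delta_c for e in evals],
                "significant": [e.significant for e in evals],
            }
        )
    if len(df) == 0:
        raise ValueError("at least one endpoint is required")
    n = len(df)
    n_sig = int(df["significant"].sum())
    sig = df.loc[df["significant"], "delta_c"]
    quartiles = (
        {"q25": float(sig.quantile(0.25)), "q50": float(sig.quantile(0.50)),
         "q75": float(sig.quantile(0.75))}
        if len(sig)
        else {"q25": np.nan, "q50": np.nan, "q75": np.nan}
    )
    return {
        "n_endpoints": n,
        "n_significant": n_sig,
        "pct_significant": round(100.0 * n_sig / n, 1),
        "delta_c_quartiles": quartiles,
    }
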