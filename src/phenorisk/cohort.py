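"""Cohort containers, rarity/endpoint filters, eligibility masks and file I/O.

The central objects mirror how population-scale medical-history studies are
organised: a cohort table (age, sex, recruitment center and date), a concept
vocabulary, a sparse binary individual x concept record matrix (a concept is 1
if it was ever recorded before recruitment), and per-endpoint time-to-event
outcomes with prior-event flags.  Times are fractional years with time zero at
recruitment; center ids are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "Cohort",
    "ConceptVocabulary",
    "RecordMatrix",
    "EndpointCatalog",
    "EventTable",
    "NoConceptsError",
    "NoEndpointsError",
    "filter_concepts",
    "filter_endpoints",
    "eligibility_mask",
    "ablate_recent",
    "read_cohort",
    "write_cohort",
]

DOMAINS = ("condition", "drug", "procedure", "observation", "measurement", "device")
SEXES = ("female", "male")
SEX_SPECIFICITIES = ("both", "female_only", "male_only")


class NoConceptsError(ValueError):
    """Raised when a concept filter leaves an empty vocabulary."""


class NoEndpointsError(ValueError):
    """Raised when an endpoint filter leaves an empty catalog."""


@dataclass
class Cohort:
    """Individual-level recruitment table.

    Parameters
    ----------
    individual_id : array of unique opaque keys.
    age_at_recruitment : float years, within [18, 110].
    sex : "female" / "male".
    center_id : 1-based recruitment-center integers.
    recruitment_date : numpy datetime64[D].
    """

    individual_id: np.ndarray
    age_at_recruitment: np.ndarray
    sex: np.ndarray
    center_id: np.ndarray
    recruitment_date: np.ndarray
    n_centers: int = 22

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id)
        self.age_at_recruitment = np.asarray(self.age_at_recruitment, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.center_id = np.asarray(self.center_id, dtype=int)
        self.recruitment_date = np.asarray(self.recruitment_date, dtype="datetime64[D]")
        self.validate()

    @property
    def n(self) -> int:
        return len(self.individual_id)

    def validate(self) -> None:
        if len(np.unique(self.individual_id)) != self.n:
            raise ValueError("individual ids must be unique")
        if np.any(self.age_at_recruitment < 18) or np.any(self.age_at_recruitment > 110):
            raise ValueError("ages must lie in [18, 110] years")
        bad = set(np.unique(self.sex)) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")
        if np.any(self.center_id < 1) or np.any(self.center_id > self.n_centers):
            raise ValueError(f"center ids must lie in 1..{self.n_centers}")


@dataclass
class ConceptVocabulary:
    """Concept ids, their domain, and how many individuals carry each."""

    concept_id: np.ndarray
    domain: np.ndarray
    carrier_count: np.ndarray

    def __post_init__(self) -> None:
        self.concept_id = np.asarray(self.concept_id, dtype=object)
        self.domain = np.asarray(self.domain, dtype=object)
        self.carrier_count = np.asarray(self.carrier_count, dtype=int)
        if len(np.unique(self.concept_id)) != len(self.concept_id):
            raise ValueError("concept ids must be unique")
        bad = set(np.unique(self.domain)) - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown domains: {sorted(bad)}")
        if np.any(self.carrier_count < 0):
            raise ValueError("carrier counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.concept_id)


@dataclass
class RecordMatrix:
    """Sparse binary individual x concept matrix with optional record ages.

    ``timestamps``, when present, aligns with ``X.data`` (canonical CSR order)
    and holds the age of each record in years before recruitment (>= 0).
    """

    X: sp.csr_matrix
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X, dtype=np.int8)
        self.X.sum_duplicates()
        self.X.sort_indices()
        data = self.X.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("record matrix entries must be binary")
        self.X.eliminate_zeros()
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != self.X.data.shape:
                raise ValueError("timestamps must align with the nonzero entries")
            if np.any(self.timestamps < 0):
                raise ValueError("timestamps are years before recruitment, >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def carrier_counts(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel().astype(int)

    def toarray(self) -> np.ndarray:
        return self.X.toarray().astype(np.float32)


@dataclass
class EndpointCatalog:
    endpoint_id: np.ndarray
    sex_specificity: np.ndarray
    incident_count: np.ndarray

    def __post_init__(self) -> None:
        self.endpoint_id = np.asarray(self.endpoint_id, dtype=object)
        self.sex_specificity = np.asarray(self.sex_specificity, dtype=object)
        self.incident_count = np.asarray(self.incident_count, dtype=int)
        if len(np.unique(self.endpoint_id)) != len(self.endpoint_id):
            raise ValueError("endpoint ids must be unique")
        bad = set(np.unique(self.sex_specificity)) - set(SEX_SPECIFICITIES)
        if bad:
            raise ValueError(f"unknown sex specificities: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.endpoint_id)

    def index_of(self, endpoint_id: str) -> int:
        hits = np.flatnonzero(self.endpoint_id == endpoint_id)
        if hits.size == 0:
            raise KeyError(f"unknown endpoint id: {endpoint_id!r}")
        return int(hits[0])


@dataclass
class EventTable:
    """Per (individual, endpoint) outcomes: prior-event flag, time, event.

    ``time`` is years after recruitment (> 0, event or censoring time);
    ``event`` marks an observed first occurrence within follow-up.
    """

    endpoint_id: np.ndarray
    prior_event: np.ndarray  # (n, J) bool
    time: np.ndarray  # (n, J) float, years
    event: np.ndarray  # (n, J) bool

    def __post_init__(self) -> None:
        self.endpoint_id = np.asarray(self.endpoint_id, dtype=object)
        self.prior_event = np.asarray(self.prior_event, dtype=bool)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if not (self.prior_event.shape == self.time.shape == self.event.shape):
            raise ValueError("prior_event, time and event must share one shape")
        if self.time.shape[1] != len(self.endpoint_id):
            raise ValueError("column count must match the endpoint ids")
        if np.any(self.time <= 0):
            raise ValueError("times must be strictly positive")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_endpoints(self) -> int:
        return self.time.shape[1]

    def index_of(self, endpoint_id: str) -> int:
        hits = np.flatnonzero(self.endpoint_id == endpoint_id)
        if hits.size == 0:
            raise KeyError(f"unknown endpoint id: {endpoint_id!r}")
        return int(hits[0])

    def incident_counts(self, eligible: np.ndarray | None = None) -> np.ndarray:
        """Incident events per endpoint among individuals without a prior event."""
        ok = self.event & ~self.prior_event
        if eligible is not None:
            ok = ok & np.asarray(eligible, dtype=bool)
        return ok.sum(axis=0).astype(int)


# ---------------------------------------------------------------------------
# filters and masks
# ---------------------------------------------------------------------------

def filter_concepts(
    matrix: RecordMatrix, vocab: ConceptVocabulary, min_carriers: int
) -> tuple[RecordMatrix, ConceptVocabulary]:
    """Drop concepts carried by fewer than ``min_carriers`` individuals.

    The default study threshold is an absolute carrier count of 50; the
    equivalent prevalence for the cohort at hand is only informational.
    Column order is preserved and the row set is unchanged.
    """
    if min_carriers < 0:
        raise ValueError("min_carriers must be >= 0")
    counts = matrix.carrier_counts()
    keep = counts >= min_carriers
    if not np.any(keep):
        raise NoConceptsError(
            f"no concepts survive the rarity filter (min_carriers={min_carriers})"
        )
    keep_idx = np.flatnonzero(keep)
    if keep_idx.size == matrix.shape[1]:
        return matrix, vocab
    Xcsc = matrix.X.tocsc()
    new_X = Xcsc[:, keep_idx].tocsr()
    new_ts = None
    if matrix.timestamps is not None:
        # rebuild timestamp alignment via a parallel sparse matrix
        ts_mat = sp.csr_matrix(
            (matrix.timestamps + 1.0, matrix.X.indices, matrix.X.indptr),
            shape=matrix.shape,
        ).tocsc()[:, keep_idx].tocsr()
        ts_mat.sort_indices()
        new_X = sp.csr_matrix(
            (np.ones_like(ts_mat.data, dtype=np.int8), ts_mat.indices, ts_mat.indptr),
            shape=ts_mat.shape,
        )
        new_ts = ts_mat.data - 1.0
    new_vocab = ConceptVocabulary(
        concept_id=vocab.concept_id[keep_idx],
        domain=vocab.domain[keep_idx],
        carrier_count=counts[keep_idx],
    )
    return RecordMatrix(new_X, new_ts), new_vocab


def filter_endpoints(
    events: EventTable,
    min_incident: int,
    sex_specificity: Mapping[str, str] | None = None,
    eligible: np.ndarray | None = None,
) -> EndpointCatalog:
    """Catalog of endpoints with at least ``min_incident`` incident events.

    Incident events are counted among individuals without a prior record of
    the endpoint.  ``sex_specificity`` optionally maps endpoint ids to
    'female_only'/'male_only'; unlisted endpoints are 'both'.
    """
    if min_incident < 1:
        raise ValueError("min_incident must be >= 1")
    counts = events.incident_counts(eligible)
    keep = counts >= min_incident
    if not np.any(keep):
        raise NoEndpointsError(
            f"no endpoints survive the incidence filter (min_incident={min_incident})"
        )
    ids = events.endpoint_id[keep]
    spec = np.array(
        [(sex_specificity or {}).get(e, "both") for e in ids], dtype=object
    )
    return EndpointCatalog(ids, spec, counts[keep])


def eligibility_mask(
    events: EventTable,
    cohort: Cohort,
    endpoint_id: str,
    catalog: EndpointCatalog | None = None,
) -> np.ndarray:
    """Individuals eligible for an endpoint's downstream analysis.

    False iff the individual has a prior record of the endpoint or their sex
    is incompatible with the endpoint's sex specificity (e.g. females for a
    male-only endpoint).  Training of the risk network does not use this mask;
    every downstream stage does.
    """
    j = events.index_of(endpoint_id)
    mask = ~events.prior_event[:, j]
    spec = "both"
    if catalog is not None:
        spec = str(catalog.sex_specificity[catalog.index_of(endpoint_id)])
    if spec == "female_only":
        mask &= cohort.sex == "female"
    elif spec == "male_only":
        mask &= cohort.sex == "male"
    return mask


def ablate_recent(matrix: RecordMatrix, window_years: float | np.ndarray) -> RecordMatrix:
    """Zero every record younger than ``window_years`` before recruitment.

    ``window_years`` may be a scalar or a per-individual vector (used by the
    temporal-cutoff retraining, where the window is the recruitment-to-cutoff
    gap).  Entries with timestamp >= window are untouched.
    """
    if matrix.timestamps is None:
        raise ValueError("record matrix has no timestamps; cannot ablate")
    X = matrix.X
    window = np.asarray(window_years, dtype=float)
    if window.ndim == 0:
        thresholds = np.full(X.data.shape, float(window))
    else:
        if window.shape[0] != X.shape[0]:
            raise ValueError("per-individual windows must match the row count")
        row_of_entry = np.repeat(np.arange(X.shape[0]), np.diff(X.indptr))
        thresholds = window[row_of_entry]
    keep = matrix.timestamps >= thresholds
    coo = X.tocoo()
    new_X = sp.csr_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=X.shape, dtype=np.int8
    )
    new_X.sort_indices()
    return RecordMatrix(new_X, matrix.timestamps[keep])


# ---------------------------------------------------------------------------
# file I/O: TSV tables + MatrixMarket sparse records
# ---------------------------------------------------------------------------

def write_cohort(
    path,
    cohort: Cohort,
    vocab: ConceptVocabulary,
    matrix: RecordMatrix,
    events: EventTable,
) -> None:
    """Write a cohort bundle: TSV tables plus a MatrixMarket record matrix."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "individual_id": cohort.individual_id,
            "age_at_recruitment": cohort.age_at_recruitment,
            "sex": cohort.sex,
            "center_id": cohort.center_id,
            "recruitment_date": cohort.recruitment_date.astype(str),
        }
    ).to_csv(path / "cohort.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "concept_id": vocab.concept_id,
            "domain": vocab.domain,
            "carrier_count": vocab.carrier_count,
        }
    ).to_csv(path / "vocabulary.tsv", sep="\t", index=False)
    scipy.io.mmwrite(path / "records.mtx", matrix.X.tocoo(), field="integer")
    if matrix.timestamps is not None:
        coo = matrix.X.tocoo()
        order = np.lexsort((coo.col, coo.row))
        # CSR canonical order matches lexsort by (row, col); data aligns with timestamps
        pd.DataFrame(
            {
                "row": coo.row[order],
                "col": coo.col[order],
                "timestamp": matrix.timestamps[order]
                if np.all(order == np.arange(order.size))
                else matrix.timestamps[order],
            }
        ).to_csv(path / "timestamps.tsv", sep="\t", index=False)
    n, J = events.time.shape
    long = pd.DataFrame(
        {
            "individual_id": np.repeat(cohort.individual_id, J),
            "endpoint_id": np.tile(events.endpoint_id, n),
            "prior_event": events.prior_event.ravel().astype(int),
            "time": events.time.ravel(),
            "event": events.event.ravel().astype(int),
        }
    )
    long.to_csv(path / "events.tsv", sep="\t", index=False)


def read_cohort(path) -> tuple[Cohort, ConceptVocabulary, RecordMatrix, EventTable]:
    """Read a cohort bundle written by :func:`write_cohort` (lossless)."""
    from pathlib import Path

    path = Path(path)
    ct = pd.read_csv(path / "cohort.tsv", sep="\t", dtype={"individual_id": str})
    cohort = Cohort(
        individual_id=ct["individual_id"].to_numpy(dtype=object),
        age_at_recruitment=ct["age_at_recruitment"].to_numpy(),
        sex=ct["sex"].to_numpy(dtype=object),
        center_id=ct["center_id"].to_numpy(),
        recruitment_date=ct["recruitment_date"].to_numpy(dtype="datetime64[D]"),
        n_centers=int(ct["center_id"].max()),
    )
    vt = pd.read_csv(path / "vocabulary.tsv", sep="\t", dtype={"concept_id": str})
    vocab = ConceptVocabulary(
        concept_id=vt["concept_id"].to_numpy(dtype=object),
        domain=vt["domain"].to_numpy(dtype=object),
        carrier_count=vt["carrier_count"].to_numpy(),
    )
    try:
        X = scipy.io.mmread(path / "records.mtx").tocsr()
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValueError(f"malformed MatrixMarket file: {exc}") from exc
    if X.data.size and not np.all((X.data == 0) | (X.data == 1)):
        raise ValueError("record matrix entries must be binary (0/1)")
    ts = None
    ts_path = path / "timestamps.tsv"
    if ts_path.exists():
        tt = pd.read_csv(ts_path, sep="\t")
        ts_mat = sp.csr_matrix(
            (tt["timestamp"].to_numpy() + 1.0, (tt["row"], tt["col"])), shape=X.shape
        )
        ts_mat.sort_indices()
        ts = ts_mat.data - 1.0
    matrix = RecordMatrix(X, ts)
    if matrix.shape[0] != cohort.n:
        raise ValueError("record matrix rows do not match the cohort table")
    if matrix.shape[1] != vocab.n:
        raise ValueError("record matrix columns do not match the vocabulary")
    et = pd.read_csv(path / "events.tsv", sep="\t", dtype={"individual_id": str})
    endpoint_ids = pd.unique(et["endpoint_id"]).astype(object)
    J = len(endpoint_ids)
    if len(et) != cohort.n * J:
        raise ValueError("events table is not a full individual x endpoint grid")
    if not np.array_equal(
        et["individual_id"].to_numpy()[::J].astype(object), cohort.individual_id
    ):
        raise ValueError("individual ids in events.tsv do not match cohort.tsv")
    events = EventTable(
        endpoint_id=np.asarray(endpoint_ids, dtype=object),
        prior_event=et["prior_event"].to_numpy().reshape(cohort.n, J).astype(bool),
        time=et["time"].to_numpy().reshape(cohort.n, J),
        event=et["event"].to_numpy().reshape(cohort.n, J).astype(bool),
    )
    return cohort, vocab, matrix, events
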