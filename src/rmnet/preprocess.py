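"""From raw OTU count tables to standardized relative proportions (SRP).

Pipeline order: prevalence filter -> relative abundance -> abundance/CV
filter -> time-point filter -> imputation -> per-OTU min-max
standardization.  The triplet model consumes the final SRP matrix, in which
every OTU spans [0, 1] across the time series so that "high" and "low"
regimes are comparable between OTUs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AbundanceTable",
    "ProportionTable",
    "SRPMatrix",
    "relative_abundance",
    "filter_otus_prevalence",
    "filter_otus_abundance",
    "filter_timepoints",
    "impute_missing",
    "standardize_srp",
    "counts_to_srp",
]

logger = logging.getLogger(__name__)


def _check_dims(values, missing_mask, otu_ids, time_labels):
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D matrix (OTUs x time points)")
    n, k = values.shape
    if missing_mask.shape != (n, k):
        raise ValueError("missing_mask shape does not match values")
    if len(otu_ids) != n or len(time_labels) != k:
        raise ValueError("label lengths do not match matrix dimensions")
    if len(set(otu_ids)) != n:
        raise ValueError("duplicate OTU ids")
    return values


@dataclass
class AbundanceTable:
    """OTU x time matrix of sequencing read counts.

    ``missing_mask[i, j]`` is True where no measurement exists; such entries
    are ignored by column sums and filters and later filled by imputation.
    """

    counts: np.ndarray
    otu_ids: list
    time_labels: list
    taxonomy: list | None = None
    missing_mask: np.ndarray = None

    def __post_init__(self):
        if self.missing_mask is None:
            self.missing_mask = np.zeros(np.shape(self.counts), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.counts = _check_dims(
            self.counts, self.missing_mask, self.otu_ids, self.time_labels
        )
        if self.taxonomy is not None and len(self.taxonomy) != len(self.otu_ids):
            raise ValueError("taxonomy length does not match otu_ids")
        if np.any(self.counts[~self.missing_mask] < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self):
        return self.counts.shape

    def take_otus(self, idx):
        return replace(
            self,
            counts=self.counts[idx],
            missing_mask=self.missing_mask[idx],
            otu_ids=[self.otu_ids[i] for i in idx],
            taxonomy=None if self.taxonomy is None else [self.taxonomy[i] for i in idx],
        )


@dataclass
class ProportionTable:
    """Relative proportions X_ij in [0, 1]; same layout as AbundanceTable.

    Columns sum to 1 over non-missing entries immediately after
    :func:`relative_abundance`; later OTU/time filters may break that sum.
    """

    values: np.ndarray
    otu_ids: list
    time_labels: list
    taxonomy: list | None = None
    missing_mask: np.ndarray = None

    def __post_init__(self):
        if self.missing_mask is None:
            self.missing_mask = np.zeros(np.shape(self.values), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.values = _check_dims(
            self.values, self.missing_mask, self.otu_ids, self.time_labels
        )
        obs = self.values[~self.missing_mask]
        if obs.size and (obs.min() < -1e-12 or obs.max() > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SRPMatrix:
    """Standardized relative proportions: each OTU row min-max scaled to [0, 1]."""

    values: np.ndarray
    otu_ids: list
    time_labels: list
    taxonomy: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("SRP values must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape


def relative_abundance(table: AbundanceTable) -> ProportionTable:
    """X_ij = Y_ij / Y_j with Y_j the column sum over non-missing entries."""
    counts = np.where(table.missing_mask, 0.0, table.counts)
    col_sums = counts.sum(axis=0)
    zero = np.flatnonzero(col_sums == 0)
    if zero.size:
        names = [table.time_labels[j] for j in zero]
        raise ValueError(f"time point(s) with zero total count: {names}")
    values = counts / col_sums
    values[table.missing_mask] = np.nan
    values = np.where(table.missing_mask, 0.0, values)
    return ProportionTable(
        values=values,
        otu_ids=list(table.otu_ids),
        time_labels=list(table.time_labels),
        taxonomy=None if table.taxonomy is None else list(table.taxonomy),
        missing_mask=table.missing_mask.copy(),
    )


def filter_otus_prevalence(
    table: AbundanceTable, min_fraction: float = 0.5
) -> AbundanceTable:
    """Drop OTUs observed at fewer than ``min_fraction`` of all time points.

    "Observed" means a positive, non-missing count; "fewer than" is strict,
    so an OTU present at exactly the threshold is kept.  The denominator is
    the total number of time points, including missing ones.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    present = (table.counts > 0) & ~table.missing_mask
    n_present = present.sum(axis=1)
    keep = np.flatnonzero(n_present >= min_fraction * len(table.time_labels))
    if keep.size == 0:
        warnings.warn("prevalence filter removed every OTU", UserWarning, stacklevel=2)
    return table.take_otus(keep)


def filter_otus_abundance(
    props: ProportionTable, max_prop: float = 0.1, cv_max: float = 3.4
) -> ProportionTable:
    """Drop OTU rows that are both rare and erratic.

    An OTU is removed iff its maximum proportion over non-missing entries is
    below ``max_prop`` AND its coefficient of variation (sd/mean) exceeds
    ``cv_max``.  A zero-mean row has CV = +inf, so an all-zero row fails both
    clauses and is removed.
    """
    obs = np.ma.masked_array(props.values, mask=props.missing_mask)
    row_max = obs.max(axis=1).filled(0.0)
    mean = obs.mean(axis=1).filled(0.0)
    sd = obs.std(axis=1, ddof=0).filled(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
    remove = (row_max < max_prop) & (cv > cv_max)
    keep = np.flatnonzero(~remove)
    return ProportionTable(
        values=props.values[keep],
        otu_ids=[props.otu_ids[i] for i in keep],
        time_labels=list(props.time_labels),
        taxonomy=None if props.taxonomy is None else [props.taxonomy[i] for i in keep],
        missing_mask=props.missing_mask[keep],
    )


def filter_timepoints(
    props: ProportionTable, max_prop: float = 0.1, otu_fraction: float = 0.6
) -> ProportionTable:
    """Drop time points that are both low-signal and sparsely populated.

    Time point k is removed iff its maximum proportion is below ``max_prop``
    AND the fraction of OTUs with a non-zero, non-missing value there is
    below ``otu_fraction``.
    """
    obs = np.ma.masked_array(props.values, mask=props.missing_mask)
    col_max = obs.max(axis=0).filled(0.0)
    frac_nonzero = ((props.values > 0) & ~props.missing_mask).mean(axis=0)
    remove = (col_max < max_prop) & (frac_nonzero < otu_fraction)
    keep = np.flatnonzero(~remove)
    if keep.size == 0:
        raise ValueError("time-point filter removed every time point")
    return ProportionTable(
        values=props.values[:, keep],
        otu_ids=list(props.otu_ids),
        time_labels=[props.time_labels[j] for j in keep],
        taxonomy=None if props.taxonomy is None else list(props.taxonomy),
        missing_mask=props.missing_mask[:, keep],
    )


def impute_missing(
    props: ProportionTable,
    n_components: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ProportionTable:
    """Fill missing entries by iterative EM-style probabilistic-PCA imputation.

    Missing cells are initialized from column means, then repeatedly replaced
    by a rank-``n_components`` truncated-SVD reconstruction of the
    column-centered matrix until the imputed values change by less than
    ``tol`` (max-abs) or ``max_iter`` sweeps elapse.  Observed entries are
    never altered; imputed values are clipped to [0, 1].
    """
    X = props.values.copy()
    mask = props.missing_mask
    if not mask.any():
        return ProportionTable(
            values=X,
            otu_ids=list(props.otu_ids),
            time_labels=list(props.time_labels),
            taxonomy=None if props.taxonomy is None else list(props.taxonomy),
            missing_mask=np.zeros_like(mask),
        )
    n, k = X.shape
    if mask.mean() >= 0.5:
        raise ValueError("more than half of the entries are missing")
    kk = min(n_components, n - 1, k - 1)
    if kk < 1:
        raise ValueError("matrix too small for low-rank imputation")

    col_mean = np.nanmean(np.where(mask, np.nan, X), axis=0)
    filled = np.where(mask, col_mean[None, :], X)
    converged = False
    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        centered = filled - mu
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        recon = (u[:, :kk] * s[:kk]) @ vt[:kk] + mu
        new = np.where(mask, recon, X)
        delta = np.max(np.abs(new[mask] - filled[mask]))
        filled = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "imputation did not converge within %d iterations (last change %.3g); "
            "returning best estimate",
            max_iter,
            delta,
        )
    filled = np.where(mask, np.clip(filled, 0.0, 1.0), X)
    return ProportionTable(
        values=filled,
        otu_ids=list(props.otu_ids),
        time_labels=list(props.time_labels),
        taxonomy=None if props.taxonomy is None else list(props.taxonomy),
        missing_mask=np.zeros_like(mask),
    )


def standardize_srp(props: ProportionTable) -> SRPMatrix:
    """Per-OTU min-max scaling: P_ij = (X_ij - X_min) / (X_max - X_min).

    The min and max are taken per OTU row across time points, so every OTU
    spans its own high/low regimes.  A constant row is an error: such an OTU
    has no dynamics and cannot participate in any triplet — remove it first.
    """
    if props.missing_mask.any():
        raise ValueError("impute missing values before standardization")
    X = props.values
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    flat = np.flatnonzero((hi - lo).ravel() == 0)
    if flat.size:
        names = [props.otu_ids[i] for i in flat]
        raise ValueError(
            f"constant OTU row(s) {names}: min-max scaling undefined; "
            "remove these OTUs before standardization"
        )
    return SRPMatrix(
        values=(X - lo) / (hi - lo),
        otu_ids=list(props.otu_ids),
        time_labels=list(props.time_labels),
        taxonomy=None if props.taxonomy is None else list(props.taxonomy),
    )


def counts_to_srp(
    table: AbundanceTable,
    min_fraction: float = 0.5,
    max_prop: float = 0.1,
    cv_max: float = 3.4,
    otu_fraction: float = 0.6,
    n_components: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SRPMatrix:
    """Run the full preprocessing chain from counts to an SRP matrix."""
    table = filter_otus_prevalence(table, min_fraction)
    props = relative_abundance(table)
    props = filter_otus_abundance(props, max_prop, cv_max)
    props = filter_timepoints(props, max_prop, otu_fraction)
    props = impute_missing(props, n_components, max_iter, tol)
    return standardize_srp(props)
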