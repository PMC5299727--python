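"""Real-data preparation: prevalence filtering, covariate de-correlation,
standardization.

Typical use on a genus-level abundance table paired with functional
covariates (e.g. KEGG orthology group abundances): drop taxa observed in
fewer than 5% of samples, collapse clusters of highly correlated
covariates to one representative each (average-linkage clustering on the
dissimilarity 1 - Pearson correlation, cut at a chosen height), then
centre and scale the surviving covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .tables import CovariateTable, TaxaCountTable

__all__ = [
    "PreprocessConfig",
    "filter_prevalence",
    "decorrelate_covariates",
    "standardize",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the preparation pipeline.

    ``cluster_cut`` is a height on the 1 - correlation dissimilarity
    scale: 0.5 merges covariates correlated above 0.5 on average.
    Representatives are chosen by maximum variance unless an explicit
    ``representatives`` list overrides the rule (domain knowledge often
    picks the biologically meaningful member of a cluster).
    """

    min_prevalence: float = 0.05
    cluster_cut: float = 0.5
    representatives: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_prevalence < 1.0:
            raise ValueError("min_prevalence must lie in (0, 1)")
        if self.cluster_cut < 0:
            raise ValueError("cluster_cut must be non-negative")


def filter_prevalence(Y: TaxaCountTable, min_prevalence: float = 0.05) -> TaxaCountTable:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples.

    Column order is preserved.  Raises if every taxon would be removed.
    """
    if not 0.0 < min_prevalence < 1.0:
        raise ValueError("min_prevalence must lie in (0, 1)")
    prevalence = (Y.counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    if keep.sum() < 2:
        raise ValueError(
            f"prevalence filter at {min_prevalence} leaves fewer than two taxa"
        )
    return TaxaCountTable(
        Y.counts[:, keep],
        Y.sample_ids,
        [t for t, k in zip(Y.taxon_ids, keep) if k],
    )


def decorrelate_covariates(
    X: CovariateTable, config: PreprocessConfig | None = None
) -> tuple[CovariateTable, pd.DataFrame]:
    """Collapse correlated covariates to one representative per cluster.

    Average-linkage hierarchical clustering on the dissimilarity
    1 - Pearson correlation, cut at ``config.cluster_cut``.  Returns the
    reduced table (original column order) and a report mapping every
    input covariate to its cluster and representative.
    """
    config = config or PreprocessConfig()
    if X.n_covariates < 2:
        raise ValueError("need at least two covariates to cluster")
    sd = X.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = X.covariate_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"covariate {bad!r} is constant; correlation undefined")
    corr = np.corrcoef(X.values, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Zl = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Zl, t=config.cluster_cut, criterion="distance")

    variance = X.values.var(axis=0, ddof=1)
    rep_for_cluster: dict[int, int] = {}
    user = set(config.representatives or ())
    unknown = user - set(X.covariate_ids)
    if unknown:
        raise ValueError(f"unknown representative covariates: {sorted(unknown)}")
    for cl in np.unique(labels):
        members = np.flatnonzero(labels == cl)
        named = [i for i in members if X.covariate_ids[i] in user]
        if len(named) > 1:
            raise ValueError(
                "more than one user representative in one cluster: "
                f"{[X.covariate_ids[i] for i in named]}"
            )
        rep_for_cluster[int(cl)] = named[0] if named else int(
            members[np.argmax(variance[members])]
        )
    keep_idx = sorted(rep_for_cluster.values())
    report = pd.DataFrame(
        {
            "covariate_id": X.covariate_ids,
            "cluster": labels,
            "representative": [
                X.covariate_ids[rep_for_cluster[int(c)]] for c in labels
            ],
            "kept": [i in keep_idx for i in range(X.n_covariates)],
        }
    )
    reduced = CovariateTable(
        X.values[:, keep_idx],
        [X.covariate_ids[i] for i in keep_idx],
        sample_ids=X.sample_ids,
    )
    return reduced, report


def standardize(X: CovariateTable) -> CovariateTable:
    """Centre columns to mean zero and scale to unit sample variance (n-1).

    Idempotent; raises on constant columns.
    """
    sd = X.values.std(axis=0, ddof=1)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad = X.covariate_ids[int(np.argmax((sd == 0) | ~np.isfinite(sd)))]
        raise ValueError(f"covariate {bad!r} is constant; cannot standardize")
    values = (X.values - X.values.mean(axis=0)) / sd
    return CovariateTable(
        values, X.covariate_ids, sample_ids=X.sample_ids, standardized=True
    )
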