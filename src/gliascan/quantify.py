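"""Normalised transcript abundances, immunogenic-potential scores and
expression-profile clustering.

The normalised transcript abundance of a UPF in a sample is
``100 * reads(sample, UPF) / total reads(sample)`` — a per-100-transcript
expression measure.  The CD immunogenic potential of a sample is the
abundance-weighted mean number of canonical DQ2.5 epitope cores per
transcript: ``sum_u canonical(u) * abundance(s, u) / 100``.

Samples are grouped into expression profiles by average-linkage
hierarchical clustering on the Pearson correlation distance ``1 - r``
between their abundance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class AbundanceMatrix:
    """Samples x UPFs matrix: raw read counts and per-100 abundances."""

    raw_counts: pd.DataFrame
    values: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def upfs(self) -> list[str]:
        return list(self.values.columns)


def normalise(raw_counts: pd.DataFrame) -> AbundanceMatrix:
    """Per-100-transcript normalisation; every row then sums to 100."""
    totals = raw_counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    values = raw_counts.div(totals, axis=0) * 100.0
    return AbundanceMatrix(raw_counts.copy(), values)


def apply_upf_filter(
    matrix: AbundanceMatrix, min_abundance: float = 0.1, min_reads: int = 6
) -> tuple[AbundanceMatrix, list[str]]:
    """Keep UPFs seen at >= *min_abundance* with >= *min_reads* reads in
    at least one sample (defaults: abundance 0.1, more than 5 reads).

    Abundances are not renormalised after filtering — retained values
    keep their per-100 scale, so filtered rows may sum below 100.
    Returns (filtered matrix, dropped UPF ids).
    """
    ok = ((matrix.values >= min_abundance) & (matrix.raw_counts >= min_reads)).any(axis=0)
    kept = [u for u in matrix.upfs if ok[u]]
    dropped = [u for u in matrix.upfs if not ok[u]]
    return AbundanceMatrix(matrix.raw_counts[kept], matrix.values[kept]), dropped


def immunogenic_potential(
    matrix: AbundanceMatrix, canonical_counts: pd.Series
) -> pd.Series:
    """Canonical DQ2.5 epitopes per transcript, per sample.

    ``canonical_counts`` maps UPF id -> number of canonical cores.
    """
    missing = set(matrix.upfs) - set(canonical_counts.index)
    if missing:
        raise ValueError(f"canonical counts missing for UPFs: {sorted(missing)}")
    weights = canonical_counts.loc[matrix.upfs].astype(float)
    return (matrix.values * weights).sum(axis=1) / 100.0


def epitope_abundance(
    matrix: AbundanceMatrix, epitope_counts: pd.DataFrame, epitope_name: str
) -> pd.Series:
    """Per-100-transcript abundance of one epitope core, per sample.

    ``epitope_counts`` is the UPF x epitope occurrence matrix; the
    result is sum_u count(u, epitope) * abundance(s, u), i.e. the
    per-transcript epitope frequency expressed per 100 transcripts.
    """
    if epitope_name not in epitope_counts.columns:
        raise KeyError(f"unknown epitope {epitope_name!r}")
    missing = set(matrix.upfs) - set(epitope_counts.index)
    if missing:
        raise ValueError(f"epitope counts missing for UPFs: {sorted(missing)}")
    weights = epitope_counts[epitope_name].loc[matrix.upfs].astype(float)
    return (matrix.values * weights).sum(axis=1)


def pearson_matrix(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlations of abundance vectors.

    Zero-variance samples yield NaN entries (flagged, not an error).
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("need >= 2 UPF dimensions for correlations")
    arr = matrix.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)


@dataclass
class ProfileAssignment:
    """Expression-profile grouping of samples.

    ``linkage`` is the scipy merge history; cutting it at ``threshold``
    reproduces ``groups`` exactly.
    """

    groups: dict[str, int]
    linkage: np.ndarray
    threshold: float

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))


def cluster_profiles(
    matrix: AbundanceMatrix, threshold: float = 0.5
) -> ProfileAssignment:
    """Average-linkage clustering on correlation distance d = 1 - r.

    Groups are the connected components after cutting merges above
    *threshold*; group ids are renumbered in sample order.  NaN
    correlations (zero-variance samples) are treated as distance 2,
    the metric maximum.
    """
    if threshold <= 0:
        raise ValueError("distance threshold must be > 0")
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples to cluster")
    corr = pearson_matrix(matrix).to_numpy()
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(linkage, t=threshold, criterion="distance")
    relabel: dict[int, int] = {}
    groups = {}
    for sample, lab in zip(matrix.samples, labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        groups[sample] = relabel[lab]
    return ProfileAssignment(groups, linkage, threshold)
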