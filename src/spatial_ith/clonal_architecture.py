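"""Clonality from cancer cell fractions and the intra-tumoral heterogeneity index.

A mutation with CCF > 0.8 is clonal; the main cluster C_main of a region
is the cluster with the largest mean CCF among clusters comprising more
than one mutation, and ITH = n_sub / (n_main + n_sub) where n_sub counts
mutations in all other clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CCFAssignment",
    "ClonalSummary",
    "classify_clonality",
    "identify_main_cluster",
    "ith_index",
    "cluster_ccf",
    "read_ccf_table",
]


@dataclass(frozen=True)
class CCFAssignment:
    """Per-mutation cancer cell fraction and cluster label in one region."""

    key: tuple[str, int, str, str]
    region: str
    ccf: float
    cluster_id: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ccf <= 1.0:
            raise ValueError(f"ccf {self.ccf} outside [0, 1]")
        if self.cluster_id < 0:
            raise ValueError("cluster_id must be >= 0")


@dataclass
class ClonalSummary:
    n_main: int
    n_sub: int
    ith: float
    main_cluster_id: int


class NoMainClusterError(ValueError):
    """No cluster comprises more than one mutation."""


def classify_clonality(ccf: float) -> str:
    """'clonal' iff CCF strictly exceeds 0.8, else 'subclonal'."""
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"ccf {ccf} outside [0, 1]")
    return "clonal" if ccf > 0.8 else "subclonal"


def identify_main_cluster(assignments: Sequence[CCFAssignment]) -> int:
    """Main (founding) cluster of one region.

    Among clusters with more than one mutation, the one with the largest
    mean CCF; ties broken by larger size, then smaller cluster id.
    """
    if not assignments:
        raise NoMainClusterError("no assignments")
    by_cluster: dict[int, list[float]] = {}
    for a in assignments:
        by_cluster.setdefault(a.cluster_id, []).append(a.ccf)
    eligible = {cid: v for cid, v in by_cluster.items() if len(v) > 1}
    if not eligible:
        raise NoMainClusterError("no main cluster: no cluster has > 1 mutation")
    # sort key: (-mean ccf, -size, id)
    best = min(
        eligible.items(),
        key=lambda kv: (-float(np.mean(kv[1])), -len(kv[1]), kv[0]),
    )
    return best[0]


def ith_index(assignments: Sequence[CCFAssignment]) -> ClonalSummary:
    """ITH = n_sub / (n_main + n_sub) for one region's clustered mutations."""
    main = identify_main_cluster(assignments)
    n_main = sum(1 for a in assignments if a.cluster_id == main)
    n_sub = sum(1 for a in assignments if a.cluster_id != main)
    total = n_main + n_sub
    return ClonalSummary(
        n_main=n_main,
        n_sub=n_sub,
        ith=n_sub / total,
        main_cluster_id=main,
    )


_VAR_FLOOR = 1e-6


def _gmm_1d(values: np.ndarray, k: int, n_iter: int = 300) -> tuple[np.ndarray, float]:
    """Deterministic 1-D Gaussian-mixture EM.

    Means are initialised at the (i + .5)/k quantiles of the value
    distribution, so the fit depends only on the multiset of inputs and
    labels are stable under input permutation.  Returns (hard labels
    ordered by descending component mean, BIC).
    """
    n = values.size
    means = np.quantile(values, (np.arange(k) + 0.5) / k)
    variances = np.full(k, max(values.var(), _VAR_FLOOR))
    weights = np.full(k, 1.0 / k)
    ll = -np.inf
    resp = np.full((n, k), 1.0 / k)
    for _ in range(n_iter):
        # E step (log-space for stability)
        logp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (values[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        log_norm = m + np.log(np.exp(logp - m).sum(axis=1, keepdims=True))
        resp = np.exp(logp - log_norm)
        new_ll = float(log_norm.sum())
        # M step
        nk = resp.sum(axis=0) + 1e-12
        means = (resp * values[:, None]).sum(axis=0) / nk
        variances = np.maximum(
            (resp * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / nk,
            _VAR_FLOOR,
        )
        weights = nk / n
        if new_ll - ll < 1e-10:
            ll = new_ll
            break
        ll = new_ll
    n_params = 3 * k - 1  # means, variances, free weights
    bic = -2.0 * ll + n_params * np.log(n)
    labels = resp.argmax(axis=1)
    # drop empty components, relabel by descending mean
    used = np.unique(labels)
    remap = {int(old): rank for rank, old in enumerate(used[np.argsort(-means[used])])}
    return np.array([remap[int(l)] for l in labels], dtype=int), bic


def cluster_ccf(ccfs: Sequence[float], max_clusters: int = 6) -> np.ndarray:
    """Deterministic stand-in 1-D clusterer for CCF values.

    Fits one-dimensional Gaussian mixtures for k = 1..max_clusters with
    quantile-initialised EM and selects k by BIC.  This is an explicitly
    simple surrogate for a Bayesian clone-clustering model: it is only
    meant to give reproducible cluster labels when none are supplied
    with the CCF table.  Label 0 is always the highest-CCF cluster.
    """
    values = np.asarray(ccfs, dtype=float)
    if values.size < 2:
        return np.zeros(values.size, dtype=int)
    if np.allclose(values, values[0]):
        return np.zeros(values.size, dtype=int)
    best_labels = np.zeros(values.size, dtype=int)
    best_score = np.inf
    for k in range(1, max_clusters + 1):
        labels, bic = _gmm_1d(values, k)
        if bic < best_score - 1e-9:
            best_score = bic
            best_labels = labels
    return best_labels


def read_ccf_table(path: str | Path) -> list[CCFAssignment]:
    """Read a CCF TSV (patient_id, region, chrom, pos, ref, alt, ccf[, cluster_id]).

    If cluster_id is absent, cluster_ccf is invoked per (patient, region).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["patient_id", "region", "chrom", "pos", "ref", "alt", "ccf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if "cluster_id" not in df.columns or df["cluster_id"].isna().all():
        parts = []
        for _, grp in df.groupby(["patient_id", "region"], sort=False):
            grp = grp.copy()
            grp["cluster_id"] = cluster_ccf(grp["ccf"].to_numpy())
            parts.append(grp)
        df = pd.concat(parts)
    return [
        CCFAssignment(
            key=(str(r.chrom), int(r.pos), str(r.ref), str(r.alt)),
            region=str(r.region),
            ccf=float(r.ccf),
            cluster_id=int(r.cluster_id),
        )
        for r in df.itertuples()
    ]
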