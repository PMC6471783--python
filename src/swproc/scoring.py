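"""Rank-based implementation-strength scoring.

Clusters are ranked on each quantitative implementation measure (rank 1
= best, per the measure's declared direction of benefit, mid-rank
averaging for ties), ranks are linearly rescaled to [0, 1] via
``(n - rank) / (n - 1)``, rescaled scores are averaged within each
implementation domain (fidelity, reach, adoption), and domain scores
are averaged into a single composite per cluster.  A domain missing for
a cluster (e.g. an adoption review falling beyond the trial window) is
simply dropped from that cluster's composite mean, and the number of
domains actually used is recorded.

Because every step is rank-based, the composite is invariant to any
strictly monotone transformation of a raw measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DOMAINS",
    "rank_clusters",
    "rescale_ranks",
    "domain_score",
    "composite_score",
    "score_measures",
    "spearman",
]

DOMAINS = ("fidelity", "reach", "adoption")
_DIRECTIONS = ("higher_is_better", "lower_is_better")


def rank_clusters(values, direction: str = "higher_is_better", name: str = "measure") -> np.ndarray:
    """Rank clusters on one measure; rank 1 is best.

    Ties get the mean of the tied rank positions; missing (NaN) values
    are excluded from ranking and returned as NaN.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if mask.sum() == 0:
        raise ValueError(f"measure {name!r} has no non-missing values")
    if mask.sum() < 2:
        raise ValueError(f"measure {name!r} needs at least 2 non-missing values to rank")
    ranks = np.full(values.shape, np.nan)
    signed = -values[mask] if direction == "higher_is_better" else values[mask]
    ranks[mask] = rankdata(signed, method="average")
    return ranks


def rescale_ranks(ranks, n: int | None = None) -> np.ndarray:
    """Map ranks over ``n`` clusters linearly onto [0, 1]: best -> 1, worst -> 0."""
    ranks = np.asarray(ranks, dtype=float)
    if n is None:
        n = int(np.isfinite(ranks).sum())
    if n < 2:
        raise ValueError("rescaling needs at least 2 ranked clusters")
    return (n - ranks) / (n - 1)


def domain_score(measure_scores: pd.DataFrame) -> pd.Series:
    """Per-cluster unweighted mean of rescaled measure scores in one domain.

    ``measure_scores`` is a clusters x measures frame of [0, 1] scores;
    a cluster's missing measures are skipped (mean over what is
    available).  Clusters with no available measure get NaN.
    """
    if measure_scores.shape[1] < 1:
        raise ValueError("domain has no measures")
    return measure_scores.mean(axis=1, skipna=True)


def composite_score(domain_scores: pd.DataFrame) -> pd.DataFrame:
    """Combine per-domain scores into the composite ScoreTable.

    ``domain_scores`` is a clusters x domains frame ([0, 1] or NaN).
    The composite is the mean over each cluster's available domains;
    ``n_domains_used`` records how many contributed.  A cluster with no
    available domain is an error.
    """
    n_used = domain_scores.notna().sum(axis=1)
    if (n_used == 0).any():
        bad = list(domain_scores.index[n_used == 0])
        raise ValueError(f"clusters with no available domain score: {bad}")
    out = domain_scores.copy()
    out["composite"] = domain_scores.mean(axis=1, skipna=True)
    out["n_domains_used"] = n_used
    return out


def score_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Full scoring pipeline from a long measure table to a ScoreTable.

    Parameters
    ----------
    measures : DataFrame
        Long format with columns ``cluster_id, measure_name, domain,
        direction, value`` (and optionally ``available``; unavailable
        rows are treated as missing).  Each (cluster, measure) pair may
        appear at most once.

    Returns
    -------
    DataFrame indexed by cluster_id with one ``<domain>_score`` column
    per domain present, plus ``composite`` and ``n_domains_used``.
    """
    required = {"cluster_id", "measure_name", "domain", "direction", "value"}
    missing_cols = required - set(measures.columns)
    if missing_cols:
        raise ValueError(f"measure table missing columns: {sorted(missing_cols)}")
    df = measures.copy()
    if "available" in df.columns:
        df.loc[~df["available"].astype(bool), "value"] = np.nan
    dup = df.duplicated(subset=["cluster_id", "measure_name"])
    if dup.any():
        raise ValueError("duplicate (cluster, measure) rows in measure table")
    unknown = set(df["domain"]) - set(DOMAINS)
    if unknown:
        raise ValueError(f"unknown domains: {sorted(unknown)}")

    clusters = pd.Index(sorted(df["cluster_id"].unique()), name="cluster_id")
    domain_frames: dict[str, pd.DataFrame] = {}
    for domain, sub in df.groupby("domain"):
        cols = {}
        for name, msub in sub.groupby("measure_name"):
            direction = msub["direction"].iloc[0]
            if (msub["direction"] != direction).any():
                raise ValueError(f"measure {name!r} declares conflicting directions")
            values = msub.set_index("cluster_id")["value"].reindex(clusters)
            ranks = rank_clusters(values.to_numpy(), direction, name=name)
            cols[name] = rescale_ranks(ranks)
        domain_frames[domain] = pd.DataFrame(cols, index=clusters)

    dscores = pd.DataFrame(
        {f"{d}_score": domain_score(frame) for d, frame in domain_frames.items()},
        index=clusters,
    )
    # keep canonical domain order where present
    ordered = [f"{d}_score" for d in DOMAINS if f"{d}_score" in dscores.columns]
    return composite_score(dscores[ordered])


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of tie-averaged ranks.

    Pairs with a missing value in either vector are dropped; at least 3
    complete pairs are required, and a constant vector (zero rank
    variance) is an error rather than a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    rx = rankdata(x[mask], method="average")
    ry = rankdata(y[mask], method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
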