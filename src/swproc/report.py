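"""Descriptive summaries, display rounding and the end-to-end pipeline.

``summarize_context`` and ``summarize_training`` reproduce the
arithmetic of the cluster-description and training-coverage tables:
unweighted means over clusters with non-missing values, with the number
of contributing clusters reported per column.  ``run_pipeline`` wires
the whole chain together — simulate (or ingest) a trial, score
implementation, compute per-site effects, pool and meta-regress — and
writes a manifest recording seeds and file hashes so a run is
verifiably reproducible.

All computation is done in full precision; ``round_half_up`` exists
only for display and is never fed back into downstream numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scoring
from .meta import dl_pool, forest_data, meta_regression
from .simulate import SimParams, simulate_study
from .swfit import fit_logistic, site_effect

__all__ = [
    "round_half_up",
    "summarize_context",
    "summarize_training",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("swproc")

KNOWN_CONFIG_KEYS = {
    "n_clusters",
    "n_steps",
    "periods_per_step",
    "baseline_event_rate",
    "treatment_log_or",
    "centre_effects",
    "centre_trends",
    "deliveries_per_period",
    "implementation_coupling",
    "implementation_noise_sd",
    "seed",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for display (68.25 -> 68.3 at 1 digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_context(records: pd.DataFrame, id_col: str = "site") -> pd.DataFrame:
    """All-sites summary of a cluster-context table.

    Every numeric column is averaged (unweighted) over the clusters with
    a non-missing value; ``n_clusters`` reports how many contributed to
    each column's mean.
    """
    if len(records) < 1:
        raise ValueError("need at least one cluster record")
    numeric = records.drop(columns=[id_col], errors="ignore").select_dtypes("number")
    return pd.DataFrame(
        {
            "mean": numeric.mean(axis=0, skipna=True),
            "sd": numeric.std(axis=0, ddof=1, skipna=True),
            "n_clusters": numeric.notna().sum(axis=0),
        }
    )


def summarize_training(trained: pd.Series, totals: pd.Series | None = None) -> pd.DataFrame:
    """Training-coverage table from per-site trained counts and workforce totals.

    Returns one row per site (percentage NaN where the workforce total
    is unknown) plus an ``overall`` row whose total is the sum of all
    trained counts and whose percentage uses only sites with known
    totals.
    """
    trained = pd.Series(trained, dtype=float)
    if (trained < 0).any():
        raise ValueError("trained counts must be non-negative")
    if totals is None:
        totals = pd.Series(np.nan, index=trained.index)
    totals = pd.Series(totals, dtype=float).reindex(trained.index)
    if ((trained > totals) & totals.notna()).any():
        raise ValueError("trained count exceeds workforce total for some site")
    pct = 100.0 * trained / totals
    out = pd.DataFrame({"trained": trained, "total": totals, "pct": pct})
    known = totals.notna()
    overall_pct = (
        100.0 * trained[known].sum() / totals[known].sum() if known.any() and totals[known].sum() > 0 else np.nan
    )
    out.loc["overall"] = [trained.sum(), totals[known].sum() if known.any() else np.nan, overall_pct]
    return out


class PipelineConfig:
    """Validated simulation/pipeline configuration (YAML or JSON mapping)."""

    def __init__(self, mapping: dict):
        unknown = set(mapping) - KNOWN_CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.n_clusters = int(mapping.get("n_clusters", 10))
        self.n_steps = int(mapping.get("n_steps", 9))
        self.periods_per_step = int(mapping.get("periods_per_step", 1))
        sim_keys = KNOWN_CONFIG_KEYS - {"n_clusters", "n_steps", "periods_per_step"}
        kwargs = {k: mapping[k] for k in sim_keys if k in mapping}
        for key in ("centre_effects", "centre_trends", "deliveries_per_period"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        self.sim_params = SimParams(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        mapping = yaml.safe_load(text)
        if not isinstance(mapping, dict):
            raise ValueError("config file must hold a mapping")
        return cls(mapping)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute simulate -> score -> per-site effects -> meta on one config.

    Writes ``cluster_periods.csv``, ``implementation_measures.csv``,
    ``scores.csv``, ``site_effects.csv``, ``fit.csv``,
    ``meta_summary.csv``, ``metareg_summary.csv``, ``forest.csv`` and a
    ``manifest.json`` with the seed and SHA-256 of every output.  The
    run is deterministic in (config, seed): identical inputs give
    byte-identical outputs.  On failure, partial outputs are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, float_format="%.10g", **kwargs)
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(df))

    try:
        design, cells, measures = simulate_study(
            config.n_clusters, config.n_steps, config.periods_per_step, config.sim_params, seed=seed
        )
        emit(cells, "cluster_periods.csv", index=False)
        emit(measures, "implementation_measures.csv", index=False)

        scores = scoring.score_measures(measures)
        emit(scores, "scores.csv")

        effects = [site_effect(sub, label=str(cid)) for cid, sub in cells.groupby("cluster_id")]
        site_df = pd.DataFrame(
            {
                "site_id": [e.label for e in effects],
                "log_effect": [e.log_effect for e in effects],
                "se": [e.se for e in effects],
                "or": [e.estimate for e in effects],
                "ci_low": [e.ci_low for e in effects],
                "ci_high": [e.ci_high for e in effects],
            }
        )
        emit(site_df, "site_effects.csv", index=False)

        pooled_fit = fit_logistic(cells, formula="pooled")
        emit(pooled_fit.summary(robust=True), "fit.csv", index=False)

        pooled = dl_pool(effects)
        emit(pooled.summary(), "meta_summary.csv", index=False)
        emit(forest_data(effects, pooled), "forest.csv", index=False)

        covariate = scores["composite"].reindex([int(e.label) for e in effects]).to_numpy()
        metareg = meta_regression(effects, covariate)
        emit(metareg.summary(), "metareg_summary.csv", index=False)

        manifest = {
            "seed": seed if seed is not None else config.sim_params.seed,
            "n_clusters": config.n_clusters,
            "n_steps": config.n_steps,
            "periods_per_step": config.periods_per_step,
            "files": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        (out / "manifest.json").unlink(missing_ok=True)
        raise
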