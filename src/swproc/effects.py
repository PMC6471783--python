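"""Unadjusted pre/post process effect measures with 95% confidence intervals.

Implements the two-by-two comparisons a process evaluation makes
between the pre-implementation and post-implementation observation
windows: simple proportions, odds ratios with Woolf (log) standard
errors and Haldane-Anscombe continuity correction, and
proportion ratios (risk ratios) with Katz log-method intervals.

Proportion ratios and odds ratios are deliberately kept distinct: when
a post-implementation proportion reaches 100% the odds ratio is
undefined while the proportion ratio is not, and published per-site
"OR" columns are sometimes in fact post/pre proportion ratios.  Both
are available and labelled by ``measure_kind``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "TwoByTwo",
    "EffectEstimate",
    "proportion",
    "odds_ratio",
    "proportion_ratio",
    "effects_from_counts",
]

Z95 = 1.959963984540054  # norm.ppf(0.975)


@dataclass(frozen=True)
class TwoByTwo:
    """Counts for a post-vs-pre (exposed-vs-unexposed) 2x2 table.

    a: post with outcome, b: post without, c: pre with outcome, d: pre without.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or not math.isfinite(cell):
                raise ValueError("2x2 cells must be non-negative finite counts")

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def transpose(self) -> "TwoByTwo":
        """Swap the pre and post rows (outcome margins unchanged)."""
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class EffectEstimate:
    """A log-scale effect with its standard error and 95% CI.

    ``ci_low``/``ci_high`` are on the natural (exponentiated) scale, so
    ``ci_low <= exp(log_effect) <= ci_high``.
    """

    log_effect: float
    se: float
    ci_low: float
    ci_high: float
    measure_kind: str
    label: str = ""

    @property
    def estimate(self) -> float:
        """Point estimate on the natural (ratio) scale."""
        return math.exp(self.log_effect)

    def __post_init__(self) -> None:
        if not math.isfinite(self.se) or self.se < 0:
            raise ValueError("standard error must be finite and >= 0")


def _wald(log_effect: float, se: float, kind: str, label: str) -> EffectEstimate:
    return EffectEstimate(
        log_effect=log_effect,
        se=se,
        ci_low=math.exp(log_effect - Z95 * se),
        ci_high=math.exp(log_effect + Z95 * se),
        measure_kind=kind,
        label=label,
    )


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator``, full precision.

    Rounding to the display precision is a reporting concern and never
    happens here.
    """
    if denominator <= 0:
        raise ZeroDivisionError("proportion undefined for non-positive denominator")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return 100.0 * numerator / denominator


def odds_ratio(table: TwoByTwo, continuity: bool = False, label: str = "") -> EffectEstimate:
    """Unadjusted odds ratio with Woolf SE and 95% Wald CI.

    ``log_effect = ln(ad / bc)``, ``se = sqrt(1/a + 1/b + 1/c + 1/d)``.
    With ``continuity=True`` and any zero cell, 0.5 is added to every
    cell (Haldane-Anscombe); without it a zero cell raises, because the
    odds ratio is genuinely undefined there.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.has_zero_cell:
        if not continuity:
            raise ValueError(
                "odds ratio undefined with a zero cell; pass continuity=True "
                "for the Haldane-Anscombe 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return _wald(log_or, se, "odds_ratio", label)


def proportion_ratio(
    p_post: float,
    p_pre: float,
    counts: tuple[int, int, int, int] | None = None,
    label: str = "",
) -> EffectEstimate:
    """Post/pre proportion (risk) ratio, optionally with a Katz CI.

    Parameters
    ----------
    p_post, p_pre : float
        Proportions on any common scale (percent or fraction); the
        ratio is scale-invariant.  ``p_pre`` must be positive.
    counts : (x_post, n_post, x_pre, n_pre), optional
        Raw numerators and denominators.  When given, the standard
        error is the Katz log method
        ``sqrt(1/x_post - 1/n_post + 1/x_pre - 1/n_pre)`` and a 95%
        Wald CI on the log scale is attached; without counts the SE and
        CI are reported as 0 and degenerate at the point estimate.
    """
    if p_pre <= 0:
        raise ValueError("proportion ratio undefined when the pre proportion is 0")
    if p_post < 0:
        raise ValueError("proportions must be non-negative")
    ratio = p_post / p_pre
    if counts is None:
        log_ratio = math.log(ratio) if ratio > 0 else math.nan
        return EffectEstimate(log_ratio, 0.0, ratio, ratio, "proportion_ratio", label)
    x1, n1, x0, n0 = counts
    if min(x1, x0) <= 0 or min(n1, n0) <= 0:
        raise ValueError("Katz CI needs positive numerators and denominators")
    se = math.sqrt(1 / x1 - 1 / n1 + 1 / x0 - 1 / n0)
    return _wald(math.log(ratio), se, "proportion_ratio", label)


def effects_from_counts(counts) -> "list[EffectEstimate]":
    """Pre/post effect estimates from a long process-count table.

    ``counts`` is a DataFrame with columns ``cluster_id, stage, metric,
    numerator, denominator`` where ``stage`` is ``pre`` or ``post``.
    For every (cluster, metric) pair with both stages present, returns a
    proportion ratio (Katz CI) and an odds ratio (continuity-corrected
    if needed), labelled ``<cluster>:<metric>``.
    """
    required = {"cluster_id", "stage", "metric", "numerator", "denominator"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"process-count table missing columns: {sorted(missing)}")
    bad_stage = set(counts["stage"]) - {"pre", "post"}
    if bad_stage:
        raise ValueError(f"unknown stages: {sorted(bad_stage)}")
    out: list[EffectEstimate] = []
    for (cid, metric), sub in counts.groupby(["cluster_id", "metric"]):
        stages = sub.set_index("stage")
        if not {"pre", "post"}.issubset(stages.index):
            continue
        x0, n0 = int(stages.loc["pre", "numerator"]), int(stages.loc["pre", "denominator"])
        x1, n1 = int(stages.loc["post", "numerator"]), int(stages.loc["post", "denominator"])
        label = f"{cid}:{metric}"
        if x0 > 0:
            katz = (x1, n1, x0, n0) if x1 > 0 else None
            out.append(
                proportion_ratio(proportion(x1, n1), proportion(x0, n0), counts=katz, label=label)
            )
        out.append(odds_ratio(TwoByTwo(x1, n1 - x1, x0, n0 - x0), continuity=True, label=label))
    if not out:
        raise ValueError("no (cluster, metric) pair has both pre and post rows")
    return out
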