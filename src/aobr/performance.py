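"""COD-removal bookkeeping for regular and split-feeding operation.

Per-compartment removal is referenced to the total fed COD: compartment i
removes ``removal_i = Q_i (C_in,i - C_eff,i) / (Q_total C_feed) x 100 %``,
where ``Q_i`` is the flow through the compartment and ``C_in,i`` the
flow-weighted mix of the upstream effluent with any fresh feed stream.
With this total-feed denominator the contributions telescope: their sum
equals the overall removal 1 - C_effluent/C_feed for a single-strength
feed, for regular and split feeding alike. For regular feeding (all flow
through every compartment) the formula reduces to the plain
(influent - effluent)/initial influent convention.

Stage summaries use the paper-style operating stages (days 1-14, 15-28,
29-35 by default, overridable) with arithmetic mean and sample (n-1)
standard deviation; group comparison is classical one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, IncompleteChainError
from .reactor import ReactorConfig

__all__ = [
    "STAGE_DAYS",
    "stage_for_day",
    "compartment_influent",
    "RemovalSummary",
    "per_compartment_removal",
    "StageSummary",
    "stage_summary",
    "AnovaResult",
    "one_way_anova",
]

STAGE_DAYS: dict[str, tuple[int, int]] = {"I": (1, 14), "II": (15, 28), "III": (29, 35)}


def stage_for_day(day: int, stage_days: dict[str, tuple[int, int]] | None = None) -> str:
    """Operating stage containing a given day."""
    stage_days = stage_days or STAGE_DAYS
    for stage, (lo, hi) in stage_days.items():
        if lo <= day <= hi:
            return stage
    raise ConfigError(f"day {day} falls in no stage")


def compartment_influent(upstream_flow: float, upstream_cod: float,
                         feed_flow: float, feed_cod: float) -> float:
    """Flow-weighted COD of an upstream stream merged with a feed stream."""
    if upstream_flow < 0 or feed_flow < 0:
        raise ConfigError("flows must be >= 0")
    total = upstream_flow + feed_flow
    if total == 0:
        raise ConfigError("at least one merging stream must carry flow")
    return (upstream_flow * upstream_cod + feed_flow * feed_cod) / total


@dataclass
class RemovalSummary:
    """Per-compartment and overall COD removal, percent of total fed COD."""

    per_compartment_removal: np.ndarray  # %
    cumulative_removal: np.ndarray  # running sum, %
    overall_removal: float  # %
    influent_mg_L: np.ndarray | None = None
    effluent_mg_L: np.ndarray | None = None

    @classmethod
    def from_contributions(cls, contributions) -> "RemovalSummary":
        """Build a summary from already-computed per-compartment percentages."""
        c = np.asarray(contributions, dtype=float)
        cum = np.cumsum(c)
        return cls(per_compartment_removal=c, cumulative_removal=cum,
                   overall_removal=float(cum[-1]))


def per_compartment_removal(effluent_cod, feed_cod: float,
                            config: ReactorConfig) -> RemovalSummary:
    """Removal contribution of each compartment in a feed chain.

    ``effluent_cod`` holds each compartment's effluent concentration in
    chain order (one value per compartment; missing entries are an error).
    Compartment influents are reconstructed by flow-weighted mixing of the
    upstream effluent with the local feed stream, then each contribution is
    referenced to the total fed COD mass rate.
    """
    if feed_cod <= 0:
        raise ConfigError("feed_cod must be > 0")
    eff = np.asarray(effluent_cod, dtype=float)
    n = config.n_compartments
    if eff.size != n:
        missing = n - eff.size
        raise IncompleteChainError(
            f"expected effluent values for {n} compartments, got {eff.size} "
            f"({missing} missing)")
    if np.any(np.isnan(eff)):
        idx = int(np.flatnonzero(np.isnan(eff))[0]) + 1
        raise IncompleteChainError(f"missing effluent value for compartment {idx}")

    feed_q = config.feed_flows
    total_mass_rate = config.total_flow * feed_cod
    contributions = np.empty(n)
    influents = np.empty(n)
    q_up, c_up = 0.0, 0.0
    for i in range(n):
        q_i = q_up + feed_q[i]
        if q_i == 0.0:
            influents[i] = 0.0
            contributions[i] = 0.0
        else:
            influents[i] = compartment_influent(q_up, c_up, feed_q[i], feed_cod)
            contributions[i] = 100.0 * q_i * (influents[i] - eff[i]) / total_mass_rate
        q_up, c_up = q_i, eff[i]
    cum = np.cumsum(contributions)
    return RemovalSummary(per_compartment_removal=contributions,
                          cumulative_removal=cum,
                          overall_removal=float(cum[-1]),
                          influent_mg_L=influents, effluent_mg_L=eff)


@dataclass
class StageSummary:
    stage: str
    n_days: int
    removal_mean: float  # %
    removal_sd: float  # %
    effluent_mean: float  # mg/L
    effluent_sd: float  # mg/L


def stage_summary(records: pd.DataFrame, stage: str,
                  reactor_id: str | None = None,
                  stage_days: dict[str, tuple[int, int]] | None = None) -> StageSummary:
    """Mean +/- sample sd of overall removal and effluent COD within a stage.

    ``records`` is a long-format table with columns ``day``, ``stage``,
    ``reactor_id``, ``compartment`` (``feed``/``effluent``/index) and
    ``cod_mg_L``; each day must carry a feed and an effluent entry.
    """
    df = records
    if reactor_id is not None:
        df = df[df["reactor_id"] == reactor_id]
    df = df[df["stage"] == stage]
    if df.empty:
        raise ConfigError(f"no records for stage {stage!r}")
    feed = df[df["compartment"] == "feed"].set_index("day")["cod_mg_L"]
    effl = df[df["compartment"] == "effluent"].set_index("day")["cod_mg_L"]
    days = feed.index.intersection(effl.index)
    if len(days) < 2:
        raise ConfigError(
            f"stage {stage!r} needs >= 2 days with feed and effluent records")
    removal = 100.0 * (1.0 - effl.loc[days] / feed.loc[days])
    return StageSummary(
        stage=stage, n_days=len(days),
        removal_mean=float(removal.mean()), removal_sd=float(removal.std(ddof=1)),
        effluent_mean=float(effl.loc[days].mean()),
        effluent_sd=float(effl.loc[days].std(ddof=1)),
    )


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    significant: bool  # at alpha = 0.05


def one_way_anova(*groups, alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA across groups of removal values."""
    if len(groups) < 2:
        raise ConfigError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ConfigError("each group needs >= 2 values")
        if not np.all(np.isfinite(g)):
            raise ConfigError("groups must contain finite values")
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(f_statistic=float(f), p_value=float(p),
                       significant=bool(p < alpha))
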