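"""Two-tier hit classification.

Tier ``phospho_specific``: the siRNA significantly changes the phospho-tau
channel and the phospho/total ratio while the total-tau channel shows no
significant change — the signature of a kinase acting on the phospho
epitope rather than on tau expression. Tier ``dual_effect``: significant
change in both channels, irrespective of the ratio — a candidate modulator
of tau expression. Hits in either tier may be decreasers or increasers;
direction never gates tier membership.

Significance thresholds are configurable. The channel threshold defaults
to 0.05; the ratio threshold defaults to 0.06, slightly looser, because
the published phospho-specific set includes ratio p-values up to 0.057
while all channel p-values respect 0.05 — the published "significant" for
the ratio readout is evidently not a strict 0.05, so the two cutoffs are
kept as separate knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .published import DUAL_EFFECT, PHOSPHO_SPECIFIC

__all__ = ["Thresholds", "HitCall", "classify", "classify_table", "build_report", "hit_counts"]

TIER_NONE = "none"


@dataclass(frozen=True)
class Thresholds:
    alpha_channel: float = 0.05
    alpha_ratio: float = 0.06
    min_cells: int | None = None

    def __post_init__(self) -> None:
        for a in (self.alpha_channel, self.alpha_ratio):
            if not (0 < a <= 1):
                raise ValueError("significance levels must lie in (0, 1]")


@dataclass(frozen=True)
class HitCall:
    gene: str
    sirna_id: str
    tier: str  # phospho_specific | dual_effect | none
    direction: str | None  # decreaser | increaser, None for tier none
    passed_criteria: dict = field(default_factory=dict)
    missing_data: bool = False


def classify(summary: dict | pd.Series, th: Thresholds = Thresholds()) -> HitCall:
    """Classify one per-siRNA summary row into a tier.

    Expects ``phospho_p``, ``total_p``, ``ratio_p`` and ``phospho_avg``
    (plus ``cell_count`` when a cell floor is configured). Missing
    p-values yield tier ``none`` with ``missing_data`` set.
    """
    get = summary.get if isinstance(summary, dict) else summary.__getitem__
    p_ph, p_tot, p_rat = (get("phospho_p"), get("total_p"), get("ratio_p"))
    if any(p is None or not np.isfinite(p) for p in (p_ph, p_tot, p_rat)):
        return HitCall(get("gene"), get("sirna_id"), TIER_NONE, None, {}, missing_data=True)
    checks = {
        "phospho_significant": p_ph <= th.alpha_channel,
        "total_significant": p_tot <= th.alpha_channel,
        "ratio_significant": p_rat <= th.alpha_ratio,
    }
    if th.min_cells is not None:
        checks["enough_cells"] = get("cell_count") >= th.min_cells
        if not checks["enough_cells"]:
            return HitCall(get("gene"), get("sirna_id"), TIER_NONE, None, checks)
    if checks["phospho_significant"] and checks["total_significant"]:
        tier = DUAL_EFFECT
    elif checks["phospho_significant"] and not checks["total_significant"] and checks["ratio_significant"]:
        tier = PHOSPHO_SPECIFIC
    else:
        tier = TIER_NONE
    direction = None
    if tier != TIER_NONE:
        direction = "decreaser" if get("phospho_avg") < 1.0 else "increaser"
    return HitCall(get("gene"), get("sirna_id"), tier, direction, checks)


def classify_table(summaries: pd.DataFrame, th: Thresholds = Thresholds()) -> pd.DataFrame:
    """Classify every summary row; returns gene/sirna_id/tier/direction table."""
    calls = [classify(rec, th) for _, rec in summaries.iterrows()]
    df = pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "sirna_id": [c.sirna_id for c in calls],
            "tier": [c.tier for c in calls],
            "direction": [c.direction for c in calls],
            "missing_data": [c.missing_data for c in calls],
        }
    )
    support = (
        df[df["tier"] != TIER_NONE].groupby("gene")["sirna_id"].nunique().rename("gene_sirnas_hit")
    )
    return df.merge(support, on="gene", how="left").fillna({"gene_sirnas_hit": 0}).astype(
        {"gene_sirnas_hit": int}
    )


def _ordered(block: pd.DataFrame, key: str) -> pd.DataFrame:
    dec = block[block["direction"] == "decreaser"].sort_values(key, kind="mergesort")
    inc = block[block["direction"] == "increaser"].sort_values(key, kind="mergesort")
    return pd.concat([dec, inc], ignore_index=True)


def build_report(
    calls: pd.DataFrame, summaries: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked hit tables in the published layout.

    The phospho-specific table lists decreasers then increasers, each
    ascending by ratio average; the dual-effect table likewise, ascending
    by phospho average. Both carry the ten summary columns plus tier and
    direction.
    """
    from .stats import SUMMARY_COLUMNS

    cols = [c for c in SUMMARY_COLUMNS if c in summaries.columns]
    merged = calls.merge(summaries[cols], on=["gene", "sirna_id"], how="left")
    t1 = _ordered(merged[merged["tier"] == PHOSPHO_SPECIFIC], "ratio_avg")
    t2 = _ordered(merged[merged["tier"] == DUAL_EFFECT], "phospho_avg")
    keep = cols + ["tier", "direction", "gene_sirnas_hit"]
    keep = [c for c in keep if c in merged.columns]
    return t1.reindex(columns=keep), t2.reindex(columns=keep)


def hit_counts(calls: pd.DataFrame) -> dict:
    """Counts per tier/direction, for the JSON run summary."""
    out = {PHOSPHO_SPECIFIC: 0, DUAL_EFFECT: 0, TIER_NONE: 0}
    for tier, n in calls["tier"].value_counts().items():
        out[tier] = int(n)
    out["decreasers"] = int((calls["direction"] == "decreaser").sum())
    out["increasers"] = int((calls["direction"] == "increaser").sum())
    return out
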