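"""End-to-end validation runs on plates with planted effects.

These helpers drive the full imaging pipeline (render -> segment -> ring
measurement -> plate normalization -> replicate t-tests -> tier calling)
on synthetic plates whose ground truth is known, and score how well the
planted multiplicative effects and their tier/direction are recovered.
Used both by the test suite and by the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import substream
from .hits import Thresholds, classify_table
from .imagequant import QuantConfig, aggregate_well, quantify_image
from .platemap import make_platemap
from .stats import normalize_screen, summarize_screen
from .synth import Baselines, EffectSpec, NoiseModel, render_well_image, simulate_screen_tables

__all__ = [
    "PLANTED_EFFECTS",
    "rendered_screen_wells",
    "planted_recovery_runs",
    "expected_normalized",
    "score_runs",
]

#: planted (phospho_factor, total_factor) pairs and the tier/direction they imply
PLANTED_EFFECTS: dict[str, tuple[float, float, str, str]] = {
    "KIN_PHOS_DOWN": (0.67, 1.0, "phospho_specific", "decreaser"),
    "KIN_DUAL_DOWN": (0.61, 0.65, "dual_effect", "decreaser"),
    "KIN_PHOS_UP": (1.5, 1.0, "phospho_specific", "increaser"),
}


def rendered_screen_wells(
    platemap: pd.DataFrame,
    effects: dict[str, EffectSpec],
    noise: NoiseModel,
    seed: int,
    image_shape: tuple[int, int] = (256, 256),
    cell_count_mean: float = 60.0,
    config: QuantConfig = QuantConfig(),
    baselines: Baselines = Baselines(),
) -> pd.DataFrame:
    """Render and quantify every occupied well of a plate map, in memory.

    Identical generative substreams to :func:`tauscreen.synth.render_screen_images`
    (keyed by plate/well), without touching disk.
    """
    rows = []
    for rec in platemap.itertuples(index=False):
        if rec.role == "empty":
            continue
        if rec.role == "non_silencing":
            eff = EffectSpec("NS", 1.0, 1.0, cell_count_mean)
        else:
            eff = effects.get(rec.gene, EffectSpec(rec.gene, 1.0, 1.0, cell_count_mean))
        rng = substream(seed, "well", rec.plate_id, rec.well)
        rw = render_well_image(eff, noise, image_shape=image_shape, baselines=baselines, rng=rng)
        _, cells = quantify_image(rw.image, config)
        wm = aggregate_well(
            cells, rec.plate_id, rec.well, int(rec.replicate), exclude_border=config.exclude_border
        )
        rows.append(
            {
                "plate_id": rec.plate_id,
                "well": rec.well,
                "replicate": rec.replicate,
                "role": rec.role,
                "gene": rec.gene,
                "sirna_id": rec.sirna_id,
                "cell_count": wm.cell_count,
                "phospho_mean": wm.phospho_mean,
                "total_mean": wm.total_mean,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryRuns:
    """Scored outcome of repeated planted-effect screens."""

    calls: pd.DataFrame  # one row per (run, gene): tier, direction, correct
    summaries: pd.DataFrame  # per (run, gene) summary rows
    call_accuracy: float  # fraction of correct (gene, run) tier+direction calls
    recovery: pd.DataFrame  # per gene/channel: pooled mean avg, planted factor, |bias|, sem


def planted_recovery_runs(
    n_runs: int = 100,
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    cell_count_mean: float = 60.0,
    noise: NoiseModel = NoiseModel(),
    thresholds: Thresholds = Thresholds(),
    rendered: bool = True,
    effects: dict[str, tuple[float, float, str, str]] | None = None,
) -> RecoveryRuns:
    """Repeat a small planted-effect screen ``n_runs`` times and score it.

    Each run is one plate layout holding the planted genes plus triplicate
    NS controls, replicated as three physical plates (n = 3 replicates per
    siRNA). ``rendered=False`` uses the fast table path with the same
    generative model.
    """
    planted = effects or PLANTED_EFFECTS
    genes = sorted(planted)
    eff = {
        g: EffectSpec(g, planted[g][0], planted[g][1], cell_count_mean) for g in genes
    }
    wells_per_plate = len(genes) + 3  # exactly the occupied wells
    call_rows = []
    summary_rows = []
    for run in range(n_runs):
        run_seed = (seed + 7919 * run) % (2**31)
        pm = make_platemap(
            genes, sirnas_per_gene=1, replicates=3, controls_per_plate=3,
            wells_per_plate=wells_per_plate, seed=run_seed,
        )
        if rendered:
            wells = rendered_screen_wells(
                pm, eff, noise, run_seed, image_shape=image_shape,
                cell_count_mean=cell_count_mean,
            )
        else:
            wells = simulate_screen_tables(
                pm, effects=eff, noise=noise, seed=run_seed, cell_count_mean=cell_count_mean
            ).wells
        summaries = summarize_screen(normalize_screen(wells))
        calls = classify_table(summaries, thresholds)
        merged = calls.merge(summaries, on=["gene", "sirna_id"])
        for rec in merged.itertuples(index=False):
            want_tier, want_dir = planted[rec.gene][2], planted[rec.gene][3]
            call_rows.append(
                {
                    "run": run,
                    "gene": rec.gene,
                    "tier": rec.tier,
                    "direction": rec.direction,
                    "correct": rec.tier == want_tier and rec.direction == want_dir,
                }
            )
            summary_rows.append(
                {
                    "run": run,
                    "gene": rec.gene,
                    "phospho_avg": rec.phospho_avg,
                    "total_avg": rec.total_avg,
                    "ratio_avg": rec.ratio_avg,
                }
            )
    calls = pd.DataFrame(call_rows)
    summaries = pd.DataFrame(summary_rows)
    return RecoveryRuns(
        calls=calls,
        summaries=summaries,
        call_accuracy=float(calls["correct"].mean()),
        recovery=_recovery_table(summaries, planted, noise, cell_count_mean),
    )


def expected_normalized(
    factor: float,
    noise: NoiseModel,
    baselines_value: float = 6000.0,
    cell_count_mean: float = 60.0,
    n_controls: int = 3,
) -> float:
    """Expected percent-of-control readout for a planted factor.

    Two small, known offsets separate the expectation from the planted
    factor itself: the additive imaging background (never subtracted, per
    the measurement design) pulls readouts toward 1 by
    ``bg (1 - f) / (B + bg)``, and dividing by the mean of a finite
    control set inflates the expectation by its relative variance
    (second-order delta-method term). Both are O(1e-2) or smaller at the
    default settings.
    """
    b, bg = baselines_value, noise.background_level
    base = (b * factor + bg) / (b + bg)
    rel_var_control_mean = (
        noise.well_cv**2 + noise.cell_cv**2 / max(cell_count_mean, 1.0)
    ) / n_controls
    return base * (1.0 + rel_var_control_mean)


def _recovery_table(
    summaries: pd.DataFrame, planted, noise: NoiseModel, cell_count_mean: float
) -> pd.DataFrame:
    rows = []
    for gene, grp in summaries.groupby("gene"):
        for channel, idx in (("phospho", 0), ("total", 1)):
            target = planted[gene][idx]
            expected = expected_normalized(target, noise, cell_count_mean=cell_count_mean)
            vals = grp[f"{channel}_avg"].to_numpy()
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            rows.append(
                {
                    "gene": gene,
                    "channel": channel,
                    "planted": target,
                    "expected": float(expected),
                    "recovered": float(vals.mean()),
                    "abs_bias": float(abs(vals.mean() - target)),
                    "z_vs_model": float(abs(vals.mean() - expected) / sem),
                    "sem": float(sem),
                }
            )
    return pd.DataFrame(rows)


def score_runs(runs: RecoveryRuns) -> dict:
    """Headline numbers of a recovery experiment, JSON-friendly."""
    return {
        "call_accuracy": runs.call_accuracy,
        "n_calls": int(len(runs.calls)),
        "max_recovery_abs_bias": float(runs.recovery["abs_bias"].max()),
        "max_recovery_z_vs_model": float(runs.recovery["z_vs_model"].max()),
    }
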