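"""Plate normalization and replicate statistics.

Every well readout is expressed as a fraction of the mean of the
non-silencing (NS) control wells on the *same physical plate*; the per-well
phospho/total ratio is formed after normalization. Per siRNA, replicate
wells are then summarised as mean, sample SD (n-1 denominator) and a
two-tailed p-value for each of the three readouts (phospho, total, ratio).

The significance test: each replicate is paired with its own plate's
controls, and after normalization the control value is identically 1, so
the paired two-tailed t-test against controls reduces to a one-sample
two-tailed t-test of the n normalized replicate values against 1.0 with
n-1 degrees of freedom. For triplicates (df = 2) the two-sided tail
probability has the closed form

    p = 1 - |t| / sqrt(t^2 + 2),      t = (avg - 1) / (sd / sqrt(n)).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NoControlWellsError",
    "normalize_plate",
    "normalize_screen",
    "t_test_vs_control",
    "p_two_tailed_df2",
    "summarize_sirna",
    "summarize_screen",
    "recompute_table_pvalues",
    "SUMMARY_COLUMNS",
]

#: published-table column order for summary CSV output
SUMMARY_COLUMNS = [
    "gene",
    "sirna_id",
    "cell_count",
    "phospho_avg",
    "phospho_sd",
    "phospho_p",
    "total_avg",
    "total_sd",
    "total_p",
    "ratio_avg",
    "ratio_sd",
    "ratio_p",
]

_READOUTS = ("phospho", "total", "ratio")


class NoControlWellsError(ValueError):
    """A plate has no usable non-silencing control wells."""


def normalize_plate(wells: pd.DataFrame, min_cells: int = 0) -> pd.DataFrame:
    """Normalize one plate's wells to its NS-control means.

    ``wells`` must carry ``role``, ``cell_count``, ``phospho_mean`` and
    ``total_mean`` for a single plate. Wells with ``cell_count`` at or
    below ``min_cells`` (and empty wells) are dropped. Adds
    ``phospho_norm``, ``total_norm`` and ``ratio`` columns.
    """
    usable = wells[(wells["cell_count"] > max(min_cells, 0)) & np.isfinite(wells["phospho_mean"])]
    ns = usable[usable["role"] == "non_silencing"]
    if ns.empty:
        plate = wells["plate_id"].iloc[0] if len(wells) else "?"
        raise NoControlWellsError(f"plate {plate} has no usable non-silencing control wells")
    ns_phospho = float(ns["phospho_mean"].mean())
    ns_total = float(ns["total_mean"].mean())
    if ns_phospho <= 0 or ns_total <= 0:
        raise NoControlWellsError("non-silencing control means must be positive")
    out = usable.copy()
    out["phospho_norm"] = out["phospho_mean"] / ns_phospho
    out["total_norm"] = out["total_mean"] / ns_total
    out["ratio"] = out["phospho_norm"] / out["total_norm"]
    return out


def normalize_screen(wells: pd.DataFrame, min_cells: int = 0) -> pd.DataFrame:
    """Apply :func:`normalize_plate` per ``plate_id`` across a screen."""
    parts = [normalize_plate(g, min_cells=min_cells) for _, g in wells.groupby("plate_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


def p_two_tailed_df2(t: float | np.ndarray):
    """Closed-form two-sided Student-t tail probability for 2 df."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    return 1.0 - t / np.sqrt(t * t + 2.0)


def t_test_vs_control(avg: float, sd: float, n: int) -> float:
    """Two-tailed p for normalized replicates against the control value 1.0.

    One-sample Student t with ``n - 1`` df. Degenerate dispersion: sd = 0
    with avg != 1 gives the smallest positive float (the effect is exact);
    avg = 1 gives p = 1.
    """
    if n < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if avg == 1.0:
        return 1.0
    if sd == 0.0:
        return float(np.nextafter(0.0, 1.0))
    t = (avg - 1.0) / (sd / math.sqrt(n))
    return float(2.0 * sps.t.sf(abs(t), df=n - 1))


def summarize_sirna(norm_wells: pd.DataFrame) -> dict:
    """Summarise the replicate wells of a single siRNA.

    Returns one record with ``gene``, ``sirna_id``, ``cell_count`` (mean
    over replicates, rounded for reporting) and, for each readout,
    ``n/avg/sd/p``. With fewer than 2 finite replicates for a readout the
    p-value (and sd) are NaN rather than an error, so partially failed
    siRNAs still appear in reports.
    """
    rec = {
        "gene": norm_wells["gene"].iloc[0],
        "sirna_id": norm_wells["sirna_id"].iloc[0],
        "cell_count": int(round(norm_wells["cell_count"].mean())),
    }
    cols = {"phospho": "phospho_norm", "total": "total_norm", "ratio": "ratio"}
    for name in _READOUTS:
        x = pd.to_numeric(norm_wells[cols[name]], errors="coerce").dropna().to_numpy()
        n = x.size
        rec[f"{name}_n"] = n
        rec[f"{name}_avg"] = float(x.mean()) if n else np.nan
        rec[f"{name}_sd"] = float(x.std(ddof=1)) if n >= 2 else np.nan
        rec[f"{name}_p"] = (
            t_test_vs_control(rec[f"{name}_avg"], rec[f"{name}_sd"], n) if n >= 2 else np.nan
        )
    return rec


def summarize_screen(norm_wells: pd.DataFrame) -> pd.DataFrame:
    """Per-siRNA summaries for every target siRNA in a normalized well table."""
    targets = norm_wells[norm_wells["role"] == "target"]
    recs = [
        summarize_sirna(g) for _, g in targets.groupby(["gene", "sirna_id"], sort=True)
    ]
    df = pd.DataFrame(recs)
    ordered = SUMMARY_COLUMNS + [c for c in df.columns if c not in SUMMARY_COLUMNS]
    return df[ordered]


def _p_interval_under_rounding(avg: float, sd: float, n: int, step: float = 1e-3) -> tuple[float, float]:
    """Range of p attainable when avg and sd are rounded to ``step``.

    p is monotone decreasing in |avg - 1| and increasing in sd, so the
    extremes sit at corners of the rounding box.
    """
    h = step / 2.0
    lo_avg, hi_avg = avg - h, avg + h
    # |avg - 1| extremes over the avg interval
    if lo_avg <= 1.0 <= hi_avg:
        near, far = 1.0, max(abs(lo_avg - 1.0), abs(hi_avg - 1.0)) + 1.0
    elif hi_avg < 1.0:
        near, far = hi_avg, lo_avg
    else:
        near, far = lo_avg, hi_avg
    p_lo = t_test_vs_control(far, max(sd - h, 0.0), n)
    p_hi = t_test_vs_control(near, sd + h, n)
    return p_lo, p_hi


def recompute_table_pvalues(summaries: pd.DataFrame, n: int = 3) -> pd.DataFrame:
    """Audit published per-gene rows: recompute each p from its avg/sd.

    ``summaries`` carries ``{readout}_avg``, ``{readout}_sd`` and the
    published ``{readout}_p`` for readouts phospho/total/ratio. Emits one
    row per (gene row, readout) with the recomputed p, the absolute
    deviation from the published value, and ``dev_beyond_rounding``: the
    part of that deviation not explained by 3-decimal rounding of the
    published avg/sd inputs (the distance from the published p to the
    interval of p-values attainable within the rounding box). Rows with
    sd = 0 are flagged ``degenerate`` and excluded from deviation
    statistics.
    """
    rows = []
    for idx, rec in summaries.reset_index(drop=True).iterrows():
        for name in _READOUTS:
            avg, sd, p_pub = rec[f"{name}_avg"], rec[f"{name}_sd"], rec[f"{name}_p"]
            degenerate = sd == 0
            p_new = t_test_vs_control(float(avg), float(sd), n)
            if degenerate:
                beyond = np.nan
            else:
                p_lo, p_hi = _p_interval_under_rounding(float(avg), float(sd), n)
                beyond = max(p_lo - p_pub, p_pub - p_hi, 0.0)
            rows.append(
                {
                    "row": idx,
                    "gene": rec.get("gene", ""),
                    "readout": name,
                    "avg": avg,
                    "sd": sd,
                    "p_published": p_pub,
                    "p_recomputed": p_new,
                    "abs_dev": np.nan if degenerate else abs(p_new - p_pub),
                    "dev_beyond_rounding": beyond,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional report annotation)."""
    p = np.asarray(p, dtype=np.float64)
    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = sps.false_discovery_control(p[finite], method="bh")
    return q
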