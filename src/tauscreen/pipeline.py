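"""End-to-end reproducible pipeline: simulate -> quantify -> analyze -> call hits.

A run is described by a :class:`PipelineConfig` (JSON-serialisable); every
enabled stage reads its inputs from disk (or the previous stage), writes
its outputs under ``out_dir`` and logs one line per plate/stage. A run
manifest (package and library versions, seed, parameter hash) makes any
output reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .hits import Thresholds, build_report, classify_table, hit_counts
from .imagequant import QuantConfig, quantify_directory
from .platemap import make_platemap, read_platemap, write_platemap
from .stats import bh_qvalues, normalize_screen, summarize_screen
from .synth import (
    EffectSpec,
    NoiseModel,
    render_screen_images,
    simulate_screen_tables,
)

log = logging.getLogger("tauscreen")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Parameters for a full (or partial) screen run."""

    out_dir: str = "tauscreen_run"
    seed: int = 0
    # --- simulate ---
    simulate: bool = True
    n_genes: int = 30
    sirnas_per_gene: int = 2
    replicates: int = 3
    controls_per_plate: int = 3
    wells_per_plate: int = 96
    cell_count_mean: float = 300.0
    effects: dict[str, list[float]] = field(default_factory=dict)  # gene -> [phospho, total]
    noise: dict[str, float] = field(default_factory=dict)  # NoiseModel overrides
    render_images: bool = False
    image_shape: tuple[int, int] = (512, 512)
    images_dir: str | None = None
    # --- quantify ---
    quantify: bool = False
    ring_width: int = 4
    min_area: int = 30
    # --- analyze ---
    analyze: bool = True
    min_cells: int = 0
    bh_fdr: bool = False
    wells_csv: str | None = None
    platemap_csv: str | None = None
    # --- hit calling ---
    call_hits: bool = True
    alpha_channel: float = 0.05
    alpha_ratio: float = 0.06

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise) if self.noise else NoiseModel()

    def effect_specs(self) -> dict[str, EffectSpec]:
        return {
            g: EffectSpec(g, pf, tf, self.cell_count_mean)
            for g, (pf, tf) in self.effects.items()
        }

    def param_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.image_shape, list):
        cfg.image_shape = tuple(cfg.image_shape)
    return cfg


def _write_manifest(cfg: PipelineConfig, out: Path) -> None:
    import numpy, scipy, skimage

    manifest = {
        "tauscreen": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "param_hash": cfg.param_hash(),
        "config": asdict(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns paths of the artifacts.

    Raises with stage context on the first failing stage; a failed stage
    writes nothing downstream of itself.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(cfg, out)
    artifacts: dict[str, str] = {"manifest": str(out / "manifest.json")}

    platemap = None
    wells = None

    if cfg.simulate:
        log.info("simulate: %d genes x %d siRNAs x %d replicates", cfg.n_genes, cfg.sirnas_per_gene, cfg.replicates)
        platemap = make_platemap(
            cfg.n_genes,
            cfg.sirnas_per_gene,
            replicates=cfg.replicates,
            controls_per_plate=cfg.controls_per_plate,
            wells_per_plate=cfg.wells_per_plate,
            seed=cfg.seed,
        )
        write_platemap(platemap, out / "platemap.csv")
        artifacts["platemap"] = str(out / "platemap.csv")
        effects = cfg.effect_specs()
        noise = cfg.noise_model()
        if cfg.render_images:
            images_dir = Path(cfg.images_dir or out / "images")
            log.info("simulate: rendering %d wells to %s", int((platemap["role"] != "empty").sum()), images_dir)
            truth = render_screen_images(
                platemap,
                images_dir,
                effects=effects,
                noise=noise,
                seed=cfg.seed,
                image_shape=tuple(cfg.image_shape),
                cell_count_mean=cfg.cell_count_mean,
            )
            truth.to_csv(out / "ground_truth_cells.csv", index=False)
            artifacts["images_dir"] = str(images_dir)
            artifacts["ground_truth"] = str(out / "ground_truth_cells.csv")
        else:
            sim = simulate_screen_tables(
                platemap,
                effects=effects,
                noise=noise,
                seed=cfg.seed,
                cell_count_mean=cfg.cell_count_mean,
            )
            wells = sim.wells
            wells.to_csv(out / "wells.csv", index=False)
            artifacts["wells"] = str(out / "wells.csv")
        truth_rows = [
            {"gene": g, "phospho_factor": e.phospho_factor, "total_factor": e.total_factor}
            for g, e in effects.items()
        ]
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth_effects.csv", index=False)

    if cfg.quantify:
        if platemap is None:
            if cfg.platemap_csv is None:
                raise ValueError("quantify stage needs a plate map (run simulate or set platemap_csv)")
            platemap = read_platemap(cfg.platemap_csv)
        images_dir = cfg.images_dir or str(Path(cfg.out_dir) / "images")
        if not Path(images_dir).is_dir():
            raise FileNotFoundError(f"quantify stage: image directory not found: {images_dir}")
        log.info("quantify: measuring wells in %s", images_dir)
        qc = QuantConfig(ring_width=cfg.ring_width, min_area=cfg.min_area)
        wells = quantify_directory(images_dir, platemap, qc)
        wells.to_csv(out / "wells.csv", index=False)
        artifacts["wells"] = str(out / "wells.csv")

    summaries = None
    if cfg.analyze:
        if wells is None:
            if cfg.wells_csv is None:
                raise ValueError("analyze stage needs a well table (run simulate/quantify or set wells_csv)")
            wells = pd.read_csv(cfg.wells_csv)
        log.info("analyze: normalizing %d wells on %d plates", len(wells), wells["plate_id"].nunique())
        norm = normalize_screen(wells, min_cells=cfg.min_cells)
        norm.to_csv(out / "normalized_wells.csv", index=False)
        summaries = summarize_screen(norm)
        if cfg.bh_fdr:
            for r in ("phospho", "total", "ratio"):
                summaries[f"{r}_q"] = bh_qvalues(summaries[f"{r}_p"].to_numpy())
        summaries.to_csv(out / "gene_summaries.csv", index=False)
        artifacts["normalized_wells"] = str(out / "normalized_wells.csv")
        artifacts["gene_summaries"] = str(out / "gene_summaries.csv")
        try:
            from .reporting import qc_figure

            qc_path = out / "qc.png"
            qc_figure(norm, summaries, qc_path)
            artifacts["qc_figure"] = str(qc_path)
        except Exception as exc:  # pragma: no cover - plotting is best-effort
            log.warning("analyze: QC figure skipped (%s)", exc)

    if cfg.call_hits:
        if summaries is None:
            raise ValueError("call-hits stage needs gene summaries (enable analyze)")
        th = Thresholds(cfg.alpha_channel, cfg.alpha_ratio, cfg.min_cells or None)
        calls = classify_table(summaries, th)
        t1, t2 = build_report(calls, summaries)
        calls.to_csv(out / "hit_calls.csv", index=False)
        t1.to_csv(out / "hits_phospho_specific.csv", index=False)
        t2.to_csv(out / "hits_dual_effect.csv", index=False)
        (out / "hit_counts.json").write_text(json.dumps(hit_counts(calls), indent=2) + "\n")
        log.info("call-hits: %s", hit_counts(calls))
        artifacts.update(
            hit_calls=str(out / "hit_calls.csv"),
            hits_phospho_specific=str(out / "hits_phospho_specific.csv"),
            hits_dual_effect=str(out / "hits_dual_effect.csv"),
            hit_counts=str(out / "hit_counts.json"),
        )
    return artifacts
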