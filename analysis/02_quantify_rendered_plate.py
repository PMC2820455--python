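"""Render one plate as images and check the quantitation against ground truth.

Renders a 6-well-per-plate mini-screen (3 planted genes + NS triplicate,
3 replicate plates) to 16-bit TIFFs under scratch/, runs nucleus
segmentation and 4-px ring measurement on them, and compares the
normalized per-gene readouts with the planted factors. Images are bulky
scratch output; only the measurement tables land under results/.
"""

from pathlib import Path

from tauscreen.imagequant import QuantConfig, quantify_directory
from tauscreen.platemap import make_platemap
from tauscreen.stats import normalize_screen, summarize_screen
from tauscreen.synth import EffectSpec, NoiseModel, render_screen_images

ROOT = Path(__file__).resolve().parents[1]
SEED = 2026
CELLS = 60.0  # cells per imaged 256x256 field

PLANTED = {
    "KIN_PHOS_DOWN": (0.67, 1.00),
    "KIN_DUAL_DOWN": (0.61, 0.65),
    "KIN_PHOS_UP": (1.50, 1.00),
}


def main() -> None:
    pm = make_platemap(sorted(PLANTED), sirnas_per_gene=1, replicates=3,
                       controls_per_plate=3, wells_per_plate=6, seed=SEED)
    effects = {g: EffectSpec(g, p, t, CELLS) for g, (p, t) in PLANTED.items()}
    images_dir = ROOT / "scratch" / "plate_images"
    truth = render_screen_images(pm, images_dir, effects=effects, noise=NoiseModel(),
                                 seed=SEED, image_shape=(256, 256), cell_count_mean=CELLS)
    print(f"rendered {pm['plate_id'].nunique()} plates "
          f"({len(truth)} cells) to {images_dir}")

    wells = quantify_directory(images_dir, pm, QuantConfig())
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    wells.to_csv(out / "rendered_plate_wells.csv", index=False)

    summaries = summarize_screen(normalize_screen(wells))
    summaries.to_csv(out / "rendered_plate_summaries.csv", index=False)
    report = summaries.set_index("gene")[["phospho_avg", "total_avg", "ratio_avg"]]
    report["planted_phospho"] = [PLANTED[g][0] for g in report.index]
    report["planted_total"] = [PLANTED[g][1] for g in report.index]
    print(report.round(3).to_string())
    worst = (report["phospho_avg"] - report["planted_phospho"]).abs().max()
    print(f"worst phospho recovery error: {worst:.3f} (fraction of control)")


if __name__ == "__main__":
    main()
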