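"""Simulate a kinome-style siRNA screen with planted knockdown effects.

Generates a tables-only synthetic screen — 120 genes x 2 siRNAs x 3
replicate wells plus triplicate non-silencing controls on every plate —
with a handful of planted effects spanning the regimes the analysis must
distinguish: phospho-specific knockdown, dual knockdown of both channels,
a phospho increaser, and a sub-threshold nibble. Writes the plate map,
the well table and the ground truth under results/screen/.
"""

from pathlib import Path

from tauscreen.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]

#: planted (phospho_factor, total_factor); all other genes are null (1, 1)
PLANTED = {
    "GENE0001": [0.672, 0.979],  # phospho-specific decreaser (MARK2-like)
    "GENE0002": [0.61, 0.65],    # dual decreaser (EIF2AK2-like)
    "GENE0003": [1.50, 1.00],    # phospho-specific increaser
    "GENE0004": [0.92, 1.00],    # weak effect, below triplicate resolution
}


def main() -> None:
    cfg = PipelineConfig(
        out_dir=str(ROOT / "results" / "screen"),
        seed=2026,
        n_genes=120,
        sirnas_per_gene=2,
        effects=PLANTED,
        analyze=False,
        call_hits=False,
    )
    artifacts = run_pipeline(cfg)
    print("simulated screen written:")
    for k, v in artifacts.items():
        print(f"  {k}: {v}")
    print(f"planted effects: {PLANTED}")


if __name__ == "__main__":
    main()
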