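"""Two-tier hit calling on the simulated screen.

Applies the classifier (channel alpha 0.05, ratio alpha 0.06) to the
per-siRNA summaries from 03_replicate_statistics.py and writes the two
ranked hit tables plus a counts JSON under results/.
"""

import json
from pathlib import Path

import pandas as pd

from tauscreen.hits import Thresholds, build_report, classify_table, hit_counts

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    summaries = pd.read_csv(ROOT / "results" / "gene_summaries.csv")
    calls = classify_table(summaries, Thresholds())
    t1, t2 = build_report(calls, summaries)
    out = ROOT / "results"
    t1.to_csv(out / "hits_phospho_specific.csv", index=False)
    t2.to_csv(out / "hits_dual_effect.csv", index=False)
    counts = hit_counts(calls)
    (out / "hit_counts.json").write_text(json.dumps(counts, indent=2) + "\n")

    print(f"tier counts: {counts}")
    show = ["gene", "sirna_id", "phospho_avg", "ratio_avg", "tier", "direction"]
    print("phospho-specific table (top rows):")
    print(t1[show].head(6).round(3).to_string(index=False))
    print("dual-effect table:")
    print(t2[show].head(6).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
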