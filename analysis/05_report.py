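#!/usr/bin/env python
"""Compose the analysis outputs into ``results/report.md``."""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"

SECTIONS = [
    ("Demographics and morphology", "demographic_comparison.csv"),
    ("Quantitative parameters", "quantitative_comparison.csv"),
    ("ROC ranking of significant parameters", "roc_quantitative.csv"),
    ("Published model performance", "published_model_performance.csv"),
    ("Refit per-phase models", "refit_models.csv"),
    ("Stepwise-screened models", "screened_models.csv"),
]


def main() -> None:
    parts = ["# Four-phase renal CT quantitation: synthetic-cohort report\n"]
    for title, fname in SECTIONS:
        path = RESULTS / fname
        if not path.exists():
            continue
        parts.append(f"## {title}\n")
        parts.append(pd.read_csv(path).round(3).to_markdown(index=False))
        parts.append("")
    out = RESULTS / "report.md"
    out.write_text("\n".join(parts))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
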