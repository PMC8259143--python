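#!/usr/bin/env python
"""Voxel-phantom study: simulate lesions, run the three-ROI protocol.

Renders a 16-lesion four-phase phantom cohort (8 ccRCC-like with strong
enhancement patches and cysts, 8 AML.wovf-like with milder heterogeneity),
measures every lesion with the ROI(1)/(2)/(3) protocol and derives
NEV/RER/HDT/SHR. Writes ``results/phantom_measurements.csv`` and prints the
class contrast of the key corticomedullary-phase parameters, which should
reproduce the qualitative findings: higher RER under the small ROI and
higher heterogeneity (HDT/SHR) in the ccRCC-like class.
"""

from pathlib import Path

from renalct import io, pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    table = pipeline.measure_phantom_cohort(8, 8, seed=SEED)
    io.write_cohort(table, RESULTS / "phantom_measurements.csv")
    print(f"measured {len(table)} phantom lesions "
          f"(mean enhancing regions: {table.n_enhancing_regions.mean():.1f})")
    for col in ("AVT_CMP_2", "RER_CMP_2", "HDT_CMP", "SHR_CMP"):
        cc = table.loc[table.label == "ccRCC", col].mean()
        aml = table.loc[table.label == "AML.wovf", col].mean()
        print(f"  {col:10s} ccRCC {cc:7.1f}  AML.wovf {aml:7.1f}")


if __name__ == "__main__":
    main()
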