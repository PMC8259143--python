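# Lesion-table column dictionary

CSV dialect: UTF-8, comma-separated, header row, `.` decimal point.

| Column | Type | Units | Meaning |
|---|---|---|---|
| `lesion_id` | str | — | unique lesion identifier |
| `label` | str | — | `ccRCC` or `AML.wovf` |
| `age` | float | years | patient age |
| `size_cm` | float | cm | maximum cross-sectional tumor diameter |
| `gender` | str | — | `male` / `female` |
| `location` | str | — | `left` / `right` kidney |
| `growth_pattern` | str | — | `endophytic` / `exophytic` |
| `pseudocapsule` | int | 0/1 | low-attenuation rim around the mass observed |
| `cystic` | int | 0/1 | cystic degeneration observed |
| `angular` | int | 0/1 | angular (pyramidal, ≤ 90°) tumor–parenchyma interface |
| `AVT_<phase>_<k>` | float | HU | mean tumor attenuation, phase ∈ {PCP, CMP, NP, EP}, ROI variant k ∈ {1, 2, 3} |
| `AVC_<phase>` | float | HU | mean attenuation of adjacent homogeneous renal cortex |
| `NEV_<phase>_<k>` | float | HU | net enhancement, `AVT_<phase>_<k> − AVT_PCP_<k>` (enhanced phases) |
| `RER_<phase>_<k>` | float | % | relative enhancement ratio, `AVT/AVC × 100` (enhanced phases) |
| `HDT_<phase>` | float | HU | tumor heterogeneity: SD of attenuation within ROI(3) |
| `HDP_<phase>` | float | HU | psoas SD at the ROI(3) level (noise reference) |
| `SHR_<phase>` | float | % | standardized heterogeneous ratio, `HDT/HDP × 100` |
| `complete` | bool | — | all four phases measured (measurement tables) |
| `n_enhancing_regions` | int | — | enhancing regions detected in CMP (phantom tables) |

ROI variants: 1 = 50–100 mm² on the most-enhancing region; 2 = 10–20 mm²
inside the brightest patch; 3 = whole-tumor ROI, edge 2–3 mm inside the
boundary, geometry fixed on EP.
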