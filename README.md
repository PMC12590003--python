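# barsense

Analysis toolkit for **barcoded pathway-sensor assays** and the behavioral
readouts that accompany them in neuronal phenotyping studies.

A pathway-sensor assay infects cultured neurons with a library of reporter
constructs: each *sensor* — a cluster of transcription-factor binding sites
or a human promoter — drives a transcribed RNA barcode, so sequencing read
counts of the barcodes measure the activity of many signaling pathways
(MAPK/IEG, calcium, stress, immune, …) from a single well in parallel. A
minimal-promoter control reporter with no response element anchors
well-to-well normalization. `barsense` takes such an experiment from raw
FASTQ to annotated differential-response tables, and additionally scores
the standard behavioral metrics of the accompanying phenotyping battery
(open-field thigmotaxis, IntelliCage preference and SPRT learning time,
Y-maze spontaneous alternation, calcium ΔF). Seeded simulators generate
every input with known ground truth, so the whole pipeline is testable
end-to-end against parameter recovery.

## The model at the core

Counts of sensor *i* in well *j* follow a negative binomial,

    K_ij ~ NB( mean = s_j · μ_ij ,  var = μ + α_i μ² )

* **size factors** `s_j`: geometric mean of the well's four control-reporter
  barcode counts, anchored to geometric mean 1 across wells;
* **dispersion** `α_i`: per-sensor method-of-moments on normalized counts,
  pooled over within-stratum residuals;
* **Wald test**: for each contrast, a two-group fit with means `s_j·q` and
  `s_j·q·2^L`; `z = L/SE` with the SE from observed Fisher information;
* **Benjamini–Hochberg** adjustment within a contrast family;
* **fold-change gating**: significance stars (`*` … `****` at adjusted
  p ≤ 0.05/0.01/0.001/0.0001) are shown only where |log2FC| > 1.5.

See `docs/methods.md` for the estimators, tie-breaks and limitations.

## Worked example

Simulate a small assay (2 genotypes × {vehicle, AMPA 10 µM} × 4 replicates),
collapse barcode tags to sensors, and test the responses. The knockout
genotype attenuates responses (γ = 0.4 in the default effect table):

```python
import barsense as bs
from barsense.diff import Contrast
from barsense.simulate import default_effects, simulate_counts

panel = bs.build_default_panel(seed=1)                 # 22 sensors + control, 48 tags
sheet = bs.build_design(genotypes=("control", "cKO"), treatments=("AMPA",),
                        doses=(10.0,), timepoints=(4,), n_replicates=4, seed=2)
tag_counts, truth = simulate_counts(panel, sheet, default_effects(panel), seed=3)

model = bs.ResponseModel.from_quantification(tag_counts, panel, sheet)
res = model.fit([
    Contrast("AMPA10_ctrl_vs_veh", {"treatment": "AMPA", "genotype": "control"},
             {"treatment": "vehicle", "genotype": "control"}),
    Contrast("AMPA10_cKO_vs_veh", {"treatment": "AMPA", "genotype": "cKO"},
             {"treatment": "vehicle", "genotype": "cKO"}),
])
print(res.summary(max_rows=8))
```

```
Differential sensor response (NB Wald test)
============================================================
sensors: 23   contrasts: 2
fold-change gate: |log2FC| > 1.5   BH families: 1
annotated cells: 9 / 46
------------------------------------------------------------
sensor        contrast                  log2FC     SE     p_adj  label
EGR1p         AMPA10_ctrl_vs_veh          2.83   0.17  1.55e-63  ****
CRE           AMPA10_ctrl_vs_veh          2.79   0.20  7.59e-44  ****
SRE           AMPA10_ctrl_vs_veh          2.77   0.21  8.76e-39  ****
SARE          AMPA10_ctrl_vs_veh          2.75   0.22  8.11e-36  ****
UPRE-v2       AMPA10_ctrl_vs_veh          2.89   0.24  9.64e-33  ****
FOSBp         AMPA10_ctrl_vs_veh          2.76   0.25  2.22e-27  ****
FOSp          AMPA10_ctrl_vs_veh          2.87   0.32  1.21e-18  ****
NR4A1p        AMPA10_ctrl_vs_veh          2.83   0.34  2.41e-16  ****
... (38 more rows)
```

The simulated truth for these activity sensors is log2FC = 2.73 in control
neurons (Hill curve at 10 µM) and 1.09 in the knockout (γ·Lmax attenuation);
the fitted estimates recover the control effect within their standard errors
and only strongly responding cells get annotated — the 1.09 knockout effects
stay below the 1.5 gate, mirroring how fold-change gating separates the two
genotypes. `res.heatmap_matrix()` exports the log2FC/annotation grid and
`res.dose_response()` the mean ± SEM response table.

Behavioral metrics work the same way from tidy inputs:

```python
traj = bs.simulate_open_field(wall_attraction=0.9, seed=1)
bs.zone_metrics(traj).time_fraction["strip1"]   # -> 1.00 (thigmotactic agent)
bs.preference_score(30, 10)                     # -> 0.5
bs.spontaneous_alternation(list("ABCBAC"))      # -> 75.0
bs.sprt_learning_time([True] * 15).visit_index  # -> 9
```

There is also a CLI mirroring the library (`barsense simulate assay`,
`barsense quantify`, `barsense test`, `barsense summarize`,
`barsense behavior openfield|ymaze|intellicage|calcium`).

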