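# nuctrans

Per-cell quantification of nuclear translocation from imaging flow
cytometry, for cell biologists measuring how much of a cytoplasmic factor
(a transcription factor such as CREB3L1 or NF-κB, a signaling protein, a
reporter construct) has moved into the nucleus after a treatment.

An imaging flow cytometer records, for every cell in flow, a small
multichannel microscopy image — here a DNA-stain (nuclear) channel and a
fluorescent reporter channel — plus scalar features (brightfield area,
aspect ratio, viability-dye intensity). `nuctrans` implements the standard
analysis chain on top of those images:

1. **Gating** — keep only single, live, nucleated cells, using brightfield
   area and aspect ratio (singlets), a Live/Dead stain (viability), and the
   DNA-stain total (nucleation). A separate quadrant classifier bins events
   by annexin-V × viability-dye positivity into the four apoptosis states.
2. **Nuclear masking** — segment a per-cell nuclear region of interest from
   the DNA-stain image (Gaussian smoothing → Otsu threshold → binary
   closing → hole filling → largest connected component).
3. **Similarity score (SS)** — for each cell, the Pearson correlation *r*
   between the reporter and DNA-stain pixel values **inside the nuclear
   mask**, log-transformed:

   SS = ln((1 + r′)/(1 − r′)),  r′ = clamp(r, ±(1 − 10⁻⁶))

   High SS ⇒ the reporter's spatial distribution matches the nucleus
   (nuclear localization); low/negative SS ⇒ cytoplasmic distribution.
4. **Fisher's discriminant ratio (Rd)** — the population-level shift in SS
   between a treated and a control group:

   Rd = (mean SS_test − mean SS_control) / (sd SS_test + sd SS_control)

5. **Companion assays** — ΔΔCT relative gene expression
   (fold change = 2^−ΔΔCT, calibrated by default to the cohort-mean ΔCT) and
   relative-proliferation normalization (pre-treatment count = 0 %,
   untreated end point = 100 %).

Because real instrument data is rarely shareable, the package ships a
seeded synthetic event generator: cells are rendered as concentric disks
with a controllable nuclear fraction of the reporter, planted gate
categories (singlet/doublet/dead/anucleate), and Gaussian or Poisson
noise — so the entire pipeline is testable against known ground truth.

## Worked example

```python
import numpy as np
from nuctrans import (SyntheticPopulationSpec, generate_population,
                      score_events, rd_panel)

groups = {}
for i, (label, frac) in enumerate([("control", 0.2), ("treated", 0.8)]):
    spec = SyntheticPopulationSpec(n_events=200, nuclear_fraction_mean=frac,
                                   group_label=label, seed=10 + i)
    groups[label] = score_events(generate_population(spec))

for label, scores in groups.items():
    ss = [s.ss for s in scores if s.valid]
    print(f"{label}: median SS = {np.median(ss):.3f}")
for entry in rd_panel(groups, "control"):
    print(f"Rd({entry.test_label} vs {entry.control_label}) = {entry.rd:.2f}")
```

Output:

```
control: median SS = -1.198
treated: median SS = 3.714
Rd(treated vs control) = 3.27
```

The control population (20 % of the reporter nuclear) sits at negative
SS — anti-correlation with the DNA stain, predominantly cytoplasmic —
while the treated population (80 % nuclear) shifts far up the SS scale;
Rd = 3.27 says the two SS distributions are separated by 3.27 summed
standard deviations.

The same analysis runs from the shell:

```sh
nuctrans simulate --config sim.yaml --out data/
nuctrans run --in data/ --out results/ --control control
```

writing per-event score tables, group summaries, an Rd table, and a
machine-readable run log (counts reconcile at every stage; reruns are
byte-identical).

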