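# opdcyto

Label-free quantitative-phase cytometry for neutrophil subtyping.

High-risk myelodysplastic syndromes (MDS) disturb neutrophil maturation.
In interferometric phase microscopy (IPM), healthy blood contains two
neutrophil subpopulations — **H cells** (decondensed chromatin: low
optical path delay in the nucleus, ROS-bearing high-OPD vesicles, lower
dry mass) and **L cells** (mature polymorphonuclear cells: high nuclear
OPD, higher dry mass) — while high-risk MDS blood is almost devoid of H
cells (~20% vs ~4%). `opdcyto` implements the full computational chain
that turns raw off-axis interferograms into that cohort-level readout,
plus a ground-truthed phantom generator so every stage is testable
without instrument data.

## The measurement chain

1. **Reconstruction** — an off-axis interferogram
   `I = a + b·cos(2π f·r + φ)` encodes the sample phase `φ` on a carrier
   `f`. The +1 Fourier order is windowed out, demodulated, the phase
   unwrapped and converted to optical path delay,
   `OPD(x,y) = (n̄_o(x,y) − n_m)·h(x,y)` in nm, and a polynomial
   background surface removed.
2. **Morphometry** — the cell is segmented by a simple OPD threshold plus
   morphological dilation; 2D features (area `S_C`, perimeter) come from
   the mask, 3D features from the OPD values: the average OPD ⟨OPD⟩ and
   the dry mass

   `M = S_C · ⟨OPD⟩ / α`,  α ≈ 0.19 µm³/pg,

   the classical refractive-increment relation (in these units: µm² ×
   µm / (µm³/pg) → pg).
3. **Classification** — a 1D threshold placed where the empirical CDFs of
   the two classes cross (operationally: the balanced-misclassification
   minimizer, i.e. the crossing of the H survival curve and the L CDF),
   or a 5-fold cross-validated logistic model on (dry mass, ⟨OPD⟩).
4. **Cohort analysis** — cells outside the 5th–95th percentile band of the
   sorted-cell perimeter distribution are excluded as probable
   non-neutrophils; per-group pooled H fractions are compared with a
   two-sided two-proportion z test (per-feature group differences with a
   two-sample t test), α = 0.05.

The **phantom** module generates neutrophil OPD maps with the class
morphologies above (plateau-shaped cell body, round/banded/lobed nucleus
with class-specific OPD contrast, focal vesicles), calibrated to the
reported per-class feature means (area 100/98 µm², perimeter 54/51 µm,
⟨OPD⟩ 120/200 nm, dry mass 59/96 pg for H/L), and renders them into 8-bit
off-axis interferograms on the 1280×1024 camera raster.

## Worked example

```python
from opdcyto import PipelineConfig, run_end_to_end
import json

manifest = run_end_to_end(PipelineConfig(seed=7, out_dir="run"))
results = json.load(open("run/results.json"))
print(results["group_h_fractions"], results["statistic"], results["p_value"])
```

Output (seed 7):

```
{'BBD': 0.21868787276341947, 'MDS': 0.09113300492610837} 5.19265937567147 2.0731126922213002e-07
```

The run simulates a sorted training set (77 H / 94 L cells), fits the
dry-mass CDF-intersection threshold (here 74.0 pg, training accuracy
0.947), simulates a healthy-like cohort (575 cells, 20% H mixing) and an
MDS-like cohort (481 cells, 4% H), gates them on perimeter (503 and 406
cells survive), and classifies each cell. The healthy-like group shows
21.9% H cells versus 9.1% in the MDS-like group — the MDS figure sits
above the 4% mixing because a dry-mass-only threshold misreads a few
percent of L cells — and the two-proportion test rejects equality
decisively (z = 5.19, p = 2×10⁻⁷), reproducing the qualitative H-cell
deficit readout.

Every stage is also exposed on the command line (`opdcyto simulate`,
`reconstruct`, `features`, `classify`, `cohort`, `run`); see `--help`.

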