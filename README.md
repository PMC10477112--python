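# plaquant

Quantification of proximity-ligation-assay (PLA) signals in 3D confocal
z-stacks, for experiments that compare APP–secretase colocalization between
cell populations (e.g. neural progenitor cells vs mature neurons).

A PLA produces one diffraction-limited fluorescent dot wherever two
antibody-bound proteins lie within ~40 nm, so the total dot area is a
colocalization readout. `plaquant` implements the two quantification macros
such experiments rely on, the surrounding statistics, and an algebraic
decomposition of antibody-mixture signals:

* **macro 1** — per-image score from a {nucleus, PLA} stack pair:
  3D Gaussian pre-blur (σ = 3 nucleus / σ = 1 PLA), best-focus plane by
  maximal mean intensity, Li minimum-cross-entropy threshold (nucleus) and
  Triangle threshold (PLA) computed on that plane and applied to the whole
  stack, connected-component size filtering, then

  `ratio = PLA foreground voxels / nucleus foreground voxels`

  (normalizing dot area to cell number via the DAPI area);
* **macro 2** — percentage of a GFP-tagged organelle volume (Rab5a / Rab7a /
  Lamp1) occupied by PLA signal:
  `percent = 100 · |PLA ∩ ORG| / |ORG|` after per-channel Triangle
  thresholding;
* **group statistics** — ROUT outlier removal at Q = 0.1 % (robust
  Lorentzian location fit, RSDR from the 68.27th percentile of residuals,
  FDR-gated removal), pooled-variance two-tailed Student's *t*, fold changes
  against a calibrator group, the ΔΔCT rule
  `RQ = 2^−((CT_t−CT_ref)_sample − (CT_t−CT_ref)_cal)`, and half-LOD
  censoring of below-detection measurements;
* **CTF decomposition** — a C-terminal APP antibody detects both full-length
  APP (flAPP) and its C-terminal fragment (CTF), so its PLA signal is
  `T = F + C`. From two measured fold changes `r_F` (flAPP signal) and `r_T`
  (total C-terminal signal), minimizing over all feasible splits gives
  `C_npc/C_neu ≥ 1/r_T` and `C_npc/F_npc ≥ (r_F − r_T)/r_T`;
* **synthetic scenes** — a seeded generator of two-channel stacks (DAPI-like
  nuclei, Gaussian PLA dots, vesicle fields, Poisson + Gaussian noise) with
  exact voxel-level ground truth, so the whole pipeline is testable without
  microscopy data.

## Worked example

One command simulates a two-group experiment (neurons built with 63 % more
dots than NPCs), quantifies every stack with both macros, runs the
statistics, and derives the CTF bounds:

```bash
plaq run-all --out demo --seed 1 --n 8
cat demo/report.txt
```

```
== pla ==
images quantified: 16 (of 16)
== stats ==
ROUT (Q=0.001): removed 0 of 8 (NPC), 0 of 8 (neuron)
NPC: mean=0.62605 sem=0.01224 n=8
neuron: mean=0.86512 sem=0.01083 n=8
fold change neuron vs NPC (calibrator=1): 1.3819
t=-14.6226 df=14 p=7.13e-10 significant=True
== organelle ==
Rab5a occupancy, NPC: mean=21.288% sem=0.636 n=8
Rab5a occupancy, neuron: mean=9.528% sem=0.276 n=8
== ctf ==
min NPC:neuron CTF ratio >= 4.762
min NPC CTF:flAPP ratio >= 6.762
```

Reading the output: per-image PLA/nucleus ratios average 0.63 in the "NPC"
group and 0.87 in the "neuron" group — a 1.38-fold increase the *t* test
calls highly significant; Rab5a-organelle occupancy differs between the
groups as constructed; and with the measured fold changes (flAPP/BACE1
signal up 63 %, total C-terminal signal down to 0.21×) the CTF/BACE1
colocalization must be at least 4.76× lower in neurons than in NPCs, and at
least 6.76× the flAPP/BACE1 colocalization within NPCs.

The same steps are available piecewise (`plaq simulate`, `plaq
quantify-pla`, `plaq quantify-organelle`, `plaq compare`, `plaq ctf-bounds`)
and as library calls; every results CSV records the thresholds and
best-focus planes used per image.

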