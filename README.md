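# cardiophen

Quantitative phenotyping for stem-cell-derived cardiomyocytes (hiPSC-CMs),
built around the measurements used to characterise fatty-acid-challenged
HADHA-deficient cells: calcium-transient kinetics, action-potential and
optical-wave durations, beat-rate variability, micropost twitch forces,
Seahorse mitochondrial flux, RNA-seq maturation scoring, image morphometrics
and cardiolipin-aware lipidomics. It is aimed at groups running these assays
who want the analysis layer to be reusable, tested and free of one-off
scripts.

Every analysis stage has a matching synthetic-data generator
(`cardiophen.synth`) whose named presets encode published group means, so
each stage is validated by parameter recovery — generate noiselessly from a
preset, run the analysis, and the encoded value must come back.

## What it computes

- **Calcium transients** (`calcium`): cell segmentation and background-
  corrected trace extraction from imaging stacks; per-beat F, F0, F/F0,
  T_peak, T50R, T90R and the matched rates; relaxation constant from a
  least-squares fit of `A·exp(−t/τ) + C` on the 10–90% recovery limb.
- **Electrophysiology** (`electro`): APD50/APD90 from the maximum-dV/dt
  upstroke to the 50%/90% repolarization crossings of (peak − resting);
  optical-wave WD50/WD90, amplitude and maximum depolarization rate.
- **Rhythm** (`rhythm`): beat detection, ΔBI = |BI<sub>n+1</sub> − BI<sub>n</sub>|,
  fraction of ΔBI > 250 ms, and the 95% covariance (chi-square) Poincaré
  ellipse of (BI<sub>n</sub>, BI<sub>n+1</sub>) with its major/minor axis ratio.
- **Microposts** (`microposts`): per-post deflections Δ_i, total twitch force
  `F_twitch = Σ k_post·Δ_i` (k_post = 56.5 nN/μm), twitch velocity, and power
  in fW (nN·μm/s).
- **Mitochondrial flux** (`mito_flux`): per-cell OCR normalization and the
  mitostress decomposition — max OCR = FCCP − oligomycin, ATP production =
  basal − oligomycin, proton leak = oligomycin − antimycin/rotenone (so
  ATP + leak + non-mito = basal exactly) — plus palmitate utilization.
- **Enrichment & scRNA-seq QC** (`enrich`): ±1.5-fold DE sets, upper-tail
  hypergeometric pathway enrichment, the pathways × conditions net-benefit
  matrix `−log10(p_up/p_down)`, the 40%-mito / 200-gene / 2000-UMI cell
  filter, and cluster z-score summaries.
- **Morphometrics** (`morpho`): object area and circularity `4πA/P²` with a
  corner-corrected subpixel perimeter, Pearson + Manders colocalization, and
  the 2×4 nucleation chi-square (df = 3).
- **Lipidomics** (`lipids`): a parser for cardiolipin/acyl-carnitine species
  names (`tetra[18:2]-CL`, `[18:1][18:1][18:2][18:2]`, `AC(16:0-OH)`, ...),
  mTIC normalization, and the standard class summaries (long-chain and
  hydroxylated acyl-carnitine sums, TG totals, CL chain queries,
  tetra[18:2]-CL fraction, fold changes vs a reference group).

## Worked example

```python
from cardiophen import synth
from cardiophen.calcium import extract_trace, transient_metrics
from cardiophen.mito_flux import mitostress_metrics, normalize_ocr

# Calcium: a noiseless 5-beat stack from the wild-type preset
sim = synth.gen_imaging("WT_12D_GlcFA")
ana = transient_metrics(extract_trace(sim.stack), pacing=0.5, with_tau=True)
print(f"F/F0 = {ana.mean.fold:.3f}, tau = {ana.mean.tau:.3f} s")

# Seahorse: per-cell mitostress metrics from the same preset family
ocr = synth.gen_ocr("WT_12D_GlcFA")
_, m = mitostress_metrics(normalize_ocr(ocr.assay))
print(f"max OCR = {m.max_ocr:.1f}, ATP = {m.atp_production:.1f}, "
      f"leak = {m.proton_leak:.2f} pmol/min/cell")
```

prints

```
F/F0 = 2.030, tau = 0.630 s
max OCR = 359.0, ATP = 93.0, leak = 3.64 pmol/min/cell
```

i.e. the analysis pipeline recovers exactly the wild-type group means the
preset encodes: a 2.03-fold calcium rise relaxing with τ = 0.63 s, and the
mitostress decomposition of a healthy fatty-acid-oxidising cardiomyocyte.

A small CLI writes synthetic datasets (with ground truth) to disk:

```bash
cardiophen presets --modality calcium
cardiophen simulate imaging --preset WT_12D_GlcFA --seed 0 --out sim/
```

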