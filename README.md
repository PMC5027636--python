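# peasta

Analysis pipeline for **paired single-cell protein and RNA quantification by
qPCR** — proximity extension assay (PEA) readouts for proteins alongside
specific target amplification (STA) readouts for RNAs, measured in the same
single cells on a microfluidic qPCR platform.

It is written for groups running (or re-analyzing) multiplexed single-cell
PEA/STA experiments who need the full statistical chain, not just the
normalization: background-calibrated detection, probe qualification from
dilution ladders, correlation dynamics with permutation nulls, differential
screens, networks, classification, and trajectory clustering — each piece
unit-tested against independent oracles, with a synthetic-data generator
that produces realistic studies with known ground truth.

## The model in brief

All statistics operate on ΔCt, a nonnegative log2 abundance (one unit ≈ one
doubling; 0 = undetected):

* RNA: ΔCt = max(24 − Ct, 0); protein: ΔCt = max(bg − Ct, 0), with per-assay
  background bg estimated from zero-cell capture sites (Ct clipped to 24).
* Detection: one-sided normal background on the ΔCt scale; a value is
  detected when ΔCt > z(1−α)·σ_bg, α = 0.01. The limit of detection is the
  smallest quantity detected in ≥ 7 of 8 replicates.
* Probe qualification: on a dilution ladder, the contiguous window of ≥ 3
  levels maximizing R² − 0.03·(levels removed) in the OLS fit of mean ΔCt on
  log2 quantity; a probe is reliable if the window is rising, detected, and
  spans 1.3 cell equivalents.
* Single-cell distributions are bimodal: fraction expressing π plus a normal
  (μ, σ) over expressing cells. Differential calls therefore pair Fisher's
  exact test on detection with Mann–Whitney U on expressing cells, BH-
  corrected per in-silico gate experiment.
* Correlation edges: Spearman ρ exceeding the permutation-null threshold
  null_mean + z(1−α)·√null_var, computed per time point (≈ 0.29 at α = 0.01
  for n ≈ 70–90 cells, hence the working rule ρ > 0.3).

`docs/methods.md` documents every convention and degenerate case.

## Worked example

The numbered scripts under `analysis/` run the complete study on synthetic
data generated at study scale (116 assays: 89 RNA + 27 protein over 27
paired genes; 253 cells across 0/24/48 h of stimulation; 35 zero-cell
background wells):

```sh
python analysis/01_simulate_study.py      # writes results/simulated/
python analysis/02_preprocess.py          # ΔCt + background + cell culling
python analysis/03_calibrate_probes.py    # dilution panels, windows, LOD
python analysis/04_correlations.py        # paired ρ dynamics + permutation tests
python analysis/05_gating.py              # model fits + 116-gate screen
python analysis/06_network.py             # null calibration + seed networks
python analysis/07_classify.py            # PCA + random-forest AUC
python analysis/08_trajectories.py        # quadrant gating + clustering
```

Selected output (seed 0):

```
median RNAs detected per cell: 54 before cull, 54 after
culled 5/253 cells (<35 RNAs); retained per time point: {0.0: 90, 24.0: 77, 48.0: 81}

protein panel: 28/38 probes reliable; reliable windows span 7.9 doublings on average
rna panel: 89/96 probes reliable; reliable windows span 8.0 doublings on average

t=   0 hr: mean paired rho 0.25 (+-0.10) over 27 genes
t=  24 hr: mean paired rho 0.30 (+-0.12) over 27 genes
t=  48 hr: mean paired rho 0.26 (+-0.13) over 27 genes
mean coefficient of variation: protein 0.91 vs RNA 0.94

permutation null over 10 pairs x 3 time points: |mean| <= 0.002, var <= 0.014
edge threshold at alpha=0.01: rho > 0.27 (working threshold 0.3)

protein: one-vs-rest AUC 0.99 at 0 hr, 0.91 at 24 hr, 0.88 at 48 hr
    rna: one-vs-rest AUC 0.64 at 0 hr, 0.54 at 24 hr, 0.55 at 48 hr
```

Reading this: a median cell expresses 54 of the 89 qualified RNAs, and the
35-RNA cull removes only a small low-quality tail. Probe qualification
recovers the panel's built-in failure modes (saturated and signal-free
probes are rejected; windows average ~8 doublings). Paired RNA–protein
correlations are weakly positive (ρ̄ ≈ 0.25–0.30) — single-cell RNA and
protein levels are far from proxies for each other — while the permutation
null shows any |ρ| below ~0.3 is indistinguishable from label noise at these
cell counts. The protein panel both varies less (lower CV) and classifies
stimulation time point far better than the RNA panel, the signature of a
buffered but condition-responsive proteome.

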