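# mpskit

Quantitative analysis toolkit for liver-MPS (microphysiological system)
microtissue studies. It re-implements, as tested reusable components, the
analysis machinery of a scaffold-based liver NASH model:

- **`mpskit.fixtures`** — seeded synthetic generators standing in for raw
  data: slide mosaics of scaffolds populated with microtissues, confocal
  Z-stacks with depth-dependent defocus, first-order drug-decay time courses,
  expression matrices with group/plate/residual structure, and biomarker
  panels with detection limits. Every generator returns machine-readable
  ground truth for recovery testing.
- **`mpskit.imaging`** — the automated fibrosis quantification workflow:
  stitch low-magnification nuclei tiles (cross-correlation refinement,
  feathered blending), detect circular scaffolds, place a fixed 8-ROI array,
  pick the in-focus plane of each Z-stack (variance of Laplacian on the
  nuclei channel), segment microtissues (Gaussian smooth → Otsu → connected
  components → size filter), measure background-subtracted total α-SMA /
  collagen-I intensity per microtissue, and aggregate per FOV and per
  scaffold with condition fold-change comparisons.
- **`mpskit.pk`** — in-vitro pharmacokinetics: recovery vs nominal input,
  rapid-equilibrium-dialysis fraction unbound, log-linear half-life fitting,
  piecewise-exponential simulation of daily spike-to-nominal dosing with
  periodic full media changes, and clinical-Cmax-anchored dose translation.
- **`mpskit.omics`** — top-N DEG ranking, directional marker-set concordance,
  one-sided Fisher's-exact enrichment with Bonferroni correction, cluster
  comparison across conditions, per-row z-score matrices, a stand-in Welch
  differential-expression test with Benjamini–Hochberg FDR, and a
  plate/batch null miscall-rate simulator.
- **`mpskit.panels`** — biomarker-panel detectability filtering with an
  exclusion report, one-way ANOVA with Sidak-corrected pairwise comparisons,
  and Oil-Red-O absorbance normalisation to total protein.
- **`mpskit.workflow`** — configuration, orchestration and manifests for
  reproducible end-to-end synthetic runs.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter
recovery, closed-form checks, oracle equivalences, statistical calibration).

## Command line

```sh
mpskit demo --seed 1 --out out/            # full synthetic end-to-end run
mpskit imaging run --seed 1 --out out/     # same pipeline, imaging focus
mpskit fixtures decay --t-half 12 --noise-cv 0.05 --out decay.csv
mpskit pk fit decay.csv
mpskit pk simulate --t-half 12 --dose 0.5
mpskit pk translate --plasma-cmax 0.5 --liver-cmax 12.5 \
    --multiplier plasma:1 --multiplier plasma:10 --multiplier liver:1
mpskit omics concordance deg.csv markers.gmt
mpskit omics batchsim --n-genes 10000 --residual-sd 1.0
mpskit panel filter panel.csv
```

The demo writes per-microtissue, per-scaffold and condition-comparison CSVs
plus a ROI coordinate file and a run manifest (config hash, seed, outputs).

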