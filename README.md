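# chlorospec

Non-destructive estimation of leaf chlorophyll content (mg g⁻¹) from
visible/near-infrared reflectance spectra (350–2500 nm), with a
principled answer to the question every calibration campaign faces:
*how many samples must be sent to wet chemistry for the calibration set
to represent the population?*

The package implements, end to end:

* **Preprocessing** — absorbance transform A = log₁₀(1/R) and
  Savitzky–Golay smoothing (first-order polynomial, 15-band window).
* **Kennard–Stone (KS) selection** — deterministic max–min sample
  selection producing the calibration/validation split and serial nested
  subsets (60, 100, …, 260 of 280).
* **The MSD representativeness statistic** — for each subset size *i*
  and each retained principal component *j*, Gaussian kernel density
  estimates of the subset scores P_s(x_j ∈ ss) and the validation
  population scores P_p(x_j) are compared by the squared Euclidean
  density distance

      d²_j = ∫_a^b ( P_p(x_j) − P_s(x_j ∈ ss) )² dx_j ,
      msd  = (1/k) Σ_{j=1..k} d²_j ,

  with a shared bandwidth (Silverman's rule on the population scores)
  and kernel. Sweeping msd over subset sizes and taking the elbow
  nominates the smallest representative subset.
* **Calibration models** — PLS1 regression (NIPALS) with the
  latent-variable count chosen by leave-one-out CV, VIP scores flagging
  informative bands (VIP > 1); and a Cubist-style rule-based model
  (model trees with linear models in the nodes, committee ensembles,
  nearest-neighbour correction) grid-searched over committees
  {2, 4, 6, 8} × neighbours {10, 20, 30, 40} under seeded 10-fold CV.
* **Evaluation** — R², RMSE(P), RPIQ, bias/MBE and per-species /
  per-month summaries.
* **Synthetic study generator** — leaf spectra with the study's design
  (5 species × 10 months × 7 replicates = 350 samples), species
  chlorophyll means from the field summary, a seasonal factor peaking in
  August, chlorophyll-sensitive bands at 500–640 nm and 740–1100 nm and
  water bands at 1450/1940 nm, so the whole pipeline is testable without
  any download.

## Worked example

```python
import chlorospec as cs

# synthetic study design: 350 leaf samples on a 1 nm grid, seed 1
spectra, meta = cs.simulate_dataset(cs.GeneratorConfig(seed=1))
absorb = cs.preprocess(spectra)           # log10(1/R) + SG(15, 1)

# Kennard-Stone 280/70 split in 99%-variance PC space
pcs = cs.fit_pca(absorb.values, var_threshold=0.99).scores
cal, val = cs.ks_split(pcs, 280)

# MSD sweep over nested subsets 60..260
results, nominated = cs.msd_sweep(absorb.values[cal], absorb.values[val])
for r in results:
    print(f"size {r.subset_size:3d}  msd {r.msd:.4f}")
print("nominated subset size:", nominated)
```

prints (seed 1):

```
size  60  msd 0.0388
size 100  msd 0.0280
size 140  msd 0.0246
size 180  msd 0.0201
size 220  msd 0.0199
size 260  msd 0.0163
```

The MSD falls as the KS subset grows — small subsets over-represent the
spectral extremes, so their PC score densities sit far from the
validation population's — and the elbow rule nominates the smallest size
within 10% of the sweep minimum. Fitting both models on the nominated
subset and evaluating on the 70 held-out samples:

```python
y = meta["chlorophyll"].to_numpy()
sub_space = cs.fit_pca(absorb.values[cal], var_threshold=0.99).scores
sub = cal[cs.kennard_stone(sub_space, nominated)]

plsr = cs.fit_plsr(absorb.values[sub], y[sub], max_lv=20)
print(cs.evaluate(y[val], cs.predict_plsr(plsr, absorb.values[val])))
```

gives `r2=0.99995, rmse=0.0032, bias=-0.0005` (mg g⁻¹): on this
noise-controlled synthetic design the chlorophyll signal is linear in
absorbance, so PLSR recovers it almost exactly; the Cubist-style model
(`cs.grid_search_cubist`) reaches `rmse=0.0025`, slightly better, the
same ordering the field study reports. VIP scores
(`cs.vip_scores(plsr)`) exceed 1 inside the generator's signal bands.

The same workflow is available as a CLI:

```bash
chlorospec run --simulate study --seed 1 --out runs/replica
chlorospec simulate --size tiny --seed 1 --out data/
chlorospec preprocess --sg-window 15 --sg-order 1 data/spectra.csv out.csv
```

`runs/replica/` then holds the preprocessed spectra, the id lists, the
MSD sweep table, both serialized models, evaluation reports, and the
density/MSD, predicted-vs-observed, VIP and monthly-trend figures.

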