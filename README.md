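# lysokit

Analysis toolkit for neuronal lysosome proteomics: dynamic-SILAC protein
turnover, organelle-enrichment statistics, and ratiometric lysosomal pH.

## Who this is for

Labs studying organelle biology in post-mitotic neurons (e.g. iPSC-derived
i³Neurons) with some combination of:

* **dynamic SILAC (dSILAC)** — switch cultures to heavy-lysine medium and
  follow label incorporation to measure protein half-lives;
* **organelle enrichment proteomics** — Lyso-APEX proximity labeling,
  Lyso-IP immunopurification, or Lyso-BAR antibody-guided biotinylation,
  quantified as protein × sample intensity tables;
* **ratiometric pH imaging** — pH-sensitive Oregon Green 488 / pH-insensitive
  Alexa 555 dextran ratios per lysosome, calibrated with nigericin-clamped
  buffers.

The package takes plain TSV/CSV tables (MaxQuant-evidence-like peptide
tables, protein matrices, per-object fluorescence tables) and produces
volcano-ready statistics, half-life tables and pH reports. Raw spectral
search, image segmentation and live pathway-database queries are out of
scope. Seeded synthetic-data generators with known ground truth
(`lysokit.simulate`) let every pipeline stage be validated end to end.

## The models

**Turnover.** Under first-order decay with rate constant *k*, pre-existing
(light) protein follows L(t) ∝ e^(−kt) and newly made (heavy) protein
mirrors it, so the heavy-to-light ratio is Ψ(t) = e^(kt) − 1. A single
sampling time t_s then gives

    t½ = t_s · ln 2 / ln(1 + Ψ),

and a multi-day course (1, 2, 4, 6 days) gives *k* by least squares on the
light fraction L/(L+H) against e^(−kt). Apparent protein half-lives are the
mean over unique peptides, per biological replicate. No amino-acid-recycling
or cell-division correction is applied (post-mitotic cultures).

**Differential turnover.** Per-protein Welch t-tests on replicate half-lives
in days, Benjamini–Hochberg correction within each comparison, and no
fold-change gate (half-life effects are small); plus fraction-altered
summaries, |Δt½| heatmaps, PCA and hierarchical clustering of half-life
profiles, and a user-supplied-gene-set hypergeometric test.

**Enrichment.** Intensities are normalized to an endogenously biotinylated
reference protein (PCCA), log2-transformed, tested with Welch t-tests and
BH-corrected, then gated at q < 0.05 and a 1.5-fold ratio. Spatial-control
filtering removes cytosolic/nonspecific labeling; paired lysosome/cytosol
contrasts yield translocation calls.

**pH.** A strictly monotone calibration curve (linear, cubic or 4-parameter
logistic) maps 488/555 ratio to pH; per-lysosome ratios are inverted by
bisection, wells are the statistical unit, and proton concentrations are
reported both as the mean of per-object 10^(−pH) and as 10^(−mean pH).

## Worked example

```python
import lysokit as lk

# dSILAC: 200 proteins, 4 replicates, 20% CV, sampled at 1/2/4/6 days
table, truth = lk.generate_dsilac(lk.DSilacDesign(n_proteins=200, noise_cv=0.2), seed=7)
res = lk.HalfLifeModel(table, sampling_time_h=96).fit()
print(res.summary())

# ratiometric pH: WT vs progranulin-knockout neurons, 15 wells per group
calib, objects, _ = lk.generate_ph(seed=7)
curve = lk.fit_calibration(calib, model="linear")
assay = lk.PHAssayModel(objects, curve).fit()
print(assay.group_compare("WT", "GRN_KO").summary())
```

prints

```
Half-life estimation summary
  method:               single_timepoint
  sampling time:        96 h
  peptide estimates:    4000 (0 censored)
  protein estimates:    800 across 200 proteins
  median protein half-life [WT]: 3.812 days

Lysosomal pH: WT vs GRN_KO
  WT: pH 4.32 ± 0.02 (15 wells), [H+] ≈ 51.5 μM (10^-mean pH: 48.4 μM)
  GRN_KO: pH 4.81 ± 0.03 (15 wells), [H+] ≈ 18.4 μM (10^-mean pH: 15.5 μM)
  proton fold change (A/B): 2.80 (from mean pH: 3.12)
  Welch p (well means): 5.58e-27
```

The median recovered half-life sits near the planted 4-day median; the pH
pipeline recovers the planted group means (4.31 and 4.81) and shows the
characteristic ~3-fold proton-concentration drop a 0.5-unit pH increase
implies.

The same workflows are available from the shell:

```sh
lysokit simulate --kind dsilac --seed 1 --out-dir run/
lysokit halflife --peptides run/peptides.tsv --metadata run/samples.tsv --out-dir run/hl
lysokit diffturn --half-lives run/hl/half_lives.tsv --group-a KO --group-b WT --out-dir run/dt
```

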