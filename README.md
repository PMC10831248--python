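# massphot

Analysis pipeline for characterizing peptidisc-reconstituted membrane proteins
by single-molecule mass photometry, exercised end-to-end on synthetic
landing-event data with known ground truth.

The package covers:

- **`massphot.synthetic`** — seeded simulation of per-event mass/contrast
  tables: Gaussian instrument error (σ ≈ 10–15 kDa), Poisson landing counts,
  a hard detection limit that hides small free ligands, exact 1:1 mass-action
  binding equilibria with ligand depletion, and a linear contrast–mass model.
- **`massphot.calibration`** — linear contrast-to-mass calibration against
  standards (pooled before/after runs, per-run slope drift reported), Gaussian
  KDE mass spectra (σ = 5 kDa kernel, unit area), peak finding and FWHM.
- **`massphot.decomposition`** — constrained two-Gaussian fits (centers fixed
  to receptor and receptor+ligand sequence mass ± 1 kDa, shared fixed sigma),
  single-Gaussian purity fits, and baseline subtraction of the zero-ligand
  apparent complex fraction.
- **`massphot.titration`** — depletion-corrected free ligand
  (`[free] = [titrated] − f·[receptor]`), the 1 nM free-ligand inclusion
  filter, bounded hyperbolic (Hill, coefficient 1) fits with 0–100 %
  asymptote bounds, and replicate pooling/summaries.
- **`massphot.composition`** — phosphate-assay standard curve, peptidisc
  composition arithmetic (0.8 kDa per lipid, 4.5 kDa per scaffold peptide),
  and exhaustive integer stoichiometry assignment of multi-component species.
- **`massphot.cli`** — a `massphot` command with JSON run configs.

## CLI

Every subcommand takes a JSON config and an output directory. Unknown config
keys are rejected and stochastic runs require an explicit seed (exit status 2
on config errors, 1 on flagged fit failures).

```sh
massphot simulate  --config sim.json   --out out/   # event table from species mixture
massphot calibrate --config cal.json   --out out/   # contrast-to-mass line
massphot spectrum  --config spec.json  --out out/   # KDE spectrum + peaks/FWHM
massphot decompose --config dec.json   --out out/   # constrained two-Gaussian fit
massphot titrate   --config titr.json  --out out/   # isotherm + bounded Hill fit
massphot compose   --config comp.json  --out out/   # disc composition arithmetic
massphot assign    --config asgn.json  --out out/   # integer stoichiometry
```

Example end-to-end titration config (simulate → decompose → correct → fit):

```json
{
  "receptor_mass": 208.0,
  "ligand_mass": 29.4,
  "simulate": {
    "seed": 5,
    "kd_true": 50.0,
    "receptor_total": 200.0,
    "ligand_totals": [0, 25, 50, 100, 225, 450, 900],
    "n_events": 5000,
    "replicate_seeds": [5, 6, 7]
  }
}
```

`titrate` also accepts `points_csv` (precomputed titration points) or
`events_dir` + `conditions_json` (per-condition event CSVs).

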