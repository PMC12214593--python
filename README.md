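# bretpharm

Quantitative analysis of GPCR–β-arrestin coupling with BRET biosensors,
built around one question: when a receptor reshapes and redirects
β-arrestin, is that behavior carried by the receptor's transmembrane
**helix-bundle** or by its phosphorylated **C-terminus**?

The package implements the full workflow for the classic domain-swap
design — the class A β2-adrenergic receptor (b2AR), the class B
vasopressin V2 receptor (V2R), and their tail-swapped chimeras b2V2
and V2b2 — from raw plate-reader wells to a per-readout
*transferability coefficient*:

* **BRET processing** (`bretpharm.bret`): mock-labeling correction,
  baseline and vehicle normalization, 2–4 min window averaging,
  anchored concentration–response assembly.
* **Pharmacological gating** (`bretpharm.gating`): four-parameter
  logistic fits
  `y = bottom + (top − bottom)/(1 + 10^((log10 EC50 − x)·h))` with a
  responder gate (|Hill| > 0.1, EC50 within 10⁻³–10⁰·³ µM, manual
  overrides); non-responders are assigned exactly zero.
* **Conformational fingerprints** (`bretpharm.fingerprints`): gated
  responses of the FlAsH positions F1–F10, max-sensor normalization,
  agglomerative clustering under Manhattan distance.
* **Functional readouts** (`bretpharm.readouts`): phospho-immunoassay
  OD normalization (negative control → 0%, positive control → 100%),
  pERK/totalERK ratios and trapezoidal AUC, Rab5 co-localization fold
  changes.
* **Transferability** (`bretpharm.transferability`): per-assay
  harmonization and, for quartet responses r(·),

      tail  = |r(b2AR) − r(b2V2)| + |r(V2R) − r(V2b2)|
      core  = |r(b2AR) − r(V2b2)| + |r(V2R) − r(b2V2)|
      coefficient = tail − core

  positive ⇒ the readout follows the C-terminus, negative ⇒ the
  helix-bundle; |r(b2AR) − r(V2R)| scales the bubble-plot markers.
* **Synthetic data** (`bretpharm.synthetic`): seeded generators with
  known ground truth for every input class — BRET plates, responder
  panels, ERK kinetics (transient vs sustained), phospho plates and
  co-localization tables — so every stage is testable end to end
  without any download.

See `docs/methods.md` for the model assumptions, parameter defaults
and known limitations.

## Worked example

Simulate a small plate for b2AR and V2R with the F5 conformational
sensor, process it, fit and gate, then run the two end-to-end
attribution studies:

```python
from bretpharm import synthetic, workflows
from bretpharm.synthetic import NoiseModel, PlateDesign, SensorTruth

design = PlateDesign(
    receptors=("b2AR", "V2R"),
    sensors=("F5",),
    concentrations_uM=(0.001, 0.01, 0.1, 1.0, 10.0),
    timepoints_min=(-3, -2, -1, 0, 1, 2, 3, 4, 5),
)
truths = {
    ("b2AR", "F5"): SensorTruth("b2AR", "F5", 0.0, 0.08, -1.3, 1.0, True),
    ("V2R", "F5"): SensorTruth("V2R", "F5", 0.0, 0.20, -1.0, 1.1, True),
}
wells = synthetic.gen_bret_plate(design, truths, NoiseModel(sd_ratio=0.002, seed=42))
result = workflows.run_bret_pipeline(wells)
print(result["gates"][["receptor", "sensor", "log_ec50", "hill", "status", "gated_value"]])

endo = workflows.endosomal_arrestin_study(seed=42)
erk = workflows.erk_kinetics_study(seed=42)
print(f"endosomal arrestin delivery: coefficient {endo.coefficient:+.2f} ({endo.label})")
print(f"ERK1/2 activation AUC:       coefficient {erk.coefficient:+.2f} ({erk.label})")
```

Output:

```
receptor sensor  log_ec50     hill     status  gated_value
     V2R     F5 -0.999842 1.116462 responding    19.822472
    b2AR     F5 -1.398349 0.996737 responding     7.545087
endosomal arrestin delivery: coefficient +1.28 (C-terminus transferable)
ERK1/2 activation AUC:       coefficient -9.89 (helix-bundle transferable)
```

Both sensors pass the responder gate; the fitted EC50s and Hill slopes
sit at the generating values (V2R truth: log EC50 −1.0, Hill 1.1) up
to plate noise, and the gated values are the measured Δ net BRET
changes (%) at the highest tested concentration. The two studies
recover the configured domain drivers: arrestin delivery to endosomes
increases only for receptors carrying the V2R tail (positive
coefficient), while ERK kinetics follow the helix-bundle (negative
coefficient — the sustained V2R-bundle time course accumulates more
normalized area than the transient b2AR-bundle one).

The same pipeline is available from the shell:

```
bretpharm simulate    --config sim.yaml --seed 1 --out data/
bretpharm process     --in data/wells.csv --convention percent --out proc/
bretpharm fit         --in proc/concresp.csv --out fits/
bretpharm fingerprint --in fits/gates.csv --cluster complete --out fp/
bretpharm transfer    --in fits/gates.csv --out transfer.csv
```

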