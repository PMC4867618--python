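# hed — histone ensemble dynamics

`hed` is a Python toolkit for characterizing proteins that combine a folded
core with long intrinsically disordered tails — the situation of the
isolated histone H2A-H2B heterodimer, whose solution ensemble shows a rigid
histone fold flanked by ~30-residue flexible tails that are not completely
random coils.  It reimplements, as a reusable pipeline, the analyses such a
study needs:

* **Chemical shift index (CSI).**  Secondary shifts Δδ = δ_obs − δ_rc for
  Cα/Cβ, combined as Δδ(Cα) − Δδ(Cβ) and thresholded into per-residue
  helix (+1) / strand (−1) / coil (0) indices.
* **Geometry-based secondary structure.**  A self-contained Kabsch–Sander
  (DSSP-style) assignment — H-bond energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
  E < −0.5 — aggregated over a multi-model ensemble into per-residue class
  propensities and secondary-structure elements (propensity strictly above
  a threshold, default 0.8).
* **Ensemble geometry.**  Kabsch superposition, per-residue Cα RMSF after
  core alignment, the local bend metric d(Cα_{i−4}, Cα_{i+4}) (≈11–13 Å in
  a helix, ≈28 Å in an extended strand; dips in disordered tails reveal
  bends), and Shrake–Rupley backbone accessible surface area with
  Gly-X-Gly-style relative exposure.
* **Chemical-shift-driven model selection.**  Rescoring of candidate
  models by E_CS = E + c·χ², with
  χ² = Σ ((δ_pred − δ_obs)/σ)² over backbone atoms (HN, Hα, N, Cα, Cβ, C′)
  and c = 0.25, followed by the two-stage rule: keep the 20 models with
  lowest E_CS, then the 10 of those with lowest Cα-RMSD to the single
  lowest-E_CS model.  Shift prediction is a pluggable callable.
* **Exchange and NOE dynamics.**  H/D-exchange protection classes from
  last-identifiable timepoints; fast amide–water exchange rates kex fitted
  from water-saturation-transfer intensity pairs at several relaxation
  delays (sensitive for 0.1 s⁻¹ < kex < 10 s⁻¹); heteronuclear NOE ratios
  classified flexible (< 0), intermediate, rigid (> 0.5), with run-length
  region calling.
* **Synthetic data.**  Ideal-geometry peptides with prescribed
  helix/strand/coil segments, rigid-core/mobile-tail ensembles, shift
  tables, saturation-transfer intensities (via the same forward model the
  fitter uses) and score tables — every stage is testable with known
  ground truth, no spectra required.

## Worked example

```python
from hed.synthetic import (SyntheticSpec, build_ideal_peptide,
                           perturb_ensemble, simulate_hetex,
                           simulate_score_table)
from hed.secstruct import ensemble_propensity, define_elements
from hed.ensemble_geom import ca_rmsf
from hed.model_select import select_core_models
from hed.exchange import fit_kex_table

# a 28-residue chain: 6-residue tails around a 16-residue helix
spec = SyntheticSpec(sequence="GSAKTRSSRAGLQFPVGRVHRLLRKGNY",
                     ss_string="CCCCCC" + "H" * 16 + "CCCCCC",
                     core_range=(7, 22), noise_core=0.2, noise_tail=3.0,
                     n_models=10, seed=42)
ens = perturb_ensemble(build_ideal_peptide(spec), spec)

define_elements(ensemble_propensity(ens), threshold=0.8)
#  class chain  start  end
#  helix     A      8   21

rmsf = ca_rmsf(ens, {("A", r) for r in range(7, 23)})
# core mean 0.30 Å, tail mean 4.87 Å — the tails are an order of
# magnitude more mobile than the helix

scores, pool = simulate_score_table(1000, seed=42)
ids, table = select_core_models(scores, pool)
# ids -> ['m0205', 'm0741', 'm0998', ...]: 10 models, all inside the
# 20-lowest-E_CS set; best E_CS here -321.0

fits = fit_kex_table(simulate_hetex([0.5, 2.0, 8.0], r1=1.5, i_eq=1.0,
                                    noise_frac=0.02, seed=7))
#  residue   kex    r1  in_window
#        1 0.509 1.575       True
#        2 2.119 1.574       True
#        3 5.692 1.062       True
# slow/mid rates recover within a few percent at 2% noise; accuracy
# degrades toward the upper edge of the sensitivity window
```

The same stages are scriptable from the shell: `hed synth`, `hed csi`,
`hed ss`, `hed geom`, `hed select`, `hed hx`, `hed kex`, `hed noe`,
`hed io validate` (see `hed --help`).

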