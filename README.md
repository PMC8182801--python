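# thermex

Thermal expansion tensors and population surveys for organic molecular
crystals, from nothing more than variable-temperature unit-cell parameters.

## The problem

Laboratory variable-temperature diffraction makes it easy to measure how a
molecular crystal's unit cell responds to heating, but a single number is
rarely enough: expansion is a symmetric second-rank tensor, and molecular
crystals (mostly monoclinic and triclinic) need the full principal-axis
treatment before values can be compared between structures.  Knowing
whether a newly measured coefficient is *exceptional* further requires
population context — the distribution of coefficients across many
crystals.  `thermex` provides both halves:

- **Per-family analysis.**  For a set of determinations of one crystal
  phase at several temperatures, it fits the volumetric coefficient
  α_V = (1/V)(ΔV/ΔT) by unweighted least squares of V against T
  (heteroscedasticity-consistent standard errors), builds linear Lagrangian
  strain tensors e = ½(F + Fᵀ) − I relative to the lowest-temperature cell
  from the reduced unit-cell parameters, and diagonalises dε/dT to obtain
  the three principal coefficients α_L with uncertainties, the principal
  axes, the anisotropy measure {α_L(max) − α_L(min)}/Σα_L, and a negative
  thermal expansion (NTE) classification.  All coefficients are referenced
  to the cell extrapolated to 298 K and quoted in p.p.m. K⁻¹; for small
  strains α_V ≃ Σα_L.
- **Database curation.**  Given a flat table of structure determinations
  (refcode, cell, temperature, R-factor, flags), it screens entries,
  partitions each refcode family into structure families by similarity of
  Niggli-reduced cells (metric deformation measure, tolerance 0.12 — this
  tolerates alternative space-group settings such as P2₁/c vs P2₁/n),
  deduplicates temperatures (10 K grouping, lowest-R representative;
  unrecorded "room temperature" becomes 293 K), and applies the window
  filters (90–300 K, a representative at ≥273 K, span ≥50 K).
- **Population statistics.**  Histograms (25 p.p.m. K⁻¹ bins), a normal
  fit to the α_V histogram, a skew-normal fit to the pooled α_L histogram
  approximated by two half-normals, 3σ exceptionality thresholds, an R² >
  0.96 linearity screen, and outlier tables that surface extreme expansion,
  suspect apparent-NTE two-point families, and extreme anisotropy.
- **Synthetic database extracts.**  The real survey input is a proprietary
  database, so `thermex.synthetic` generates CSD-like entry tables with
  planted tensors and realistic archive error modes (wrong reported
  temperatures, unflagged high-pressure determinations, phase-transition
  anomalies, duplicate publications, alternative settings), with a parallel
  truth table for validation.

## Worked example

```python
import pandas as pd
from thermex import fit_single_family

cells = pd.DataFrame({
    "a": [10.0, 10.2], "b": [10.0, 10.2], "c": [10.0, 10.2],
    "alpha": [90.0]*2, "beta": [90.0]*2, "gamma": [90.0]*2,
    "temperature_K": [100.0, 300.0],
})
res = fit_single_family(cells)
print(res.alpha_l, res.alpha_v.alpha_v_298)
```

Each axis grows 2% over 200 K, i.e. a strain rate of 1.0×10⁻⁴ K⁻¹ at the
100 K reference; re-referencing to 298 K gives α_L = 10⁻⁴/(1 + 10⁻⁴·198) =
98.06 p.p.m. K⁻¹ per axis, and the volume fit gives α_V = 288.6
p.p.m. K⁻¹, consistent with Σα_L = 294.2 within the small-strain
approximation (1.9%).  Running `python examples/fit_single_family.py`
prints exactly this:

```
isotropic cubic family (2 temperature points)
  alpha_L(298 K) per axis : 98.06 p.p.m./K (x3)
  alpha_V(298 K)          : 288.6 p.p.m./K
  sum of alpha_L          : 294.2 p.p.m./K (matches alpha_V to first order)
```

The other examples survey a 500-family synthetic extract
(`examples/run_synthetic_survey.py`) and classify a hypothetical new
measurement against the surveyed population (`examples/classify_new_measurement.py`);
the `thermex` command line (`thermex survey run`, `thermex survey
fit-family`, `thermex synth generate`) wraps the same calls for shell use.

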