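# rai2ctbp

Quantitative analyses of RAI2-induced CtBP polymerization — from circulating
tumor cell (CTC) marker calling in prostate cancer cohorts to the structural
geometry of the CtBP/RAI2 filament.

## Scientific background

CtBP1/2 are NAD(H)-dependent tetrameric transcriptional corepressors. RAI2
is an intrinsically disordered protein carrying two identical short linear
CtBP-binding motifs (ALDLS) in tandem. The tandem motif lets one RAI2 chain
bridge two CtBP tetramers, polymerizing them into filaments in which
successive tetramer layers are related by a 3₁ screw axis (120° rotation,
5 nm rise), visible in cells as nuclear CtBP/RAI2 foci. Loss of RAI2 in
prostate cancer is associated with progression to treatment-resistant,
neuroendocrine-like disease — measurable as a drop in *RAI2* transcript
detection in CTCs from patient blood.

This package implements the quantitative procedures that support those
observations, each as tested, reusable library code plus seeded synthetic
generators with ground truth:

| Stage | Method |
|---|---|
| `rai2ctbp.ctc` | ΔCq imputation (missing → gene max + 2), censoring (> healthy mean + 1 SD), positivity (ΔCq < healthy mean), AR-or-KRT19 CTC rule, cohort frequency tables, exact Fisher test, ΔΔCT fold change |
| `rai2ctbp.coloc` | line-profile extraction, integer-shift cross-correlation alignment to a reference, mean ± SD profiles, colocalization efficiency |
| `rai2ctbp.foci` | uniform background subtraction, 3D connected components, 0.1 µm³ lower volume cutoff, per-cell counts, unpaired t-test |
| `rai2ctbp.nmr` | CSP `Δδ = sqrt(ΔδH² + (ΔδN/6.5)²)`, titration intensity ratios I/I₀, heteronuclear NOE I_sat/I_unsat |
| `rai2ctbp.filament` | screw operator layer stacking, layer spacings, filament length `(n−1)·rise + thickness`, unique-unit search, PDB export |
| `rai2ctbp.binding` | single-site ITC simulation `[MX] = ((N·Mt + Xt + Kd) − √((N·Mt + Xt + Kd)² − 4·N·Mt·Xt))/2` with perfusion dilution, least-squares parameter recovery, Guinier fit `I(s) = I(0)·e^{−(sRg)²/3}` on `s ≤ 1.3/Rg` |
| `rai2ctbp.synthetic` | seeded generators for all of the above, each emitting machine-readable ground truth |

## Worked example

Recover the binding parameters of the tandem-motif filament interaction
(dissociation constant 1 µM, stoichiometry N = 0.5 RAI2 per CtBP subunit —
two RAI2 peptides bridging each tetramer–tetramer interface):

```python
from rai2ctbp import binding
from rai2ctbp.binding import BindingParams, TitrationScheme

scheme = TitrationScheme(cell_conc=10.0, syringe_conc=50.0,
                         injection_volume=10.0, n_injections=30)
iso = binding.simulate_isotherm(
    BindingParams(kd=1.0, n_stoich=0.5, dh=-10.0), scheme)
fit = binding.fit_isotherm(iso, scheme)
print(f"K_d = {fit.params.kd:.3f} uM, N = {fit.params.n_stoich:.3f}")
```

prints

```
K_d = 1.000 uM, N = 0.500
```

— the fit inverts the same single-site mass-balance model that generated
the heats, so the noise-free round trip is exact. The analysis drivers
under `analysis/` run every stage in sequence:

```bash
python analysis/01_simulate_inputs.py     # seeded synthetic data + ground truth
python analysis/02_ctc_cohorts.py         # cohort frequencies + Fisher tests
python analysis/03_colocalization.py      # profile alignment, 90% efficiency
python analysis/04_foci_quantification.py # foci >= 0.1 um^3, t-test
python analysis/05_nmr_titration.py       # I/I0 ratios, CSPs, hetNOE
python analysis/06_filament_geometry.py   # 120deg/5nm screw, 30 nm filament
python analysis/07_binding_and_scattering.py
```

`02_ctc_cohorts.py`, fed the published per-cohort counts, prints the CTC
detection frequencies 67 / 70 / 91 / 89 % (HSPC / CRPC / AVPC / NEPC) and
the *RAI2* detection rates among CTC-positive samples 89 / 35 / 19 %
(CRPC / AVPC / NEPC); `06_filament_geometry.py` prints constant 5 nm layer
spacings, a 30 nm six-layer filament, and the 3-layer unique unit.

The same stages are available as a CLI (`rai2ctbp simulate|call-ctc|coloc|
foci|csp|filament|itc|run-all|report`); `run-all` executes everything under
one seed and writes a manifest, tables, and a JSON summary.

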