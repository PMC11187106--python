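"""ITC parameter recovery and Guinier analysis.

Simulates single-site titrations at the two reported binding regimes — the
single-ALDLS-motif variant (K_d = 5 µM, N = 1) and the tandem-motif filament
interaction (K_d = 1 µM, N = 0.5) — and recovers the parameters by fitting.
Also fits the Guinier law to scattering data generated from it.  Outputs
under results/binding/.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rai2ctbp import binding
from rai2ctbp.binding import BindingParams, TitrationScheme

OUT = Path("results/binding")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    experiments = {
        "single_motif_variant": (
            BindingParams(kd=5.0, n_stoich=1.0, dh=-10.0),
            TitrationScheme(syringe_conc=100.0),
        ),
        "tandem_wt_filament": (
            BindingParams(kd=1.0, n_stoich=0.5, dh=-10.0),
            TitrationScheme(syringe_conc=50.0),
        ),
    }
    summary = {}
    rows = []
    for name, (params, scheme) in experiments.items():
        iso = binding.simulate_isotherm(params, scheme)
        fit = binding.fit_isotherm(iso, scheme)
        summary[name] = {
            "true": dataclasses.asdict(params),
            "fit": dataclasses.asdict(fit.params),
            "residual_norm": fit.residual_norm,
        }
        for mr, q in zip(iso.molar_ratio, iso.heat):
            rows.append({"experiment": name, "molar_ratio": mr, "heat_ucal": q})
        print(
            f"{name}: recovered K_d = {fit.params.kd:.3f} uM "
            f"(true {params.kd}), N = {fit.params.n_stoich:.3f} "
            f"(true {params.n_stoich})"
        )
    pd.DataFrame(rows).to_csv(OUT / "isotherms.csv", index=False)

    rg_true = 3.0
    s = np.linspace(0.01, 1.0, 120)
    intensity = 100.0 * np.exp(-((s * rg_true) ** 2) / 3.0)
    gfit = binding.guinier_fit(s, intensity)
    summary["guinier"] = dataclasses.asdict(gfit)
    pd.DataFrame({"s_inv_nm": s, "intensity": intensity}).to_csv(
        OUT / "scattering.dat", sep=" ", index=False, header=False
    )
    print(
        f"Guinier: Rg = {gfit.rg:.4f} nm (true {rg_true}), "
        f"I(0) = {gfit.i0:.2f}, window s <= {gfit.s_max_used:.3f}"
    )
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
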