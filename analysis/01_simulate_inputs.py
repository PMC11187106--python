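"""Generate every synthetic input the downstream analyses consume.

Writes qPCR ΔCq cohorts (with ground-truth positivity), two-channel line
profiles, a 3D foci image with its cell mask, and an HSQC titration peak
list under results/data/.  All generators are seeded, so rerunning this
script reproduces the files byte for byte.
"""

from pathlib import Path

import numpy as np
import tifffile

from rai2ctbp import pipeline, synthetic

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = pipeline.RunConfig(seed=SEED)

    healthy = synthetic.HealthyDonorSpec(
        gene_mean={"AR": 8.0, "KRT19": 9.0, "RAI2": 10.0},
        gene_sd={"AR": 0.5, "KRT19": 0.5, "RAI2": 0.5},
    )
    specs = [
        synthetic.CohortSpec(
            name=c["name"],
            n_samples=c["n_samples"],
            gene_positive_fraction={
                "AR": c["ar"], "KRT19": c["krt19"], "RAI2": c["rai2"]
            },
            positive_shift={g: 6.0 for g in ("AR", "KRT19", "RAI2")},
            missing_rate=0.05,
            noise_sd=0.5,
        )
        for c in pipeline.DEFAULT_COHORTS
    ]
    ds = synthetic.gen_qpcr_cohorts(specs, healthy, cfg.child_seed("qpcr"))
    ds.samples.to_csv(OUT / "qpcr.csv", index=False)
    ds.truth.to_csv(OUT / "qpcr_truth.csv", index=False)
    ds.healthy.to_csv(OUT / "healthy_donors.csv", index=False)
    print(f"qPCR: {ds.samples.sample_id.nunique()} samples x 3 genes, "
          f"{int(ds.samples.missing_flag.sum())} missing entries")

    profs = synthetic.gen_line_profiles(
        synthetic.ProfileSpec(coincidence_fraction=0.9), cfg.child_seed("coloc")
    )
    profs.to_frame().to_csv(OUT / "profiles.csv", index=False)
    profs.truth.to_csv(OUT / "profiles_truth.csv", index=False)
    print(f"profiles: {profs.n_profiles} scans, "
          f"{int(profs.truth.coincident.sum())} truly coincident")

    img, truth, mask = synthetic.gen_foci_image(
        synthetic.ImageSpec(), cfg.child_seed("foci")
    )
    tifffile.imwrite(OUT / "foci.tif", img.voxels.astype(np.float32))
    tifffile.imwrite(OUT / "cells.tif", mask.astype(np.uint16))
    truth.to_csv(OUT / "foci_truth.csv", index=False)
    print(f"foci image: {img.voxels.shape} voxels, {len(truth)} foci in "
          f"{truth.cell_id.nunique()} cells")

    series = synthetic.gen_titration_series(
        synthetic.TitrationSpec(), cfg.child_seed("csp")
    )
    series.peaks.to_csv(OUT / "peaks.tsv", sep="\t", index=False)
    print(f"titration: {series.peaks.residue.nunique()} residues x "
          f"{len(series.ratios)} ratios")


if __name__ == "__main__":
    main()
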