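"""Seeded synthetic-data generators with ground truth.

Every generator is a pure function of ``(spec, seed)``: the same inputs give
byte-identical outputs.  Each emits machine-readable ground truth sufficient
to score the downstream analysis stage, so the whole pipeline is testable
without any experimental data.

The defaults emulate the study conditions: prostate-cancer cohorts
HSPC/CRPC/AVPC/NEPC with 10 healthy donors for the ΔCq reference; 100
two-channel line profiles over 3 µm scans; nuclear foci in DAPI-defined cell
masks; HSQC titrations at molar ratios 1:0 / 1:0.4 / 1:0.7 / 1:1 over RAI2
residues 303–362 with the tandem ALDLS sites at 316–320 and 342–346; and a
9.5 × 9.5 × 5 nm tetramer layer as the filament building block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "HealthyDonorSpec",
    "ProfileSpec",
    "ImageSpec",
    "TitrationSpec",
    "LayerSpec",
    "QPCRDataset",
    "ProfileSet",
    "VolumetricImage",
    "TitrationSeries",
    "LayerModel",
    "gen_qpcr_cohorts",
    "gen_line_profiles",
    "gen_foci_image",
    "gen_titration_series",
    "gen_layer_model",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one patient cohort of qPCR ΔCq measurements."""

    name: str
    n_samples: int
    gene_positive_fraction: Mapping[str, float]
    positive_shift: Mapping[str, float]
    missing_rate: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for g, f in self.gene_positive_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"positive fraction for {g} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class HealthyDonorSpec:
    """Healthy-donor reference cohort (default 10 donors)."""

    gene_mean: Mapping[str, float]
    gene_sd: Mapping[str, float]
    n_donors: int = 10

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2 (SD must be computable)")
        for g, s in self.gene_sd.items():
            if s < 0:
                raise ValueError(f"gene_sd for {g} must be >= 0")


@dataclass(frozen=True)
class ProfileSpec:
    """Two-channel line-intensity profile set (default: 100 foci, 3 µm)."""

    n_profiles: int = 100
    length: float = 3.0  # µm
    step: float = 0.03  # µm per sample -> ~100 samples over 3 µm
    peak_sigma: float = 0.15  # µm
    coincidence_fraction: float = 1.0
    peak_amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    jitter_sd: float = 0.15  # µm, channel-A peak position scatter

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.length / self.step < 8:
            raise ValueError("profile must span at least 8 samples")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        if not 0.0 <= self.coincidence_fraction <= 1.0:
            raise ValueError("coincidence_fraction outside [0, 1]")


@dataclass(frozen=True)
class ImageSpec:
    """3D two-channel image of nuclear foci inside disjoint cell masks."""

    shape: tuple[int, int, int] = (20, 128, 128)  # z, y, x voxels
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)  # µm per axis
    n_cells: int = 4
    # fixed count per cell, or ("poisson", mean) for per-cell variation
    foci_per_cell: int | tuple[str, float] = 5
    focus_radius: float | tuple[float, float] = 0.4  # µm; scalar or (lo, hi)
    amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be > 0 on each axis")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be >= 1 on each axis")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class TitrationSpec:
    """HSQC titration of CtBP onto a ¹⁵N-labelled disordered fragment.

    Intensity attenuation at the final titration point reaches
    ``site_attenuation`` at binding-site centers and decays back to 1 with
    distance (Gaussian, ``attenuation_halfwidth`` residues), giving the
    bilobal pattern seen with two tandem sites.
    """

    residues: Sequence[int] = tuple(range(303, 363))
    ratios: Sequence[float] = (0.0, 0.4, 0.7, 1.0)
    binding_sites: Sequence[tuple[int, int]] = ((316, 320), (342, 346))
    site_attenuation: float = 0.1
    attenuation_halfwidth: float = 4.0
    csp_scale: float = 0.1  # ppm, max CSP at site centers at final ratio
    noise_sd: float = 0.0  # intensity noise

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError("residues must be non-empty")
        r = np.asarray(self.ratios, dtype=float)
        if r[0] != 0.0 or np.any(np.diff(r) <= 0):
            raise ValueError("ratios must be strictly increasing from 0")
        lo, hi = min(self.residues), max(self.residues)
        for a, b in self.binding_sites:
            if a > b or a < lo or b > hi:
                raise ValueError(f"binding site ({a}, {b}) outside residue range")
        if not 0.0 <= self.site_attenuation <= 1.0:
            raise ValueError("site_attenuation outside [0, 1]")


@dataclass(frozen=True)
class LayerSpec:
    """Point-cloud template of one tetramer layer (9.5 × 9.5 × 5 nm)."""

    n_points: int = 64
    lateral_extent: float = 9.5  # nm
    thickness: float = 5.0  # nm
    shape: str = "box"

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if self.lateral_extent <= 0 or self.thickness <= 0:
            raise ValueError("extents must be > 0")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class QPCRDataset:
    """Tidy per-sample, per-gene ΔCq table with ground truth.

    ``samples`` columns: sample_id, cohort, gene, dcq, missing_flag,
    imputed_flag, censored_flag.  Missing values carry ``dcq = NaN`` and
    ``missing_flag = True`` — never a sentinel number, so imputation is
    observable.  ``truth`` columns: sample_id, cohort, gene, true_positive.
    ``healthy`` columns: donor_id, gene, dcq.
    """

    samples: pd.DataFrame
    truth: pd.DataFrame
    healthy: pd.DataFrame


@dataclass
class ProfileSet:
    """Two-channel line profiles on a common uniform grid.

    ``channel_a``/``channel_b`` have shape (n_profiles, n_samples);
    ``truth`` columns: profile, coincident, a_peak_um (true channel-A peak
    position, µm).
    """

    positions: np.ndarray  # µm
    channel_a: np.ndarray
    channel_b: np.ndarray
    truth: pd.DataFrame

    @property
    def n_profiles(self) -> int:
        return self.channel_a.shape[0]

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV layout: position_um, then A/B columns per profile."""
        cols = {"position_um": self.positions}
        for i in range(self.n_profiles):
            cols[f"A{i:03d}"] = self.channel_a[i]
            cols[f"B{i:03d}"] = self.channel_b[i]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProfileSet":
        a_cols = [c for c in frame.columns if c.startswith("A")]
        b_cols = [c for c in frame.columns if c.startswith("B")]
        truth = pd.DataFrame(
            {"profile": range(len(a_cols)), "coincident": pd.NA, "a_peak_um": np.nan}
        )
        return cls(
            positions=frame["position_um"].to_numpy(float),
            channel_a=frame[a_cols].to_numpy(float).T,
            channel_b=frame[b_cols].to_numpy(float).T,
            truth=truth,
        )


@dataclass
class VolumetricImage:
    """Voxel grid (channels, z, y, x) with physical voxel size in µm."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class TitrationSeries:
    """Per-residue HSQC peaks across titration ratios.

    ``peaks`` columns: residue, ratio, dH_ppm, dN_ppm, intensity.
    ``truth`` columns: residue, attenuation (intensity ratio at the final
    titration point), in_site.
    """

    peaks: pd.DataFrame
    truth: pd.DataFrame
    ratios: tuple[float, ...]


@dataclass
class LayerModel:
    """One tetramer layer as a point cloud (nm), centered on the origin."""

    points: np.ndarray  # (n, 3) in nm, columns x, y, z
    thickness: float
    label: int = 0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_qpcr_cohorts(
    specs: Sequence[CohortSpec],
    healthy: HealthyDonorSpec,
    seed: int,
) -> QPCRDataset:
    """Generate a per-sample × per-gene ΔCq dataset with ground truth.

    Positive samples draw ``ΔCq = healthy mean − positive_shift + noise``;
    negatives sit at the healthy mean plus noise.  A ``missing_rate`` subset
    of entries is flagged missing (ΔCq = NaN).  Lower ΔCq means higher
    transcript abundance, so a positive shift moves positives below the
    healthy reference.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    genes = list(healthy.gene_mean)
    for spec in specs:
        for g in spec.positive_shift:
            if g not in healthy.gene_mean:
                raise ValueError(
                    f"gene {g!r} in positive_shift has no healthy reference"
                )
    rng = np.random.default_rng(seed)

    donor_rows = []
    for d in range(healthy.n_donors):
        for g in genes:
            donor_rows.append(
                {
                    "donor_id": f"HD{d:02d}",
                    "gene": g,
                    "dcq": healthy.gene_mean[g]
                    + rng.normal(0.0, healthy.gene_sd.get(g, 0.0)),
                }
            )

    sample_rows = []
    truth_rows = []
    for spec in specs:
        for i in range(spec.n_samples):
            sid = f"{spec.name}-{i:03d}"
            for g in genes:
                frac = spec.gene_positive_fraction.get(g, 0.0)
                positive = bool(rng.random() < frac)
                shift = spec.positive_shift.get(g, 0.0) if positive else 0.0
                dcq = healthy.gene_mean[g] - shift + rng.normal(0.0, spec.noise_sd)
                missing = bool(rng.random() < spec.missing_rate)
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "cohort": spec.name,
                        "gene": g,
                        "dcq": np.nan if missing else dcq,
                        "missing_flag": missing,
                        "imputed_flag": False,
                        "censored_flag": False,
                    }
                )
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "cohort": spec.name,
                        "gene": g,
                        "true_positive": positive,
                    }
                )

    return QPCRDataset(
        samples=pd.DataFrame(sample_rows),
        truth=pd.DataFrame(truth_rows),
        healthy=pd.DataFrame(donor_rows),
    )


def gen_line_profiles(spec: ProfileSpec, seed: int) -> ProfileSet:
    """Generate two-channel line profiles with known coincidence labels.

    Each profile carries a channel-A Gaussian focus near the scan center
    (position jittered across profiles).  A ``coincidence_fraction``-sized
    subset additionally carries a channel-B peak at the same position; the
    remaining profiles show channel-B background + noise only.  The number of
    coincident profiles is ``round(fraction · n)`` so constructed sets hit
    the target fraction exactly at high SNR.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(np.floor(spec.length / spec.step)) + 1
    positions = np.arange(n_samples) * spec.step
    center = spec.length / 2.0

    n_coinc = int(round(spec.coincidence_fraction * spec.n_profiles))
    coincident = np.zeros(spec.n_profiles, dtype=bool)
    coincident[rng.choice(spec.n_profiles, size=n_coinc, replace=False)] = True

    a = np.empty((spec.n_profiles, n_samples))
    b = np.empty((spec.n_profiles, n_samples))
    peak_pos = np.empty(spec.n_profiles)
    for i in range(spec.n_profiles):
        x0 = center + rng.normal(0.0, spec.jitter_sd)
        x0 = float(np.clip(x0, positions[0], positions[-1]))
        peak_pos[i] = x0
        shape = np.exp(-((positions - x0) ** 2) / (2.0 * spec.peak_sigma**2))
        a[i] = (
            spec.background
            + spec.peak_amplitude * shape
            + rng.normal(0.0, spec.noise_sd, n_samples)
        )
        b_peak = spec.peak_amplitude * shape if coincident[i] else 0.0
        b[i] = spec.background + b_peak + rng.normal(0.0, spec.noise_sd, n_samples)

    truth = pd.DataFrame(
        {
            "profile": np.arange(spec.n_profiles),
            "coincident": coincident,
            "a_peak_um": peak_pos,
        }
    )
    return ProfileSet(positions=positions, channel_a=a, channel_b=b, truth=truth)


def _rasterize_sphere(
    grid: np.ndarray,
    center_um: np.ndarray,
    radius_um: float,
    voxel_size: np.ndarray,
    value: float,
) -> int:
    """Add ``value`` to voxels whose centers fall inside the sphere.

    Returns the number of voxels set (partial-volume effects at the boundary
    are accepted; rasterization is by voxel-center-inside test).
    """
    lo = np.maximum(
        np.floor((center_um - radius_um) / voxel_size - 0.5).astype(int), 0
    )
    hi = np.minimum(
        np.ceil((center_um + radius_um) / voxel_size + 0.5).astype(int),
        np.asarray(grid.shape),
    )
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij"
    )
    centers = (np.stack([zz, yy, xx], axis=-1) + 0.5) * voxel_size
    inside = np.sum((centers - center_um) ** 2, axis=-1) <= radius_um**2
    grid[zz[inside], yy[inside], xx[inside]] += value
    return int(inside.sum())


def gen_foci_image(
    spec: ImageSpec, seed: int, max_retries: int = 200
) -> tuple[VolumetricImage, pd.DataFrame, np.ndarray]:
    """Generate a 3D foci image, ground-truth focus table, and cell-label mask.

    Cells are disjoint rectangular regions tiling the xy plane (stand-ins for
    DAPI-segmented nuclei).  Foci are hard spheres placed without overlap
    inside their cell — with a two-voxel clearance between surfaces so that
    rasterized spheres stay resolvable as separate connected components —
    and rasterized by the voxel-center-inside test.  The
    ground-truth table lists each focus's cell, centroid (µm), radius and
    analytic volume (4/3)πr³.

    Raises ``RuntimeError`` if a focus cannot be placed without overlap
    within ``max_retries`` attempts.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    vs = np.asarray(spec.voxel_size, dtype=float)

    # tile cells along x (disjoint masks, one strip per cell)
    if nx < spec.n_cells:
        raise ValueError("shape too small to hold n_cells disjoint masks")
    mask = np.zeros(spec.shape, dtype=np.uint16)
    bounds = np.linspace(0, nx, spec.n_cells + 1).astype(int)
    for c in range(spec.n_cells):
        mask[:, :, bounds[c] : bounds[c + 1]] = c + 1

    img = np.full(spec.shape, float(spec.background))
    clearance = 2.0 * float(vs.max())
    truth_rows = []
    for c in range(spec.n_cells):
        placed: list[tuple[np.ndarray, float]] = []
        if isinstance(spec.foci_per_cell, tuple):
            kind, mean = spec.foci_per_cell
            if kind != "poisson":
                raise ValueError(f"unknown foci_per_cell distribution {kind!r}")
            n_foci = int(rng.poisson(mean))
        else:
            n_foci = int(spec.foci_per_cell)
        for _ in range(n_foci):
            if isinstance(spec.focus_radius, tuple):
                r = float(rng.uniform(*spec.focus_radius))
            else:
                r = float(spec.focus_radius)
            x_lo, x_hi = bounds[c] * vs[2], bounds[c + 1] * vs[2]
            extent = np.array([nz * vs[0], ny * vs[1], x_hi])
            low = np.array([r, r, x_lo + r])
            high = extent - r
            if np.any(high <= low):
                raise RuntimeError("cell region too small for focus radius")
            for _attempt in range(max_retries + 1):
                center = rng.uniform(low, high)
                if all(
                    np.linalg.norm(center - c0) > r + r0 + clearance
                    for c0, r0 in placed
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place focus without overlap in cell {c + 1} "
                    f"after {max_retries} retries"
                )
            placed.append((center, r))
            _rasterize_sphere(img, center, r, vs, spec.amplitude)
            truth_rows.append(
                {
                    "cell_id": c + 1,
                    "z_um": center[0],
                    "y_um": center[1],
                    "x_um": center[2],
                    "radius_um": r,
                    "volume_um3": 4.0 / 3.0 * np.pi * r**3,
                }
            )

    img += rng.normal(0.0, spec.noise_sd, spec.shape)
    truth = pd.DataFrame(
        truth_rows,
        columns=["cell_id", "z_um", "y_um", "x_um", "radius_um", "volume_um3"],
    )
    return VolumetricImage(voxels=img, voxel_size=tuple(vs)), truth, mask


def gen_titration_series(spec: TitrationSpec, seed: int) -> TitrationSeries:
    """Generate per-residue HSQC peaks across titration ratios.

    Random-coil-like baseline shifts (δH ≈ 8.3 ppm, δN ≈ 118 ppm) are drawn
    once per residue; intensities at ratio 0 are normalized to 1.  At the
    final ratio, residues at binding-site centers attenuate to
    ``site_attenuation``, recovering to 1 with a Gaussian profile of width
    ``attenuation_halfwidth``; intermediate ratios interpolate linearly.
    CSPs grow with the same profile up to ``csp_scale`` ppm (placed on δH).
    """
    rng = np.random.default_rng(seed)
    residues = np.asarray(spec.residues, dtype=int)
    ratios = np.asarray(spec.ratios, dtype=float)

    dh0 = 8.3 + rng.normal(0.0, 0.25, residues.size)
    dn0 = 118.0 + rng.normal(0.0, 3.0, residues.size)

    # binding weight in [0, 1]: 1 at site centers, ->0 far from any site
    weight = np.zeros(residues.size)
    for a, b in spec.binding_sites:
        c = 0.5 * (a + b)
        weight = np.maximum(
            weight,
            np.exp(-((residues - c) ** 2) / (2.0 * spec.attenuation_halfwidth**2)),
        )

    rows = []
    rmax = ratios[-1]
    for j, ratio in enumerate(ratios):
        frac = ratio / rmax if rmax > 0 else 0.0
        atten = 1.0 - (1.0 - spec.site_attenuation) * weight * frac
        intensity = atten + (
            rng.normal(0.0, spec.noise_sd, residues.size) if j > 0 else 0.0
        )
        dh = dh0 + spec.csp_scale * weight * frac
        for k, res in enumerate(residues):
            rows.append(
                {
                    "residue": int(res),
                    "ratio": float(ratio),
                    "dH_ppm": dh[k],
                    "dN_ppm": dn0[k],
                    "intensity": float(intensity[k]),
                }
            )

    in_site = np.zeros(residues.size, dtype=bool)
    for a, b in spec.binding_sites:
        in_site |= (residues >= a) & (residues <= b)
    truth = pd.DataFrame(
        {
            "residue": residues,
            "attenuation": 1.0 - (1.0 - spec.site_attenuation) * weight,
            "in_site": in_site,
        }
    )
    return TitrationSeries(
        peaks=pd.DataFrame(rows), truth=truth, ratios=tuple(ratios)
    )


def _halton(n: int, base: int) -> np.ndarray:
    """First n points of the van der Corput sequence in the given base."""
    out = np.empty(n)
    for i in range(n):
        f, r, x = 1.0, 0.0, i + 1
        while x > 0:
            f /= base
            r += f * (x % base)
            x //= base
        out[i] = r
    return out


def gen_layer_model(spec: LayerSpec) -> LayerModel:
    """Deterministic tetramer-layer point cloud, centered on the origin.

    The first points are box corners (so the bounding box is exactly
    lateral_extent × lateral_extent × thickness); the rest follow a Halton
    sequence inside the box.  The cloud is deliberately not 3-fold symmetric
    about the stacking (z) axis, so screw rotations are detectable.
    """
    n = spec.n_points
    a = spec.lateral_extent / 2.0
    t = spec.thickness / 2.0
    # corner order chosen so any prefix >= 2 spans the full bounding box
    corners = np.array(
        [
            [-a, -a, -t],
            [a, a, t],
            [a, -a, -t],
            [-a, a, t],
            [-a, -a, t],
            [a, a, -t],
            [a, -a, t],
            [-a, a, -t],
        ]
    )
    pts = [corners[: min(n, 8)]]
    if n > 8:
        m = n - 8
        u = np.column_stack([_halton(m, 2), _halton(m, 3), _halton(m, 5)])
        interior = (u - 0.5) * np.array([2 * a, 2 * a, 2 * t]) * 0.9
        # skew the interior cloud so no accidental rotational symmetry survives
        interior[:, 0] += 0.05 * a * np.sin(np.arange(m))
        pts.append(interior)
    points = np.vstack(pts)
    return LayerModel(points=points, thickness=spec.thickness, label=0)
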