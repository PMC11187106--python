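"""Screw-axis filament geometry.

A RAI2-mediated CtBP filament stacks tetramer layers under a screw operator:
each successive layer is the previous one rotated by ``angle`` degrees about
the filament axis and translated by ``rise`` nm along it.  The defaults
(120°, 5 nm) give the 3₁ screw of the study's fiber: a 3-layer unique unit
and, for six layers of 5 nm thickness, a 6 × 5 nm = 30 nm filament.
Positive angle means a right-handed screw about +axis; handedness is a
parameter because a flipped assignment is the mirrored operator (−angle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .synthetic import LayerModel

__all__ = [
    "ScrewOperator",
    "FilamentModel",
    "apply_screw",
    "layer_spacings",
    "filament_length",
    "unique_unit",
    "write_filament",
    "read_filament",
]


@dataclass(frozen=True)
class ScrewOperator:
    angle: float = 120.0  # degrees per step
    rise: float = 5.0  # nm per step
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be > 0")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be nonzero")
        object.__setattr__(self, "axis", tuple(a / n))

    def matrix(self, k: int = 1) -> np.ndarray:
        """Rotation matrix of k applications."""
        return Rotation.from_rotvec(
            np.deg2rad(k * self.angle) * np.asarray(self.axis)
        ).as_matrix()


@dataclass
class FilamentModel:
    layers: list[LayerModel]
    operator: ScrewOperator

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def apply_screw(
    layer: LayerModel, op: ScrewOperator, n_layers: int
) -> FilamentModel:
    """Stack ``n_layers`` copies of ``layer`` under the screw operator.

    Layer k is R(k·angle)·points + k·rise·axis, so composition is exact:
    applying the operator twice equals one application of (2·angle, 2·rise).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    axis = np.asarray(op.axis)
    layers = []
    for k in range(n_layers):
        pts = layer.points @ op.matrix(k).T + k * op.rise * axis
        layers.append(LayerModel(points=pts, thickness=layer.thickness, label=k))
    return FilamentModel(layers=layers, operator=op)


def layer_spacings(filament: FilamentModel) -> np.ndarray:
    """Axial distances between successive layer centroids (nm).

    For a screw-generated filament these all equal the rise — the repeating
    5 nm layer interval of the fiber.
    """
    if filament.n_layers < 2:
        return np.array([])
    axis = np.asarray(filament.operator.axis)
    centroids = np.array([l.points.mean(axis=0) for l in filament.layers])
    return np.diff(centroids @ axis)


def filament_length(filament: FilamentModel) -> float:
    """Material axial extent: (n_layers − 1)·rise + layer thickness.

    Equals n·rise when thickness matches the rise (six 5-nm layers → 30 nm).
    """
    if filament.n_layers < 1:
        raise ValueError("empty filament")
    return float(
        (filament.n_layers - 1) * filament.operator.rise
        + filament.layers[0].thickness
    )


def unique_unit(op: ScrewOperator, tol: float = 1e-6, k_max: int = 1000):
    """Smallest k ≥ 1 with k·angle ≡ 0 (mod 360°) within tol, else "aperiodic".

    120° gives 3 (the three-layer unique unit of the 3₁ filament).
    """
    for k in range(1, k_max + 1):
        r = (k * op.angle) % 360.0
        if min(r, 360.0 - r) <= tol:
            return k
    return "aperiodic"


def write_filament(filament: FilamentModel, path) -> None:
    """Write the filament as a pseudo-atom PDB, one chain per layer.

    Coordinates are Å (nm × 10); chain identifiers increase with layer
    index.  PDB fixed-width precision limits round-trips to ~1e-3 Å.
    """
    if filament.n_layers == 0:
        raise ValueError("empty filament")
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    if filament.n_layers > len(chain_ids):
        raise ValueError("too many layers for distinct chain identifiers")
    st = gemmi.Structure()
    st.name = "filament"
    model = gemmi.Model("1")
    for k, layer in enumerate(filament.layers):
        chain = gemmi.Chain(chain_ids[k])
        for j, (x, y, z) in enumerate(layer.points):
            res = gemmi.Residue()
            res.name = "DUM"
            res.seqid = gemmi.SeqId(j + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(10.0 * x, 10.0 * y, 10.0 * z)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_filament(path, operator: ScrewOperator | None = None) -> FilamentModel:
    """Read a pseudo-atom PDB written by :func:`write_filament` (nm units)."""
    st = gemmi.read_structure(str(path))
    layers = []
    for k, chain in enumerate(st[0]):
        pts = np.array(
            [[a.pos.x, a.pos.y, a.pos.z] for res in chain for a in res]
        ) / 10.0
        layers.append(LayerModel(points=pts, thickness=np.nan, label=k))
    return FilamentModel(
        layers=layers, operator=operator or ScrewOperator()
    )
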