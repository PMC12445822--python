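"""Structure-based region measurements on PDB frames.

Three measurements support the structural side of the meta-analysis:

* funnel lysine counts — how many lysines (FK) and acetylated lysines (FKac)
  of a superoxide-dismutase sequence fall inside the named "funnel" region
  that steers superoxide toward the catalytic centre;
* cavity volume — free volume inside a fixed-radius sphere over a catalytic
  site, computed by counting axis-aligned grid points not occluded by any
  protein atom (a grid/sphere scheme in the style of pocket-volume tools);
* minimum residue distance — closest atom-atom approach between two residue
  sets.

Multi-model PDB files are treated as trajectories: one :class:`StructureFrame`
per MODEL record.  Producing the frames (the molecular-dynamics engine,
solvation, thermostats) is out of scope; this module only measures them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

__all__ = [
    "ATOMIC_RADII",
    "StructureFrame",
    "RegionDefinition",
    "CavityProbe",
    "VolumeSeries",
    "read_structure",
    "funnel_lysine_counts",
    "cavity_volume",
    "min_residue_distance",
    "volume_trajectory",
]

#: Fixed per-element radii (Angstrom) used for grid occlusion.
ATOMIC_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
_DEFAULT_RADIUS = 1.70


@dataclass
class StructureFrame:
    """Atoms of one model: coordinates plus residue/atom metadata."""

    residue_numbers: np.ndarray  # (n,) int, author numbering
    residue_names: list[str]
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n, 3) float, Angstrom
    frame_index: int = 0
    chain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_radii(self, probe_radius: float = 0.0) -> np.ndarray:
        return np.array(
            [ATOMIC_RADII.get(e.upper(), _DEFAULT_RADIUS) + probe_radius
             for e in self.elements]
        )

    def residue_mask(self, residue_numbers: Iterable[int]) -> np.ndarray:
        wanted = set(int(r) for r in residue_numbers)
        present = set(self.residue_numbers.tolist())
        missing = wanted - present
        if missing:
            raise KeyError(f"residues not in frame: {sorted(missing)}")
        return np.isin(self.residue_numbers, list(wanted))

    def residue_centroid(self, residue_numbers: Iterable[int]) -> np.ndarray:
        return self.coords[self.residue_mask(residue_numbers)].mean(axis=0)

    def translated(self, offset: Sequence[float]) -> "StructureFrame":
        return StructureFrame(
            self.residue_numbers.copy(), list(self.residue_names),
            list(self.atom_names), list(self.elements),
            self.coords + np.asarray(offset, dtype=float),
            self.frame_index, list(self.chain_ids))


@dataclass(frozen=True)
class RegionDefinition:
    """Named inclusive 1-based residue ranges (e.g. the SODA funnel)."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for start, end in self.ranges:
            if start < 1 or end < start:
                raise ValueError(f"invalid range ({start}, {end})")

    def __contains__(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.ranges)


@dataclass(frozen=True)
class CavityProbe:
    """Sphere + grid parameters for cavity volume measurement."""

    center: tuple[float, float, float]
    radius: float = 8.0
    grid_spacing: float = 0.5
    probe_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0 < self.grid_spacing <= self.radius):
            raise ValueError("grid_spacing must lie in (0, radius]")


@dataclass(frozen=True)
class VolumeSeries:
    """Per-frame cavity volumes with mean and population SD."""

    volumes: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.volumes))

    @property
    def sd(self) -> float:
        return float(np.std(self.volumes))  # population SD


def read_structure(path: str | Path) -> list[StructureFrame]:
    """Read a (multi-model) PDB file into one frame per MODEL.

    Only ATOM records are kept (waters and other HETATM entries are not part
    of the protein); a file without any is an error.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("frame", str(path))
    frames: list[StructureFrame] = []
    for model in structure:
        resnum, resnames, atnames, elements, coords, chains = [], [], [], [], [], []
        for chain in model:
            for residue in chain:
                hetfield = residue.id[0]
                if hetfield != " ":
                    continue  # HETATM / water
                for atom in residue:
                    resnum.append(residue.id[1])
                    resnames.append(residue.resname.strip())
                    atnames.append(atom.get_name())
                    elements.append((atom.element or "C").strip() or "C")
                    coords.append(atom.coord)
                    chains.append(chain.id)
        if resnum:
            frames.append(StructureFrame(
                np.array(resnum), resnames, atnames, elements,
                np.array(coords, dtype=float), frame_index=len(frames),
                chain_ids=chains))
    if not frames:
        raise ValueError(f"no ATOM records found in {path}")
    return frames


def funnel_lysine_counts(
    sequence: str,
    region: RegionDefinition,
    kac_positions: Iterable[int],
) -> tuple[int, int]:
    """(FK, FKac): lysines, and acetylated lysines, inside a sequence region."""
    sequence = sequence.upper()
    kac = set(int(p) for p in kac_positions)
    out_of_range = [p for p in kac if not (1 <= p <= len(sequence))]
    if out_of_range:
        raise ValueError(f"Kac positions outside sequence: {sorted(out_of_range)}")
    fk = sum(1 for i, aa in enumerate(sequence, start=1)
             if aa == "K" and i in region)
    fkac = sum(1 for p in kac if sequence[p - 1] == "K" and p in region)
    return fk, fkac


def cavity_volume(frame: StructureFrame | None, probe: CavityProbe) -> float:
    """Free volume (Angstrom^3) inside the probe sphere.

    An axis-aligned grid at ``grid_spacing`` is centred on the probe centre;
    grid points inside the sphere and farther than ``r_atom + probe_radius``
    from every atom each contribute ``spacing**3``.
    """
    center = np.asarray(probe.center, dtype=float)
    spacing = probe.grid_spacing
    n = int(math.floor(probe.radius / spacing))
    axis = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    points = points[np.linalg.norm(points, axis=1) <= probe.radius] + center

    if frame is not None and frame.n_atoms:
        radii = frame.atom_radii(probe.probe_radius)
        # atoms too far from the sphere cannot occlude any grid point
        reach = probe.radius + radii
        near = np.linalg.norm(frame.coords - center, axis=1) <= reach
        if near.any():
            d = cdist(points, frame.coords[near])
            free = np.all(d > radii[near], axis=1)
            points = points[free]
    return float(len(points)) * spacing**3


def min_residue_distance(
    frame: StructureFrame,
    residues_a: Iterable[int],
    residues_b: Iterable[int],
) -> float:
    """Minimum atom-atom Euclidean distance between two residue sets."""
    mask_a = frame.residue_mask(residues_a)
    mask_b = frame.residue_mask(residues_b)
    return float(cdist(frame.coords[mask_a], frame.coords[mask_b]).min())


def volume_trajectory(
    frames: Sequence[StructureFrame],
    probe: CavityProbe,
) -> VolumeSeries:
    """Cavity volume per frame, with mean and population SD over the series."""
    if not frames:
        raise ValueError("no frames")
    return VolumeSeries(tuple(cavity_volume(f, probe) for f in frames))
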