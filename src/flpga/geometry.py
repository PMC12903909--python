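"""3D structures of the H2-activated catalyst and steric descriptors.

Candidates are embedded from their Int2 SMILES with RDKit distance
geometry (ETKDG, seeded) and refined by a pluggable optimizer backend;
from the optimized structure we extract the B-N distance ``d``, the
orientation angle ``Phi`` between the open coordination sites, and
buried-volume fractions around the Lewis centers.

Phi convention: in Int2 the acid's empty p orbital holds the hydride and
the base's lone pair holds the proton, so the site directions are taken
as the B->H(hydride) and N->H(proton) bond vectors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

#: Bondi van-der-Waals radii (Angstrom); frozen descriptor constants.
VDW_RADII = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
VDW_DEFAULT = 1.70

BURIED_VOLUME_RADII = (2.0, 2.5, 3.0, 3.5)  # Angstrom


class GeometryError(ValueError):
    pass


class EmbeddingError(GeometryError):
    """Distance-geometry embedding failed; candidate-level, run continues."""


@dataclass
class Structure3D:
    """Cartesian structure with the designated Lewis-pair atom indices."""

    symbols: list[str]
    coords: np.ndarray  # (n, 3), Angstrom
    energy: float | None = None  # backend units (hartree for semiempirical)
    b_index: int | None = None
    n_index: int | None = None
    hydride_index: int | None = None
    proton_index: int | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.symbols), 3):
            raise GeometryError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        for idx, el in ((self.b_index, "B"), (self.n_index, "N"),
                        (self.hydride_index, "H"), (self.proton_index, "H")):
            if idx is not None:
                if not 0 <= idx < len(self.symbols):
                    raise GeometryError(f"designated index {idx} out of range")
                if self.symbols[idx] != el:
                    raise GeometryError(
                        f"designated atom {idx} is {self.symbols[idx]}, expected {el}")


class OptimizerBackend(Protocol):
    """Contract for geometry refinement engines."""

    def optimize(self, structure: Structure3D) -> tuple[Structure3D, float]:
        """Return (refined structure, total energy)."""
        ...


class IdentityBackend:
    """No-op optimizer; energy is a deterministic hash of the structure.

    Lets the full pipeline run (and be reproducible) without any external
    quantum-chemistry program.
    """

    def optimize(self, structure: Structure3D) -> tuple[Structure3D, float]:
        key = ",".join(structure.symbols).encode()
        key += np.round(structure.coords, 3).tobytes()
        energy = -(zlib.crc32(key) % 10**6) / 10**4  # pseudo-energy, reproducible
        return replace(structure, energy=energy), energy


def _designated_indices(mol: Chem.Mol) -> tuple[int, int, int, int]:
    b_idx = n_idx = None
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 5 and atom.GetFormalCharge() == -1:
            b_idx = atom.GetIdx()
        if atom.GetAtomicNum() == 7 and atom.GetFormalCharge() == 1:
            n_idx = atom.GetIdx()
    if b_idx is None or n_idx is None:
        raise GeometryError("Int2 must carry [B-] and [N+] centers")

    def first_h(idx: int) -> int:
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetAtomicNum() == 1:
                return nb.GetIdx()
        raise GeometryError(f"designated atom {idx} bears no hydrogen")

    return b_idx, n_idx, first_h(b_idx), first_h(n_idx)


def embed_and_optimize(smiles_int2: str, backend: OptimizerBackend,
                       seed: int, max_attempts: int = 5) -> Structure3D:
    """Embed Int2 with seeded distance geometry and refine with the backend.

    Embedding is retried with ``seed, seed+1, ...`` up to ``max_attempts``
    times; exhaustion raises :class:`EmbeddingError` (candidate-level
    failure, the caller assigns worst fitness and continues).
    """
    mol = Chem.MolFromSmiles(smiles_int2)
    if mol is None:
        raise GeometryError(f"unparsable SMILES {smiles_int2!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    conf_id = -1
    for attempt in range(max_attempts):
        params.randomSeed = int(seed) + attempt
        conf_id = AllChem.EmbedMolecule(mol, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(
            f"distance-geometry embedding failed after {max_attempts} attempts")
    conf = mol.GetConformer(conf_id)
    coords = np.array([[*conf.GetAtomPosition(i)] for i in range(mol.GetNumAtoms())])
    b_idx, n_idx, h_idx, p_idx = _designated_indices(mol)
    structure = Structure3D(
        symbols=[a.GetSymbol() for a in mol.GetAtoms()], coords=coords,
        b_index=b_idx, n_index=n_idx, hydride_index=h_idx, proton_index=p_idx)
    refined, energy = backend.optimize(structure)
    refined.energy = energy
    return refined


@dataclass(frozen=True)
class GeometricDescriptors:
    d: float    # Angstrom
    phi: float  # degrees, [0, 180]


def compute_d_phi(s: Structure3D) -> GeometricDescriptors:
    """B-N distance and the angle between the B->hydride and N->proton vectors."""
    if None in (s.b_index, s.n_index, s.hydride_index, s.proton_index):
        raise GeometryError("designated atom indices not set")
    b, n = s.coords[s.b_index], s.coords[s.n_index]
    v_b = s.coords[s.hydride_index] - b
    v_n = s.coords[s.proton_index] - n
    nb, nn = np.linalg.norm(v_b), np.linalg.norm(v_n)
    if nb < 1e-8 or nn < 1e-8:
        raise GeometryError("degenerate geometry: zero-length site direction vector")
    cosang = np.clip(np.dot(v_b, v_n) / (nb * nn), -1.0, 1.0)
    return GeometricDescriptors(d=float(np.linalg.norm(b - n)),
                                phi=float(np.degrees(np.arccos(cosang))))


def _occupancy_fraction(points: np.ndarray, s: Structure3D, center: int,
                        radius: float) -> float:
    """Fraction of probe-sphere sample points inside any neighbor vdW sphere."""
    c = s.coords[center]
    occupied = np.zeros(len(points), dtype=bool)
    for i, (sym, pos) in enumerate(zip(s.symbols, s.coords)):
        if i == center:
            continue
        rv = VDW_RADII.get(sym, VDW_DEFAULT)
        if np.linalg.norm(pos - c) > radius + rv:
            continue  # cannot intersect the probe sphere
        occupied |= np.einsum("ij,ij->i", points - pos, points - pos) <= rv * rv
        if occupied.all():
            break
    return float(occupied.mean()) if len(points) else 0.0


def buried_volume(s: Structure3D, center: int, radius: float,
                  method: str = "grid", spacing: float = 0.1,
                  n_samples: int = 200_000, seed: int = 0) -> float:
    """Fraction of the probe sphere around ``center`` buried by neighbors.

    The probe sphere of the given radius is centered on the atom; a point
    is buried when it falls inside the van-der-Waals sphere (Bondi radii,
    hydrogens included) of any *other* atom. ``method="grid"`` uses a
    deterministic cubic grid (default spacing 0.1 Angstrom);
    ``method="montecarlo"`` uses seeded uniform sampling and serves as a
    stochastic cross-check.
    """
    if radius <= 0:
        raise GeometryError("radius must be positive")
    c = s.coords[center]
    if method == "grid":
        ax = np.arange(-radius, radius + spacing / 2, spacing)
        g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = g[np.einsum("ij,ij->i", g, g) <= radius * radius] + c
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        g = rng.uniform(-radius, radius, size=(n_samples, 3))
        pts = g[np.einsum("ij,ij->i", g, g) <= radius * radius] + c
    else:
        raise GeometryError(f"unknown buried-volume method {method!r}")
    return _occupancy_fraction(pts, s, center, radius)


@dataclass(frozen=True)
class BuriedVolumeSet:
    center: int
    fractions: tuple[float, float, float, float]  # at 2.0, 2.5, 3.0, 3.5 A


def buried_volume_set(s: Structure3D, center: int, method: str = "grid",
                      seed: int = 0) -> BuriedVolumeSet:
    """Buried volumes at the four standard radii around one Lewis center."""
    fr = tuple(buried_volume(s, center, r, method=method, seed=seed)
               for r in BURIED_VOLUME_RADII)
    return BuriedVolumeSet(center=center, fractions=fr)  # type: ignore[arg-type]


# --- XYZ I/O --------------------------------------------------------------

def write_xyz(s: Structure3D, path: str | Path, comment: str = "") -> None:
    lines = [str(len(s.symbols)), comment.replace("\n", " ")]
    for sym, (x, y, z) in zip(s.symbols, s.coords):
        lines.append(f"{sym} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> Structure3D:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].strip())
    symbols, coords = [], []
    for line in lines[2:2 + n]:
        sym, x, y, z = line.split()[:4]
        symbols.append(sym)
        coords.append((float(x), float(y), float(z)))
    return Structure3D(symbols=symbols, coords=np.array(coords))
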