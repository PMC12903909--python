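"""Fragment pools defining the gene alphabets of an IFLP chromosome.

A chromosome draws from four pools: acid substituents (bound to the Lewis
boron), base substituents (bound to the Lewis nitrogen), backbones (the
covalent tether, which carries the B and N atoms themselves), and backbone
substituents (optional decorations). Fragments are SMILES with explicit
attachment points written as dummy atoms ``[*:n]``.

Backbone socket convention (reserved atom-map numbers on the dummies):

====  =============================================
map   socket
====  =============================================
1, 2  acid-substituent sockets on the Lewis boron
3, 4  base-substituent sockets on the Lewis nitrogen
5-7   decoration sockets along the backbone
====  =============================================

A boron (nitrogen) center with fewer than two sockets is partially or
fully ring-embedded ("endocyclic"); the corresponding substituent genes
are silenced during expression. Substituent and decoration fragments carry
exactly one attachment point whose map number is irrelevant.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from rdkit import Chem

ROLES = ("acid_substituent", "base_substituent", "backbone", "backbone_substituent")

ACID_SOCKET_MAPS = (1, 2)
BASE_SOCKET_MAPS = (3, 4)
DECORATION_SOCKET_MAPS = (5, 6, 7)


class LibraryError(ValueError):
    """Raised for an invalid fragment library (bad SMILES, layout, or topology)."""


@dataclass(frozen=True)
class FragmentRecord:
    """One SMILES fragment with explicit attachment points."""

    fragment_id: str
    smiles: str
    role: str
    n_attachment_points: int


@dataclass(frozen=True)
class BackboneTopology:
    """Slot structure a backbone offers, inferred from its socket labels."""

    boron_mode: str  # "exocyclic" | "endocyclic"
    nitrogen_mode: str
    n_acid_sub_slots: int
    n_base_sub_slots: int
    n_decoration_slots: int


@dataclass
class FragmentLibrary:
    """Validated fragment pools plus per-backbone topology."""

    pools: dict[str, list[FragmentRecord]]
    topology: dict[str, BackboneTopology]

    def pool_sizes(self) -> tuple[int, int, int, int]:
        return tuple(len(self.pools[r]) for r in ROLES)  # type: ignore[return-value]

    def get(self, fragment_id: str) -> FragmentRecord:
        rec = self._index().get(fragment_id)
        if rec is None:
            raise LibraryError(f"unknown fragment id {fragment_id!r}")
        return rec

    def _index(self) -> Mapping[str, FragmentRecord]:
        if not hasattr(self, "_idx"):
            object.__setattr__(
                self, "_idx",
                {r.fragment_id: r for pool in self.pools.values() for r in pool},
            )
        return self._idx  # type: ignore[attr-defined]


def _attachment_maps(mol: Chem.Mol) -> list[int]:
    return [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def _lewis_atom(mol: Chem.Mol, atomic_num: int, socket_maps: tuple[int, ...],
                fragment_id: str) -> Chem.Atom:
    """The designated Lewis center: the B/N adjacent to its sockets, or the
    unique such element when the center carries no socket at all."""
    sockets = [a for a in mol.GetAtoms()
               if a.GetAtomicNum() == 0 and a.GetAtomMapNum() in socket_maps]
    if sockets:
        owners = {nb.GetIdx() for d in sockets for nb in d.GetNeighbors()}
        if len(owners) != 1:
            raise LibraryError(
                f"backbone {fragment_id!r}: sockets {socket_maps} attach to "
                f"{len(owners)} different atoms; they must share one Lewis center")
        atom = mol.GetAtomWithIdx(owners.pop())
        if atom.GetAtomicNum() != atomic_num:
            raise LibraryError(
                f"backbone {fragment_id!r}: sockets {socket_maps} are not on "
                f"the expected element (Z={atomic_num})")
        return atom
    candidates = [a for a in mol.GetAtoms() if a.GetAtomicNum() == atomic_num]
    if len(candidates) != 1:
        raise LibraryError(
            f"backbone {fragment_id!r}: no socket marks the Lewis center and "
            f"{len(candidates)} candidate atoms of Z={atomic_num} exist")
    return candidates[0]


def infer_topology(record: FragmentRecord) -> BackboneTopology:
    """Derive slot counts and ring modes from a backbone's socket labels."""
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:  # load path validates first; guard for direct calls
        raise LibraryError(f"backbone {record.fragment_id!r}: unparsable SMILES")
    maps = _attachment_maps(mol)
    n_acid = sum(m in ACID_SOCKET_MAPS for m in maps)
    n_base = sum(m in BASE_SOCKET_MAPS for m in maps)
    n_dec = sum(m in DECORATION_SOCKET_MAPS for m in maps)
    if n_acid + n_base + n_dec != len(maps):
        bad = [m for m in maps
               if m not in ACID_SOCKET_MAPS + BASE_SOCKET_MAPS + DECORATION_SOCKET_MAPS]
        raise LibraryError(
            f"backbone {record.fragment_id!r}: unreserved socket map numbers {bad}")
    b_atom = _lewis_atom(mol, 5, ACID_SOCKET_MAPS, record.fragment_id)
    n_atom = _lewis_atom(mol, 7, BASE_SOCKET_MAPS, record.fragment_id)
    b_mode = "endocyclic" if b_atom.IsInRing() else "exocyclic"
    n_mode = "endocyclic" if n_atom.IsInRing() else "exocyclic"
    if b_mode == "endocyclic" and n_acid > 1:
        raise LibraryError(
            f"backbone {record.fragment_id!r}: endocyclic boron offers at most "
            f"one acid-substituent slot, found {n_acid}")
    if n_mode == "endocyclic" and n_base > 1:
        raise LibraryError(
            f"backbone {record.fragment_id!r}: endocyclic nitrogen offers at most "
            f"one base-substituent slot, found {n_base}")
    return BackboneTopology(b_mode, n_mode, n_acid, n_base, n_dec)


def _parse_line(lineno: int, line: str) -> FragmentRecord:
    parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split(","))]
    if len(parts) != 3:
        raise LibraryError(f"line {lineno}: expected 'role<sep>id<sep>smiles', got {line!r}")
    role, fid, smi = parts
    if role not in ROLES:
        raise LibraryError(f"line {lineno}: unknown role {role!r}")
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise LibraryError(f"line {lineno}: unparsable SMILES {smi!r} (fragment {fid!r})")
    n_att = len(_attachment_maps(mol))
    if role == "backbone":
        if n_att < 2:
            raise LibraryError(
                f"line {lineno}: backbone {fid!r} needs >=2 labeled attachment "
                f"points, found {n_att}")
    elif n_att != 1:
        raise LibraryError(
            f"line {lineno}: {role} {fid!r} needs exactly 1 attachment point, "
            f"found {n_att}")
    return FragmentRecord(fid, smi, role, n_att)


def load_library(path: str | Path) -> FragmentLibrary:
    """Load and validate a flat-text fragment library.

    One record per line, tab- or comma-separated: ``role, id, smiles``.
    Blank lines and ``#`` comments are ignored. Raises :class:`LibraryError`
    with the offending line number on any invalid record.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    return _load_lines(lines)


def _load_lines(lines: Iterable[str]) -> FragmentLibrary:
    pools: dict[str, list[FragmentRecord]] = {r: [] for r in ROLES}
    seen: dict[str, set[str]] = {r: set() for r in ROLES}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rec = _parse_line(lineno, line)
        if rec.fragment_id in seen[rec.role]:
            raise LibraryError(
                f"line {lineno}: duplicate fragment id {rec.fragment_id!r} "
                f"in role {rec.role!r}")
        seen[rec.role].add(rec.fragment_id)
        pools[rec.role].append(rec)
    missing = [r for r in ROLES if not pools[r]]
    if missing:
        raise LibraryError(f"missing role section(s): {missing}")
    topology = {r.fragment_id: infer_topology(r) for r in pools["backbone"]}
    return FragmentLibrary(pools=pools, topology=topology)


def save_library(lib: FragmentLibrary, path: str | Path) -> None:
    """Serialize back to the flat tab-separated layout (round-trip stable)."""
    out = []
    for role in ROLES:
        for rec in lib.pools[role]:
            out.append(f"{role}\t{rec.fragment_id}\t{rec.smiles}")
    Path(path).write_text("\n".join(out) + "\n")


def load_builtin_library() -> FragmentLibrary:
    """The miniature built-in fragment set (6 acids, 4 bases, 5 backbones,
    2 decorations) shipped for tests and demos; no download required."""
    text = (importlib.resources.files("flpga") / "data" / "minilib.tsv").read_text()
    return _load_lines(text.splitlines())


def count_from_sizes(n_acid: int, n_base: int, n_backbone: int, n_decoration: int) -> int:
    """Upper-bound size of the fully expressed chromosome space.

    Ordered substituent slots: two acid and two base slots each draw
    independently from their pool; one backbone slot; the decoration pool
    contributes one multiplicative choice. Gene silencing and the A/B vs
    B/A symmetry of identical substituent pairs are deliberately ignored,
    so this over-counts the number of distinct molecules.
    """
    if min(n_acid, n_base, n_backbone, n_decoration) < 1:
        raise LibraryError("pool sizes must be positive")
    return n_acid ** 2 * n_base ** 2 * n_backbone * n_decoration


def count_space(lib: FragmentLibrary) -> int:
    """Upper-bound chromosome count of a library (see :func:`count_from_sizes`)."""
    return count_from_sizes(*lib.pool_sizes())
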