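"""Deterministic expression and assembly of IFLP chromosomes.

A chromosome is an ordered 8-tuple of fragment ids::

    (acid_sub_1, acid_sub_2, base_sub_1, base_sub_2,
     backbone, decoration_1, decoration_2, decoration_3)

Expression silences genes for which the backbone's topology offers no
socket (e.g. an endocyclic nitrogen loses its second substituent slot);
silenced genes stay in the tuple so that crossover remains positional,
but never influence assembly or fitness. Assembly welds each expressed
substituent's attachment point onto the matching backbone socket with a
single bond, removes the dummy atoms, and emits canonical SMILES for the
free catalyst (Int1) and for the H2-activated zwitterion (Int2: hydride
on B, formal charge -1; proton on N, formal charge +1; neutral overall).
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .fragment_library import (
    ACID_SOCKET_MAPS,
    BASE_SOCKET_MAPS,
    DECORATION_SOCKET_MAPS,
    FragmentLibrary,
    LibraryError,
)

GENE_SLOTS = (
    "acid_sub_1", "acid_sub_2", "base_sub_1", "base_sub_2",
    "backbone", "decoration_1", "decoration_2", "decoration_3",
)
_SLOT_ROLES = (
    "acid_substituent", "acid_substituent",
    "base_substituent", "base_substituent",
    "backbone",
    "backbone_substituent", "backbone_substituent", "backbone_substituent",
)
# gene slot index -> backbone socket map number it fills
_SLOT_SOCKET = {0: 1, 1: 2, 2: 3, 3: 4, 5: 5, 6: 6, 7: 7}

_LEWIS_B_PROP = "flp_lewis_boron"
_LEWIS_N_PROP = "flp_lewis_nitrogen"


class AssemblyError(ValueError):
    """Raised when welding produces an invalid molecule or sockets are left open."""


@dataclass(frozen=True)
class Chromosome:
    """Eight gene ids plus the expression mask implied by the backbone."""

    genes: tuple[str, str, str, str, str, str, str, str]
    expression_mask: tuple[bool, bool, bool, bool, bool, bool, bool, bool]

    def expressed_genes(self) -> dict[str, str]:
        return {GENE_SLOTS[i]: g for i, (g, e) in
                enumerate(zip(self.genes, self.expression_mask)) if e}


@dataclass(frozen=True)
class AssembledCandidate:
    chromosome: Chromosome
    smiles_int1: str
    smiles_int2: str
    provenance: dict[str, str]  # gene slot -> fragment id actually used


def express(chromosome_genes: tuple[str, ...], lib: FragmentLibrary) -> Chromosome:
    """Set the expression mask from the backbone's topology.

    The mask is a pure function of the backbone gene: a substituent or
    decoration gene is expressed iff the backbone offers the corresponding
    socket. Role mismatches and unknown ids are fatal.
    """
    if len(chromosome_genes) != 8:
        raise LibraryError(f"expected 8 genes, got {len(chromosome_genes)}")
    for i, gid in enumerate(chromosome_genes):
        rec = lib.get(gid)
        if rec.role != _SLOT_ROLES[i]:
            raise LibraryError(
                f"gene slot {GENE_SLOTS[i]!r} requires role {_SLOT_ROLES[i]!r} "
                f"but fragment {gid!r} has role {rec.role!r}")
    topo = lib.topology[chromosome_genes[4]]
    mask = (
        topo.n_acid_sub_slots >= 1,
        topo.n_acid_sub_slots >= 2,
        topo.n_base_sub_slots >= 1,
        topo.n_base_sub_slots >= 2,
        True,
        topo.n_decoration_slots >= 1,
        topo.n_decoration_slots >= 2,
        topo.n_decoration_slots >= 3,
    )
    return Chromosome(tuple(chromosome_genes), mask)  # type: ignore[arg-type]


def _find_socket(mol: Chem.Mol, map_num: int) -> int | None:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == map_num:
            return atom.GetIdx()
    return None


def _weld(core: Chem.Mol, socket_map: int, fragment_smiles: str) -> Chem.Mol:
    """Join a one-point fragment onto the core socket with a single bond."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    n_core = core.GetNumAtoms()
    core_dummy = _find_socket(combo, socket_map)
    if core_dummy is None or core_dummy >= n_core:
        raise AssemblyError(f"socket [*:{socket_map}] not found on core")
    frag_dummy = next(
        (a.GetIdx() for a in combo.GetAtoms()
         if a.GetIdx() >= n_core and a.GetAtomicNum() == 0), None)
    if frag_dummy is None:
        raise AssemblyError(f"fragment {fragment_smiles!r} has no attachment point")
    core_anchor = combo.GetAtomWithIdx(core_dummy).GetNeighbors()[0].GetIdx()
    frag_anchor = combo.GetAtomWithIdx(frag_dummy).GetNeighbors()[0].GetIdx()
    combo.AddBond(core_anchor, frag_anchor, Chem.BondType.SINGLE)
    for idx in sorted((core_dummy, frag_dummy), reverse=True):
        combo.RemoveAtom(idx)
    return combo.GetMol()


def _mark_lewis_atoms(mol: Chem.Mol, backbone_id: str, lib: FragmentLibrary) -> None:
    from .fragment_library import _lewis_atom  # shared designation rule

    _lewis_atom(mol, 5, ACID_SOCKET_MAPS, backbone_id).SetBoolProp(_LEWIS_B_PROP, True)
    _lewis_atom(mol, 7, BASE_SOCKET_MAPS, backbone_id).SetBoolProp(_LEWIS_N_PROP, True)


def _tagged_atom(mol: Chem.Mol, prop: str) -> int:
    for atom in mol.GetAtoms():
        if atom.HasProp(prop):
            return atom.GetIdx()
    raise AssemblyError(f"lost track of designated atom ({prop})")


def _add_h2(mol: Chem.Mol, b_idx: int, n_idx: int) -> Chem.Mol:
    """Hydride onto B (charge -1) and proton onto N (charge +1)."""
    m = Chem.RWMol(mol)
    b, n = m.GetAtomWithIdx(b_idx), m.GetAtomWithIdx(n_idx)
    if b.GetTotalValence() >= 4:
        raise AssemblyError("boron cannot accept a hydride (already tetravalent)")
    if n.GetTotalValence() >= 4:
        raise AssemblyError("nitrogen cannot accept a proton (already tetravalent)")
    b.SetNumExplicitHs(b.GetNumExplicitHs() + 1)
    b.SetFormalCharge(b.GetFormalCharge() - 1)
    b.SetNoImplicit(True)
    n.SetNumExplicitHs(n.GetNumExplicitHs() + 1)
    n.SetFormalCharge(n.GetFormalCharge() + 1)
    out = m.GetMol()
    Chem.SanitizeMol(out)
    return out


def assemble(chromosome: Chromosome, lib: FragmentLibrary) -> AssembledCandidate:
    """Weld all expressed genes into one molecule; pure and deterministic.

    Raises :class:`AssemblyError` on valence violations or leftover sockets.
    """
    backbone_id = chromosome.genes[4]
    mol = Chem.MolFromSmiles(lib.get(backbone_id).smiles)
    _mark_lewis_atoms(mol, backbone_id, lib)
    provenance = {"backbone": backbone_id}
    for slot, socket_map in _SLOT_SOCKET.items():
        if not chromosome.expression_mask[slot]:
            continue
        gid = chromosome.genes[slot]
        mol = _weld(mol, socket_map, lib.get(gid).smiles)
        provenance[GENE_SLOTS[slot]] = gid
    leftover = [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if leftover:
        raise AssemblyError(f"unfilled backbone sockets remain: maps {leftover}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitize subclasses
        raise AssemblyError(
            f"valence violation after welding: {Chem.MolToSmiles(mol, canonical=False)}"
        ) from exc
    smiles_int1 = Chem.MolToSmiles(mol)
    int2 = _add_h2(mol, _tagged_atom(mol, _LEWIS_B_PROP), _tagged_atom(mol, _LEWIS_N_PROP))
    return AssembledCandidate(
        chromosome=chromosome,
        smiles_int1=smiles_int1,
        smiles_int2=Chem.MolToSmiles(int2),
        provenance=provenance,
    )


def to_int2(smiles_int1: str) -> str:
    """H2-activate a free catalyst SMILES: hydride to the trivalent Lewis
    boron, proton to the trivalent Lewis nitrogen; canonical, net neutral.

    Without backbone provenance the designated pair is found structurally:
    the unique neutral trivalent boron and the first neutral nitrogen with
    a free valence. Raises :class:`AssemblyError` when no such pair exists.
    """
    mol = Chem.MolFromSmiles(smiles_int1)
    if mol is None:
        raise AssemblyError(f"unparsable SMILES {smiles_int1!r}")
    borons = [a.GetIdx() for a in mol.GetAtoms()
              if a.GetAtomicNum() == 5 and a.GetFormalCharge() == 0
              and a.GetTotalValence() == 3]
    nitrogens = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetAtomicNum() == 7 and a.GetFormalCharge() == 0
                 and a.GetTotalValence() == 3]
    if not borons:
        raise AssemblyError("no trivalent boron available for hydride attachment")
    if not nitrogens:
        raise AssemblyError("no trivalent nitrogen available for proton attachment")
    return Chem.MolToSmiles(_add_h2(mol, borons[0], nitrogens[0]))
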