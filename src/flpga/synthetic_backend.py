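"""Download-free descriptor backend and fixture generator.

Real descriptor evaluation needs semiempirical geometry optimization; at
desk scale we instead attach a deterministic additive property model:
every fragment carries fixed FEPA/FEHA/steric contributions and every
backbone a base geometry (d0, phi0) that expressed substituents perturb.
The resulting fitness landscape is smooth, GA-learnable, and has a known
global optimum that exhaustive enumeration can certify — the test surface
a physics backend cannot provide quickly. It makes no claim of physical
accuracy.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembler import AssembledCandidate, Chromosome, assemble, express
from .fitness import C_OPT_DEFAULT, DescriptorSet, scs_score
from .fragment_library import FragmentLibrary, LibraryError, _load_lines
from .quench_model import QuenchDataset, QuenchSample, label


class SyntheticBackendError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentContribution:
    fepa: float = 0.0    # kcal/mol, base-side additive term
    feha: float = 0.0    # kcal/mol, acid-side additive term
    steric: float = 0.0  # dimensionless bulk term
    d: float = 0.0       # Angstrom perturbation (backbones: absolute d0)
    phi: float = 0.0     # degrees perturbation (backbones: absolute phi0)


@dataclass
class FragmentPropertyTable:
    """Per-fragment additive contributions; must cover the whole library."""

    contributions: dict[str, FragmentContribution]
    steric_midpoint: float = 0.0   # steric sum mapped to BWDistance 2.0 A
    steric_scale: float = 1.0

    def get(self, fragment_id: str) -> FragmentContribution:
        try:
            return self.contributions[fragment_id]
        except KeyError:
            raise SyntheticBackendError(
                f"no property-table entry for fragment {fragment_id!r}") from None

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fragment_id", "fepa", "feha", "steric", "d", "phi"])
            for fid, c in self.contributions.items():
                w.writerow([fid, c.fepa, c.feha, c.steric, c.d, c.phi])

    @classmethod
    def from_csv(cls, path: str | Path) -> "FragmentPropertyTable":
        contrib = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                contrib[row["fragment_id"]] = FragmentContribution(
                    float(row["fepa"]), float(row["feha"]), float(row["steric"]),
                    float(row["d"]), float(row["phi"]))
        return cls(contributions=contrib)


_ACID_SLOTS = (0, 1)
_BASE_SLOTS = (2, 3)
_DECOR_SLOTS = (5, 6, 7)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def synth_descriptors(candidate: AssembledCandidate, table: FragmentPropertyTable,
                      noise_sd: float = 0.0, seed: int = 0) -> DescriptorSet:
    """Deterministic descriptors from additive fragment contributions.

    FEPA sums the backbone plus base-side terms; FEHA the backbone plus
    acid-side terms; d and phi start at the backbone's base geometry and
    accumulate substituent perturbations (phi clipped to [0, 180]). The
    quench index comes from a synthetic BWDistance, a logistic function of
    the total steric bulk, thresholded at 2.0 Angstrom. Optional Gaussian
    noise is seeded; noise_sd = 0 is exactly reproducible.
    """
    chrom = candidate.chromosome
    backbone = table.get(chrom.genes[4])
    fepa, feha = backbone.fepa, backbone.feha
    d, phi = backbone.d, backbone.phi
    steric = backbone.steric
    for slot in range(8):
        if slot == 4 or not chrom.expression_mask[slot]:
            continue
        c = table.get(chrom.genes[slot])
        steric += c.steric
        d += c.d
        phi += c.phi
        if slot in _ACID_SLOTS:
            feha += c.feha
        elif slot in _BASE_SLOTS:
            fepa += c.fepa
        else:  # decorations nudge both sides weakly
            fepa += c.fepa
            feha += c.feha
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fepa += rng.normal(0, noise_sd)
        feha += rng.normal(0, noise_sd)
        d += rng.normal(0, noise_sd * 0.01)
        phi += rng.normal(0, noise_sd * 0.1)
    phi = min(180.0, max(0.0, phi))
    bwd = 1.2 + 2.2 * _sigmoid(table.steric_scale * (steric - table.steric_midpoint))
    return DescriptorSet(
        fepa=fepa, feha=feha, d=d, phi=phi,
        scs=scs_score(candidate.smiles_int1), q=label(bwd))


class SyntheticBackend:
    """DescriptorBackend adapter around a property table (see ga_engine)."""

    def __init__(self, table: FragmentPropertyTable, noise_sd: float = 0.0,
                 seed: int = 0):
        self.table, self.noise_sd, self.seed = table, noise_sd, seed

    def descriptors(self, candidate: AssembledCandidate) -> DescriptorSet:
        return synth_descriptors(candidate, self.table, self.noise_sd, self.seed)


def make_quench_fixture(n: int, separation: float = 0.5, seed: int = 0) -> QuenchDataset:
    """Synthetic quench dataset emulating the bimodal BWDistance structure.

    Half the pairs are datively quenched (BWDistance around 1.6 Angstrom,
    low buried volumes) and half frustrated (around 3.0 Angstrom, high
    buried volumes); labels follow the 2.0 Angstrom rule. ``separation``
    is the gap between the feature-cluster centers: 0.5 yields linearly
    separable classes, 0 makes the features uninformative (null model).
    """
    if n < 4:
        raise SyntheticBackendError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    half = n // 2
    samples = []
    for i in range(n):
        frustrated = i >= half
        center = 0.45 + (separation / 2 if frustrated else -separation / 2)
        feats = np.clip(rng.normal(center, 0.03, size=8), 0.0, 1.0)
        bwd = rng.normal(3.0, 0.25) if frustrated else rng.normal(1.6, 0.08)
        bwd = max(0.5, bwd)
        samples.append(QuenchSample(
            pair_id=f"pair_{i:04d}", features=tuple(feats),
            bwdistance=bwd, label=label(bwd)))
    return QuenchDataset(samples=samples, provenance={
        "separation": separation, "seed": seed, "boundary": 2.0,
        "centers_bwd": (1.6, 3.0)})


# --- planted-optimum mini space ------------------------------------------

_PLANTED_LIB_LINES = """\
acid_substituent\ta_me\tC[*:1]
acid_substituent\ta_et\tCC[*:1]
acid_substituent\ta_cf3\tFC(F)(F)[*:1]
acid_substituent\ta_ph\t[*:1]c1ccccc1
base_substituent\tb_me\tC[*:1]
base_substituent\tb_et\tCC[*:1]
base_substituent\tb_ipr\tCC(C)[*:1]
backbone\tk_ophen\t[*:1]B([*:2])c1ccccc1N([*:3])[*:4]
backbone\tk_gem\t[*:1]B([*:2])CN([*:3])[*:4]
backbone_substituent\ts_me\tC[*:1]
""".splitlines()


@dataclass(frozen=True)
class PlantedSpace:
    """A mini library + table whose global optimum is known by construction."""

    library: FragmentLibrary
    table: FragmentPropertyTable
    optimum_genes: tuple[str, ...]
    optimum_smiles_int2: str


def make_planted_space(seed: int = 0) -> PlantedSpace:
    """Build the planted-optimum synthetic landscape for GA validation.

    4 acids x 3 bases x 2 backbones (no decoration slots) span 288 fully
    expressed gene tuples. One chromosome (same acid in both acid slots,
    same base in both base slots) is planted on the targets exactly:
    FEPA + FEHA = -317.2 kcal/mol, d = 2.7 Angstrom, phi = 100 degrees.
    Every other fragment carries a strictly positive seeded deviation on
    each property, so the total deviation is additive over mismatched
    genes: the landscape is smooth and hill-climbable, the planted
    chromosome is its unique optimum (verifiable by enumeration), and
    partial matches are strictly better than random combinations.
    """
    lib = _load_lines(_PLANTED_LIB_LINES)
    rng = np.random.default_rng(seed)
    acids = [r.fragment_id for r in lib.pools["acid_substituent"]]
    bases = [r.fragment_id for r in lib.pools["base_substituent"]]
    backbones = [r.fragment_id for r in lib.pools["backbone"]]
    a_opt = acids[rng.integers(len(acids))]
    b_opt = bases[rng.integers(len(bases))]
    k_opt = backbones[rng.integers(len(backbones))]
    opt = (a_opt, a_opt, b_opt, b_opt, k_opt, "s_me", "s_me", "s_me")

    a0, b0 = -30.0, -50.0  # kcal/mol, per-substituent baseline strengths
    contrib: dict[str, FragmentContribution] = {}
    for fid in acids:
        dev = 0.0 if fid == a_opt else rng.uniform(3.0, 12.0)
        contrib[fid] = FragmentContribution(
            feha=a0 + dev, steric=1.0,
            d=0.0 if fid == a_opt else rng.uniform(0.05, 0.30),
            phi=0.0 if fid == a_opt else rng.uniform(3.0, 15.0))
    for fid in bases:
        dev = 0.0 if fid == b_opt else rng.uniform(3.0, 12.0)
        contrib[fid] = FragmentContribution(
            fepa=b0 + dev, steric=1.0,
            d=0.0 if fid == b_opt else rng.uniform(0.05, 0.30),
            phi=0.0 if fid == b_opt else rng.uniform(3.0, 15.0))
    split = rng.uniform(0.55, 0.75)  # share of c_opt on the FEPA side
    for fid in backbones:
        dev = 0.0 if fid == k_opt else rng.uniform(5.0, 15.0)
        contrib[fid] = FragmentContribution(
            fepa=C_OPT_DEFAULT * split - 2 * b0 + dev,
            feha=C_OPT_DEFAULT * (1.0 - split) - 2 * a0,
            steric=2.0,
            d=2.7 + (0.0 if fid == k_opt else rng.uniform(0.1, 0.4)),
            phi=100.0 - (0.0 if fid == k_opt else rng.uniform(5.0, 20.0)))
    for rec in lib.pools["backbone_substituent"]:
        contrib[rec.fragment_id] = FragmentContribution()

    # high frustration everywhere: steric sums >= 4 sit far above midpoint 0
    table = FragmentPropertyTable(contributions=contrib,
                                  steric_midpoint=0.0, steric_scale=1.0)
    cand = assemble(express(opt, lib), lib)
    return PlantedSpace(library=lib, table=table, optimum_genes=opt,
                        optimum_smiles_int2=cand.smiles_int2)


def enumerate_space(lib: FragmentLibrary):
    """Yield every fully specified gene tuple of a library (decorations
    fixed to the pool order's combinations only when slots exist)."""
    acids = [r.fragment_id for r in lib.pools["acid_substituent"]]
    bases = [r.fragment_id for r in lib.pools["base_substituent"]]
    backbones = [r.fragment_id for r in lib.pools["backbone"]]
    decs = [r.fragment_id for r in lib.pools["backbone_substituent"]]
    for bb in backbones:
        topo = lib.topology[bb]
        dec_pools = [decs if topo.n_decoration_slots >= k else [decs[0]]
                     for k in (1, 2, 3)]
        for a1 in acids:
            for a2 in acids:
                for b1 in bases:
                    for b2 in bases:
                        for d1 in dec_pools[0]:
                            for d2 in dec_pools[1]:
                                for d3 in dec_pools[2]:
                                    yield (a1, a2, b1, b2, bb, d1, d2, d3)
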