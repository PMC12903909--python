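"""Fitness scores mapping candidate descriptors to the GA objectives.

Three scores drive the multi-objective optimization:

* **Chemistry score** CS = Q / r_chem, where r_chem is the Euclidean
  distance of the candidate's (FEPA, FEHA) point from the maximum-TOF
  line FEPA + FEHA = c_opt (default -317.2 kcal/mol) and Q is the binary
  quench index. Maximized.
* **Geometry score** GS = G * Q, with G a weighted sum of peak-normalized
  Gaussian scores of the B-N distance d and orientation angle Phi against
  their targets. Maximized.
* **Synthetic complexity score** SCS in [1, 5] (higher = more complex).
  Minimized.

FEPA/FEHA are free energies of proton/hydride attachment in kcal/mol
(more negative = stronger base/acid). Low-level (semiempirical) values
are passed through a fitted linear correction before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from rdkit import Chem
from scipy import stats

#: distance from the maximum-TOF line below which CS saturates at 1/EPSILON
EPSILON_DEFAULT = 1e-3
C_OPT_DEFAULT = -317.2  # kcal/mol, FEPA + FEHA at maximum predicted TOF


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorSet:
    """Everything the fitness function consumes for one candidate."""

    fepa: float  # kcal/mol, free energy of proton attachment (N basicity)
    feha: float  # kcal/mol, free energy of hydride attachment (B acidity)
    d: float     # Angstrom, B-N distance in Int2
    phi: float   # degrees, donor-acceptor orientation angle in Int2
    scs: float   # synthetic complexity, [1, 5]
    q: int       # binary quench index: 1 = frustrated, 0 = quenched

    def __post_init__(self):
        if not 1.0 <= self.scs <= 5.0:
            raise ConfigurationError(f"scs must lie in [1, 5], got {self.scs}")
        if self.q not in (0, 1):
            raise ConfigurationError(f"q must be 0 or 1, got {self.q}")


@dataclass(frozen=True)
class FitnessVector:
    cs: float
    gs: float
    scs: float


@dataclass(frozen=True)
class FitnessConfig:
    """Tunable constants of the score functions (units in field comments)."""

    c_opt: float = C_OPT_DEFAULT     # kcal/mol
    sigma_d: float = 0.60            # Angstrom
    sigma_phi: float = 0.75          # radians unless phi_units == "degrees"
    phi_units: str = "radians"       # units under which sigma_phi applies
    c1: float = 0.5                  # weight of the distance score
    c2: float = 0.5                  # weight of the angle score
    epsilon: float = EPSILON_DEFAULT
    d_target: float = 2.7            # Angstrom
    phi_target: float = 100.0        # degrees


def r_chem(fepa: float, feha: float, c_opt: float = C_OPT_DEFAULT) -> float:
    """Euclidean distance of (FEPA, FEHA) from the line FEPA + FEHA = c_opt.

    Point-to-line distance in the chemical-descriptor plane:
    ``|fepa + feha - c_opt| / sqrt(2)``. Depends only on the cumulative
    acid-base strength, not on how it is split between the centers.
    """
    return abs(fepa + feha - c_opt) / math.sqrt(2.0)


def gaussian_score(p: float, p_target: float, sigma: float) -> float:
    """Peak-normalized Gaussian score exp(-(p - p_target)^2 / (2 sigma^2)).

    Equals 1 exactly on target and decays symmetrically; sigma sets the
    tolerance width in the units of ``p``.
    """
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be positive, got {sigma}")
    z = (p - p_target) / sigma
    return math.exp(-0.5 * z * z)


def geometry_score(f_d: float, f_phi: float, c1: float = 0.5, c2: float = 0.5) -> float:
    """Weighted sum G = c1*f_d + c2*f_phi of the two geometric scores."""
    if c1 < 0 or c2 < 0:
        raise ConfigurationError("geometry weights must be non-negative")
    return c1 * f_d + c2 * f_phi


def scores(ds: DescriptorSet, config: FitnessConfig = FitnessConfig()) -> FitnessVector:
    """Map a descriptor set to (CS, GS, SCS).

    Q = 0 gates both CS and GS to exactly 0; r_chem is floored at
    ``config.epsilon`` so CS saturates at 1/epsilon on the TOF line.
    """
    rc = r_chem(ds.fepa, ds.feha, config.c_opt)
    cs = ds.q / max(rc, config.epsilon)
    f_d = gaussian_score(ds.d, config.d_target, config.sigma_d)
    if config.phi_units == "radians":
        f_phi = gaussian_score(math.radians(ds.phi), math.radians(config.phi_target),
                               config.sigma_phi)
    elif config.phi_units == "degrees":
        f_phi = gaussian_score(ds.phi, config.phi_target, config.sigma_phi)
    else:
        raise ConfigurationError(f"phi_units must be radians|degrees, got {config.phi_units!r}")
    gs = geometry_score(f_d, f_phi, config.c1, config.c2) * ds.q
    return FitnessVector(cs=cs, gs=gs, scs=ds.scs)


@dataclass(frozen=True)
class LinearCorrection:
    """Per-descriptor linear map from low-level to high-level energies."""

    slope: float
    intercept: float  # kcal/mol
    r2: float

    def apply(self, x: float) -> float:
        return self.slope * x + self.intercept


def fit_linear_correction(pairs: list[tuple[float, float]]) -> LinearCorrection:
    """Ordinary least squares fit of high-level on low-level energies.

    ``pairs`` are (low-level, high-level) values in kcal/mol; at least
    three pairs are required and the low-level values must not be constant.
    """
    if len(pairs) < 3:
        raise ConfigurationError(f"need >=3 pairs to fit a correction, got {len(pairs)}")
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if max(x) == min(x):
        raise ConfigurationError("degenerate fit: low-level values are constant")
    res = stats.linregress(x, y)
    return LinearCorrection(slope=res.slope, intercept=res.intercept,
                            r2=res.rvalue ** 2)


# --- synthetic complexity -------------------------------------------------

def _heuristic_scs(mol: Chem.Mol) -> float:
    """Documented heuristic complexity score in [1, 5].

    A monotone saturating function of heavy-atom count, ring count, ring
    fusion (bonds shared between rings) and stereocenters. It preserves
    the published model's scale and direction (1 = trivial, 5 = very
    complex) but is *not* equivalent to the trained neural-network scorer,
    which can be plugged in as an external backend.
    """
    n_heavy = mol.GetNumHeavyAtoms()
    ri = mol.GetRingInfo()
    n_rings = ri.NumRings()
    ring_bonds = [set(bonds) for bonds in ri.BondRings()]
    n_fused = sum(
        len(ring_bonds[i] & ring_bonds[j])
        for i in range(len(ring_bonds)) for j in range(i + 1, len(ring_bonds)))
    n_stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    raw = 0.05 * n_heavy + 0.30 * n_rings + 0.25 * n_fused + 0.30 * n_stereo
    return 1.0 + 4.0 * (1.0 - math.exp(-raw))


def scs_score(smiles: str, backend: str = "heuristic-fallback",
              external_model=None) -> float:
    """Synthetic complexity of a molecule, clipped to [1, 5].

    ``backend="external-model"`` delegates to a supplied callable
    (SMILES -> score), e.g. a trained complexity network; the default
    heuristic fallback needs no trained weights and is deterministic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    if backend == "external-model":
        if external_model is None:
            raise ConfigurationError("external-model backend requires a callable")
        score = float(external_model(smiles))
    elif backend == "heuristic-fallback":
        score = _heuristic_scs(mol)
    else:
        raise ConfigurationError(f"unknown scs backend {backend!r}")
    return min(5.0, max(1.0, score))
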