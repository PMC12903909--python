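"""Reported descriptor values for the ten lead IFLP candidates (FLP1-10).

These are published reference numbers used in regression tests of the
fitness arithmetic; fields not reported for a candidate are None. Energy
spans are in kcal/mol (effective activation energy of the catalytic
cycle, TDI to TDTS); FEPA/FEHA in kcal/mol; d in Angstrom; phi in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LeadCandidate:
    name: str
    fepa: float | None = None
    feha: float | None = None
    cumulative: float | None = None  # FEPA + FEHA when only the sum is reported
    d: float | None = None
    phi: float | None = None
    energy_span: float | None = None


LEAD_CANDIDATES = {
    "FLP1": LeadCandidate("FLP1", fepa=-228.6, feha=-87.3, d=2.7, phi=73.1,
                          energy_span=28.9),
    "FLP2": LeadCandidate("FLP2", d=2.53, phi=96.2),
    "FLP3": LeadCandidate("FLP3", d=3.06, phi=63.3),
    "FLP4": LeadCandidate("FLP4", cumulative=-315.2, phi=129.0, energy_span=20.5),
    "FLP5": LeadCandidate("FLP5", cumulative=-317.2, phi=65.0),
    "FLP9": LeadCandidate("FLP9", cumulative=-313.3, d=2.83, phi=59.0,
                          energy_span=22.8),
    "FLP10": LeadCandidate("FLP10", cumulative=-316.1, d=2.79, phi=93.0,
                           energy_span=16.6),
}


def cumulative_strength(fepa: float, feha: float) -> float:
    """Cumulative acid-base strength FEPA + FEHA in kcal/mol."""
    return fepa + feha


def energy_span_difference(span_a: float, span_b: float) -> float:
    """Difference between two catalytic-cycle energy spans, kcal/mol."""
    return span_a - span_b
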