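"""Hierarchical (Chimera-style) scalarization and Pareto extraction.

Objectives are ranked in a fixed priority order, each with a relative
degradation tolerance. Candidates whose first objective lies within the
tolerance band of the best value form the accepted region and are ranked
among themselves by the second objective's band, and so on; candidates
outside a band rank strictly worse than everyone inside it. The result is
a single merit per candidate (smaller = better) defining a total order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_VALID_NAMES = {"CS": "maximize", "GS": "maximize", "SCS": "minimize"}


class ScalarizerError(ValueError):
    pass


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective of the hierarchy.

    ``tolerance`` is the accepted relative degradation from the best value
    in the evaluation batch, as a fraction of the batch's value range
    (0 = only ties with the best pass, 1 = everything passes).
    """

    name: str
    direction: str  # "maximize" | "minimize"
    tolerance: float

    def __post_init__(self):
        if self.direction not in ("maximize", "minimize"):
            raise ScalarizerError(f"direction must be maximize|minimize, "
                                  f"got {self.direction!r}")
        if self.tolerance < 0:
            raise ScalarizerError("tolerance must be non-negative")


#: The default hierarchy of the optimization runs: chemistry first with a
#: 25% band, geometry a close second at 10%, synthetic complexity at 25%.
DEFAULT_OBJECTIVES = (
    ObjectiveSpec("CS", "maximize", 0.25),
    ObjectiveSpec("GS", "maximize", 0.10),
    ObjectiveSpec("SCS", "minimize", 0.25),
)

_TOL_EPS = 1e-12


def chimera_scalarize(objectives: np.ndarray,
                      specs: tuple[ObjectiveSpec, ...] | list[ObjectiveSpec]
                      ) -> np.ndarray:
    """Merit per candidate (lower = better) under the hierarchical scheme.

    ``objectives`` is a (candidates x objectives) matrix ordered like
    ``specs``. Minimization objectives are negated internally so all
    columns maximize. Candidates with any NaN objective rank worst, in
    stable input order; ties elsewhere also break by input order.

    Limit behaviors: a single objective reduces to sorting by it; all
    tolerances 0 reduce to exact lexicographic order; tolerance 1 on an
    objective makes it transparent, deferring fully to the next one.
    """
    X = np.array(objectives, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if n == 0:
        raise ScalarizerError("empty population")
    if m != len(specs):
        raise ScalarizerError(f"{m} objective columns vs {len(specs)} specs")
    for j, spec in enumerate(specs):
        if spec.direction == "minimize":
            X[:, j] = -X[:, j]

    order: list[int] = []
    ok = [i for i in range(n) if not np.isnan(X[i]).any()]
    bad = [i for i in range(n) if np.isnan(X[i]).any()]

    def rank(idx: list[int], level: int) -> None:
        # Terminal region: every band satisfied; order by the last
        # objective ("better satisfies all requirements"), stably.
        if level == m:
            order.extend(sorted(idx, key=lambda i: (-X[i, m - 1], i)))
            return
        tol = specs[level].tolerance
        while idx:
            col = X[idx, level]
            best, worst = col.max(), col.min()
            if best == worst:
                inside, outside = idx, []
            else:
                thr = best - tol * (best - worst)
                inside = [i for i in idx if X[i, level] >= thr - _TOL_EPS]
                outside = [i for i in idx if X[i, level] < thr - _TOL_EPS]
            rank(inside, level + 1)
            idx = outside  # re-rank the rejected region at this same level

    rank(ok, 0)
    order.extend(bad)
    merit = np.empty(n)
    merit[np.array(order, dtype=int)] = np.arange(n, dtype=float)
    return merit


def pareto_front(objectives: np.ndarray,
                 directions: tuple[str, ...] | list[str] | None = None
                 ) -> list[int]:
    """Indices of the non-dominated candidates.

    A candidate is dominated when another is at least as good on every
    objective and strictly better on one (directions respected;
    default: maximize all).
    """
    X = np.array(objectives, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if directions is not None:
        for j, d in enumerate(directions):
            if d == "minimize":
                X[:, j] = -X[:, j]
            elif d != "maximize":
                raise ScalarizerError(f"bad direction {d!r}")
    # lexicographic descending sort: any dominator precedes its dominated
    # candidate, so testing against current front members is sufficient
    by_first = sorted(range(n), key=lambda i: tuple(-X[i]))
    front: list[int] = []
    for i in by_first:
        dominated = any(
            np.all(X[j] >= X[i]) and np.any(X[j] > X[i]) for j in front)
        if not dominated:
            front.append(i)
    return sorted(front)
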