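"""Frustration vs. dative quenching of a Lewis acid-base pair.

A pair is *quenched* when the acid and base collapse into a classical
dative adduct (B-N around 1.6 Angstrom) and *frustrated* when sterics
keep them apart. Ground truth comes from a Boltzmann-weighted LA-LB
distance (BWDistance) over multi-start geometry optimizations; the
distribution is strongly bimodal around the 2.0 Angstrom decision
boundary. A random forest then predicts the binary quench index Q from
eight buried-volume fractions (four radii around each Lewis center), so
that the expensive multi-start protocol is needed only to build training
data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score

KB_KCAL_MOL_K = 1.987204259e-3  # Boltzmann constant, kcal/(mol K)
BOUNDARY_DEFAULT = 2.0          # Angstrom
N_FEATURES = 8                  # 4 radii x {acid center, base center}


class QuenchModelError(ValueError):
    pass


@dataclass(frozen=True)
class QuenchSample:
    pair_id: str
    features: tuple[float, ...]  # 8 buried-volume fractions in [0, 1]
    bwdistance: float            # Angstrom
    label: int                   # 1 = frustrated, 0 = quenched

    def __post_init__(self):
        if len(self.features) != N_FEATURES:
            raise QuenchModelError(
                f"expected {N_FEATURES} features, got {len(self.features)}")
        if self.label not in (0, 1):
            raise QuenchModelError(f"label must be 0/1, got {self.label}")


@dataclass
class QuenchDataset:
    samples: list[QuenchSample]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.pair_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise QuenchModelError("duplicate pair_ids in dataset")

    def X(self) -> np.ndarray:
        return np.array([s.features for s in self.samples])

    def y(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pair_id"] + [f"vbur_{i}" for i in range(N_FEATURES)]
                       + ["bwdistance", "label"])
            for s in self.samples:
                w.writerow([s.pair_id, *s.features, s.bwdistance, s.label])

    @classmethod
    def from_csv(cls, path: str | Path) -> "QuenchDataset":
        samples = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                feats = tuple(float(row[f"vbur_{i}"]) for i in range(N_FEATURES))
                samples.append(QuenchSample(row["pair_id"], feats,
                                            float(row["bwdistance"]),
                                            int(row["label"])))
        return cls(samples=samples)


def bwdistance(runs: list[tuple[float, float]], temperature: float = 298.15) -> float:
    """Boltzmann-weighted LA-LB distance over multi-start optimizations.

    ``runs`` are (final distance in Angstrom, relative energy in kcal/mol)
    pairs; weights are exp(-dE / kT) with energies re-referenced to the
    minimum for numerical stability. The result is a convex combination of
    the run distances: the minimum-energy distance as T -> 0 and the
    arithmetic mean as T -> infinity.
    """
    if not runs:
        raise QuenchModelError("bwdistance requires at least one run")
    if temperature <= 0:
        raise QuenchModelError("temperature must be positive")
    e_min = min(e for _, e in runs)
    kt = KB_KCAL_MOL_K * temperature
    weights = [math.exp(-(e - e_min) / kt) for _, e in runs]
    total = sum(weights)
    return sum(d * w for (d, _), w in zip(runs, weights)) / total


def label(bwd: float, boundary: float = BOUNDARY_DEFAULT) -> int:
    """1 (frustrated) when BWDistance exceeds the boundary, else 0 (quenched).

    A pair exactly on the boundary is labeled quenched: rejecting a
    borderline catalyst is cheaper than accepting a dead one.
    """
    if bwd <= 0:
        raise QuenchModelError("bwdistance must be positive")
    return 1 if bwd > boundary else 0


def train_classifier(ds: QuenchDataset, seed: int,
                     n_estimators: int = 200) -> RandomForestClassifier:
    """Fit the random-forest quench classifier on the 8 buried-volume features."""
    y = ds.y()
    if len(set(y.tolist())) < 2:
        raise QuenchModelError("training requires both classes present")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(ds.X(), y)
    return clf


def cross_validate(ds: QuenchDataset, k: int = 20, seed: int = 0,
                   n_estimators: int = 200) -> dict:
    """Stratified k-fold cross-validated accuracy of the quench classifier.

    Falls back to unstratified folds when ``k`` exceeds the minority-class
    count (e.g. leave-one-out). Returns mean, std and the per-fold scores.
    """
    n = len(ds.samples)
    if k > n:
        raise QuenchModelError(f"k={k} exceeds the {n} samples")
    if k < 2:
        raise QuenchModelError("k must be at least 2")
    y = ds.y()
    minority = min(np.bincount(y))
    if k <= minority:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    fold_scores = cross_val_score(clf, ds.X(), y, cv=cv, scoring="accuracy")
    return {"mean": float(fold_scores.mean()), "std": float(fold_scores.std()),
            "fold_scores": [float(s) for s in fold_scores], "k": k}


def predict_q(features, model: RandomForestClassifier) -> int:
    """Binary quench index for one pair (majority vote of the forest)."""
    feats = np.asarray(features, dtype=float).ravel()
    if feats.shape[0] != N_FEATURES:
        raise QuenchModelError(f"expected {N_FEATURES} features, got {feats.shape[0]}")
    return int(model.predict(feats.reshape(1, -1))[0])
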