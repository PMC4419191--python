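"""One-dimensional self-organizing maps for intensity-profile clustering.

A 1D-SOM arranges K prototype profiles along a chain; batch training pulls
each prototype toward the profiles assigned to it and, through a Gaussian
neighborhood on the chain index, toward the profiles of nearby prototypes.
The result is a topology-preserving clustering: similar condition-mean
profiles end up in neighboring clusters, so the ordered prototype heatmap
reads like a smooth catalogue of intensity patterns.

Training is deterministic given the seed.  The neighborhood width sigma
decays geometrically from ``sigma0`` (default K/4) to ``sigmaf`` over the
epochs; at sigma -> 0 the update reduces to batch k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .defaults import SOM_K

__all__ = ["SOMModel", "train_1dsom", "assign_clusters", "cluster_composition"]


@dataclass
class SOMModel:
    """Trained 1D-SOM: ordered prototypes and feature -> cluster assignment.

    Cluster indices are 1-based positions along the prototype chain.
    """

    prototypes: np.ndarray  # K×C
    assignment: np.ndarray  # length F, values 1..K
    epochs: int
    sigma0: float
    sigmaf: float
    seed: int

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]

    def quantization_error(self, profiles: np.ndarray) -> float:
        d = cdist(np.asarray(profiles, float), self.prototypes, "sqeuclidean")
        return float(d.min(axis=1).mean())


def _init_prototypes(
    profiles: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Linear chain between the two most distant profiles of a seeded subsample."""
    F = profiles.shape[0]
    sub = profiles[rng.choice(F, size=min(F, 1000), replace=False)]
    d = cdist(sub, sub)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    if k == 1:
        return sub[[i]].copy()
    t = np.linspace(0.0, 1.0, k)[:, None]
    return (1 - t) * sub[i] + t * sub[j]


def train_1dsom(
    profiles: np.ndarray,
    k: int = SOM_K,
    epochs: int = 50,
    sigma0: float | None = None,
    sigmaf: float = 0.5,
    seed: int = 0,
) -> SOMModel:
    """Batch-train a 1D-SOM on F×C profiles (typically unit-norm condition means)."""
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    F, C = x.shape
    if F < 1 or k < 1:
        raise ValueError("need at least one profile and one prototype")
    if C < 2:
        raise ValueError("profiles need at least two conditions")
    if k > F:
        warnings.warn(
            f"more prototypes ({k}) than profiles ({F}); some clusters will be empty",
            UserWarning,
            stacklevel=2,
        )
    if sigma0 is None:
        sigma0 = k / 4.0
    sigma0 = max(float(sigma0), 1e-12)
    sigmaf = max(float(sigmaf), 1e-12)

    rng = np.random.default_rng(seed)
    w = _init_prototypes(x, k, rng)
    idx = np.arange(k)
    for e in range(epochs):
        frac = e / max(epochs - 1, 1)
        sigma = sigma0 * (sigmaf / sigma0) ** frac
        bmu = cdist(x, w, "sqeuclidean").argmin(axis=1)
        h = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * sigma**2))
        weights = h[:, bmu]  # K×F
        denom = weights.sum(axis=1)
        new_w = w.copy()  # empty clusters keep their previous prototype
        nz = denom > 1e-300
        new_w[nz] = (weights[nz] @ x) / denom[nz, None]
        w = new_w
    assignment = cdist(x, w, "sqeuclidean").argmin(axis=1) + 1
    return SOMModel(
        prototypes=w,
        assignment=assignment,
        epochs=epochs,
        sigma0=sigma0,
        sigmaf=sigmaf,
        seed=seed,
    )


def assign_clusters(model: SOMModel, profiles: np.ndarray) -> np.ndarray:
    """Nearest-prototype assignment (1-based); ties go to the lowest index."""
    x = np.atleast_2d(np.asarray(profiles, dtype=float))
    if x.shape[1] != model.prototypes.shape[1]:
        raise ValueError("profile dimensionality does not match the model")
    return cdist(x, model.prototypes, "sqeuclidean").argmin(axis=1) + 1


def cluster_composition(
    assignment: np.ndarray, provenance: Sequence[str], k: int | None = None
) -> pd.DataFrame:
    """Per-cluster feature counts and fractions by source kind.

    Mirrors the stacked bar plot under the prototype heatmap: for each
    non-empty cluster, which fraction of its rows comes from each omics
    kind.  Empty clusters are reported with zero counts and no fractions.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(provenance):
        raise ValueError("assignment and provenance lengths differ")
    if k is None:
        k = int(assignment.max()) if len(assignment) else 0
    kinds = sorted(set(provenance))
    rows = []
    for c in range(1, k + 1):
        in_c = assignment == c
        total = int(in_c.sum())
        row: dict[str, object] = {"cluster": c, "n": total}
        for kind in kinds:
            cnt = int(np.sum(in_c & (np.asarray(provenance) == kind)))
            row[f"n_{kind}"] = cnt
            row[f"frac_{kind}"] = cnt / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
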