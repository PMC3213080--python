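"""Growth-pattern clustering of sensitive strains at a focal dose.

Sensitive strains show qualitatively distinct growth trajectories at the
mid-range dose (default 0.008% MMS): some grow with no drug-induced lag but
a reduced plateau, some grow slower throughout, and some sit in a very long
lag before recovering slowly.  A one-dimensional self-organizing map with
three nodes separates these modes; within each class, strains are ordered by
average-linkage hierarchical clustering for heatmap display.

Features are per-strain time profiles of blank-corrected OD at the focal
dose, normalized by the strain's own untreated plateau, averaged over
QC-passing replicates.

The SOM here is deliberately minimal and fully deterministic: a 3x1 node
chain, Gaussian neighborhood, linearly decaying learning rate and radius,
node initialization from seeded random data rows, and re-seeding of any node
that ends up empty from the farthest member of the largest node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .dose_response import StrainSummary
from .growth_metrics import plateau as plateau_of
from .plate_io import GrowthCurve

logger = logging.getLogger(__name__)

DEFAULT_FOCAL_DOSE = 0.008


@dataclass(frozen=True)
class SOMParams:
    n_classes: int = 3
    epochs: int = 1000
    lr_start: float = 0.5
    lr_end: float = 0.01
    radius_start: float = 1.0
    radius_end: float = 0.1


@dataclass
class FeatureMatrix:
    strain_ids: list[str]
    times: np.ndarray
    features: np.ndarray  # shape (n_strains, n_times)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.strain_ids):
            raise ValueError("features must be (n_strains, n_times)")


@dataclass
class SOMResult:
    assignments: dict[str, int]          # strain -> class label in {1, 2, 3}
    prototypes: np.ndarray               # (n_classes, n_times) node weights
    class_curves: np.ndarray             # (n_classes, n_times) mean member curve
    seed: int
    params: SOMParams
    degenerate: bool = False


def build_features(
    summaries: Mapping[str, StrainSummary],
    curves: Sequence[GrowthCurve],
    focal_dose: float = DEFAULT_FOCAL_DOSE,
) -> FeatureMatrix:
    """Assemble plateau-normalized mean profiles at the focal dose.

    A strain enters the matrix when it has at least one curve at the focal
    dose and a positive untreated plateau; others are excluded with a
    warning.  Internal missing time points are linearly interpolated onto
    the union grid.
    """
    by_strain_focal: dict[str, list[GrowthCurve]] = {}
    by_strain_untreated: dict[str, list[GrowthCurve]] = {}
    for c in curves:
        if c.strain_id not in summaries:
            continue
        if float(c.dose) == float(focal_dose):
            by_strain_focal.setdefault(c.strain_id, []).append(c)
        if float(c.dose) == 0.0:
            by_strain_untreated.setdefault(c.strain_id, []).append(c)

    grid = np.unique(np.concatenate([c.times for cs in by_strain_focal.values() for c in cs])) \
        if by_strain_focal else np.array([])

    ids, rows = [], []
    for strain in sorted(summaries):
        focal = by_strain_focal.get(strain)
        untreated = by_strain_untreated.get(strain)
        if not focal or not untreated:
            logger.warning("strain %s: no curve at dose %g; excluded from clustering",
                           strain, focal_dose)
            continue
        p0 = float(np.mean([plateau_of(c.od) for c in untreated]))
        if p0 <= 0:
            logger.warning("strain %s: non-positive untreated plateau; excluded", strain)
            continue
        profs = [np.interp(grid, c.times, c.od) for c in focal]
        rows.append(np.mean(profs, axis=0) / p0)
        ids.append(strain)
    return FeatureMatrix(ids, grid, np.array(rows).reshape(len(ids), -1))


def train_som(
    features: FeatureMatrix,
    params: SOMParams | None = None,
    seed: int = 0,
) -> SOMResult:
    """Train the 3x1 SOM and assign each strain to its best-matching node.

    Fully deterministic given (features, seed, params): node weights start
    from seeded random data rows; each epoch presents all rows in a seeded
    random order; learning rate and neighborhood radius decay linearly.
    Nodes left empty after training are re-seeded from the farthest member
    of the largest node and the result is flagged degenerate.
    """
    params = params or SOMParams()
    X = features.features
    n, d = X.shape
    k = params.n_classes
    if n < k:
        raise ValueError(f"need at least {k} strains, got {n}")
    rng = np.random.default_rng(seed)
    weights = X[rng.choice(n, size=k, replace=False)].astype(float).copy()
    node_pos = np.arange(k, dtype=float)

    for epoch in range(params.epochs):
        frac = epoch / max(1, params.epochs - 1)
        lr = params.lr_start + frac * (params.lr_end - params.lr_start)
        radius = params.radius_start + frac * (params.radius_end - params.radius_start)
        for i in rng.permutation(n):
            x = X[i]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            h = np.exp(-((node_pos - node_pos[bmu]) ** 2) / (2.0 * radius ** 2))
            weights += lr * h[:, None] * (x - weights)

    bmus = np.argmin(
        ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2), axis=1
    )

    degenerate = False
    for node in range(k):
        if np.any(bmus == node):
            continue
        degenerate = True
        largest = int(np.bincount(bmus, minlength=k).argmax())
        members = np.nonzero(bmus == largest)[0]
        far = members[
            int(np.argmax(((X[members] - weights[largest]) ** 2).sum(axis=1)))
        ]
        weights[node] = X[far]
        bmus = np.argmin(
            ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2), axis=1
        )

    assignments = {s: int(b) + 1 for s, b in zip(features.strain_ids, bmus)}
    class_curves = np.vstack(
        [
            X[bmus == node].mean(axis=0) if np.any(bmus == node) else weights[node]
            for node in range(k)
        ]
    )
    return SOMResult(assignments, weights, class_curves, seed, params, degenerate)


def order_within_class(
    features: FeatureMatrix, assignments: Mapping[str, int]
) -> dict[int, list[str]]:
    """Heatmap row order: average-linkage leaf order within each class,
    ties broken by strain id."""
    idx = {s: i for i, s in enumerate(features.strain_ids)}
    order: dict[int, list[str]] = {}
    for label in sorted(set(assignments.values())):
        members = sorted(s for s, l in assignments.items() if l == label)
        if len(members) <= 1:
            order[label] = members
            continue
        sub = features.features[[idx[s] for s in members]]
        z = linkage(pdist(sub, metric="euclidean"), method="average")
        order[label] = [members[i] for i in leaves_list(z)]
    return order


def summarize_classes(
    assignments: Mapping[str, int], summaries: Mapping[str, StrainSummary]
) -> dict[int, dict[str, float | int | None]]:
    """Per-class GI50 mean, sd and member count (sd None for singletons)."""
    out: dict[int, dict[str, float | int | None]] = {}
    for label in sorted(set(assignments.values())):
        gi50s = [
            summaries[s].gi50_mean
            for s, l in assignments.items()
            if l == label and s in summaries and summaries[s].gi50_mean is not None
        ]
        arr = np.array(gi50s, dtype=float)
        out[label] = {
            "n": len(gi50s),
            "gi50_mean": float(arr.mean()) if arr.size else None,
            "gi50_sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
        }
    return out
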