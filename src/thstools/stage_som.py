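"""Desiccation-stage classification of OJIP transients with a hexagonal SOM.

A Kohonen self-organizing map is trained on fast chlorophyll-a fluorescence
transients (min–max normalized per curve), its nodes are then labelled by
majority vote of the mapped training curves, and new transients are assigned
the label of their best-matching unit.  This is the two-layer construction —
competitive prototype layer plus a label layer with predefined stage nodes —
used to gate leaf sampling by photosynthetic stress state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import CONDITIONS

#: stage order used for deterministic tie-breaking (earlier stage wins)
STAGE_ORDER = {s: i for i, s in enumerate(CONDITIONS)}


@dataclass
class OJIPCurve:
    """One fast-fluorescence transient on a shared log-time grid."""

    times: np.ndarray
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("fluorescence values must be non-negative")


@dataclass
class SOMParams:
    """Training schedule; linear decays over ``epochs``.

    ``radius_start``/``radius_end`` default to None, meaning they are
    resolved against the lattice at training time: grids of 3x3 and larger
    use half the grid diameter capped at 2.0 (the 4x4 default grid resolves
    to the standard 2.0 -> 0.5 schedule); a minimal 2x2 map uses a sub-unit
    neighbourhood (0.4 -> 0.2), since a Gaussian wider than the whole
    lattice drags all four prototypes together and leaves dead units.
    """

    epochs: int = 500
    lr_start: float = 0.5
    lr_end: float = 0.01
    radius_start: float | None = None
    radius_end: float | None = None
    seed: int = 0


@dataclass
class SOMModel:
    """Trained hexagonal map: prototypes plus per-node stage labels."""

    grid_shape: tuple[int, int]
    prototypes: np.ndarray  # (n_nodes, dim), row-major (row, col) order
    node_labels: list[str]
    params: SOMParams
    qe_history: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def node_rc(self, index: int) -> tuple[int, int]:
        return divmod(index, self.grid_shape[1])

    def to_json(self) -> str:
        return json.dumps({
            "grid_shape": list(self.grid_shape),
            "prototypes": self.prototypes.tolist(),
            "node_labels": self.node_labels,
            "params": self.params.__dict__,
            "qe_history": self.qe_history,
        })

    @classmethod
    def from_json(cls, text: str) -> "SOMModel":
        d = json.loads(text)
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            prototypes=np.array(d["prototypes"], dtype=float),
            node_labels=list(d["node_labels"]),
            params=SOMParams(**d["params"]),
            qe_history=list(d["qe_history"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        return cls.from_json(Path(path).read_text())


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Per-curve min–max scaling; flat curves map to all-zeros.

    Fluorescence amplitude depends on leaf optics, so only the shape of the
    transient is classified.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _hex_positions(grid_shape: tuple[int, int]) -> np.ndarray:
    """2-D plane coordinates of a pointy-top hexagonal lattice (odd rows
    shifted half a unit)."""
    rows, cols = grid_shape
    pos = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * math.sqrt(3) / 2)
    return pos


def train_som(
    curves: Sequence[OJIPCurve],
    grid_shape: tuple[int, int] = (4, 4),
    params: SOMParams | None = None,
) -> SOMModel:
    """Train the map on labelled transients and label its nodes.

    Classical online Kohonen updates: Euclidean best-matching unit, Gaussian
    neighbourhood on the hexagonal lattice, linearly decaying radius and
    learning rate.  Prototypes are initialized from randomly chosen training
    curves (seeded).  After training each node takes the majority label of
    the curves mapped to it; ties break toward the earlier desiccation stage
    and nodes with no mapped curves inherit the label of the nearest (in
    prototype space) labelled node.
    """
    params = params or SOMParams()
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    labels = [c.label for c in curves]
    if any(lab is None for lab in labels):
        raise ValueError("training curves must be labelled")
    present = set(labels)
    missing = set(CONDITIONS) - present
    if missing:
        raise ValueError(f"no training curves for stage(s): {sorted(missing)}")
    grid0 = curves[0].times
    for c in curves[1:]:
        if c.times.shape != grid0.shape or not np.allclose(c.times, grid0):
            raise ValueError("all curves must share one time grid")

    X = np.stack([minmax_normalize(c.values) for c in curves])
    n, dim = X.shape
    n_nodes = rows * cols
    rng = np.random.default_rng(params.seed)
    init_idx = rng.choice(n, size=n_nodes, replace=n_nodes > n)
    protos = X[init_idx].copy()

    pos = _hex_positions(grid_shape)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    half_diameter = math.sqrt(grid_d2.max()) / 2.0
    small_grid = max(rows, cols) <= 2
    r_start = params.radius_start
    if r_start is None:
        r_start = 0.4 if small_grid else min(2.0, half_diameter)
    r_end = params.radius_end
    if r_end is None:
        r_end = 0.2 if small_grid else min(0.5, r_start / 2.0)

    qe_history: list[float] = []
    for epoch in range(params.epochs):
        frac = epoch / max(params.epochs - 1, 1)
        lr = params.lr_start + frac * (params.lr_end - params.lr_start)
        radius = r_start + frac * (r_end - r_start)
        order = rng.permutation(n)
        qe = 0.0
        for i in order:
            x = X[i]
            d2 = ((protos - x) ** 2).sum(axis=1)
            bmu = int(np.argmin(d2))  # first index wins ties: (row, col) order
            qe += math.sqrt(d2[bmu])
            h = np.exp(-grid_d2[bmu] / (2.0 * radius * radius))
            protos += (lr * h)[:, None] * (x - protos)
        qe_history.append(qe / n)

    # label layer: majority vote per node
    votes: dict[int, dict[str, int]] = {}
    for i in range(n):
        d2 = ((protos - X[i]) ** 2).sum(axis=1)
        bmu = int(np.argmin(d2))
        votes.setdefault(bmu, {}).setdefault(labels[i], 0)
        votes[bmu][labels[i]] += 1
    node_labels: list[str | None] = [None] * n_nodes
    for node, counts in votes.items():
        best = max(counts.items(), key=lambda kv: (kv[1], -STAGE_ORDER[kv[0]]))
        node_labels[node] = best[0]
    labelled = [i for i, lab in enumerate(node_labels) if lab is not None]
    for node in range(n_nodes):
        if node_labels[node] is None:
            d2 = ((protos[labelled] - protos[node]) ** 2).sum(axis=1)
            node_labels[node] = node_labels[labelled[int(np.argmin(d2))]]

    return SOMModel(grid_shape, protos, node_labels, params, qe_history)


def best_matching_unit(model: SOMModel, values: np.ndarray) -> int:
    """Index of the node with minimal Euclidean distance to the (normalized)
    curve; ties break by (row, col) order."""
    x = minmax_normalize(values)
    if x.shape[0] != model.prototypes.shape[1]:
        raise ValueError(
            f"curve has {x.shape[0]} points but the map expects "
            f"{model.prototypes.shape[1]}"
        )
    d2 = ((model.prototypes - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def classify_stage(model: SOMModel, curve: OJIPCurve | np.ndarray) -> str:
    """Stage label of the best-matching unit."""
    values = curve.values if isinstance(curve, OJIPCurve) else np.asarray(curve)
    return model.node_labels[best_matching_unit(model, values)]
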