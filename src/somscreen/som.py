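"""Self-organizing map on a hexagonal grid.

The map is an n x n grid of nodes, each holding a weight vector m_c of the
same dimension as the input panel.  Training pulls the weight vectors
toward the data while a shrinking neighborhood kernel on the grid keeps
nearby nodes similar, so the trained map is a topology-preserving 2-D
projection of the measurement space.

Fit quality is summarized by the average quantization error

    eps_q = (1/N) * sum_i || x_i - m_{bmu(x_i)} ||

the mean Euclidean distance from each of the N data samples to the weight
vector of its best matching node.  Because random initialization makes
every run slightly different, an experiment trains several maps from
consecutive seeds and keeps the one with the smallest eps_q, breaking ties
by the number of mixed-class nodes, then by the number of measurements in
mixed nodes, then by seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import hexgrid


def choose_grid_side(n_mice: int) -> int:
    """Smallest n such that an n x n grid has at least one node per mouse.

    Sized so that, absent real cluster structure, each mouse's replicate
    measurements could occupy a node of their own and no artificial
    grouping is forced.  Callers may override (experiments occasionally
    pick a larger map to spread the data out).
    """
    if n_mice < 1:
        raise ValueError("need at least one mouse")
    side = int(np.ceil(np.sqrt(n_mice)))
    while side * side < n_mice:  # guard against float edge cases
        side += 1
    while side > 1 and (side - 1) * (side - 1) >= n_mice:
        side -= 1
    return side


@dataclass
class TrainingParams:
    """Schedule and kernel for SOM training.

    Defaults: 400 batch epochs with a gaussian neighborhood whose radius
    decays exponentially from side/2 down to 0.25 grid units.  The small
    terminal radius matters statistically: the grid is sized so each mouse
    can occupy a node of its own, and the downstream rank-sum test treats
    node weight vectors as (approximately) independent per-mouse
    prototypes.  A terminal kernel still coupling adjacent nodes would
    shrink same-class prototypes toward each other and inflate the test.
    The online scheme additionally uses a learning rate decaying from
    ``initial_rate`` to ``final_rate``.
    """

    epochs: int = 400
    scheme: str = "batch"            # "batch" | "online"
    initial_radius: float | None = None   # default side/2
    final_radius: float = 0.25
    initial_rate: float = 0.5
    final_rate: float = 0.01
    neighborhood: str = "gaussian"   # "gaussian" | "bubble"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.scheme not in ("batch", "online"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.neighborhood not in ("gaussian", "bubble"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.initial_radius is not None and self.initial_radius < self.final_radius:
            raise ValueError("initial_radius must be >= final_radius")
        if self.final_radius <= 0:
            raise ValueError("final_radius must be positive")
        if not (0 < self.initial_rate <= 1 and 0 < self.final_rate <= 1):
            raise ValueError("rates must lie in (0, 1]")


@dataclass
class SOMap:
    """A trained (or freshly initialized) hexagonal SOM."""

    side: int
    weights: np.ndarray            # (side^2, d), row-major node order
    seed: int
    params: TrainingParams
    trained: bool = False

    @property
    def n_nodes(self) -> int:
        return self.side * self.side

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def node_weight(self, coord: tuple[int, int]) -> np.ndarray:
        return self.weights[hexgrid.node_index(coord, self.side)]


def _check_data(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a non-empty 2-D matrix")
    if not np.isfinite(data).all():
        raise ValueError("data contains non-finite values")
    return data


def _radius_schedule(params: TrainingParams, side: int) -> np.ndarray:
    r0 = params.initial_radius if params.initial_radius is not None else max(side / 2.0, 1.0)
    r1 = params.final_radius
    T = params.epochs
    if T == 1:
        return np.array([r0])
    t = np.arange(T) / (T - 1)
    return r0 * (r1 / r0) ** t


def _kernel(dist: np.ndarray, radius: float, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return np.exp(-(dist ** 2) / (2.0 * radius ** 2))
    return (dist <= radius).astype(float)


def train(data: np.ndarray, side: int,
          params: TrainingParams | None = None, seed: int = 0) -> SOMap:
    """Train a hexagonal SOM on a [0,1]-normalized data matrix.

    Weights start uniform in [0,1]^d from a generator seeded with ``seed``,
    so the result is fully determined by (data, params, seed).  Batch
    training recomputes every node as the kernel-weighted mean of the
    samples around its winners each epoch; online training applies the
    classic per-sample Kohonen update in a seeded shuffled order.
    """
    data = _check_data(data)
    if side < 1:
        raise ValueError("side must be >= 1")
    params = params or TrainingParams()
    rng = np.random.default_rng(seed)
    n_nodes = side * side
    d = data.shape[1]
    weights = rng.random((n_nodes, d))
    gdist = hexgrid.grid_distances(side)
    radii = _radius_schedule(params, side)

    if params.scheme == "batch":
        for radius in radii:
            bmu = np.argmin(cdist(data, weights), axis=1)
            h = _kernel(gdist[:, bmu], radius, params.neighborhood)  # (nodes, samples)
            denom = h.sum(axis=1)
            numer = h @ data
            upd = denom > 1e-12
            weights[upd] = numer[upd] / denom[upd, None]
    else:
        rates = params.initial_rate * (
            params.final_rate / params.initial_rate) ** (
            np.arange(params.epochs) / max(params.epochs - 1, 1))
        for radius, rate in zip(radii, rates):
            for i in rng.permutation(data.shape[0]):
                x = data[i]
                b = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
                h = _kernel(gdist[:, b], radius, params.neighborhood)
                weights += rate * h[:, None] * (x - weights)

    return SOMap(side=side, weights=weights, seed=seed, params=params, trained=True)


def bmu_indices(som: SOMap, data: np.ndarray) -> np.ndarray:
    """Row-major node index of the best matching node of every sample.

    Ties in distance resolve to the row-major-earlier node (argmin picks
    the first minimum).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != som.dim:
        raise ValueError(f"dimension mismatch: {data.shape[1]} != {som.dim}")
    return np.argmin(cdist(data, som.weights), axis=1)


def best_matching_node(som: SOMap, x: np.ndarray) -> tuple[int, int]:
    """Grid coordinate of the node whose weight vector is nearest to x."""
    idx = int(bmu_indices(som, np.asarray(x, dtype=float)[None, :])[0])
    return hexgrid.node_coord(idx, som.side)


def quantization_error(som: SOMap, data: np.ndarray) -> float:
    """Average distance from each data sample to its best matching node."""
    data = _check_data(data)
    if data.shape[1] != som.dim:
        raise ValueError("dimension mismatch")
    dists = cdist(data, som.weights)
    return float(dists.min(axis=1).mean())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_map(som: SOMap, path) -> None:
    """Write a map as a JSON header line followed by one whitespace-separated
    row per node: row index, column index, then the weight components."""
    import json
    from dataclasses import asdict

    lines = [json.dumps({"side": som.side, "seed": som.seed,
                         "trained": som.trained,
                         "params": asdict(som.params)}, sort_keys=True)]
    for i in range(som.n_nodes):
        r, c = hexgrid.node_coord(i, som.side)
        lines.append(" ".join([str(r), str(c)] +
                              [repr(float(v)) for v in som.weights[i]]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_map(path) -> SOMap:
    """Inverse of :func:`save_map`; exact for weights written with repr."""
    import json

    with open(path) as fh:
        header = json.loads(fh.readline())
        rows = [line.split() for line in fh if line.strip()]
    side = int(header["side"])
    weights = np.full((side * side, len(rows[0]) - 2), np.nan)
    for parts in rows:
        idx = hexgrid.node_index((int(parts[0]), int(parts[1])), side)
        weights[idx] = [float(v) for v in parts[2:]]
    return SOMap(side=side, weights=weights, seed=int(header["seed"]),
                 params=TrainingParams(**header["params"]),
                 trained=bool(header["trained"]))


# ---------------------------------------------------------------------------
# multi-run selection
# ---------------------------------------------------------------------------

@dataclass
class RunRecord:
    seed: int
    som: SOMap
    epsilon_q: float
    n_mixed_nodes: int
    n_measurements_in_mixed: int


@dataclass
class RunSelection:
    runs: list[RunRecord]
    best_index: int

    @property
    def best(self) -> RunRecord:
        return self.runs[self.best_index]

    def table(self):
        """Run summary in the conventional schema: quantization error,
        number of mixed-class nodes, measurements in mixed nodes."""
        import pandas as pd
        return pd.DataFrame({
            "run": np.arange(1, len(self.runs) + 1),
            "seed": [r.seed for r in self.runs],
            "avg_quantization_error": [r.epsilon_q for r in self.runs],
            "n_mixed_nodes": [r.n_mixed_nodes for r in self.runs],
            "n_measurements_in_mixed": [r.n_measurements_in_mixed for r in self.runs],
        })


def select_best(records: Sequence[RunRecord]) -> int:
    """Index minimizing (eps_q, mixed nodes, measurements in mixed, seed)."""
    if not records:
        raise ValueError("no runs")
    keys = [(r.epsilon_q, r.n_mixed_nodes, r.n_measurements_in_mixed, r.seed)
            for r in records]
    return min(range(len(records)), key=keys.__getitem__)


def multi_run_select(data: np.ndarray, labels: Sequence[str], side: int,
                     n_runs: int = 10, params: TrainingParams | None = None,
                     base_seed: int = 1) -> RunSelection:
    """Train ``n_runs`` maps from consecutive seeds and keep the best.

    ``labels`` are per-row class codes, used only to count mixed-class
    nodes for the tie-break (never during training).
    """
    from . import maps as _maps  # runtime import; maps builds on this module

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    data = _check_data(data)
    labels = list(labels)
    if len(labels) != data.shape[0]:
        raise ValueError("labels length mismatch")
    records: list[RunRecord] = []
    for k in range(n_runs):
        seed = base_seed + k
        som = train(data, side, params=params, seed=seed)
        eps = quantization_error(som, data)
        assignment = _maps.assign_measurements(som, data, labels)
        lmap = _maps.label_nodes(assignment)
        n_mixed, n_meas = _maps.mixed_node_stats(lmap)
        records.append(RunRecord(seed, som, eps, n_mixed, n_meas))
    return RunSelection(runs=records, best_index=select_best(records))
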