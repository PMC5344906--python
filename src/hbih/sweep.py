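"""Parameter-sweep engine: 1-D ISI-bifurcation diagrams and 1/2-D maps
of firing rate, pattern code, Lyapunov exponents, Lempel-Ziv complexity
and distinct-ISI counts.

Every grid point is simulated independently from the deterministic
default initial state — there is no state carry-over between points, so
results cannot depend on the direction the parameter axis is traversed.
Per-point randomness (the MLE perturbation direction) is seeded from the
grid seed and the point's coordinates, which makes tables bit-identical
regardless of worker count or execution order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .chaos import EmbeddingConfig, binarize, isi_lyapunov, lempel_ziv, mle_ode
from .integrate import DEFAULT_DT, DEFAULT_EQUILIBRATION, IntegrationError, simulate
from .model import ModelParameters
from .slow_analysis import count_distinct_intervals
from .spikes import classify_pattern, detect_spikes, isi

__all__ = ["SweepGrid", "run_sweep", "isi_bifurcation"]

_KNOWN_MEASURES = {"rate", "pattern", "mle", "isile", "lz", "n_isi_clusters"}


@dataclass
class SweepGrid:
    """A 1- or 2-axis parameter grid plus the simulation protocol.

    ``axes`` maps parameter names to ``(start, stop, step)`` (inclusive
    grids); ``overrides`` are fixed parameter replacements applied on top
    of the defaults; ``measures`` selects what is computed per point.
    """

    axes: dict[str, tuple[float, float, float]]
    overrides: dict[str, float] = field(default_factory=dict)
    measures: tuple[str, ...] = ("rate", "pattern")
    duration: float = 150_000.0
    dt: float = DEFAULT_DT
    equilibration: float = DEFAULT_EQUILIBRATION
    record_stride: int = 80
    slow_only: bool = False
    seed: int = 0
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    mle_time: float = 100_000.0

    def __post_init__(self):
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("grids must have 1 or 2 axes")
        valid = {f.name for f in ModelParameters.__dataclass_fields__.values()}
        for name in list(self.axes) + list(self.overrides):
            if name not in valid:
                raise ValueError(f"unknown parameter {name!r}")
        unknown = set(self.measures) - _KNOWN_MEASURES
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        for name, (start, stop, step) in self.axes.items():
            if step <= 0:
                raise ValueError(f"axis {name!r} must have step > 0")

    def axis_values(self, name: str) -> np.ndarray:
        start, stop, step = self.axes[name]
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return start + step * np.arange(n)

    def points(self):
        names = list(self.axes)
        grids = [self.axis_values(n) for n in names]
        for idx in itertools.product(*(range(len(g)) for g in grids)):
            yield idx, {n: float(g[i]) for n, g, i in zip(names, grids, idx)}

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["embedding"] = asdict(self.embedding)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SweepGrid":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if "embedding" in d:
            d["embedding"] = EmbeddingConfig(
                **{k: tuple(v) if k == "dims" else v
                   for k, v in d["embedding"].items()}
            )
        d["axes"] = {k: tuple(v) for k, v in d["axes"].items()}
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        return cls(**d)


def _point_seed(grid_seed: int, idx: tuple[int, ...]) -> int:
    ss = np.random.SeedSequence([int(grid_seed)] + [int(i) for i in idx])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _evaluate_point(grid: SweepGrid, idx, coords) -> dict:
    row: dict = dict(coords)
    row.update(status="ok", n_spikes=0, rate=np.nan, pattern=None,
               spikes_per_burst=None, mle=np.nan, isile=np.nan,
               isile_significant=False, lz=np.nan, n_isi_clusters=None)
    params = ModelParameters().replace(**{**grid.overrides, **coords})
    try:
        traj = simulate(
            params,
            duration=grid.duration,
            dt=grid.dt,
            equilibration=grid.equilibration,
            slow_only=grid.slow_only,
            record_stride=grid.record_stride,
        )
    except IntegrationError as exc:
        row["status"] = f"blow-up: {exc}"
        return row
    train = detect_spikes(traj)
    intervals = isi(train)
    row["n_spikes"] = len(train)
    row["rate"] = train.rate
    row["_isis"] = intervals
    if "pattern" in grid.measures:
        code = classify_pattern(traj, train, min_duration=min(30_000.0, grid.duration))
        row["pattern"] = code.code
        row["spikes_per_burst"] = code.spikes_per_burst
    if "n_isi_clusters" in grid.measures and len(intervals) >= 10:
        row["n_isi_clusters"] = count_distinct_intervals(intervals)
    if "isile" in grid.measures:
        res = isi_lyapunov(intervals, grid.embedding)
        row["isile"] = res.value
        row["isile_significant"] = res.significant
    if "lz" in grid.measures and len(train) >= 3:
        word, _ = binarize(train.spike_times, duration=traj.duration,
                           t_start=float(traj.times[0]))
        row["lz"] = lempel_ziv(word).normalized
    if "mle" in grid.measures:
        row["mle"] = mle_ode(
            params,
            total_time=grid.mle_time,
            dt=grid.dt,
            equilibration=grid.equilibration,
            slow_only=grid.slow_only,
            seed=_point_seed(grid.seed, idx),
        ).value
    return row


def run_sweep(grid: SweepGrid, n_jobs: int = 1, keep_isis: bool = False) -> pd.DataFrame:
    """Evaluate every grid point; one row per point, in grid order.

    Failed points are recorded with a non-"ok" status rather than
    aborting the sweep.  ``keep_isis`` retains the per-point ISI array in
    a ``_isis`` column (used by :func:`isi_bifurcation`).
    """
    tasks = list(grid.points())
    rows = Parallel(n_jobs=n_jobs)(
        delayed(_evaluate_point)(grid, idx, coords) for idx, coords in tasks
    )
    table = pd.DataFrame(rows)
    if not keep_isis and "_isis" in table.columns:
        table = table.drop(columns=["_isis"])
    return table


def isi_bifurcation(grid: SweepGrid, n_jobs: int = 1) -> pd.DataFrame:
    """Long-format ISI bifurcation table for a single-axis grid.

    One row per (axis value, individual ISI), carrying the point's
    interval-series Lyapunov exponent for coloring scatter plots.
    """
    if len(grid.axes) != 1:
        raise ValueError("isi_bifurcation needs a single-axis grid")
    axis = next(iter(grid.axes))
    measures = set(grid.measures) | {"isile"}
    grid = SweepGrid(**{**asdict_shallow(grid), "measures": tuple(measures)})
    table = run_sweep(grid, n_jobs=n_jobs, keep_isis=True)
    rows = []
    for _, r in table.iterrows():
        for value in np.atleast_1d(r.get("_isis", np.empty(0))):
            rows.append(
                {
                    axis: r[axis],
                    "isi": float(value),
                    "isile": r["isile"],
                    "isile_significant": r["isile_significant"],
                }
            )
    return pd.DataFrame(rows, columns=[axis, "isi", "isile", "isile_significant"])


def asdict_shallow(grid: SweepGrid) -> dict:
    return {
        "axes": grid.axes,
        "overrides": grid.overrides,
        "measures": grid.measures,
        "duration": grid.duration,
        "dt": grid.dt,
        "equilibration": grid.equilibration,
        "record_stride": grid.record_stride,
        "slow_only": grid.slow_only,
        "seed": grid.seed,
        "embedding": grid.embedding,
        "mle_time": grid.mle_time,
    }
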