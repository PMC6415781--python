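"""End-to-end pipeline: input or simulation -> adjacency -> spectrum -> tree.

A :class:`RunConfig` fully determines a run (including every seed), so the
same configuration always produces byte-identical JSON reports.  Stages are
logged with their wall time; any stage failure is re-raised with the stage
name attached.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .coding import BinaryCodeTable, DendrogramTree, assign_codes, build_dendrogram
from .dissimilarity import AdjacencyMatrix, TrajectoryEnsemble, build_adjacency
from .errors import InputError, PipelineError
from .flows import (
    bickley_ensemble,
    quadruple_eddy_ensemble,
    random_noise_ensemble,
)
from .io import (
    read_adjacency,
    read_trajectories,
    write_adjacency,
    write_eigen_solution,
)
from .plotting import plot_dendrogram
from .spectral import SpectralSolution, solve_coloring

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "color_and_code"]

log = logging.getLogger("scsc")

_SIMULATORS = {
    "quadruple-eddy": lambda n, seed, kw: quadruple_eddy_ensemble(n, seed, **kw),
    "bickley": lambda n, seed, kw: bickley_ensemble(n, seed, **kw),
    "noise": lambda n, seed, kw: random_noise_ensemble(n, kw.pop("T", 500), seed),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Exactly one of ``trajectories``, ``adjacency`` or ``simulate`` must be
    given.  ``simulate`` is a mapping with keys ``system`` (one of
    ``quadruple-eddy``, ``bickley``, ``noise``), ``n``, and optional
    simulator keywords (``n_saved``, ``dt``, ``n_steps``, ``T``).
    """

    trajectories: str | None = None
    adjacency: str | None = None
    simulate: dict | None = None
    metric: str = "trajectory"
    periodic_lengths: list | None = None
    depth: int = 7
    stop_when_no_split: bool = True
    min_branch_z: float = 0.0
    seed: int = 0
    delimiter: str | None = None
    outdir: str = "."
    prefix: str = "scsc"
    plot: bool = False
    plot_labels: bool = True
    eigensolver_tol: float = 1e-8

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        sources = [
            s for s in (self.trajectories, self.adjacency, self.simulate) if s
        ]
        if len(sources) != 1:
            raise InputError(
                "exactly one of trajectories, adjacency or simulate must be set"
            )
        if self.depth < 1:
            raise InputError("depth must be >= 1")
        for p in (self.trajectories, self.adjacency):
            if p is not None and not Path(p).exists():
                raise InputError(f"input path does not exist: {p}")


@dataclass
class PipelineResult:
    ensemble: TrajectoryEnsemble | None
    adjacency: AdjacencyMatrix
    solution: SpectralSolution
    codes: BinaryCodeTable
    tree: DendrogramTree
    report: dict
    paths: dict = field(default_factory=dict)


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def color_and_code(
    A: AdjacencyMatrix,
    max_depth: int = 7,
    stop_when_no_split: bool = True,
    min_branch_z: float = 0.0,
    tol: float = 1e-8,
) -> tuple[SpectralSolution, BinaryCodeTable, DendrogramTree]:
    """Solve the coloring eigenproblem and build the coded dendrogram.

    The code depth is ``max_depth`` (capped at ``n - 1``), truncated
    earlier if an entire eigenvector level refines nothing — occupied codes
    then stop growing, the natural stopping rule.
    """
    solution = solve_coloring(A, tol=tol)
    depth = min(int(max_depth), A.n - 1)
    codes = assign_codes(solution, depth)
    if stop_when_no_split:
        strings = np.array(codes.strings)
        prev = 1
        effective = depth
        for k in range(1, depth + 1):
            distinct = np.unique([s[:k] for s in strings]).size
            if distinct == prev and k > 1:
                effective = k - 1
                break
            prev = distinct
        if effective < depth:
            codes = BinaryCodeTable(
                codes.codes[:, :effective],
                depth=effective,
                inert_levels=tuple(l for l in codes.inert_levels if l <= effective),
            )
    tree = build_dendrogram(codes, solution, A, min_branch_z=min_branch_z)
    return solution, codes, tree


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the configured analysis end to end and write all exports."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = outdir / config.prefix
    paths: dict[str, str] = {}
    ensemble = None

    with _stage("input"):
        if config.simulate is not None:
            sim = dict(config.simulate)
            system = sim.pop("system")
            n = int(sim.pop("n"))
            if system not in _SIMULATORS:
                raise InputError(
                    f"unknown system {system!r}; choose from {sorted(_SIMULATORS)}"
                )
            ensemble = _SIMULATORS[system](n, config.seed, sim)
        elif config.trajectories is not None:
            ensemble = read_trajectories(
                config.trajectories,
                delimiter=config.delimiter,
                periodic_lengths=config.periodic_lengths,
            )

    with _stage("adjacency"):
        if config.adjacency is not None:
            A = read_adjacency(config.adjacency, delimiter=config.delimiter)
        else:
            A = build_adjacency(ensemble, metric=config.metric)
            path = f"{prefix}_adjacency.csv"
            write_adjacency(A, path)
            paths["adjacency"] = path

    with _stage("spectral+coding"):
        solution, codes, tree = color_and_code(
            A,
            max_depth=config.depth,
            stop_when_no_split=config.stop_when_no_split,
            min_branch_z=config.min_branch_z,
            tol=config.eigensolver_tol,
        )

    with _stage("export"):
        eig_csv = f"{prefix}_eigen.csv"
        eig_json = f"{prefix}_eigen.json"
        write_eigen_solution(
            solution, eig_csv, eig_json, labels=A.labels, n_keep=codes.depth + 1
        )
        paths.update(eigen_csv=eig_csv, eigen_json=eig_json)
        report = tree.to_dict(labels=list(A.labels) if A.labels else None)
        report["meta"] = {
            "package_version": __version__,
            "seed": config.seed,
            "metric": config.metric,
            "depth_requested": config.depth,
            "depth_used": codes.depth,
            "inert_levels": list(codes.inert_levels),
            "min_branch_z": config.min_branch_z,
            "stop_when_no_split": config.stop_when_no_split,
            "config": {k: v for k, v in asdict(config).items()},
            "eigenvalues": solution.eigenvalues[: codes.depth + 1].tolist(),
        }
        nwk = f"{prefix}_tree.nwk"
        rep = f"{prefix}_report.json"
        Path(nwk).write_text(tree.to_newick() + "\n")
        with open(rep, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths.update(newick=nwk, report=rep)
        if config.plot:
            img = f"{prefix}_dendrogram.png"
            plot_dendrogram(
                tree, img, labels=config.plot_labels, counts=config.plot_labels
            )
            paths["plot"] = img

    return PipelineResult(
        ensemble=ensemble,
        adjacency=A,
        solution=solution,
        codes=codes,
        tree=tree,
        report=report,
        paths=paths,
    )
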