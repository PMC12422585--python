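"""On-disk formats.

A connectome is a pair of plain-text files per individual: the
adjacency as a dense CSV whose header row gives the region names (row
order equals column order) and the region metadata as a TSV with
columns name, hemisphere, system, volume, x, y, z.  A cohort adds a
manifest TSV with columns individual_id, age, path.  Trajectories go
to HDF5 (datasets E, I, times plus parameter attributes), synchrony
matrices to labelled CSV, and pattern tables to TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome, RegionInfo
from .dynamics import StateTrajectory
from .synchrony import SynchronyMatrix

__all__ = [
    "write_connectome",
    "read_connectome",
    "write_cohort",
    "read_cohort",
    "export_graphml",
    "write_trajectory",
    "read_trajectory",
    "write_synchrony_matrix",
    "read_synchrony_matrix",
]


def write_connectome(connectome: Connectome, directory) -> Path:
    """Write ``<id>_adjacency.csv`` and ``<id>_regions.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = connectome.individual_id or "connectome"
    names = [r.name for r in connectome.regions]
    adj = pd.DataFrame(connectome.weights, columns=names)
    adj.to_csv(directory / f"{stem}_adjacency.csv", index=False)
    meta = pd.DataFrame(
        {
            "name": names,
            "hemisphere": [r.hemisphere for r in connectome.regions],
            "system": [r.system for r in connectome.regions],
            "volume": [r.volume for r in connectome.regions],
            "x": [r.coordinate[0] for r in connectome.regions],
            "y": [r.coordinate[1] for r in connectome.regions],
            "z": [r.coordinate[2] for r in connectome.regions],
        }
    )
    meta.to_csv(directory / f"{stem}_regions.tsv", sep="\t", index=False)
    return directory


def read_connectome(directory, individual_id: str, age: float) -> Connectome:
    directory = Path(directory)
    adj = pd.read_csv(directory / f"{individual_id}_adjacency.csv")
    meta = pd.read_csv(directory / f"{individual_id}_regions.tsv", sep="\t")
    if list(adj.columns) != list(meta["name"]):
        raise ValueError(
            f"{individual_id}: adjacency header does not match region metadata"
        )
    regions = tuple(
        RegionInfo(
            name=row["name"],
            hemisphere=row["hemisphere"],
            system=row["system"],
            volume=row["volume"],
            coordinate=(row["x"], row["y"], row["z"]),
        )
        for _, row in meta.iterrows()
    )
    return Connectome(
        weights=adj.to_numpy(dtype=float),
        regions=regions,
        age=age,
        individual_id=individual_id,
    )


def write_cohort(cohort, directory) -> Path:
    """Write every connectome plus the manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cohort:
        write_connectome(c, directory)
        rows.append({"individual_id": c.individual_id, "age": c.age, "path": "."})
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return directory


def read_cohort(directory) -> list[Connectome]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    return [
        read_connectome(directory / row["path"], row["individual_id"], row["age"])
        for _, row in manifest.iterrows()
    ]


def export_graphml(connectome: Connectome, path) -> None:
    nx.write_graphml(connectome.to_graph(), path)


def write_trajectory(trajectory: StateTrajectory, path, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("E", data=trajectory.E, compression="gzip")
        f.create_dataset("I", data=trajectory.I, compression="gzip")
        f.create_dataset("times", data=trajectory.times)
        f.attrs["steady_start"] = trajectory.steady_slice.start or 0
        f.attrs["steady_stop"] = trajectory.steady_slice.stop
        for k, v in (attrs or {}).items():
            f.attrs[k] = json.dumps(v) if isinstance(v, (dict, list)) else v


def read_trajectory(path) -> StateTrajectory:
    with h5py.File(path, "r") as f:
        return StateTrajectory(
            E=f["E"][:],
            I=f["I"][:],
            times=f["times"][:],
            steady_slice=slice(int(f.attrs["steady_start"]), int(f.attrs["steady_stop"])),
        )


def write_synchrony_matrix(matrix: SynchronyMatrix, path) -> None:
    pd.DataFrame(matrix.R, index=matrix.systems, columns=matrix.systems).to_csv(path)


def read_synchrony_matrix(path) -> SynchronyMatrix:
    df = pd.read_csv(path, index_col=0)
    return SynchronyMatrix(
        R=df.to_numpy(dtype=float), systems=tuple(df.columns), window=0.0
    )
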