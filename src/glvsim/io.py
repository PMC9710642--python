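"""TSV readers and writers for timecourses, parameters and cohorts.

Layout conventions
------------------
* One directory per individual with per-node matrices
  ``<node>_Z.tsv`` / ``<node>_X.tsv`` / ``<node>_Y.tsv``; the first column is
  ``time``, remaining columns ``<node>_0 ... <node>_{d-1}``.  UTF-8,
  tab-delimited, ``.`` decimal separator.
* Growth rates and initial abundances: one-column-per-dimension TSV
  (a single data row) with the same column naming.
* Interaction blocks: dense TSV matrices named ``<target>__<source>.tsv``.
* Cohorts: ``cases/<k>/`` and ``controls/<k>/`` subdirectories plus
  ``response_vector.tsv`` and ``manifest.tsv`` (individual id, arm, seed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .types import InteractionMap, NodeSpec, Timecourse

__all__ = [
    "write_timecourse",
    "read_timecourse",
    "write_vector",
    "read_vector",
    "write_nodes",
    "read_nodes",
    "write_interaction_map",
    "read_interaction_map",
    "write_cohort",
    "read_cohort_arm",
]


def _node_cols(node: str, dim: int) -> list[str]:
    return [f"{node}_{i}" for i in range(dim)]


def write_timecourse(directory, tc: Timecourse) -> Path:
    """Write one individual's Z/X/Y matrices to ``directory``, one TSV per node."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for node in tc.node_names:
        sl = tc.node_slice(node)
        cols = _node_cols(node, tc.node_dims[node])
        for tag, mat in (("Z", tc.Z), ("X", tc.X), ("Y", tc.Y)):
            df = pd.DataFrame(mat[:, sl], columns=cols)
            df.insert(0, "time", tc.times)
            df.to_csv(directory / f"{node}_{tag}.tsv", sep="\t", index=False)
    return directory


def read_timecourse(directory, label: str = "") -> Timecourse:
    """Read a timecourse directory written by :func:`write_timecourse`.

    Node order is alphabetical by file name, matching how a shell lists them.
    """
    directory = Path(directory)
    z_files = sorted(directory.glob("*_Z.tsv"))
    if not z_files:
        raise ConfigurationError(f"no *_Z.tsv files found in {directory}")
    node_names = [f.name[: -len("_Z.tsv")] for f in z_files]
    mats: dict[str, list[np.ndarray]] = {"Z": [], "X": [], "Y": []}
    node_dims: dict[str, int] = {}
    times = None
    for node in node_names:
        for tag in ("Z", "X", "Y"):
            df = pd.read_csv(directory / f"{node}_{tag}.tsv", sep="\t")
            times = df["time"].to_numpy()
            mats[tag].append(df.drop(columns="time").to_numpy())
        node_dims[node] = mats["Z"][-1].shape[1]
    return Timecourse(
        node_names=node_names,
        node_dims=node_dims,
        Z=np.hstack(mats["Z"]),
        X=np.hstack(mats["X"]),
        Y=np.hstack(mats["Y"]).astype(np.int64),
        times=times,
        label=label,
    )


def write_vector(path, values: np.ndarray, node: str) -> Path:
    """Write a parameter vector as a one-row, one-column-per-dimension TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(values)
    pd.DataFrame([values], columns=_node_cols(node, values.size)).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_vector(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if len(df) != 1:
        raise ConfigurationError(f"{path}: expected exactly one data row, got {len(df)}")
    return df.to_numpy().ravel().astype(float)


def write_nodes(directory, nodes: list[NodeSpec]) -> Path:
    """Write per-node growth-rate and initial-abundance vectors."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for n in nodes:
        write_vector(directory / f"{n.name}_growth_rates.tsv", n.growth_rates, n.name)
        write_vector(directory / f"{n.name}_initial_abundances.tsv", n.initial_abundances, n.name)
    return directory


def read_nodes(directory, node_names: list[str]) -> list[NodeSpec]:
    directory = Path(directory)
    nodes = []
    for name in node_names:
        g = read_vector(directory / f"{name}_growth_rates.tsv")
        z0 = read_vector(directory / f"{name}_initial_abundances.tsv")
        nodes.append(NodeSpec(name=name, dim=g.size, growth_rates=g, initial_abundances=z0))
    return nodes


def write_interaction_map(directory, imap: InteractionMap) -> Path:
    """Write each stored block as a dense headerless TSV ``<target>__<source>.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (target, source), mat in imap.blocks.items():
        np.savetxt(directory / f"{target}__{source}.tsv", mat, delimiter="\t")
    return directory


def read_interaction_map(directory) -> InteractionMap:
    directory = Path(directory)
    blocks = {}
    for f in sorted(directory.glob("*__*.tsv")):
        target, source = f.name[: -len(".tsv")].split("__", 1)
        blocks[(target, source)] = np.atleast_2d(np.loadtxt(f, delimiter="\t"))
    if not blocks:
        raise ConfigurationError(f"no interaction block files (*__*.tsv) in {directory}")
    return InteractionMap(blocks)


def write_cohort(
    directory,
    cases: list[Timecourse],
    controls: list[Timecourse] | None = None,
    response: np.ndarray | None = None,
    seed: int | None = None,
) -> Path:
    """Write a cohort (or case-control cohort) directory tree with a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    if controls is None:
        for k, tc in enumerate(cases):
            write_timecourse(directory / str(k), tc)
            rows.append({"individual": k, "arm": "cohort", "seed": seed})
    else:
        for arm, members in (("cases", cases), ("controls", controls)):
            for k, tc in enumerate(members):
                write_timecourse(directory / arm / str(k), tc)
                rows.append({"individual": k, "arm": arm[:-1], "seed": seed})
    if response is not None:
        np.savetxt(directory / "response_vector.tsv", np.atleast_2d(response), delimiter="\t")
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return directory


def read_cohort_arm(directory) -> list[Timecourse]:
    """Read all numbered individual subdirectories of a cohort arm."""
    directory = Path(directory)
    subdirs = sorted(
        (d for d in directory.iterdir() if d.is_dir() and d.name.isdigit()),
        key=lambda d: int(d.name),
    )
    if not subdirs:
        raise ConfigurationError(f"no individual subdirectories in {directory}")
    return [read_timecourse(d, label=directory.name.rstrip("s")) for d in subdirs]
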