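"""Reading and writing the pipeline's plain-text formats.

Networks travel as SIF (``source<TAB>relation<TAB>target`` with relation
``regulates`` or ``interacts``); expression and all result tables are TSV.
Floats are written with a fixed general format so that identical runs
produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import INTERACTS, REGULATES, RegulatoryNetwork, ReplicatedExpression
from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def read_network(path) -> RegulatoryNetwork:
    """Parse a SIF regulatory network.

    Sources of ``regulates`` edges are TFs and their targets TGs; a node
    that appears both as a target and as a regulator is classified TF
    (regulator wins) with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    regulations: list[tuple[str, str]] = []
    interactions: list[tuple[str, str]] = []
    targets: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            src, rel, dst = parts
            if rel == REGULATES:
                regulations.append((src, dst))
                targets.add(dst)
            elif rel == INTERACTS:
                interactions.append((src, dst))
            else:
                raise ValueError(f"{path}:{lineno}: unknown relation {rel!r}")
    net = RegulatoryNetwork()
    sources = {s for s, _ in regulations} | {n for e in interactions for n in e}
    for dual in sorted(targets & sources):
        logger.warning("node %s is both regulator and target; classified TF", dual)
    for a, b in interactions:
        net.add_interaction(a, b)
    for s, d in regulations:
        net.add_regulation(s, d)
    # a target that also regulates was upgraded to TF by role inference
    return net


def write_network(net: RegulatoryNetwork, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for u, v in net.regulation_edges():
            fh.write(f"{u}\t{REGULATES}\t{v}\n")
        for u, v in net.interaction_edges():
            fh.write(f"{u}\t{INTERACTS}\t{v}\n")


def write_replicated_expression(expr: ReplicatedExpression, path) -> None:
    """TSV with columns ``time_<t>_rep<r>``, one row per gene."""
    cols = {}
    for j, t in enumerate(expr.timepoints):
        for r, lab in enumerate(expr.replicate_labels):
            cols[f"time_{t:g}_{lab}"] = expr.values[:, j, r]
    frame = pd.DataFrame(cols, index=pd.Index(expr.gene_ids, name="gene"))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_replicated_expression(path) -> ReplicatedExpression:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    times: list[float] = []
    reps: list[str] = []
    for col in frame.columns:
        if not col.startswith("time_"):
            raise ValueError(f"unexpected column {col!r}")
        t_str, rep = col[len("time_") :].rsplit("_", 1)
        t = float(t_str)
        if t not in times:
            times.append(t)
        if rep not in reps:
            reps.append(rep)
    values = np.empty((frame.shape[0], len(times), len(reps)))
    for j, t in enumerate(times):
        for r, rep in enumerate(reps):
            values[:, j, r] = frame[f"time_{t:g}_{rep}"].to_numpy()
    return ReplicatedExpression(
        values=values,
        gene_ids=[str(g) for g in frame.index],
        timepoints=np.array(times),
        replicate_labels=reps,
    )


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    frame = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.gene_ids, name="gene"),
        columns=[f"time_{t:g}" for t in matrix.timepoints],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    times = [float(c[len("time_") :]) for c in frame.columns]
    return ExpressionMatrix(
        frame.to_numpy(float), [str(g) for g in frame.index], np.array(times)
    )


def write_table(frame: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
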