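"""Topology of the static network and the four active sub-networks.

Produces one table shaped like a classic network-properties summary: one
row for the static network and each time-range sub-network, plus mean and
SD rows for 100 size-matched random sub-networks sampled from the static
network.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from dynregnet.io import read_network, write_table
from dynregnet.pipeline import stage_seed
from dynregnet.subnetworks import RANGE_LABELS
from dynregnet.topology import random_subnetwork_ensemble, summarize


def main() -> None:
    out = RESULTS / "topology"
    static = read_network(RESULTS / "simulated" / "network.sif")

    rows = [{"network": "static", **summarize(static.graph).network}]
    for label in RANGE_LABELS:
        sub = read_network(RESULTS / "subnetworks" / f"subnetwork_{label}.sif")
        report = summarize(sub.graph).network
        rows.append({"network": label, **report})
        n_tfs, n_tgs = int(report["n_tfs"]), int(report["n_tgs"])
        if min(n_tfs, n_tgs) == 0:
            continue
        stats = random_subnetwork_ensemble(
            static, n_tfs, n_tgs, n_reps=100, seed=stage_seed(SEED, label)
        )
        rows.append({"network": f"{label}_random_mean", **stats.mean})
        rows.append({"network": f"{label}_random_sd", **stats.sd})

    table = pd.DataFrame(rows).set_index("network")
    write_table(table, out / "topology.tsv")
    cols = ["n_tfs", "n_tgs", "n_edges", "average_degree",
            "clustering_coefficient", "diameter", "average_path_length",
            "centralization"]
    print(table[cols].round(3).to_string())


if __name__ == "__main__":
    main()
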