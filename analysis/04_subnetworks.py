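"""Partition the response into four time-range active sub-networks.

Bins differentially expressed targets by peak expression and TFs by peak
reconstructed activity into immediate-early (0-1 h], mid-early (1-3 h],
mid-late (3-8 h] and very-late (8-14 h], then excerpts each range's
induced sub-network from the static network.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from dynregnet.datatypes import RegulatoryNetwork
from dynregnet.io import read_matrix, read_network, write_network, write_table
from dynregnet.subnetworks import (
    amplitude,
    default_ranges,
    extract_subnetwork,
    peak_time,
    select_active,
)


def main() -> None:
    out = RESULTS / "subnetworks"
    network = read_network(RESULTS / "simulated" / "network.sif")
    smoothed = read_matrix(RESULTS / "preprocess" / "expression_smoothed.tsv")
    degs = sorted(
        set((RESULTS / "preprocess" / "degs.txt").read_text().split())
        & set(network.tgs)
    )
    activities = pd.read_csv(
        RESULTS / "nca" / "tf_activities.tsv", sep="\t", index_col=0
    )

    ranges = default_ranges(float(smoothed.timepoints[-1]))
    tg_bins = select_active(
        smoothed.subset(degs).values, degs, smoothed.timepoints, ranges, threshold=1.0
    )
    tf_bins = select_active(
        activities.to_numpy(), list(activities.index), smoothed.timepoints,
        ranges, threshold=1.0,
    )

    rows = []
    for r in ranges:
        sub = extract_subnetwork(network, tf_bins[r.label], tg_bins[r.label], r)
        sif_net = RegulatoryNetwork()
        sif_net.graph = sub.graph
        write_network(sif_net, out / f"subnetwork_{r.label}.sif")
        rows.append(
            {
                "range": r.label,
                "interval_h": f"({r.lo:g}, {r.hi:g}]",
                "active_tfs": len(tf_bins[r.label]),
                "active_tgs": len(tg_bins[r.label]),
                "edges": sub.graph.number_of_edges(),
                "isolated": len(sub.isolated),
            }
        )
    summary = pd.DataFrame(rows)
    write_table(summary, out / "summary.tsv", index=False)

    attr = []
    for profiles, ids, role in (
        (smoothed.subset(degs).values, degs, "TG"),
        (activities.to_numpy(), list(activities.index), "TF"),
    ):
        for row, node in zip(profiles, ids):
            t_peak, flat = peak_time(row, smoothed.timepoints)
            attr.append(
                {
                    "node": node,
                    "role": role,
                    "peak_time_h": t_peak,
                    "amplitude": amplitude(row),
                    "flat": flat,
                }
            )
    write_table(pd.DataFrame(attr), out / "node_attributes.tsv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
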