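"""Time-range active sub-networks.

After a stimulus, each gene or TF profile is summarized by the time of its
peak deviation from baseline and by a scale-free amplitude statistic.
Nodes passing an amplitude threshold are binned into one of four
post-stimulus ranges — immediate-early (IE), mid-early (ME), mid-late (ML)
and very-late (VL) — and each range's active sub-network is the induced
subgraph of the static regulatory network on its active TFs and TGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datatypes import RegulatoryNetwork

RANGE_LABELS = ("IE", "ME", "ML", "VL")


@dataclass(frozen=True)
class TimeRange:
    """Half-open hour interval (lo, hi]."""

    label: str
    lo: float
    hi: float

    def contains(self, t: float) -> bool:
        return self.lo < t <= self.hi


def default_ranges(t_max: float = 14.0, boundaries=(1.0, 3.0, 8.0)) -> list[TimeRange]:
    """IE (0,1], ME (1,3], ML (3,8], VL (8, t_max] by default."""
    edges = (0.0, *boundaries, t_max)
    return [
        TimeRange(lab, edges[i], edges[i + 1]) for i, lab in enumerate(RANGE_LABELS)
    ]


@dataclass
class ActiveSubnetwork:
    time_range: TimeRange
    active_tfs: set[str]
    active_tgs: set[str]
    graph: nx.DiGraph
    isolated: set[str]


def peak_time(profile, timepoints, baseline_index: int = 0) -> tuple[float, bool]:
    """Time of largest absolute deviation from the baseline value.

    Returns ``(t_peak, flat)``: ties go to the earliest time, and a
    constant profile returns the baseline time flagged ``flat=True`` so it
    can be excluded from binning.
    """
    profile = np.asarray(profile, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if profile.shape[0] != t.shape[0]:
        raise ValueError("profile and timepoints lengths differ")
    dev = np.abs(profile - profile[baseline_index])
    if dev.max() == 0:
        return float(t[baseline_index]), True
    return float(t[int(np.argmax(dev))]), False


def amplitude(profile, baseline_index: int = 0) -> float:
    """Peak deviation from baseline in units of the deviation SD.

    max_t |x(t) - x(baseline)| / SD(x - x(baseline)); scale-free and >= 0,
    0 for a constant profile.
    """
    profile = np.asarray(profile, dtype=float)
    dev = profile - profile[baseline_index]
    sd = float(np.std(dev))
    if sd == 0:
        return 0.0
    return float(np.max(np.abs(dev)) / sd)


def select_active(
    profiles: np.ndarray,
    ids,
    timepoints,
    ranges: list[TimeRange],
    threshold: float = 1.0,
    baseline_index: int = 0,
) -> dict[str, set[str]]:
    """Assign each node to the unique range containing its peak time.

    A node is active in a range iff its amplitude is >= threshold and its
    peak falls inside that range; flat profiles and peaks at baseline are
    excluded, so every node lands in at most one range.
    """
    out: dict[str, set[str]] = {r.label: set() for r in ranges}
    for row, node in zip(np.atleast_2d(profiles), ids):
        t_peak, flat = peak_time(row, timepoints, baseline_index)
        if flat or amplitude(row, baseline_index) < threshold:
            continue
        for r in ranges:
            if r.contains(t_peak):
                out[r.label].add(node)
                break
    return out


def count_active_per_timepoint(
    profiles: np.ndarray,
    timepoints,
    threshold: float = 1.0,
    baseline_index: int = 0,
) -> dict[float, int]:
    """Number of above-threshold nodes peaking at each time point."""
    t = np.asarray(timepoints, dtype=float)
    counts = {float(tp): 0 for tp in t}
    for row in np.atleast_2d(profiles):
        t_peak, flat = peak_time(row, t, baseline_index)
        if flat or amplitude(row, baseline_index) < threshold:
            continue
        counts[t_peak] += 1
    return counts


def extract_subnetwork(
    static: RegulatoryNetwork,
    active_tfs,
    active_tgs,
    time_range: TimeRange,
) -> ActiveSubnetwork:
    """Induced subgraph of the static network on the active node sets.

    Keeps TF->TG regulation and TF-TF interaction edges whose endpoints are
    both active; isolated active nodes stay in the node sets and are
    reported separately.
    """
    active_tfs = set(active_tfs)
    active_tgs = set(active_tgs)
    if active_tfs & active_tgs:
        raise ValueError("active TF and TG sets must be disjoint")
    nodes = (active_tfs | active_tgs) & set(static.graph.nodes)
    graph = static.graph.subgraph(nodes).copy()
    isolated = {n for n in graph.nodes if graph.degree(n) == 0}
    return ActiveSubnetwork(
        time_range=time_range,
        active_tfs=active_tfs,
        active_tgs=active_tgs,
        graph=graph,
        isolated=isolated,
    )

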