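"""Connectome pathway grouping and thresholding.

Works on cell-type-labeled synapse tables (one row per unitary
connection: a specific presynaptic cell onto a specific postsynaptic
cell).  The pathway extraction rule: discard unitary connections with
fewer than 5 synapses, group the survivors by (pre type, post type) and
sum synapse counts, then discard groups below an absolute synapse count
or below a fraction of either cell type's grand pre-/postsynaptic total.
Reported connection weights are per hemisphere, i.e. half the group
total.  Two presets: ``pfl3`` (200 synapses, 1%) and
``mbon32`` (70 synapses, 0.4%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNITARY_MIN_SYNAPSES = 5
PRESETS = {
    "pfl3": {"group_min_synapses": 200, "group_min_fraction": 0.01},
    "mbon32": {"group_min_synapses": 70, "group_min_fraction": 0.004},
}

SYNAPSE_COLUMNS = ["pre_id", "pre_type", "pre_side", "post_id", "post_type",
                   "post_side", "synapses"]


def validate_synapse_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SYNAPSE_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"synapse table missing columns: {missing}")
    if t[["pre_type", "post_type"]].isna().any().any():
        raise ValueError("missing cell-type labels")
    if (t["synapses"] < 1).any():
        raise ValueError("synapse counts must be positive integers")
    return t


@dataclass
class PathwayEdge:
    """A cell-type-level connection surviving the grouping thresholds."""

    pre_type: str
    post_type: str
    total_synapses: int
    per_hemisphere: float       # total / 2 exactly
    frac_of_post_input: float   # of the post type's grand input total
    frac_of_pre_output: float   # of the pre type's grand output total


def group_and_filter(t: pd.DataFrame, unitary_min: int = UNITARY_MIN_SYNAPSES,
                     group_min_synapses: int = 200,
                     group_min_fraction: float = 0.01,
                     preset: str | None = None) -> list[PathwayEdge]:
    """Apply the unitary and group-level thresholds, in order.

    Fractions are computed against each cell type's grand totals taken
    after the unitary filter but before group filtering (so the rule is
    order-independent across groups).  A group is kept iff its summed
    synapses reach ``group_min_synapses`` and its fraction of both the
    presynaptic type's output total and the postsynaptic type's input
    total reach ``group_min_fraction``.
    """
    if preset is not None:
        params = PRESETS[preset]
        group_min_synapses = params["group_min_synapses"]
        group_min_fraction = params["group_min_fraction"]
    if len(t) == 0:
        raise ValueError("empty synapse table")
    t = validate_synapse_table(t)
    t = t[t["synapses"] >= unitary_min]
    if len(t) == 0:
        return []
    groups = (t.groupby(["pre_type", "post_type"], observed=True)["synapses"]
              .sum().reset_index())
    out_total = t.groupby("pre_type", observed=True)["synapses"].sum()
    in_total = t.groupby("post_type", observed=True)["synapses"].sum()
    edges = []
    for _, row in groups.iterrows():
        total = int(row["synapses"])
        f_out = total / float(out_total[row["pre_type"]])
        f_in = total / float(in_total[row["post_type"]])
        if total < group_min_synapses:
            continue
        if f_out < group_min_fraction or f_in < group_min_fraction:
            continue
        edges.append(PathwayEdge(pre_type=row["pre_type"], post_type=row["post_type"],
                                 total_synapses=total, per_hemisphere=total / 2.0,
                                 frac_of_post_input=f_in, frac_of_pre_output=f_out))
    edges.sort(key=lambda e: -e.total_synapses)
    return edges


def edges_to_frame(edges: list[PathwayEdge]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in edges],
                        columns=["pre_type", "post_type", "total_synapses",
                                 "per_hemisphere", "frac_of_post_input",
                                 "frac_of_pre_output"])


def two_hop_paths(t: pd.DataFrame, source_type: str, target_type: str,
                  **filter_kwargs) -> list[dict]:
    """Rank intermediate cell types on source -> X -> target chains.

    Edges come from :func:`group_and_filter` with the given thresholds;
    each chain is scored by the weaker of its two per-hemisphere edge
    weights and chains are returned strongest first.
    """
    edges = group_and_filter(t, **filter_kwargs)
    from_source = {e.post_type: e for e in edges if e.pre_type == source_type}
    to_target = {e.pre_type: e for e in edges if e.post_type == target_type}
    paths = []
    for mid in sorted(set(from_source) & set(to_target)):
        if mid in (source_type, target_type):
            continue
        e1, e2 = from_source[mid], to_target[mid]
        paths.append({"intermediate": mid,
                      "weight": min(e1.per_hemisphere, e2.per_hemisphere),
                      "edge_in": e1, "edge_out": e2})
    paths.sort(key=lambda p: -p["weight"])
    return paths
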