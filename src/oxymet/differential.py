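"""Condition-differential presence analysis of aligned feature clusters.

The central object is a boolean presence matrix: rows are feature
clusters, columns are the samples of the declared cultivation design.
On top of it sit the detectors for the study's two key patterns —
clusters synthesized only under the experimental (elevated oxygen /
oxygen+ozone) conditions, and clusters induced within a retention-time
window relative to the natural-aeration control — plus a simple matching
coefficient for comparing a presence pattern with a bioassay pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureCluster, SampleMeta

__all__ = [
    "PresenceMatrix",
    "build_presence_matrix",
    "detect_only_experimental",
    "induced_in_window",
    "presence_activity_concordance",
    "plot_presence",
]

_COLUMN_NAMES = ["strain", "condition", "week", "fraction"]


@dataclass
class PresenceMatrix:
    """Boolean cluster x sample occupancy with per-cluster consensus RT."""

    values: pd.DataFrame  # bool; index cluster_id, columns MultiIndex of design
    consensus_rt: dict[int, float]
    consensus_mass: dict[int, float]

    @property
    def control_columns(self) -> pd.Index:
        return self.values.columns[
            self.values.columns.get_level_values("condition") == "C"
        ]

    @property
    def experimental_columns(self) -> pd.Index:
        return self.values.columns[
            self.values.columns.get_level_values("condition") != "C"
        ]


def build_presence_matrix(
    clusters: list[FeatureCluster],
    design: list[SampleMeta],
    intensity_floor: float = 0.0,
) -> PresenceMatrix:
    """Occupancy of each cluster over the declared design.

    A cell is True iff the cluster holds a member from that sample with
    intensity above ``intensity_floor``.  Design samples never seen in the
    data yield all-False columns (with a warning); samples in the data but
    not in the design are ignored.
    """
    tuples = [s.as_tuple() for s in design]
    if len(set(tuples)) != len(tuples):
        raise ValueError("duplicate samples in design")
    columns = pd.MultiIndex.from_tuples(tuples, names=_COLUMN_NAMES)
    index = [c.cluster_id for c in clusters]
    mat = pd.DataFrame(False, index=index, columns=columns)
    design_set = set(tuples)
    seen: set = set()
    for cluster in clusters:
        for feat in cluster.members:
            key = feat.sample.as_tuple()
            seen.add(key)
            if key in design_set and feat.intensity > intensity_floor:
                mat.loc[cluster.cluster_id, key] = True
    unseen = design_set - seen
    if unseen:
        warnings.warn(
            f"{len(unseen)} design sample(s) had no features at all: "
            f"{sorted(unseen)[:5]}...",
            stacklevel=2,
        )
    return PresenceMatrix(
        values=mat,
        consensus_rt={c.cluster_id: c.consensus_rt for c in clusters},
        consensus_mass={c.cluster_id: c.consensus_mass for c in clusters},
    )


def detect_only_experimental(matrix: PresenceMatrix) -> set[int]:
    """Clusters absent from every control (C) sample but present somewhere else.

    Undefined (error) when the design has no control or no experimental
    columns — with nothing to contrast against, "only experimental" has no
    meaning.
    """
    ctrl = matrix.control_columns
    expt = matrix.experimental_columns
    if len(ctrl) == 0:
        raise ValueError("design has no control (C) columns")
    if len(expt) == 0:
        raise ValueError("design has no experimental columns")
    vals = matrix.values
    no_control = ~vals[ctrl].any(axis=1)
    any_expt = vals[expt].any(axis=1)
    return set(vals.index[no_control & any_expt])


def induced_in_window(
    matrix: PresenceMatrix, rt_low: float, rt_high: float
) -> set[int]:
    """Clusters in [rt_low, rt_high] more present under experimental conditions.

    Membership requires consensus RT inside the closed window and a
    strictly greater presence count over experimental columns than over
    control columns.
    """
    if rt_low >= rt_high:
        raise ValueError(f"inverted RT window ({rt_low}, {rt_high})")
    ctrl = matrix.control_columns
    expt = matrix.experimental_columns
    vals = matrix.values
    out = set()
    for cid in vals.index:
        rt = matrix.consensus_rt.get(cid)
        if rt is None or not (rt_low <= rt <= rt_high):
            continue
        if int(vals.loc[cid, expt].sum()) > int(vals.loc[cid, ctrl].sum()):
            out.add(cid)
    return out


def presence_activity_concordance(
    cluster_row, activity_row
) -> float:
    """Simple matching coefficient between two boolean vectors.

    Fraction of positions where a cluster's presence pattern agrees with a
    bioassay call pattern over the same samples in the same order; 1.0
    means the molecule's occurrence tracks the activity exactly.
    """
    a = np.asarray(cluster_row, dtype=bool)
    b = np.asarray(activity_row, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(a == b))


def plot_presence(matrix: PresenceMatrix, path: str) -> None:
    """Presence heatmap (clusters x samples) written to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = matrix.values
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * vals.shape[1]), max(3, 0.3 * vals.shape[0]))
    )
    ax.imshow(vals.to_numpy(dtype=float), aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(vals.shape[1]))
    ax.set_xticklabels(
        ["/".join(str(v) for v in col[1:]) for col in vals.columns],
        rotation=90, fontsize=6,
    )
    ax.set_yticks(range(vals.shape[0]))
    ax.set_yticklabels(
        [f"{matrix.consensus_mass.get(c, float('nan')):.4f}" for c in vals.index],
        fontsize=6,
    )
    ax.set_xlabel("sample (condition/week/fraction)")
    ax.set_ylabel("cluster consensus mass (Da)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
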