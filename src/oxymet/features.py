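"""LC-MS feature tables and cross-sample feature alignment.

A feature is one (retention time, neutral monoisotopic mass, intensity)
triple observed in one sample of the cultivation design:
strain x condition {C, O2, O3} x week x fraction {biomass, cultural_liquid}.
Features from different samples that agree in mass (ppm scale) and
retention time are aligned into clusters so presence/absence can be
compared across the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chemmass

__all__ = [
    "CONDITIONS",
    "FRACTIONS",
    "SampleMeta",
    "FeatureRecord",
    "FeatureCluster",
    "read_feature_table",
    "write_feature_table",
    "align_features",
    "clusters_to_frame",
]

CONDITIONS = ("C", "O2", "O3")
FRACTIONS = ("biomass", "cultural_liquid")

#: Default chromatographic run window, minutes (18-min gradient).
DEFAULT_RT_WINDOW = (0.0, 18.0)


@dataclass(frozen=True, order=True)
class SampleMeta:
    """One sample of the cultivation design."""

    strain: str
    condition: str
    week: int
    fraction: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        if self.week < 1:
            raise ValueError(f"week must be >= 1, got {self.week}")

    def as_tuple(self) -> tuple[str, str, int, str]:
        return (self.strain, self.condition, self.week, self.fraction)


@dataclass(frozen=True)
class FeatureRecord:
    """One LC-MS feature tied to its sample."""

    rt_min: float
    neutral_mass: float
    intensity: float
    sample: SampleMeta

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"neutral mass must be positive, got {self.neutral_mass}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass
class FeatureCluster:
    """A cross-sample group of features believed to be one molecule."""

    cluster_id: int
    members: list[FeatureRecord] = field(default_factory=list)
    consensus_mass: float = 0.0
    consensus_rt: float = 0.0

    def samples(self) -> set[tuple]:
        return {f.sample.as_tuple() for f in self.members}


_BASE_COLUMNS = {"rt_min", "intensity", "strain", "condition", "week", "fraction"}


def read_feature_table(
    path: str | Path,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
    adducts: list[chemmass.Adduct] | None = None,
) -> list[FeatureRecord]:
    """Read a feature CSV into validated records.

    Each row needs either a ``neutral_mass`` column or an ``mz`` +
    ``adduct_label`` pair (converted through the adduct arithmetic).  Rows
    carrying both are cross-checked to 1e-4 Da.
    """
    df = pd.read_csv(path, comment="#")
    missing = _BASE_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    has_neutral = "neutral_mass" in df.columns
    has_mz = "mz" in df.columns and "adduct_label" in df.columns
    if not has_neutral and not has_mz:
        raise ValueError("feature table needs neutral_mass or mz+adduct_label columns")
    if adducts is None:
        adducts = chemmass.load_default_adducts()
    adduct_map = {a.label: a for a in adducts}

    records: list[FeatureRecord] = []
    for idx, row in df.iterrows():
        neutral = float(row["neutral_mass"]) if has_neutral and pd.notna(row.get("neutral_mass")) else None
        if has_mz and pd.notna(row.get("mz")):
            label = str(row["adduct_label"])
            if label not in adduct_map:
                raise ValueError(f"row {idx}: unknown adduct label {label!r}")
            from_mz = chemmass.neutral_from_mz(float(row["mz"]), adduct_map[label])
            if neutral is not None and abs(neutral - from_mz) > 1e-4:
                raise ValueError(
                    f"row {idx}: neutral_mass {neutral} inconsistent with "
                    f"mz-derived mass {from_mz:.6f}"
                )
            neutral = neutral if neutral is not None else from_mz
        if neutral is None:
            raise ValueError(f"row {idx}: no usable mass")
        rt = float(row["rt_min"])
        if not (rt_window[0] <= rt <= rt_window[1]):
            raise ValueError(
                f"row {idx}: retention time {rt} outside run window {rt_window}"
            )
        sample = SampleMeta(
            strain=str(row["strain"]),
            condition=str(row["condition"]),
            week=int(row["week"]),
            fraction=str(row["fraction"]),
        )
        records.append(
            FeatureRecord(
                rt_min=rt,
                neutral_mass=neutral,
                intensity=float(row["intensity"]),
                sample=sample,
            )
        )
    return records


def write_feature_table(records: list[FeatureRecord], path: str | Path) -> None:
    """Write records back to the standard feature CSV schema."""
    rows = [
        {
            "rt_min": f.rt_min,
            "neutral_mass": f.neutral_mass,
            "intensity": f.intensity,
            "strain": f.sample.strain,
            "condition": f.sample.condition,
            "week": f.sample.week,
            "fraction": f.sample.fraction,
        }
        for f in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "rt_min", "neutral_mass", "intensity",
            "strain", "condition", "week", "fraction",
        ],
    ).to_csv(path, index=False)


def _median(values: list[float]) -> float:
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])


def align_features(
    features: list[FeatureRecord],
    mass_tol_ppm: float = 5.0,
    rt_tol_min: float = 0.2,
) -> list[FeatureCluster]:
    """Greedy centroid clustering of features across samples.

    Features are sorted by (mass, RT, sample) and swept in one ascending
    pass; each joins the best open cluster whose consensus (median) mass
    lies within ``mass_tol_ppm`` and consensus RT within ``rt_tol_min``
    and which does not yet hold a member from the same sample, else it
    opens a new cluster.  Candidate ties break by smaller mass gap, then
    smaller RT gap.  The sort makes the result order-invariant.

    A deterministic repair pass then merges mass-adjacent clusters whose
    consensus values are mutually within both tolerances and whose sample
    sets are disjoint: during the sweep an early outlier member can strand
    a within-tolerance fragment of one molecule as a separate cluster, and
    the merge heals exactly that case.
    """
    if mass_tol_ppm <= 0 or rt_tol_min <= 0:
        raise ValueError("alignment tolerances must be positive")
    ordered = sorted(
        features, key=lambda f: (f.neutral_mass, f.rt_min, f.sample.as_tuple())
    )
    clusters: list[FeatureCluster] = []
    for feat in ordered:
        best = None
        best_key = None
        # masses ascend, so only recent clusters can still be in range
        for cluster in reversed(clusters):
            mass_gap = feat.neutral_mass - cluster.consensus_mass
            ppm_gap = abs(mass_gap) / cluster.consensus_mass * 1e6
            if mass_gap > 0 and ppm_gap > mass_tol_ppm:
                break
            if ppm_gap > mass_tol_ppm:
                continue
            rt_gap = abs(feat.rt_min - cluster.consensus_rt)
            if rt_gap > rt_tol_min:
                continue
            if feat.sample.as_tuple() in cluster.samples():
                continue
            key = (abs(mass_gap), rt_gap, cluster.cluster_id)
            if best_key is None or key < best_key:
                best, best_key = cluster, key
        if best is None:
            best = FeatureCluster(
                cluster_id=len(clusters),
                members=[],
                consensus_mass=feat.neutral_mass,
                consensus_rt=feat.rt_min,
            )
            clusters.append(best)
        best.members.append(feat)
        best.consensus_mass = _median([f.neutral_mass for f in best.members])
        best.consensus_rt = _median([f.rt_min for f in best.members])

    changed = True
    while changed:
        changed = False
        clusters.sort(key=lambda c: (c.consensus_mass, c.consensus_rt))
        i = 0
        while i < len(clusters) - 1:
            a, b = clusters[i], clusters[i + 1]
            ppm_gap = (b.consensus_mass - a.consensus_mass) / a.consensus_mass * 1e6
            if (
                ppm_gap <= mass_tol_ppm
                and abs(a.consensus_rt - b.consensus_rt) <= rt_tol_min
                and a.samples().isdisjoint(b.samples())
            ):
                a.members.extend(b.members)
                a.consensus_mass = _median([f.neutral_mass for f in a.members])
                a.consensus_rt = _median([f.rt_min for f in a.members])
                del clusters[i + 1]
                changed = True
            else:
                i += 1
    for new_id, cluster in enumerate(clusters):
        cluster.cluster_id = new_id
    return clusters


def clusters_to_frame(clusters: list[FeatureCluster]) -> pd.DataFrame:
    """Flat cluster table (one row per member) for export."""
    rows = []
    for c in clusters:
        for f in c.members:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "consensus_mass": c.consensus_mass,
                    "consensus_rt": c.consensus_rt,
                    "rt_min": f.rt_min,
                    "neutral_mass": f.neutral_mass,
                    "intensity": f.intensity,
                    "strain": f.sample.strain,
                    "condition": f.sample.condition,
                    "week": f.sample.week,
                    "fraction": f.sample.fraction,
                }
            )
    return pd.DataFrame(rows)
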