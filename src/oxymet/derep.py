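"""Accurate-mass dereplication of feature clusters against a compound library.

A cluster is assigned a library identity only when the mass difference is
simultaneously below an absolute (Da) and a relative (ppm) bound — both
strict inequalities — and the library record's biological source genus
matches the producing strain.  Clusters with no passing record are
reported as unknown; with high-resolution data and sub-mDa gates this is
the normal fate of most features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chemmass import Adduct, MassError, load_default_adducts, mass_error, neutral_from_mz
from .complib import CompoundLibrary
from .features import FeatureCluster

__all__ = [
    "DerepParams",
    "MatchResult",
    "dereplicate",
    "dereplicate_mz",
    "summarize_identification",
    "matches_to_frame",
]


@dataclass
class DerepParams:
    """Matching gates: strict |delta| < max_delta_da AND |ppm| < max_delta_ppm."""

    max_delta_da: float = 0.001
    max_delta_ppm: float = 10.0
    adduct_set: list[Adduct] = field(default_factory=load_default_adducts)
    source_filter: str = "any"

    def __post_init__(self) -> None:
        if self.max_delta_da <= 0 or self.max_delta_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not self.adduct_set:
            raise ValueError("adduct set must be non-empty")

    def source_ok(self, biological_source: str) -> bool:
        if self.source_filter.lower() == "any":
            return True
        return biological_source.strip().lower() == self.source_filter.strip().lower()


@dataclass(frozen=True)
class MatchResult:
    """One feature/cluster -> compound assignment."""

    cluster_id: int
    compound_name: str
    adduct_label: str  # "neutral" when neutral masses were compared directly
    error: MassError
    rank: int


def _passes(err: MassError, params: DerepParams) -> bool:
    return (
        abs(err.delta_da) < params.max_delta_da
        and abs(err.delta_ppm) < params.max_delta_ppm
    )


def dereplicate(
    clusters: list[FeatureCluster],
    library: CompoundLibrary,
    params: DerepParams | None = None,
) -> dict[int, list[MatchResult]]:
    """Match cluster consensus neutral masses against the library.

    Returns every passing record per cluster, ranked by |ppm error|
    ascending (rank 1 is the reported identity); an empty list marks an
    unknown.  The deconvoluted feature masses are neutral, so no adduct
    arithmetic is involved here — see :func:`dereplicate_mz` for raw-m/z
    input.
    """
    if params is None:
        params = DerepParams()
    if len(library) == 0:
        raise ValueError("library is empty")
    out: dict[int, list[MatchResult]] = {}
    for cluster in clusters:
        center = cluster.consensus_mass
        window = max(params.max_delta_da, center * params.max_delta_ppm * 1e-6)
        hits = []
        for rec in library.mass_range_query(center, window):
            if not params.source_ok(rec.biological_source):
                continue
            err = mass_error(center, rec.monoisotopic_mass)
            if _passes(err, params):
                hits.append((rec, err))
        hits.sort(key=lambda pair: (abs(pair[1].delta_ppm), pair[0].name))
        out[cluster.cluster_id] = [
            MatchResult(
                cluster_id=cluster.cluster_id,
                compound_name=rec.name,
                adduct_label="neutral",
                error=err,
                rank=i + 1,
            )
            for i, (rec, err) in enumerate(hits)
        ]
    return out


def dereplicate_mz(
    mz_values: dict[int, float],
    library: CompoundLibrary,
    params: DerepParams | None = None,
) -> dict[int, list[MatchResult]]:
    """Match raw m/z values by trying every adduct in the configured set.

    For each (m/z, adduct) pair the implied neutral mass is compared to
    library masses under the same conjunctive gates.  Results across
    adducts are pooled and ranked by |ppm error|.
    """
    if params is None:
        params = DerepParams()
    if len(library) == 0:
        raise ValueError("library is empty")
    out: dict[int, list[MatchResult]] = {}
    for key, mz in mz_values.items():
        hits = []
        for adduct in params.adduct_set:
            try:
                neutral = neutral_from_mz(mz, adduct)
            except ValueError:
                continue
            window = max(params.max_delta_da, neutral * params.max_delta_ppm * 1e-6)
            for rec in library.mass_range_query(neutral, window):
                if not params.source_ok(rec.biological_source):
                    continue
                err = mass_error(neutral, rec.monoisotopic_mass)
                if _passes(err, params):
                    hits.append((rec, adduct.label, err))
        hits.sort(key=lambda t: (abs(t[2].delta_ppm), t[0].name, t[1]))
        out[key] = [
            MatchResult(
                cluster_id=key,
                compound_name=rec.name,
                adduct_label=label,
                error=err,
                rank=i + 1,
            )
            for i, (rec, label, err) in enumerate(hits)
        ]
    return out


def summarize_identification(
    matches: dict[int, list[MatchResult]],
    library: CompoundLibrary | None = None,
) -> dict:
    """Counts of identified vs unknown clusters, plus per-activity tallies.

    A cluster counts toward an activity when its rank-1 match's library
    record carries that annotation (requires ``library`` to look up
    annotations; omit it to get the counts alone).
    """
    identified = sum(1 for hits in matches.values() if hits)
    total = len(matches)
    summary = {
        "identified": identified,
        "unknown": total - identified,
        "total": total,
        "activities": {},
    }
    if library is not None:
        tallies: dict[str, int] = {}
        for hits in matches.values():
            if not hits:
                continue
            top = library[hits[0].compound_name]
            for act in top.activities:
                tallies[act] = tallies.get(act, 0) + 1
        summary["activities"] = dict(sorted(tallies.items()))
    return summary


def matches_to_frame(matches: dict[int, list[MatchResult]]) -> pd.DataFrame:
    """Flat match report (unknown clusters appear with empty compound name)."""
    rows = []
    for cid in sorted(matches):
        hits = matches[cid]
        if not hits:
            rows.append(
                {
                    "cluster_id": cid,
                    "compound_name": "",
                    "adduct_label": "",
                    "delta_da": float("nan"),
                    "delta_ppm": float("nan"),
                    "rank": 0,
                }
            )
        for m in hits:
            rows.append(
                {
                    "cluster_id": m.cluster_id,
                    "compound_name": m.compound_name,
                    "adduct_label": m.adduct_label,
                    "delta_da": m.error.delta_da,
                    "delta_ppm": m.error.delta_ppm,
                    "rank": m.rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "compound_name", "adduct_label", "delta_da", "delta_ppm", "rank"],
    )
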