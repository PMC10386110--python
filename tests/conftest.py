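"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive scanning or
direct arithmetic so the package implementations are checked against an
independent route, not against themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from oxymet.chemmass import mass_error
from oxymet.complib import CompoundLibrary, CompoundRecord, bundled_library
from oxymet.features import FeatureCluster


@pytest.fixture(scope="session")
def library():
    return bundled_library()


def brute_force_dereplicate(clusters, lib, params):
    """Exhaustive double loop over clusters x records; mirrors the contract."""
    out = {}
    for cluster in clusters:
        hits = []
        for rec in lib:
            if not params.source_ok(rec.biological_source):
                continue
            err = mass_error(cluster.consensus_mass, rec.monoisotopic_mass)
            if abs(err.delta_da) < params.max_delta_da and abs(err.delta_ppm) < params.max_delta_ppm:
                hits.append((abs(err.delta_ppm), rec.name))
        hits.sort()
        out[cluster.cluster_id] = [name for _, name in hits]
    return out


def random_derep_instance(rng, n_clusters=30, n_compounds=60):
    """A random library + cluster set with masses bunched to force near-hits."""
    sources = ["Streptomyces", "Rhodococcus", "Nocardia"]
    records = []
    base_masses = rng.uniform(160, 900, size=n_compounds)
    for i, m in enumerate(base_masses):
        records.append(
            CompoundRecord(
                name=f"cpd_{i:03d}",
                monoisotopic_mass=float(m),
                biological_source=sources[int(rng.integers(3))],
            )
        )
    lib = CompoundLibrary(records)
    clusters = []
    for i in range(n_clusters):
        # half the clusters sit within a few mDa/ppm of some library mass
        if rng.random() < 0.5:
            center = float(rng.choice(base_masses))
            mass = center + float(rng.normal(0, 0.0015))
        else:
            mass = float(rng.uniform(160, 900))
        clusters.append(
            FeatureCluster(
                cluster_id=i, members=[], consensus_mass=mass,
                consensus_rt=float(rng.uniform(0, 18)),
            )
        )
    return clusters, lib


def make_cluster(cluster_id, mass, rt=1.0):
    return FeatureCluster(cluster_id=cluster_id, members=[], consensus_mass=mass, consensus_rt=rt)


@pytest.fixture
def rng():
    return np.random.default_rng(20230707)


def presence_matrix_from_truth(truth, config):
    """Presence matrix built straight from the generator's realized cells.

    Bypasses feature alignment so detector properties can be tested in
    isolation: row i is planted molecule i, a cell is True iff the
    molecule survived dropout in that sample.
    """
    import pandas as pd

    from oxymet.differential import PresenceMatrix
    from oxymet.synthdata import design_cells

    cells = design_cells(config.conditions, config.weeks, config.fractions)
    cols = pd.MultiIndex.from_tuples(
        [(config.strain, c, w, f) for (c, w, f) in cells],
        names=["strain", "condition", "week", "fraction"],
    )
    names = [p.name for p in truth.planted]
    vals = pd.DataFrame(
        [[cell in truth.realized[n] for cell in cells] for n in names],
        index=range(len(names)),
        columns=cols,
    )
    rts = {i: truth.planted[i].rt for i in range(len(names))}
    masses = {i: truth.planted[i].mass for i in range(len(names))}
    return PresenceMatrix(values=vals, consensus_rt=rts, consensus_mass=masses)


def gotoh_free_end_score(q, r, match=2.0, mismatch=-1.0, open_=-5.0, extend=-2.0):
    """Affine-gap global alignment score with free terminal gaps.

    Independent three-state dynamic program: a gap of length L costs
    open + (L-1)*extend internally and nothing at either end.
    """
    n, m = len(q), len(r)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in r (consumes q)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in q (consumes r)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading query overhang, free
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # leading reference overhang, free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend, X[i][j - 1] + open_)
    best = neg
    for i in range(n + 1):  # trailing query overhang free
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):  # trailing reference overhang free
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def random_additive_matrix(rng, n_taxa):
    """Tip-tip path-length matrix of a random binary tree with positive edges.

    Returns (labels, matrix).  Path lengths are computed by brute-force
    accumulation, independent of any tree-inference code.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # each live node carries the distances from its subtree's tips to its root
    live = [({lab: 0.0}, lab) for lab in labels]
    dist = {}
    while len(live) > 1:
        i, j = sorted(rng.choice(len(live), size=2, replace=False))
        (da, _), (db, _) = live[i], live[j]
        bi = float(rng.uniform(0.1, 1.0))
        bj = float(rng.uniform(0.1, 1.0))
        for ta, la in da.items():
            for tb, lb in db.items():
                dist[frozenset((ta, tb))] = la + bi + lb + bj
        merged = {t: l + bi for t, l in da.items()}
        merged.update({t: l + bj for t, l in db.items()})
        live = [live[k] for k in range(len(live)) if k not in (i, j)]
        live.append((merged, None))
    mat = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            mat[a, b] = mat[b, a] = dist[frozenset((labels[a], labels[b]))]
    return labels, mat
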