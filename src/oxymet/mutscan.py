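"""16S rRNA substitution scanning and distance/tree phylogenetics.

The mutation scan compares each weekly 16S consensus sequence of a strain
to its week-1 baseline by pairwise global alignment, calls point
substitutions at quality-trusted, unambiguous columns, and expresses each
call in the coordinates of an external reference sequence (conventionally
the E. coli 16S gene) so it can be placed in the V1-V9 hypervariable
regions.

Because the sequences involved are near-identical amplicons of one gene,
pairwise global alignment against the baseline is used in place of a true
multiple alignment: on such inputs the two give the same substitution
columns, and the pairwise route is directly checkable against a dynamic
programming oracle.

Strain identification uses Tamura-Nei (TN93) distances and neighbor
joining, the standard pairing for 16S similarity trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "SequenceRecord",
    "SubstitutionCall",
    "RegionMap",
    "AlignmentResult",
    "SaturationError",
    "read_fasta",
    "write_fasta",
    "load_region_map",
    "global_align",
    "call_substitutions",
    "map_to_regions",
    "position_map",
    "scan_series",
    "tn93_distance",
    "tn93_matrix",
    "neighbor_joining",
]

_UNAMBIGUOUS = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")

#: Purines / pyrimidines for the two TN93 transition classes.
_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")


class SaturationError(ArithmeticError):
    """TN93 distance undefined: a logarithm argument fell to or below zero."""


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with an optional per-position trust mask."""

    id: str
    bases: str
    quality_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - _IUPAC
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC characters {sorted(bad)}")
        if not self.bases:
            raise ValueError(f"{self.id}: empty sequence")
        if self.quality_mask is not None and len(self.quality_mask) != len(self.bases):
            raise ValueError(f"{self.id}: quality mask length mismatch")

    def __len__(self) -> int:
        return len(self.bases)

    def trusted(self, pos0: int) -> bool:
        return self.quality_mask is None or self.quality_mask[pos0]


@dataclass(frozen=True)
class SubstitutionCall:
    """One point substitution, in query and reference coordinates (1-based)."""

    sample_id: str
    query_position: int
    ref_position: int | None
    ref_base: str
    alt_base: str
    region_label: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if self.ref_base not in _UNAMBIGUOUS or self.alt_base not in _UNAMBIGUOUS:
            raise ValueError("substitution bases must be unambiguous A/C/G/T")


#: Ordered (label, start, end) intervals, 1-based inclusive, non-overlapping.
RegionMap = list[tuple[str, int, int]]


def load_region_map(path: str | Path | None = None) -> RegionMap:
    """Load a V-region interval table (bundled conventional table by default)."""
    if path is None:
        with resources.files("oxymet.data").joinpath("variable_regions.csv").open("r") as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    regions = [(str(r.region), int(r.start), int(r.end)) for r in df.itertuples()]
    regions.sort(key=lambda t: t[1])
    prev_end = 0
    for label, start, end in regions:
        if start <= prev_end:
            raise ValueError(f"region {label} overlaps the previous interval")
        if end < start:
            raise ValueError(f"region {label} has end < start")
        prev_end = end
    return regions


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, bases=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), 70):
                fh.write(rec.bases[i : i + 70] + "\n")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment as two gapped strings plus its score."""

    query_aligned: str
    ref_aligned: str
    score: float


def global_align(
    query: SequenceRecord | str,
    reference: SequenceRecord | str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment with affine gaps and free ends.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``; terminal
    gaps are un-penalized, so a shorter amplicon aligns inside a longer
    reference without cost.
    """
    q = query.bases if isinstance(query, SequenceRecord) else query.upper()
    r = reference.bases if isinstance(reference, SequenceRecord) else reference.upper()
    if not q or not r:
        raise ValueError("cannot align empty sequences")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    try:
        aligner.open_internal_gap_score = gap_open
        aligner.extend_internal_gap_score = gap_extend
    except AttributeError:  # biopython < 1.88 naming
        aligner.internal_open_gap_score = gap_open
        aligner.internal_extend_gap_score = gap_extend
    aligner.end_gap_score = 0.0
    alignment = aligner.align(q, r)[0]
    return AlignmentResult(
        query_aligned=str(alignment[0]),
        ref_aligned=str(alignment[1]),
        score=float(alignment.score),
    )


def call_substitutions(
    alignment: AlignmentResult,
    sample_id: str = "",
    query_mask: tuple[bool, ...] | None = None,
    ref_mask: tuple[bool, ...] | None = None,
) -> list[SubstitutionCall]:
    """Point substitutions from an alignment, 1-based in both sequences.

    A column is called only when both bases are unambiguous A/C/G/T,
    unequal, and trusted under the respective quality masks; gap and
    ambiguity columns are skipped, never called.
    """
    qa, ra = alignment.query_aligned, alignment.ref_aligned
    if len(qa) != len(ra):
        raise ValueError("aligned strings differ in length")
    calls = []
    qpos = rpos = 0
    for qc, rc in zip(qa, ra):
        if qc != "-":
            qpos += 1
        if rc != "-":
            rpos += 1
        if qc == "-" or rc == "-":
            continue
        if qc not in _UNAMBIGUOUS or rc not in _UNAMBIGUOUS or qc == rc:
            continue
        if query_mask is not None and not query_mask[qpos - 1]:
            continue
        if ref_mask is not None and not ref_mask[rpos - 1]:
            continue
        calls.append(
            SubstitutionCall(
                sample_id=sample_id,
                query_position=qpos,
                ref_position=rpos,
                ref_base=rc,
                alt_base=qc,
            )
        )
    return calls


def map_to_regions(ref_position: int, region_map: RegionMap, ref_length: int | None = None) -> str:
    """Label a reference coordinate with its V region, else "conserved"."""
    if ref_position < 1:
        raise ValueError(f"position must be >= 1, got {ref_position}")
    if ref_length is not None and ref_position > ref_length:
        raise ValueError(f"position {ref_position} beyond reference length {ref_length}")
    for label, start, end in region_map:
        if start <= ref_position <= end:
            return label
    return "conserved"


def position_map(query: SequenceRecord | str, reference: SequenceRecord | str) -> dict[int, int]:
    """1-based query position -> reference position map via global alignment.

    Query positions aligned to a reference gap are absent from the map.
    """
    aln = global_align(query, reference)
    mapping: dict[int, int] = {}
    qpos = rpos = 0
    for qc, rc in zip(aln.query_aligned, aln.ref_aligned):
        if qc != "-":
            qpos += 1
        if rc != "-":
            rpos += 1
        if qc != "-" and rc != "-":
            mapping[qpos] = rpos
    return mapping


def scan_series(
    series: list[SequenceRecord],
    coord_reference: SequenceRecord | None = None,
    region_map: RegionMap | None = None,
) -> list[SubstitutionCall]:
    """Scan a weekly sequence series for substitutions against its baseline.

    The first record is the baseline; every later record is globally
    aligned to it and substitutions are called at trusted columns.  When a
    coordinate reference is supplied, baseline positions are re-expressed
    in its numbering (via a second alignment) and labelled with the V
    region; positions falling in a reference gap keep ``ref_position``
    None and stay unlabelled.
    """
    if len(series) < 2:
        return []
    if region_map is None:
        region_map = load_region_map()
    baseline = series[0]
    base_to_ref = (
        position_map(baseline, coord_reference) if coord_reference is not None else None
    )
    out: list[SubstitutionCall] = []
    for rec in series[1:]:
        aln = global_align(rec, baseline)
        for call in call_substitutions(
            aln,
            sample_id=rec.id,
            query_mask=rec.quality_mask,
            ref_mask=baseline.quality_mask,
        ):
            if base_to_ref is None:
                out.append(call)
                continue
            ref_pos = base_to_ref.get(call.ref_position)
            label = (
                map_to_regions(ref_pos, region_map, len(coord_reference))
                if ref_pos is not None
                else None
            )
            out.append(
                SubstitutionCall(
                    sample_id=call.sample_id,
                    query_position=call.query_position,
                    ref_position=ref_pos,
                    ref_base=call.ref_base,
                    alt_base=call.alt_base,
                    region_label=label,
                )
            )
    return out


def _paired_columns(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    return [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS
    ]


def tn93_distance(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Uses pairwise deletion: columns with a gap or ambiguity code in either
    sequence are dropped.  The model separates purine (A<->G) and
    pyrimidine (C<->T) transitions from transversions and uses empirical
    base frequencies averaged over both sequences.  No rate heterogeneity.

    Raises
    ------
    SaturationError
        When divergence is too high for the model (log argument <= 0);
        the distance is then undefined, not merely large.
    """
    sa = a.bases if isinstance(a, SequenceRecord) else a
    sb = b.bases if isinstance(b, SequenceRecord) else b
    cols = _paired_columns(sa, sb)
    n = len(cols)
    if n == 0:
        raise ValueError("no comparable (unambiguous, ungapped) columns")
    counts = {base: 0 for base in "ACGT"}
    p1 = p2 = q = 0
    for x, y in cols:
        counts[x] += 1
        counts[y] += 1
        if x == y:
            continue
        pair = {x, y}
        if pair == set(_PURINES):
            p1 += 1
        elif pair == set(_PYRIMIDINES):
            p2 += 1
        else:
            q += 1
    total = 2 * n
    g = {base: counts[base] / total for base in "ACGT"}
    g_r = g["A"] + g["G"]
    g_y = g["C"] + g["T"]
    if g_r == 0 or g_y == 0:
        raise SaturationError("degenerate base composition for TN93")
    p1 /= n
    p2 /= n
    q /= n
    k1 = 2 * g["A"] * g["G"] / g_r
    k2 = 2 * g["T"] * g["C"] / g_y
    k3 = 2 * (g_r * g_y - g["A"] * g["G"] * g_y / g_r - g["T"] * g["C"] * g_r / g_y)
    w1 = 1 - p1 / k1 - q / (2 * g_r) if k1 > 0 else 1.0
    w2 = 1 - p2 / k2 - q / (2 * g_y) if k2 > 0 else 1.0
    w3 = 1 - q / (2 * g_r * g_y)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("substitution saturation: TN93 distance undefined")
    d = 0.0
    if k1 > 0:
        d -= k1 * math.log(w1)
    if k2 > 0:
        d -= k2 * math.log(w2)
    d -= k3 * math.log(w3)
    return max(d, 0.0)


def tn93_matrix(records: list[SequenceRecord]) -> pd.DataFrame:
    """Symmetric TN93 distance matrix over aligned, equal-length records."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tn93_distance(records[i], records[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dist: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree as Newick.

    Standard Q-criterion agglomeration with the usual branch-length
    updates; joins tie-break on the smallest taxon indices.  A negative
    branch length is clamped to zero with the residual moved to its sister
    edge, keeping the pair's summed length (the usual NJ convention).  The
    final three nodes are joined to an unresolved (trifurcating) root.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.columns)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")

    nodes = [_Node(name=lab) for lab in labels]
    d = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                qij = (m - 2) * sub[i, j] - r[i] - r[j]
                if qij < best_q - 1e-12:
                    best_q = qij
                    best = (i, j)
        i, j = best
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        gi, gj = active[i], active[j]
        new = _Node(children=[(nodes[gi], li), (nodes[gj], lj)])
        # distances from the new internal node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k_local, gk in enumerate(active):
            if k_local in (i, j):
                continue
            new_row[gk] = 0.5 * (d[gi, gk] + d[gj, gk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :] = new_row
        d[:, -1] = new_row
        nodes.append(new)
        active = [g for g in active if g not in (gi, gj)] + [d.shape[0] - 1]

    # closed-form three-point solution for the last three nodes
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return root.newick() + ";"
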