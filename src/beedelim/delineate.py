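"""Supervised phenetic species delimitation.

Specimens are clustered by single linkage on a (possibly two-locus
combined) genetic distance matrix; the clustering threshold is chosen by
scanning a grid and maximizing the Hubert-Arabie adjusted Rand index
against morphospecies labels.  Taxonomic must-link constraints and an
incongruence report (clusters lumping several morphospecies, morphospecies
split over several clusters) support the iterative reconciliation of
morphology and molecules.

Missing pairwise distances (specimens sharing no locus) simply contribute
no edge at any threshold; such specimens still join a cluster through
intermediate specimens, mirroring single-linkage chaining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OTUPartition",
    "ThresholdCurve",
    "IncongruenceRecord",
    "IncongruenceReport",
    "single_linkage",
    "cut_at_threshold",
    "adjusted_rand",
    "threshold_scan",
    "default_grid",
    "apply_constraints",
    "find_incongruences",
]


@dataclass
class OTUPartition:
    """A labeling of specimens into OTUs with method provenance.

    OTU identifiers are deterministic: the lexicographically smallest
    member specimen ID.
    """

    assignment: dict[str, str]
    method: str = "unspecified"
    threshold: float | None = None

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, otu in self.assignment.items():
            out.setdefault(otu, []).append(sid)
        return {k: sorted(v) for k, v in sorted(out.items())}

    def restricted(self, ids: Sequence[str]) -> dict[str, str]:
        return {i: self.assignment[i] for i in ids if i in self.assignment}

    def as_frozensets(self, ids: Sequence[str] | None = None) -> frozenset:
        """The partition (optionally restricted) as a frozenset of
        frozensets — a label-free canonical form."""
        groups: dict[str, set[str]] = {}
        pool = self.assignment if ids is None else {
            i: self.assignment[i] for i in ids if i in self.assignment
        }
        for sid, otu in pool.items():
            groups.setdefault(otu, set()).add(sid)
        return frozenset(frozenset(g) for g in groups.values())

    def write_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("specimen_id\totu_id\n")
            for sid in sorted(self.assignment):
                fh.write(f"{sid}\t{self.assignment[sid]}\n")


def _relabel(ids: Sequence[str], comp: np.ndarray) -> dict[str, str]:
    reps: dict[int, str] = {}
    for sid, c in zip(ids, comp):
        c = int(c)
        if c not in reps or sid < reps[c]:
            reps[c] = sid
    return {sid: reps[int(c)] for sid, c in zip(ids, comp)}


def cut_at_threshold(dm: DistanceMatrix, t: float, method: str = "single-linkage") -> OTUPartition:
    """Connected components of the graph with edges where d(i, j) <= t.

    Equivalent to cutting a single-linkage dendrogram at height ``t``;
    NaN (missing) distances contribute no edge.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    vals = dm.values
    with np.errstate(invalid="ignore"):
        adj = np.isfinite(vals) & (vals <= t)
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    return OTUPartition(
        assignment=_relabel(dm.ids, comp), method=method, threshold=float(t)
    )


def single_linkage(dm: DistanceMatrix) -> np.ndarray:
    """Single-linkage merge list (SciPy linkage format) for a complete matrix.

    Cutting the resulting dendrogram at height ``t`` yields exactly the
    connected components of :func:`cut_at_threshold`.
    """
    if len(dm) < 2:
        raise ValueError("at least two items required for clustering")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError(
            "single-linkage merge list requires a complete matrix; use "
            "cut_at_threshold for matrices with missing pairs"
        )
    return linkage(squareform(dm.values, checks=False), method="single")


def adjusted_rand(
    partition_a: Mapping[str, str], partition_b: Mapping[str, str]
) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Restricted to the items present in both mappings (logged when that
    drops anything); 1 for identical partitions, about 0 for independent
    ones, negative for worse-than-chance agreement.
    """
    common = sorted(set(partition_a) & set(partition_b))
    if len(common) < len(partition_a) or len(common) < len(partition_b):
        logger.info(
            "ARI restricted to %d shared item(s) (of %d / %d)",
            len(common), len(partition_a), len(partition_b),
        )
    n = len(common)
    if n < 2:
        raise ValueError("adjusted Rand index requires at least two shared items")
    table: dict[tuple[str, str], int] = {}
    a_marg: dict[str, int] = {}
    b_marg: dict[str, int] = {}
    for item in common:
        a, b = partition_a[item], partition_b[item]
        table[(a, b)] = table.get((a, b), 0) + 1
        a_marg[a] = a_marg.get(a, 0) + 1
        b_marg[b] = b_marg.get(b, 0) + 1
    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(v, 2) for v in a_marg.values())
    sum_b = sum(comb(v, 2) for v in b_marg.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-singletons/all-one)
        return 1.0 if sum_ij == expected else 0.0
    return (sum_ij - expected) / (max_index - expected)


@dataclass
class ThresholdCurve:
    """Number of OTUs (and congruence with labels) along a threshold grid."""

    thresholds: np.ndarray
    n_otus: np.ndarray
    ari: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.n_otus = np.asarray(self.n_otus, dtype=int)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("threshold grid must be strictly ascending")
        if np.any(np.diff(self.n_otus) > 0):
            raise ValueError("n_otus must be non-increasing in the threshold")

    def write_csv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("threshold,n_otus,ari\n")
            ari = self.ari if self.ari is not None else [np.nan] * len(self.thresholds)
            for t, n, a in zip(self.thresholds, self.n_otus, ari):
                fh.write(f"{t:.6g},{n},{'' if np.isnan(a) else f'{a:.6f}'}\n")


def default_grid(stop: float = 0.05, step: float = 0.0001) -> np.ndarray:
    """Threshold grid 0..stop in steps of ``step`` (both ends included).

    The default step is fine enough to express the threshold regime where
    barcode-gap switches typically fall (a few thousandths of a
    substitution per site) exactly.
    """
    n = int(round(stop / step))
    return np.linspace(0.0, n * step, n + 1)


def threshold_scan(
    dm: DistanceMatrix,
    morph_labels: Mapping[str, str],
    grid: np.ndarray | None = None,
) -> tuple[ThresholdCurve, float]:
    """Scan clustering thresholds and pick the most label-congruent one.

    At every grid point the matrix is cut and the adjusted Rand index
    against ``morph_labels`` (restricted to labeled specimens) recorded.
    Returns the curve and ``t*``, the smallest threshold attaining the
    maximal ARI — over-splitting being the cheaper error, since residual
    lumps are harder to detect downstream than residual splits.
    """
    labels = {k: v for k, v in morph_labels.items() if v}
    labeled = sorted(set(labels) & set(dm.ids))
    if not labeled:
        raise ValueError("threshold scan requires at least some labeled specimens")
    if len(labeled) < 2:
        raise ValueError("threshold scan requires at least two labeled specimens")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    n_otus = np.empty(len(grid), dtype=int)
    ari = np.empty(len(grid))
    for k, t in enumerate(grid):
        part = cut_at_threshold(dm, t)
        n_otus[k] = part.n_otus
        ari[k] = adjusted_rand(part.restricted(labeled), labels)
    curve = ThresholdCurve(thresholds=grid, n_otus=n_otus, ari=ari)
    t_star = float(grid[int(np.argmax(ari))])  # argmax returns first maximum
    return curve, t_star


def apply_constraints(
    partition: OTUPartition, must_link: Sequence[tuple[str, str]]
) -> OTUPartition:
    """Merge OTUs joined by taxonomic must-link specimen pairs.

    Union-find over the constrained pairs; never splits anything, and is
    idempotent.  Unknown specimens in a constraint are an error.
    """
    assignment = dict(partition.assignment)
    parent: dict[str, str] = {o: o for o in set(assignment.values())}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in must_link:
        for s in (a, b):
            if s not in assignment:
                raise KeyError(f"constraint references unknown specimen {s!r}")
        ra, rb = find(assignment[a]), find(assignment[b])
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    merged = {sid: find(otu) for sid, otu in assignment.items()}
    # canonical OTU id: lexicographically smallest member
    reps: dict[str, str] = {}
    for sid, otu in merged.items():
        if otu not in reps or sid < reps[otu]:
            reps[otu] = sid
    final = {sid: reps[otu] for sid, otu in merged.items()}
    return OTUPartition(
        assignment=final,
        method=partition.method + "+constraints" if must_link else partition.method,
        threshold=partition.threshold,
    )


@dataclass(frozen=True)
class IncongruenceRecord:
    kind: str  # "lump" | "split"
    morphospecies: tuple[str, ...]
    otus: tuple[str, ...]
    specimen_ids: tuple[str, ...]
    max_within_distance: float


@dataclass
class IncongruenceReport:
    records: list[IncongruenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lumps(self) -> list[IncongruenceRecord]:
        return [r for r in self.records if r.kind == "lump"]

    @property
    def splits(self) -> list[IncongruenceRecord]:
        return [r for r in self.records if r.kind == "split"]


def _max_within(dm: DistanceMatrix | None, ids: Sequence[str]) -> float:
    if dm is None:
        return float("nan")
    idx = [dm.ids.index(i) for i in ids if i in dm.ids]
    if len(idx) < 2:
        return float("nan")
    sub = dm.values[np.ix_(idx, idx)]
    with np.errstate(invalid="ignore"):
        return float(np.nanmax(sub))


def find_incongruences(
    partition: OTUPartition,
    morph_labels: Mapping[str, str],
    dm: DistanceMatrix | None = None,
) -> IncongruenceReport:
    """Lump and split records between an OTU partition and morphospecies.

    One ``lump`` record per OTU containing more than one morphospecies;
    one ``split`` record per morphospecies spread over more than one OTU.
    Unlabeled specimens are ignored.  The report is empty exactly when the
    partition and the labels agree on every labeled specimen.
    """
    labels = {k: v for k, v in morph_labels.items() if v and k in partition.assignment}
    records: list[IncongruenceRecord] = []
    by_otu: dict[str, list[str]] = {}
    by_morph: dict[str, list[str]] = {}
    for sid, otu in partition.assignment.items():
        if sid in labels:
            by_otu.setdefault(otu, []).append(sid)
            by_morph.setdefault(labels[sid], []).append(sid)
    for otu in sorted(by_otu):
        ids = sorted(by_otu[otu])
        morphs = tuple(sorted({labels[s] for s in ids}))
        if len(morphs) > 1:
            records.append(
                IncongruenceRecord(
                    kind="lump", morphospecies=morphs, otus=(otu,),
                    specimen_ids=tuple(ids),
                    max_within_distance=_max_within(dm, ids),
                )
            )
    for morph in sorted(by_morph):
        ids = sorted(by_morph[morph])
        otus = tuple(sorted({partition.assignment[s] for s in ids}))
        if len(otus) > 1:
            records.append(
                IncongruenceRecord(
                    kind="split", morphospecies=(morph,), otus=otus,
                    specimen_ids=tuple(ids),
                    max_within_distance=_max_within(dm, ids),
                )
            )
    return IncongruenceReport(records=records)
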