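"""Unsupervised (DNA-only) species delineators and consensus resolution.

Three delineators act as independent witnesses against the
morphology-constrained clustering:

* :func:`disjunct_detect` — the barcode gap: the longest plateau in the
  OTU-count-versus-threshold curve marks the interval of thresholds over
  which clusters are stable, the signature of the switch from within- to
  between-species distances.
* :func:`ptp_delineate` — a Poisson tree process: branch lengths are
  modeled as exponential with one rate on between-species edges and
  another on within-species edges; a greedy search over species
  boundaries maximizes the two-class likelihood.
* :func:`k2p_split_rule` — pairs of supposed conspecifics more than 9%
  apart in COI K2P distance are flagged as almost certainly heterospecific.

:func:`resolve_consensus` applies the evidence rule: a morphological
grouping is overridden only when every delineator with data for the group
agrees on the same alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .delineate import IncongruenceReport, OTUPartition
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DisjunctResult",
    "PTPResult",
    "SplitFlag",
    "ContestedGroup",
    "disjunct_detect",
    "ptp_delineate",
    "k2p_split_rule",
    "k2p_rule_grouping",
    "build_evidence",
    "resolve_consensus",
]

K2P_SPLIT_THRESHOLD = 0.09


# ---------------------------------------------------------------------------
# barcode gap

@dataclass(frozen=True)
class DisjunctResult:
    threshold: float
    n_otus: int
    plateau_length: int
    start_index: int
    drop_before: int
    drop_after: int


def disjunct_detect(curve) -> DisjunctResult:
    """Locate the barcode-gap plateau of a threshold curve.

    Returns the smallest threshold beginning the longest maximal run of
    constant OTU count (ties go to the earliest run), together with the
    plateau length and the OTU-count drops flanking it.  A strictly
    decreasing curve has no plateau of length >= 2 and raises.
    """
    n_otus = np.asarray(curve.n_otus)
    thresholds = np.asarray(curve.thresholds)
    if len(n_otus) < 10:
        raise ValueError("disjunct detection needs a curve of at least 10 grid points")
    runs = []  # (start, length)
    start = 0
    for i in range(1, len(n_otus) + 1):
        if i == len(n_otus) or n_otus[i] != n_otus[start]:
            runs.append((start, i - start))
            start = i
    best_start, best_len = max(runs, key=lambda r: (r[1], -r[0]))
    if best_len < 2:
        raise ValueError("no disjunct: the threshold curve has no plateau")
    end = best_start + best_len - 1
    drop_before = (
        int(n_otus[best_start - 1] - n_otus[best_start]) if best_start > 0 else 0
    )
    drop_after = int(n_otus[end] - n_otus[end + 1]) if end + 1 < len(n_otus) else 0
    return DisjunctResult(
        threshold=float(thresholds[best_start]),
        n_otus=int(n_otus[best_start]),
        plateau_length=int(best_len),
        start_index=int(best_start),
        drop_before=drop_before,
        drop_after=drop_after,
    )


# ---------------------------------------------------------------------------
# Poisson tree process

@dataclass
class PTPResult:
    partition: OTUPartition
    lambda_between: float | None
    lambda_within: float | None
    log_likelihood: float
    long_branch_flags: list[str] = field(default_factory=list)

    @property
    def n_otus(self) -> int:
        return self.partition.n_otus


def _class_term(n: int, s: float) -> float:
    if n == 0:
        return 0.0
    return n * (np.log(n / s) - 1.0)


def ptp_delineate(
    tree: dendropy.Tree,
    min_edge: float = 1e-9,
    species_penalty: float = 3.0,
) -> PTPResult:
    """Two-rate Poisson tree process delimitation by greedy search.

    Every valid delimitation marks, for each species, the edges of its
    spanning subtree as within-species; all remaining edges (including the
    edge above each species subtree) are between-species.  Edge lengths in
    each class are modeled i.i.d. exponential, with rate MLEs
    ``lambda = n_edges / total_length`` per class.  The search starts both
    from a single species and from all-singletons and greedily toggles
    species boundaries at internal nodes (splitting a species at its root,
    or merging sibling species into their parent) while the penalized
    score improves; the better of the two ends is returned.

    Because a two-rate fit can never lose to a one-rate fit, pure
    likelihood always favors splitting; moves are therefore scored by
    ``log L - species_penalty * n_species``, an AIC-type complexity
    penalty requiring roughly ``2 Δlog L > 6`` per added boundary.  At the
    default penalty, trees whose edges come from a single exponential are
    left as one species while genuinely bimodal branch-length structure
    is still split.  Set ``species_penalty=0`` for the pure
    maximum-likelihood search (whose log-likelihood is then monotone
    along the greedy path).

    Species whose mean within-species edge length exceeds ten times the
    within-class mean ``1 / lambda_within`` are flagged: a long pendant
    edge nested among near-identical tips is the classic failure mode that
    inflates species counts.
    """
    tips = [l for l in tree.leaf_node_iter()]
    if len(tips) < 4:
        raise ValueError("PTP requires at least 4 tips")
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = [
        index[id(n.parent_node)] if n.parent_node is not None else -1 for n in nodes
    ]
    children: list[list[int]] = [[] for _ in nodes]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    lengths = np.zeros(len(nodes))
    n_perturbed = 0
    for i, n in enumerate(nodes):
        if parent[i] < 0:
            continue
        bl = n.edge.length or 0.0
        if bl <= 0:
            bl = min_edge
            n_perturbed += 1
        lengths[i] = bl
    if n_perturbed:
        logger.info("perturbed %d nonpositive edge length(s) to %g", n_perturbed, min_edge)
    is_leaf = np.array([n.is_leaf() for n in nodes])
    # edges strictly below each node: count and total length
    sub_n = np.zeros(len(nodes), dtype=int)
    sub_s = np.zeros(len(nodes))
    for i in range(len(nodes) - 1, -1, -1):
        for c in children[i]:
            sub_n[i] += sub_n[c] + 1
            sub_s[i] += sub_s[c] + lengths[c]
    total_n = len(nodes) - 1
    total_s = float(lengths.sum())

    def log_like(n_w: int, s_w: float) -> float:
        n_b = total_n - n_w
        s_b = total_s - s_w
        return _class_term(n_b, s_b) + _class_term(n_w, s_w)

    def greedy(roots: set[int]) -> tuple[set[int], float]:
        n_w = int(sum(sub_n[r] for r in roots))
        s_w = float(sum(sub_s[r] for r in roots))
        score = log_like(n_w, s_w) - species_penalty * len(roots)
        while True:
            best = None  # (score, kind, node, d_n, d_s, d_k)
            for r in sorted(roots):
                if is_leaf[r]:
                    continue
                d_n = -len(children[r])
                d_s = -float(sum(lengths[c] for c in children[r]))
                d_k = len(children[r]) - 1
                cand = (
                    log_like(n_w + d_n, s_w + d_s)
                    - species_penalty * (len(roots) + d_k)
                )
                if best is None or cand > best[0]:
                    best = (cand, "split", r, d_n, d_s)
            parents = {parent[r] for r in roots if parent[r] >= 0}
            for p in sorted(parents):
                if p in roots or not all(c in roots for c in children[p]):
                    continue
                d_n = len(children[p])
                d_s = float(sum(lengths[c] for c in children[p]))
                d_k = 1 - len(children[p])
                cand = (
                    log_like(n_w + d_n, s_w + d_s)
                    - species_penalty * (len(roots) + d_k)
                )
                if best is None or cand > best[0]:
                    best = (cand, "merge", p, d_n, d_s)
            if best is None or best[0] <= score + 1e-12:
                return roots, score
            _, kind, node, d_n, d_s = best
            score = best[0]
            n_w += d_n
            s_w += d_s
            if kind == "split":
                roots.remove(node)
                roots.update(children[node])
            else:
                for c in children[node]:
                    roots.remove(c)
                roots.add(node)

    roots_a, score_a = greedy({0})
    roots_b, score_b = greedy({i for i in range(len(nodes)) if is_leaf[i]})
    if score_a > score_b or (score_a == score_b and len(roots_a) <= len(roots_b)):
        roots = roots_a
    else:
        roots = roots_b

    # partition and per-class MLEs
    assignment: dict[str, str] = {}
    species_edges: dict[int, tuple[int, float]] = {}
    for r in sorted(roots):
        node = nodes[r]
        members = sorted(
            l.taxon.label for l in ([node] if node.is_leaf() else node.leaf_iter())
        )
        otu = members[0]
        for m in members:
            assignment[m] = otu
        species_edges[r] = (int(sub_n[r]), float(sub_s[r]))
    n_w = sum(n for n, _ in species_edges.values())
    s_w = sum(s for _, s in species_edges.values())
    n_b, s_b = total_n - n_w, total_s - s_w
    ll = _class_term(n_b, s_b) + _class_term(n_w, s_w)
    lam_b = n_b / s_b if n_b > 0 else None
    lam_w = n_w / s_w if n_w > 0 else None
    flags = []
    if lam_w is not None:
        for r, (n, s) in species_edges.items():
            if n > 0 and (s / n) > 10.0 / lam_w:
                otu = min(
                    l.taxon.label
                    for l in ([nodes[r]] if nodes[r].is_leaf() else nodes[r].leaf_iter())
                )
                flags.append(otu)
    return PTPResult(
        partition=OTUPartition(assignment=assignment, method="ptp"),
        lambda_between=lam_b,
        lambda_within=lam_w,
        log_likelihood=float(ll),
        long_branch_flags=sorted(flags),
    )


# ---------------------------------------------------------------------------
# K2P 9% rule

@dataclass(frozen=True)
class SplitFlag:
    otu: str
    pairs: tuple[tuple[str, str, float], ...]


def k2p_split_rule(
    partition: OTUPartition,
    coi_dm: DistanceMatrix,
    threshold: float = K2P_SPLIT_THRESHOLD,
) -> list[SplitFlag]:
    """Flag OTUs containing a conspecific pair beyond the K2P threshold.

    The comparison is strict: a pair at exactly the threshold is not
    flagged.  Pairs without COI data are skipped (and logged).
    """
    flags = []
    skipped = 0
    for otu, members in partition.members().items():
        present = [m for m in members if m in coi_dm.ids]
        skipped += len(members) - len(present)
        offending = []
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                d = coi_dm.get(a, b)
                if np.isfinite(d) and d > threshold:
                    offending.append((a, b, float(d)))
        if offending:
            flags.append(SplitFlag(otu=otu, pairs=tuple(offending)))
    if skipped:
        logger.info("K2P rule skipped %d specimen(s) without COI", skipped)
    return flags


def k2p_rule_grouping(
    specimen_ids: Sequence[str],
    coi_dm: DistanceMatrix,
    threshold: float = K2P_SPLIT_THRESHOLD,
) -> frozenset | None:
    """The grouping the K2P rule proposes for a set of specimens.

    Specimens are grouped by connectivity at K2P <= threshold.  Returns
    ``None`` when any specimen lacks COI data (the method is then
    unavailable for the group).
    """
    ids = sorted(specimen_ids)
    if any(s not in coi_dm.ids for s in ids):
        return None
    sub = coi_dm.submatrix(ids)
    from .delineate import cut_at_threshold

    part = cut_at_threshold(sub, threshold, method="k2p-rule")
    return part.as_frozensets()


# ---------------------------------------------------------------------------
# consensus resolution

def _group_by_label(ids: Sequence[str], labels: Mapping[str, str]) -> frozenset:
    groups: dict[str, set[str]] = {}
    for s in ids:
        groups.setdefault(labels[s], set()).add(s)
    return frozenset(frozenset(g) for g in groups.values())


@dataclass
class ContestedGroup:
    """One unresolved morphology/DNA incongruence with its evidence.

    ``evidence`` maps delineator name to the grouping (frozenset of
    frozensets of specimen IDs) that the delineator proposes for the
    group's specimens; delineators without data for the group are absent.
    """

    group_id: str
    kind: str
    specimen_ids: tuple[str, ...]
    morph_grouping: frozenset
    current_grouping: frozenset
    evidence: dict[str, frozenset] = field(default_factory=dict)


def build_evidence(
    report: IncongruenceReport,
    partition: OTUPartition,
    morph_labels: Mapping[str, str],
    ptp_partition: OTUPartition | None = None,
    disjunct_partition: OTUPartition | None = None,
    coi_dm: DistanceMatrix | None = None,
    k2p_threshold: float = K2P_SPLIT_THRESHOLD,
) -> list[ContestedGroup]:
    """Assemble the per-incongruence evidence table from the delineators.

    Each delineator contributes the grouping it induces on the contested
    specimens, when it has data for all of them.
    """
    groups = []
    for k, rec in enumerate(report):
        ids = rec.specimen_ids
        evidence: dict[str, frozenset] = {}
        for name, part in (("ptp", ptp_partition), ("disjunct", disjunct_partition)):
            if part is None:
                continue
            if all(s in part.assignment for s in ids):
                evidence[name] = part.as_frozensets(ids)
        if coi_dm is not None:
            g = k2p_rule_grouping(ids, coi_dm, k2p_threshold)
            if g is not None:
                evidence["k2p_rule"] = g
        groups.append(
            ContestedGroup(
                group_id=f"contest-{k + 1:02d}",
                kind=rec.kind,
                specimen_ids=ids,
                morph_grouping=_group_by_label(ids, morph_labels),
                current_grouping=partition.as_frozensets(ids),
                evidence=evidence,
            )
        )
    return groups


def _grouping_repr(grouping: frozenset) -> list[list[str]]:
    return sorted([sorted(g) for g in grouping])


def resolve_consensus(
    partition: OTUPartition,
    contested: Sequence[ContestedGroup],
) -> tuple[OTUPartition, list[dict]]:
    """Final OTUs: override morphology only on unanimous DNA evidence.

    For every contested group, if all delineators with data propose the
    same grouping and it differs from the morphological one, that grouping
    is adopted; otherwise the morphological grouping stands.  Groups with
    no DNA evidence at all are retained with a warning.  Uncontested OTUs
    are never modified.  Returns the final partition and a decision log.
    """
    tokens: dict[str, tuple] = {
        sid: ("keep", otu) for sid, otu in partition.assignment.items()
    }
    log: list[dict] = []
    for grp in contested:
        entry = {
            "group": grp.group_id,
            "kind": grp.kind,
            "specimens": list(grp.specimen_ids),
            "morphology": _grouping_repr(grp.morph_grouping),
            "evidence": {m: _grouping_repr(g) for m, g in grp.evidence.items()},
        }
        proposals = set(grp.evidence.values())
        if not grp.evidence:
            logger.warning(
                "contested group %s has no DNA evidence; retained", grp.group_id
            )
            chosen = grp.morph_grouping
            entry["decision"] = "no_evidence_retained"
        elif len(proposals) == 1:
            (proposal,) = proposals
            if proposal != grp.morph_grouping:
                chosen = proposal
                entry["decision"] = "dna_unanimous_adopted"
            else:
                chosen = grp.morph_grouping
                entry["decision"] = "dna_agrees_with_morphology"
        else:
            chosen = grp.morph_grouping
            entry["decision"] = "dna_not_unanimous_morphology_retained"
        entry["final"] = _grouping_repr(chosen)
        log.append(entry)
        for j, sub in enumerate(_grouping_repr(chosen)):
            for sid in sub:
                tokens[sid] = ("contest", grp.group_id, j)
    # canonical OTU ids: lexicographically smallest member per token
    members: dict[tuple, list[str]] = {}
    for sid, tok in tokens.items():
        members.setdefault(tok, []).append(sid)
    final = {}
    for tok, ids in members.items():
        rep = min(ids)
        for sid in ids:
            final[sid] = rep
    return (
        OTUPartition(
            assignment=final, method="consensus", threshold=partition.threshold
        ),
        log,
    )
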