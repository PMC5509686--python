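"""End-to-end orchestration of delimitation and community analysis.

``run_delineation`` chains distances → supervised threshold scan →
taxonomic constraints → incongruence detection → DNA-taxonomy delineators
→ consensus resolution.  ``run_community`` computes the per-plot diversity
table, compositional beta diversity and the permutation tests.  Both are
deterministic given the master seed; every stochastic stage derives its
own stream from the master seed and a fixed stage index.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from . import community as comm
from .dataio import CommunityTable, LocusAlignment, SpecimenRecord
from .delineate import (
    OTUPartition,
    ThresholdCurve,
    apply_constraints,
    cut_at_threshold,
    find_incongruences,
    threshold_scan,
)
from .distances import DistanceMatrix, combine_loci, pairwise_matrix
from .taxonomy import (
    DisjunctResult,
    PTPResult,
    build_evidence,
    disjunct_detect,
    ptp_delineate,
    resolve_consensus,
)
from .trees import neighbor_joining

logger = logging.getLogger(__name__)

__all__ = [
    "DelineationResult",
    "CommunityResult",
    "run_delineation",
    "run_community",
    "complete_matrix",
    "config_hash",
    "output_header",
]


def config_hash(params: Mapping) -> str:
    blob = json.dumps(
        {k: repr(v) for k, v in sorted(params.items())}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def output_header(seed, params: Mapping) -> str:
    return f"seed={seed} config={config_hash(params)}"


def complete_matrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Fill missing pairwise distances by shortest-path (metric) completion.

    Specimens sequenced at disjoint loci have no direct distance; the
    shortest path through shared-locus intermediaries is the tightest
    upper bound consistent with the triangle inequality.  Unreachable
    pairs raise.
    """
    vals = dm.values
    if np.all(np.isfinite(vals)):
        return dm
    n = len(dm)
    finite = np.isfinite(vals)
    graph = csr_matrix(np.where(finite, vals, 0.0))
    filled = shortest_path(graph, method="D", directed=False)
    still = ~np.isfinite(filled)
    if still.any():
        bad = [dm.ids[i] for i in sorted(set(np.where(still)[0]))]
        raise ValueError(f"specimens unreachable in distance graph: {bad[:10]}")
    n_filled = int((~finite).sum() // 2) - 0
    logger.info("completed %d missing pair(s) by shortest path", n_filled)
    return DistanceMatrix(
        ids=dm.ids, values=filled, model=dm.model + "+completed",
        sites_used=dm.sites_used, saturated=dm.saturated,
    )


@dataclass
class DelineationResult:
    locus_matrices: dict[str, DistanceMatrix]
    combined: DistanceMatrix
    coi_k2p: DistanceMatrix | None
    curve: ThresholdCurve
    t_star: float
    scan_partition: OTUPartition
    constrained_partition: OTUPartition
    incongruences: object
    disjunct: DisjunctResult | None
    disjunct_partition: OTUPartition | None
    ptp: PTPResult | None
    nj_tree: dendropy.Tree | None
    final_partition: OTUPartition
    decision_log: list[dict]
    stage_counts: dict[str, int] = field(default_factory=dict)


def _morph_labels(records: Sequence[SpecimenRecord]) -> dict[str, str]:
    return {
        r.specimen_id: r.morphospecies for r in records if r.morphospecies
    }


def _taxonomy_constraints(records: Sequence[SpecimenRecord]) -> list[tuple[str, str]]:
    """Must-link pairs from shared unambiguous taxonomic names."""
    by_taxon: dict[str, list[str]] = {}
    for r in records:
        if r.taxon_name:
            by_taxon.setdefault(r.taxon_name, []).append(r.specimen_id)
    pairs = []
    for ids in by_taxon.values():
        ids = sorted(ids)
        pairs.extend((ids[0], other) for other in ids[1:])
    return pairs


def run_delineation(
    records: Sequence[SpecimenRecord],
    alignments: Mapping[str, LocusAlignment],
    distance_method: str = "gtr",
    coi_locus: str = "COI",
    grid: np.ndarray | None = None,
    must_link: Sequence[tuple[str, str]] | None = None,
    run_ptp: bool = True,
) -> DelineationResult:
    """The full integrative delimitation pipeline on an assembled dataset.

    Distances per locus are combined by length weighting; the clustering
    threshold maximizes congruence with morphospecies labels; taxonomic
    must-link constraints (from shared taxon names, or supplied) are
    enforced; remaining incongruences are contested against the barcode
    gap, PTP and the COI K2P rule; morphology is overridden only on
    unanimous DNA evidence.
    """
    if len(records) < 2:
        raise ValueError("delineation requires at least two specimens")
    labels = _morph_labels(records)
    matrices = {
        name: pairwise_matrix(aln, method=distance_method)
        for name, aln in alignments.items()
    }
    combined = combine_loci(matrices.values())
    curve, t_star = threshold_scan(combined, labels, grid=grid)
    scan_part = cut_at_threshold(combined, t_star)
    scan_part.method = f"single-linkage/{distance_method}"
    constraints = (
        list(must_link) if must_link is not None else _taxonomy_constraints(records)
    )
    constrained = apply_constraints(scan_part, constraints)
    report = find_incongruences(constrained, labels, dm=combined)

    disjunct = disjunct_partition = None
    try:
        disjunct = disjunct_detect(curve)
        disjunct_partition = cut_at_threshold(combined, disjunct.threshold)
        disjunct_partition.method = "disjunct"
    except ValueError as exc:
        logger.warning("disjunct detection unavailable: %s", exc)

    ptp = nj_tree = None
    if run_ptp and len(combined) >= 4:
        nj_tree = neighbor_joining(complete_matrix(combined))
        # zero-length edges are perturbed at the branch-length resolution
        # of the data (half a substitution over the alignment) so that
        # clusters of identical sequences cannot form a degenerate
        # infinitely-likely within-species class
        total_sites = sum(a.length for a in alignments.values())
        ptp = ptp_delineate(nj_tree, min_edge=0.5 / max(total_sites, 1))

    coi_k2p = None
    if coi_locus in alignments and len(alignments[coi_locus].sequences) >= 2:
        coi_k2p = pairwise_matrix(alignments[coi_locus], method="k2p")

    contested = build_evidence(
        report,
        constrained,
        labels,
        ptp_partition=ptp.partition if ptp else None,
        disjunct_partition=disjunct_partition,
        coi_dm=coi_k2p,
    )
    final, decisions = resolve_consensus(constrained, contested)
    counts = {
        "specimens": len(records),
        "otus_scan": scan_part.n_otus,
        "otus_constrained": constrained.n_otus,
        "incongruences": len(report),
        "otus_disjunct": disjunct_partition.n_otus if disjunct_partition else -1,
        "otus_ptp": ptp.n_otus if ptp else -1,
        "otus_final": final.n_otus,
    }
    logger.info("delineation stages: %s", counts)
    return DelineationResult(
        locus_matrices=matrices,
        combined=combined,
        coi_k2p=coi_k2p,
        curve=curve,
        t_star=t_star,
        scan_partition=scan_part,
        constrained_partition=constrained,
        incongruences=report,
        disjunct=disjunct,
        disjunct_partition=disjunct_partition,
        ptp=ptp,
        nj_tree=nj_tree,
        final_partition=final,
        decision_log=decisions,
        stage_counts=counts,
    )


@dataclass
class CommunityResult:
    diversity: pd.DataFrame
    index_correlations: dict[str, tuple[float, float]]
    bray_curtis: pd.DataFrame
    upgma_tree: dendropy.Tree
    beta: comm.BetaResult
    anosim: tuple[float, float] | None
    permanova: tuple[float, float, float] | None
    mantel_env: tuple[float, float] | None
    comdist: pd.DataFrame
    phenogram: dendropy.Tree | None


def run_community(
    table: CommunityTable,
    tree: dendropy.Tree,
    reference_tree: dendropy.Tree | None = None,
    n_iter: int = 999,
    n_perm: int = 999,
    seed: int = 0,
    env_columns: Sequence[str] = ("altitude", "temperature", "ndmi"),
) -> CommunityResult:
    """All community analyses on a plot-by-OTU table and an OTU phylogeny.

    Habitat covariates, when present, drive the ANOSIM and PERMANOVA
    tests; the Mantel test relates Bray-Curtis dissimilarity to the
    standardized Euclidean distance over the environmental covariates.
    The with/without-reference comparison is produced when a
    reference-augmented tree is supplied.
    """
    ss = np.random.SeedSequence(seed)
    s_div, s_anosim, s_adonis, s_mantel = ss.spawn(4)
    div, corrs = comm.diversity_table(
        table, tree, reference_tree, n_iter=n_iter,
        seed=s_div,
    )
    bc = comm.dissimilarity_matrix(table)
    upg = comm.upgma(bc)
    beta = comm.beta_partition(table, mode="incidence", rarefy_to="min", seed=seed)
    anosim_res = permanova_res = mantel_res = None
    cov = table.covariates
    if cov is not None and "habitat" in cov.columns:
        groups = cov.loc[table.plots, "habitat"].to_numpy()
        _, counts = np.unique(groups, return_counts=True)
        if len(counts) >= 2 and counts.min() >= 2:
            anosim_res = comm.anosim(
                bc, groups, n_perm=n_perm, seed=np.random.default_rng(s_anosim)
            )
        permanova_res = comm.permanova(
            bc, groups, n_perm=n_perm, seed=np.random.default_rng(s_adonis)
        )
    if cov is not None:
        cols = [c for c in env_columns if c in cov.columns]
        if cols:
            env = cov.loc[table.plots, cols].to_numpy(dtype=float)
            env = (env - env.mean(axis=0)) / np.where(env.std(axis=0) == 0, 1, env.std(axis=0))
            diffs = np.linalg.norm(env[:, None, :] - env[None, :, :], axis=2)
            mantel_res = comm.mantel(
                bc, diffs, n_perm=n_perm, seed=np.random.default_rng(s_mantel)
            )
    cd = comm.comdist(tree, table)
    phen = comm.comdist_phenogram(cd) if cd.shape[0] >= 3 else None
    return CommunityResult(
        diversity=div,
        index_correlations=corrs,
        bray_curtis=bc,
        upgma_tree=upg,
        beta=beta,
        anosim=anosim_res,
        permanova=permanova_res,
        mantel_env=mantel_res,
        comdist=cd,
        phenogram=phen,
    )
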