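"""Alpha, beta and phylogenetic community diversity with permutation tests.

Implements the standard community-phylogenetics toolkit over a plot-by-OTU
abundance table and an OTU phylogeny: Gini-Simpson diversity, Faith's PD,
mean pairwise and mean nearest-taxon distance with their standardized
effect sizes (NRI/NTI under a tip-shuffle null), Bray-Curtis dissimilarity
with average-linkage clustering, a replacement/richness partition of beta
diversity with rarefaction, Mantel / ANOSIM / PERMANOVA permutation tests,
and the abundance-weighted between-community phylogenetic distance
(comdist).  Each phylogeny-derived index can be computed both on a tree of
the sampled communities only and on a reference-augmented tree, to
quantify how much reference context changes the indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata

from .dataio import CommunityTable
from .distances import DistanceMatrix
from .trees import (
    neighbor_joining,
    patristic_matrix,
    prune_to_tips,
    total_branch_length,
    tree_from_linkage,
)

logger = logging.getLogger(__name__)

__all__ = [
    "simpson_diversity",
    "faith_pd",
    "mpd",
    "mntd",
    "ses_index",
    "SESResult",
    "bray_curtis",
    "dissimilarity_matrix",
    "upgma",
    "beta_partition",
    "BetaResult",
    "mantel",
    "anosim",
    "permanova",
    "comdist",
    "comdist_phenogram",
    "diversity_table",
]


def simpson_diversity(counts: Sequence[float]) -> float:
    """Gini-Simpson diversity ``1 - Σ p_i²``.

    The probability that two randomly chosen individuals belong to
    different species; 0 for a monoculture, approaching 1 - 1/S for S
    equally abundant species.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total < 2:
        raise ValueError("Simpson diversity needs at least two individuals")
    p = x / total
    return float(1.0 - np.sum(p**2))


# ---------------------------------------------------------------------------
# phylogenetic alpha diversity

def faith_pd(tree: dendropy.Tree, community: Sequence[str]) -> float:
    """Faith's phylogenetic diversity: branch length of the minimal
    root-inclusive subtree spanning the community's taxa."""
    return total_branch_length(prune_to_tips(tree, list(community)))


def _pairs_and_weights(
    pdm: pd.DataFrame, taxa: Sequence[str], abundances: Sequence[float] | None
):
    taxa = list(taxa)
    sub = pdm.loc[taxa, taxa].to_numpy()
    if abundances is None:
        w = np.ones(len(taxa))
    else:
        w = np.asarray(abundances, dtype=float)
    return sub, w


def mpd(
    pdm: pd.DataFrame,
    taxa: Sequence[str],
    abundances: Sequence[float] | None = None,
) -> float:
    """Mean pairwise patristic distance over distinct taxon pairs.

    With abundances, pairs are weighted by abundance products.  ``pdm`` is
    a tip-by-tip patristic matrix (see :func:`beedelim.trees.patristic_matrix`).
    """
    if len(taxa) < 2:
        raise ValueError("MPD undefined for fewer than two taxa")
    sub, w = _pairs_and_weights(pdm, taxa, abundances)
    iu = np.triu_indices(len(taxa), 1)
    weights = (w[:, None] * w[None, :])[iu]
    return float(np.average(sub[iu], weights=weights))


def mntd(
    pdm: pd.DataFrame,
    taxa: Sequence[str],
    abundances: Sequence[float] | None = None,
) -> float:
    """Mean distance to the nearest other community taxon.

    Self-distances are excluded; distinct taxa at patristic distance zero
    still count as neighbors.  With abundances, the per-taxon minima are
    abundance-weighted.
    """
    if len(taxa) < 2:
        raise ValueError("MNTD undefined for fewer than two taxa")
    sub, w = _pairs_and_weights(pdm, taxa, abundances)
    masked = sub + np.diag(np.full(len(taxa), np.inf))
    mins = masked.min(axis=1)
    return float(np.average(mins, weights=w))


@dataclass(frozen=True)
class SESResult:
    observed: float
    null_mean: float
    null_sd: float
    index: float  # NRI for MPD, NTI for MNTD
    metric: str
    n_iter: int


def ses_index(
    tree_or_pdm,
    taxa: Sequence[str],
    metric: str = "mpd",
    abundances: Sequence[float] | None = None,
    n_iter: int = 999,
    seed=0,
) -> SESResult:
    """Standardized effect size of MPD (NRI) or MNTD (NTI).

    The null model shuffles tip labels across the whole phylogeny's tip
    pool: each iteration draws a random same-size taxon set from the pool
    and reassigns the observed abundances to it.  The index is the
    *negated* z-score, so phylogenetically clustered communities score
    positive (conventionally significant beyond 1.96).
    """
    if n_iter < 99:
        raise ValueError("use at least 99 null iterations")
    pdm = (
        tree_or_pdm
        if isinstance(tree_or_pdm, pd.DataFrame)
        else patristic_matrix(tree_or_pdm)
    )
    fn = {"mpd": mpd, "mntd": mntd}[metric]
    taxa = list(taxa)
    obs = fn(pdm, taxa, abundances)
    pool = list(pdm.index)
    if len(taxa) > len(pool):
        raise ValueError("community larger than the phylogeny's tip pool")
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        draw = rng.choice(len(pool), size=len(taxa), replace=False)
        if abundances is None:
            # order is irrelevant without weights; sorting keeps identical
            # draws bitwise identical (so a whole-pool community is exactly
            # degenerate)
            draw = np.sort(draw)
        null[i] = fn(pdm, [pool[k] for k in draw], abundances)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if null.max() == null.min():  # constant null; sd may round to ~1e-16
        raise ValueError(
            "degenerate null: all randomizations give the same value "
            "(community may equal the entire tip pool)"
        )
    return SESResult(
        observed=obs, null_mean=mean, null_sd=sd,
        index=float(-(obs - mean) / sd),
        metric=metric, n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# compositional beta diversity

def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity ``Σ|x_i - y_i| / Σ(x_i + y_i)`` in [0, 1]."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be nonnegative")
    denom = float((a + b).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two empty communities")
    return float(np.abs(a - b).sum() / denom)


def dissimilarity_matrix(table: CommunityTable) -> pd.DataFrame:
    plots = table.plots
    x = table.counts.to_numpy(dtype=float)
    n = len(plots)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(x[i], x[j])
    return pd.DataFrame(out, index=plots, columns=plots)


def upgma(dissim: pd.DataFrame) -> dendropy.Tree:
    """Average-linkage (UPGMA) dendrogram of a dissimilarity matrix."""
    z = linkage(squareform(dissim.to_numpy(), checks=False), method="average")
    return tree_from_linkage(z, list(dissim.index))


@dataclass(frozen=True)
class BetaResult:
    """Total beta diversity and its replacement/richness partition.

    The identity ``btotal = brepl + brich`` holds exactly: with shared
    quantity ``a`` and unilateral quantities ``b`` and ``c``,
    ``btotal = (b + c) / (a + b + c)``, ``brepl = 2 min(b, c) / (a + b + c)``
    and ``brich = |b - c| / (a + b + c)``.
    """

    btotal: float
    brepl: float
    brich: float
    mode: str
    rarefy_to: int | None = None
    n_resample: int | None = None


def _abc(x: np.ndarray, y: np.ndarray, mode: str) -> tuple[float, float, float]:
    if mode == "incidence":
        px, py = x > 0, y > 0
        a = float(np.sum(px & py))
        b = float(np.sum(px & ~py))
        c = float(np.sum(~px & py))
    elif mode == "abundance":
        a = float(np.minimum(x, y).sum())
        b = float(np.maximum(x - y, 0).sum())
        c = float(np.maximum(y - x, 0).sum())
    else:
        raise ValueError("mode must be 'incidence' or 'abundance'")
    return a, b, c


def _pairwise_beta(x: np.ndarray, y: np.ndarray, mode: str) -> tuple[float, float, float]:
    a, b, c = _abc(x, y, mode)
    denom = a + b + c
    if denom == 0:
        return 0.0, 0.0, 0.0
    return (b + c) / denom, 2 * min(b, c) / denom, abs(b - c) / denom


def _rarefy_row(row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    total = int(row.sum())
    picks = rng.choice(
        np.repeat(np.arange(len(row)), row.astype(int)), size=depth, replace=False
    )
    out = np.zeros(len(row))
    np.add.at(out, picks, 1)
    return out


def beta_partition(
    table: CommunityTable,
    mode: str = "incidence",
    rarefy_to: int | str | None = None,
    n_resample: int = 100,
    seed=0,
) -> BetaResult:
    """Multi-plot beta diversity partitioned into replacement and richness.

    The multi-plot value of each component is the mean over all plot
    pairs.  With ``rarefy_to`` (an integer, or ``"min"`` for the smallest
    plot total) plots are repeatedly subsampled without replacement to
    equal effort and the components averaged over ``n_resample`` draws;
    plots with fewer individuals than the target are excluded (logged).
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("beta diversity requires at least two plots")
    rng = np.random.default_rng(seed)
    depth: int | None = None
    if rarefy_to is not None:
        totals = counts.sum(axis=1)
        depth = int(totals[totals > 0].min()) if rarefy_to == "min" else int(rarefy_to)
        keep = totals >= depth
        if not np.all(keep):
            logger.warning(
                "excluded %d plot(s) below rarefaction depth %d",
                int(np.sum(~keep)), depth,
            )
        counts = counts[keep]
        if counts.shape[0] < 2:
            raise ValueError("fewer than two plots at the rarefaction depth")

    def mean_components(mat: np.ndarray) -> np.ndarray:
        comps = []
        for i in range(mat.shape[0]):
            for j in range(i + 1, mat.shape[0]):
                comps.append(_pairwise_beta(mat[i], mat[j], mode))
        return np.mean(comps, axis=0)

    if depth is None:
        bt, br, bh = mean_components(counts)
        return BetaResult(float(bt), float(br), float(bh), mode)
    acc = np.zeros(3)
    for _ in range(n_resample):
        resampled = np.vstack([_rarefy_row(row, depth, rng) for row in counts])
        acc += mean_components(resampled)
    bt, br, bh = acc / n_resample
    return BetaResult(float(bt), float(br), float(bh), mode, depth, n_resample)


# ---------------------------------------------------------------------------
# permutation tests

def _lower(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices(mat.shape[0], -1)]


def _as_square(d) -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("a square distance matrix is required")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    return arr


def mantel(d1, d2, n_perm: int = 999, seed=0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the lower triangles; the one-sided
    p-value counts simultaneous row/column permutations of the second
    matrix with ``r`` at least as large as observed, with the +1
    correction ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    a = _as_square(d1)
    b = _as_square(d2)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same size")
    va = _lower(a)
    if np.std(va) == 0 or np.std(_lower(b)) == 0:
        raise ValueError("Mantel test undefined for a constant matrix")
    r_obs = float(np.corrcoef(va, _lower(b))[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = np.corrcoef(va, _lower(b[np.ix_(perm, perm)]))[0, 1]
        if r >= r_obs:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def anosim(d, groups: Sequence, n_perm: int = 999, seed=0) -> tuple[float, float]:
    """ANOSIM: are between-group rank distances larger than within-group?

    ``R = (mean_between_rank - mean_within_rank) / (M / 2)`` with
    ``M = n(n-1)/2``; R near 0 means no separation, 1 complete separation.
    p by permutation of group labels with the +1 correction.
    """
    dist = _as_square(d)
    groups = np.asarray(groups)
    n = dist.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per row required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM requires at least two groups")
    if np.any(counts < 2):
        raise ValueError("ANOSIM groups must all have at least two members")
    iu = np.triu_indices(n, 1)
    ranks = rankdata(dist[iu])
    m = n * (n - 1) / 2

    def r_stat(g: np.ndarray) -> float:
        same = g[iu[0]] == g[iu[1]]
        return float((ranks[~same].mean() - ranks[same].mean()) / (m / 2.0))

    r_obs = r_stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(groups)) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def permanova(d, design: Sequence, n_perm: int = 999, seed=0) -> tuple[float, float, float]:
    """Single-term PERMANOVA (pseudo-F) on a distance matrix.

    ``design`` is either a categorical factor (group labels) or a single
    continuous covariate.  The distance matrix is Gower-centered and the
    total sum of squares partitioned; permutations shuffle raw
    observations.  Returns ``(F, R², p)``.
    """
    dist = _as_square(d)
    n = dist.shape[0]
    design = np.asarray(design)
    if len(design) != n:
        raise ValueError("one design value per row required")
    g = _gower_center(dist)
    ss_total = float(np.trace(g))
    numeric = np.issubdtype(design.dtype, np.number) and len(np.unique(design)) > min(8, n - 1)

    if numeric:
        x = np.column_stack([np.ones(n), design.astype(float)])
        df_model, df_resid = 1, n - 2
    else:
        uniq = np.unique(design)
        if len(uniq) < 2:
            raise ValueError("the design must vary")
        x = (design[:, None] == uniq[None, :]).astype(float)
        df_model, df_resid = len(uniq) - 1, n - len(uniq)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def pseudo_f(perm: np.ndarray) -> tuple[float, float]:
        gp = g[np.ix_(perm, perm)]
        h = x @ np.linalg.pinv(x.T @ x) @ x.T
        ss_model = float(np.trace(h @ gp @ h))
        ss_resid = float(np.trace((np.eye(n) - h) @ gp @ (np.eye(n) - h)))
        f = (ss_model / df_model) / (ss_resid / df_resid)
        return f, ss_model

    ident = np.arange(n)
    f_obs, ss_model = pseudo_f(ident)
    r2 = ss_model / ss_total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p, _ = pseudo_f(rng.permutation(n))
        if f_p >= f_obs:
            count += 1
    return float(f_obs), float(r2), (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# between-community phylogenetic structure

def comdist(
    tree_or_pdm, table: CommunityTable, abundance_weighted: bool = True
) -> pd.DataFrame:
    """Abundance-weighted mean phylogenetic distance between plot pairs.

    ``D(p, q) = Σ_i Σ_j f_i^p f_j^q d(i, j)`` over the two plots' taxa with
    relative abundances ``f`` (presence frequencies when unweighted).
    Note ``D(p, p)`` is the plot's Rao quadratic entropy, not zero; the
    reported matrix zeroes the diagonal for downstream tree building.
    Empty plots are excluded (logged).
    """
    pdm = (
        tree_or_pdm
        if isinstance(tree_or_pdm, pd.DataFrame)
        else patristic_matrix(tree_or_pdm)
    )
    missing = set(table.otus) - set(pdm.index)
    if missing:
        raise KeyError(f"community OTU(s) absent from the tree: {sorted(missing)}")
    counts = table.counts.to_numpy(dtype=float)
    keep = counts.sum(axis=1) > 0
    if not np.all(keep):
        logger.warning("excluded %d empty plot(s) from comdist", int(np.sum(~keep)))
    counts = counts[keep]
    plots = [p for p, k in zip(table.plots, keep) if k]
    if not abundance_weighted:
        counts = (counts > 0).astype(float)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    dmat = pdm.loc[table.otus, table.otus].to_numpy()
    out = freqs @ dmat @ freqs.T
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=plots, columns=plots)


def comdist_phenogram(comdist_df: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining phenogram of plots from a comdist matrix."""
    dm = DistanceMatrix(
        ids=list(comdist_df.index),
        values=comdist_df.to_numpy(),
        model="comdist",
        sites_used=np.zeros(comdist_df.shape, dtype=int),
    )
    return neighbor_joining(dm)


# ---------------------------------------------------------------------------
# the per-plot diversity table

def _plot_indices(
    pdm: pd.DataFrame,
    tree: dendropy.Tree,
    taxa: list[str],
    counts: np.ndarray,
    n_iter: int,
    seed,
) -> dict[str, float]:
    out: dict[str, float] = {}
    out["PD"] = faith_pd(tree, taxa)
    if len(taxa) < 2:
        for k in ("MPD", "MNTD", "NRI", "NTI"):
            out[k] = float("nan")
        return out
    out["MPD"] = mpd(pdm, taxa)
    out["MNTD"] = mntd(pdm, taxa)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    out["NRI"] = ses_index(pdm, taxa, "mpd", n_iter=n_iter, seed=np.random.default_rng(s1)).index
    out["NTI"] = ses_index(pdm, taxa, "mntd", n_iter=n_iter, seed=np.random.default_rng(s2)).index
    return out


def diversity_table(
    table: CommunityTable,
    tree: dendropy.Tree,
    reference_tree: dendropy.Tree | None = None,
    n_iter: int = 999,
    seed=0,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-plot diversity indices, optionally on two trees.

    For every plot: OTU richness (nOTU), Gini-Simpson diversity (Div),
    Faith's PD, MPD, MNTD and the standardized NRI/NTI.  When a
    reference-augmented tree is supplied every phylogeny-derived index is
    computed a second time on it (columns suffixed ``_ref``), and paired
    Pearson correlations across plots are reported for PD, MPD, MNTD, NRI
    and NTI.  Plots with a single OTU get NaN for the pair-based indices.
    """
    pdm = patristic_matrix(tree)
    pdm_ref = patristic_matrix(reference_tree) if reference_tree is not None else None
    rows = []
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    plot_seeds = master.spawn(len(table.plots))
    for plot, pseed in zip(table.plots, plot_seeds):
        counts = table.counts.loc[plot]
        taxa = [o for o in table.otus if counts[o] > 0]
        row: dict[str, object] = {
            "plot_id": plot,
            "nOTU": len(taxa),
            "Div": simpson_diversity(counts.to_numpy())
            if counts.sum() >= 2
            else float("nan"),
        }
        if not taxa:
            rows.append(row)
            continue
        s1, s2 = pseed.spawn(2)
        row.update(_plot_indices(pdm, tree, taxa, counts.to_numpy(), n_iter, s1))
        if pdm_ref is not None:
            ref_vals = _plot_indices(
                pdm_ref, reference_tree, taxa, counts.to_numpy(), n_iter, s2
            )
            row.update({f"{k}_ref": v for k, v in ref_vals.items()})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("plot_id")
    correlations: dict[str, tuple[float, float]] = {}
    if pdm_ref is not None:
        for k in ("PD", "MPD", "MNTD", "NRI", "NTI"):
            sub = df[[k, f"{k}_ref"]].dropna()
            if len(sub) >= 3 and sub[k].std() > 0 and sub[f"{k}_ref"].std() > 0:
                r, p = pearsonr(sub[k], sub[f"{k}_ref"])
                correlations[k] = (float(r), float(p))
            else:
                correlations[k] = (float("nan"), float("nan"))
    return df, correlations
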