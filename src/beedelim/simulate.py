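"""Synthetic datasets with known species and community truth.

The generator emulates the statistical structure a two-locus bee inventory
presents to the delimitation pipeline: a fast mitochondrial locus and a slow
nuclear locus evolved on a pure-birth species tree, star-shaped
intraspecific variation well below the smallest interspecific divergence
(the "barcode gap"), specimens randomly missing one locus (never both),
morphospecies labels corrupted by lumping, splitting and mislabeling, and
plots whose species pools are phylogenetically filtered by habitat.

Everything is driven by a single seed; repeated calls with the same
configuration are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .dataio import CommunityTable, LocusAlignment, SpecimenRecord
from .distances import GTRParams

import pandas as pd

__all__ = [
    "LocusSpec",
    "HabitatSpec",
    "SimulationConfig",
    "TruthBundle",
    "simulate_species_tree",
    "yule_waiting_times",
    "evolve_alignment",
    "sprout_specimens",
    "corrupt_morphospecies",
    "simulate_communities",
    "simulate_dataset",
]


@dataclass(frozen=True)
class LocusSpec:
    """One locus: name, aligned length, substitution model and relative rate.

    ``rate_multiplier`` scales the species-tree branch lengths for this
    locus; the fastest locus conventionally has multiplier 1.
    """

    name: str
    length: int
    gtr: GTRParams
    rate_multiplier: float = 1.0


@dataclass(frozen=True)
class HabitatSpec:
    """A habitat type and how it filters the regional species pool.

    ``phi`` in [0, 1] is the phylogenetic-filter strength: the probability
    that a species enters the habitat pool is proportional to
    ``(1 - phi) + phi * clade_membership`` for a focal clade chosen per
    habitat, so ``phi = 1`` restricts the pool to one clade (clustering)
    and ``phi = 0`` leaves it unstructured.  Covariates are drawn per plot
    from the stated normal distributions.
    """

    name: str
    code: str
    n_plots: int = 2
    richness_multiplier: float = 1.0
    phi: float = 0.0
    altitude: tuple[float, float] = (700.0, 60.0)
    temperature: tuple[float, float] = (22.0, 1.0)
    ndmi: tuple[float, float] = (0.1, 0.05)


def _default_loci() -> tuple[LocusSpec, ...]:
    coi = GTRParams(
        exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
        base_frequencies=(0.30, 0.15, 0.15, 0.40),
        p_inv=0.2,
        gamma_shape=1.0,
    )
    nuc28s = GTRParams(
        exchangeabilities=(1.0, 3.0, 1.0, 1.0, 3.0, 1.0),
        base_frequencies=(0.22, 0.26, 0.30, 0.22),
        p_inv=0.2,
        gamma_shape=0.8,
    )
    return (
        LocusSpec("COI", 585, coi, 1.0),
        LocusSpec("28S", 450, nuc28s, 0.25),
    )


def _default_habitats() -> tuple[HabitatSpec, ...]:
    return (
        HabitatSpec("young_rubber", "YR", 2, 1.2, 0.2, (620, 40), (23.5, 0.8), (0.00, 0.05)),
        HabitatSpec("old_rubber", "OR", 2, 0.5, 0.3, (640, 40), (23.0, 0.8), (0.30, 0.05)),
        HabitatSpec("forest_edge", "FE", 2, 1.2, 0.1, (750, 50), (22.0, 0.8), (0.25, 0.05)),
        HabitatSpec("river_bank", "RB", 2, 1.2, 0.2, (580, 30), (24.0, 0.8), (-0.05, 0.05)),
        HabitatSpec("forest", "F", 4, 0.8, 0.8, (900, 60), (20.5, 0.8), (0.40, 0.05)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic inventory.

    Defaults describe a mid-sized tropical bee survey: a few tens of
    species, one to eight sequenced specimens per species, a fast and a
    slow locus with a clean barcode gap (intraspecific distances around
    0.002, interspecific at least 0.03 in combined units), mild
    morphospecies error, and twelve plots in five habitat types with
    log-normal abundances.
    """

    n_species: int = 30
    birth_rate: float = 1.0
    specimens_per_species: tuple[int, int] = (1, 8)
    loci: tuple[LocusSpec, ...] = field(default_factory=_default_loci)
    tree_depth: float = 0.15
    min_interspecific: float = 0.03
    within_species_scale: float = 0.002
    morph_error: tuple[float, float, float] = (0.1, 0.1, 0.02)
    missing_locus_rate: float = 0.15
    n_plots: int = 12
    habitats: tuple[HabitatSpec, ...] = field(default_factory=_default_habitats)
    inclusion_rate: float = 0.5
    abundance_log_mean: float = 1.0
    abundance_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.specimens_per_species
        if not (1 <= lo <= hi):
            raise ValueError("specimens_per_species must satisfy 1 <= min <= max")
        for r in self.morph_error:
            if not 0 <= r <= 1:
                raise ValueError("morphospecies error rates must be in [0, 1]")
        if not 0 <= self.missing_locus_rate <= 1:
            raise ValueError("missing_locus_rate must be in [0, 1]")
        if self.n_species < 2:
            raise ValueError("n_species must be at least 2")

    @property
    def combined_multiplier(self) -> float:
        lens = np.array([l.length for l in self.loci], dtype=float)
        mults = np.array([l.rate_multiplier for l in self.loci])
        return float(np.sum(lens * mults) / np.sum(lens))


@dataclass
class TruthBundle:
    """Ground truth retained alongside a simulated dataset."""

    species_of: dict[str, str]
    species_tree: dendropy.Tree
    community: CommunityTable | None = None
    focal_clades: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def partition(self) -> dict[str, str]:
        return dict(self.species_of)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# species tree

def yule_waiting_times(n_species: int, birth_rate: float, rng) -> np.ndarray:
    """Exponential waiting times while 2..n lineages exist, plus the final
    pendant extension drawn while n lineages exist."""
    rng = _as_rng(rng)
    ks = np.arange(2, n_species + 1)
    return rng.exponential(1.0 / (ks * birth_rate))


def simulate_species_tree(
    n_species: int, birth_rate: float = 1.0, seed=0
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with depth normalized to 1.

    Starting from two lineages, waiting times between successive births are
    Exp(k * birth_rate) while k lineages exist; at each birth a uniformly
    chosen lineage splits.  After the n-th lineage arises the tips are
    extended by one final Exp(n * birth_rate) draw, and all branch lengths
    are rescaled so the root-to-tip depth is exactly 1.
    """
    if n_species < 2:
        raise ValueError("n_species must be at least 2")
    rng = _as_rng(seed)
    waits = yule_waiting_times(n_species, birth_rate, rng)

    tree = dendropy.Tree()
    ns = tree.taxon_namespace
    # active lineages: (node, birth_time)
    active = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        active.append([child, 0.0])
    for w in waits[:-1]:
        t += w
        idx = int(rng.integers(len(active)))
        node, born = active.pop(idx)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append([child, t])
    t += waits[-1]
    names = iter(f"S{i + 1:03d}" for i in range(n_species))
    for node, born in active:
        node.edge.length = t - born
        node.taxon = ns.new_taxon(next(names))
    depth = t
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    tree.seed_node.edge.length = None
    return tree


def _node_heights(tree: dendropy.Tree) -> dict:
    """Height (time above the tips) of every node of an ultrametric tree."""
    heights = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = max(
                heights[c] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return heights


def _floor_heights(tree: dendropy.Tree, floor: float) -> None:
    """Raise every internal node to at least ``floor`` above the tips.

    Guarantees a minimum tip-to-tip distance of ``2 * floor`` while keeping
    the tree ultrametric; the max() is monotone so parent heights stay at
    or above child heights.
    """
    heights = _node_heights(tree)
    new = {
        n: (0.0 if n.is_leaf() else max(h, floor)) for n, h in heights.items()
    }
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = new[node.parent_node] - new[node]


# ---------------------------------------------------------------------------
# sequence evolution

def _transition_matrices(q: np.ndarray, rates: np.ndarray, t: float) -> list[np.ndarray]:
    out = []
    for r in rates:
        out.append(np.eye(4) if t * r == 0 else expm(q * (t * r)))
    return out


def _evolve_states(
    parent: np.ndarray, p_mats: Sequence[np.ndarray], cats: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw child states site by site given parent states and categories."""
    child = parent.copy()
    u = rng.random(parent.shape[0])
    for c, p in enumerate(p_mats):
        cum = np.cumsum(p, axis=1)
        sel = cats == c
        if not np.any(sel):
            continue
        child[sel] = np.argmax(
            u[sel, np.newaxis] < cum[parent[sel]], axis=1
        )
    return child


def _evolve_on_tree(
    tree: dendropy.Tree,
    params: GTRParams,
    length: int,
    scale: float,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Evolve states down ``tree``; returns tip states, site categories and
    the category rates (for continuing evolution below the tips)."""
    q = params.rate_matrix()
    pi = np.asarray(params.base_frequencies)
    rates, weights = params.site_rates()
    cats = rng.choice(len(rates), size=length, p=weights)
    root_states = rng.choice(4, size=length, p=pi)
    states = {id(tree.seed_node): root_states}
    tips: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_states = root_states
        else:
            bl = (node.edge.length or 0.0) * scale
            p_mats = _transition_matrices(q, rates, bl)
            node_states = _evolve_states(
                states[id(node.parent_node)], p_mats, cats, rng
            )
        states[id(node)] = node_states
        if node.is_leaf():
            tips[node.taxon.label] = node_states
    return tips, cats, rates


_DECODE = np.array(list("ACGT"))


def _to_str(states: np.ndarray) -> str:
    return "".join(_DECODE[states])


def evolve_alignment(
    tree: dendropy.Tree,
    params: GTRParams,
    length: int,
    scale: float = 1.0,
    seed=0,
) -> LocusAlignment:
    """Simulate a gapless alignment for the tips of ``tree`` under GTR+I+G.

    The root sequence is drawn from the stationary frequencies; each branch
    applies the transition matrix ``expm(Q * branch_length * scale * r)``
    with the per-site rate ``r`` fixed across the tree (invariant sites
    stay invariant everywhere).
    """
    rng = _as_rng(seed)
    tips, _, _ = _evolve_on_tree(tree, params, length, scale, rng)
    return LocusAlignment(
        locus_name=getattr(params, "name", "locus"),
        sequences={k: _to_str(v) for k, v in sorted(tips.items())},
        length=length,
    )


# ---------------------------------------------------------------------------
# specimens

def sprout_specimens(
    species_tree: dendropy.Tree,
    config: SimulationConfig,
    seed=None,
    plot_weights: Mapping[str, tuple[Sequence[str], Sequence[float]]] | None = None,
) -> tuple[list[SpecimenRecord], dict[str, LocusAlignment], TruthBundle]:
    """Generate specimens, per-locus alignments and the truth partition.

    The species tree (depth 1) is scaled to ``config.tree_depth`` expected
    fast-locus substitutions per site, and internal nodes are floored so
    that the smallest interspecific distance is ``config.min_interspecific``
    in combined (length-weighted) units.  Each species' specimens then
    evolve on a star genealogy of pendant length ``within_species_scale /
    (2 * combined_multiplier)`` hanging from the species' tip sequence.
    Each specimen loses each locus independently with
    ``missing_locus_rate``; a specimen that would lose both keeps one,
    chosen at random.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    mbar = config.combined_multiplier
    tree = species_tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= config.tree_depth
    _floor_heights(tree, config.min_interspecific / (2.0 * mbar))
    species = sorted(t.taxon.label for t in tree.leaf_node_iter())

    lo, hi = config.specimens_per_species
    n_per = {sp: int(rng.integers(lo, hi + 1)) for sp in species}
    specimen_ids = {
        sp: [f"{sp}-{k + 1:02d}" for k in range(n_per[sp])] for sp in species
    }
    pendant = config.within_species_scale / (2.0 * mbar)

    alignments: dict[str, LocusAlignment] = {}
    seqs_by_locus: dict[str, dict[str, np.ndarray]] = {}
    for locus in config.loci:
        tips, cats, rates = _evolve_on_tree(
            tree, locus.gtr, locus.length, locus.rate_multiplier, rng
        )
        q = locus.gtr.rate_matrix()
        p_mats = _transition_matrices(
            q, rates, pendant * locus.rate_multiplier
        )
        locus_seqs: dict[str, np.ndarray] = {}
        for sp in species:
            for sid in specimen_ids[sp]:
                locus_seqs[sid] = _evolve_states(tips[sp], p_mats, cats, rng)
        seqs_by_locus[locus.name] = locus_seqs

    # locus dropout: each locus lost independently, but never both
    locus_names = [l.name for l in config.loci]
    present: dict[str, set[str]] = {}
    for sp in species:
        for sid in specimen_ids[sp]:
            kept = {
                ln for ln in locus_names
                if rng.random() >= config.missing_locus_rate
            }
            if not kept:
                kept = {locus_names[int(rng.integers(len(locus_names)))]}
            present[sid] = kept

    for locus in config.loci:
        alignments[locus.name] = LocusAlignment(
            locus_name=locus.name,
            sequences={
                sid: _to_str(s)
                for sid, s in sorted(seqs_by_locus[locus.name].items())
                if locus.name in present[sid]
            },
            length=locus.length,
        )

    plot_ids = [f"P{i + 1:02d}" for i in range(config.n_plots)]
    records = []
    species_of = {}
    for sp in species:
        for sid in specimen_ids[sp]:
            species_of[sid] = sp
            if plot_weights is not None and sp in plot_weights:
                plots, probs = plot_weights[sp]
                plot = str(plots[int(rng.choice(len(plots), p=np.asarray(probs))) ])
            else:
                plot = plot_ids[int(rng.integers(config.n_plots))]
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    plot_id=plot,
                    morphospecies=sp,  # replaced by corrupt_morphospecies
                    loci_present=frozenset(present[sid]),
                )
            )
    truth = TruthBundle(species_of=species_of, species_tree=tree)
    return records, alignments, truth


# ---------------------------------------------------------------------------
# morphospecies corruption

def corrupt_morphospecies(
    species_of: Mapping[str, str],
    morph_error: tuple[float, float, float],
    seed=0,
) -> dict[str, str]:
    """Morphospecies labels with lumping, splitting and mislabeling error.

    With ``lump_rate`` per species, its label is merged with that of a
    uniformly chosen other species; with ``split_rate`` per species (of at
    least two specimens), its specimens are split into two labels; with
    ``mislabel_rate`` per specimen, the label is replaced by a uniformly
    chosen other label.  The truth mapping is left untouched.
    """
    lump_rate, split_rate, mislabel_rate = morph_error
    rng = _as_rng(seed)
    species = sorted(set(species_of.values()))
    parent = {sp: sp for sp in species}

    def find(sp):
        while parent[sp] != sp:
            parent[sp] = parent[parent[sp]]
            sp = parent[sp]
        return sp

    for sp in species:
        if len(species) > 1 and rng.random() < lump_rate:
            others = [s for s in species if s != sp]
            other = others[int(rng.integers(len(others)))]
            ra, rb = find(sp), find(other)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    members: dict[str, list[str]] = {sp: [] for sp in species}
    for sid in sorted(species_of):
        members[species_of[sid]].append(sid)

    labels: dict[str, str] = {}
    for sp in species:
        rep = find(sp)
        ids = members[sp]
        if len(ids) >= 2 and rng.random() < split_rate:
            # random nonempty bipartition of the species' specimens
            side = rng.integers(0, 2, size=len(ids))
            if side.min() == side.max():
                side[int(rng.integers(len(ids)))] ^= 1
            for sid, s in zip(ids, side):
                labels[sid] = rep if s == 0 else f"{sp}*"
        else:
            for sid in ids:
                labels[sid] = rep

    label_pool = sorted(set(labels.values()))
    if len(label_pool) > 1 and mislabel_rate > 0:
        for sid in sorted(labels):
            if rng.random() < mislabel_rate:
                others = [l for l in label_pool if l != labels[sid]]
                labels[sid] = others[int(rng.integers(len(others)))]
    return labels


# ---------------------------------------------------------------------------
# communities

def simulate_communities(
    species_tree: dendropy.Tree,
    config: SimulationConfig,
    seed=0,
) -> tuple[CommunityTable, dict[str, tuple[str, ...]]]:
    """Plot-by-species abundance table with habitat-structured pools.

    For each habitat a focal clade is chosen (a random internal node whose
    tip set covers between a fifth and a half of the species); species
    enter a plot's pool with probability ``inclusion_rate *
    richness_multiplier * ((1 - phi) + phi * clade_membership)``.  Included
    species receive i.i.d. log-normal abundances rounded up to at least
    one individual.  Returns the table (with covariates) and the focal
    clade of each habitat.
    """
    rng = _as_rng(seed)
    species = sorted(t.taxon.label for t in species_tree.leaf_node_iter())
    n = len(species)
    internal = [
        nd for nd in species_tree.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    candidates = []
    for nd in internal:
        tips = tuple(sorted(l.taxon.label for l in nd.leaf_iter()))
        if n / 5 <= len(tips) <= n / 2:
            candidates.append(tips)
    if not candidates:  # tiny trees: fall back to the larger root child
        child = max(
            species_tree.seed_node.child_nodes(),
            key=lambda c: sum(1 for _ in c.leaf_iter()),
        )
        candidates = [tuple(sorted(l.taxon.label for l in child.leaf_iter()))]
    candidates.sort()

    rows = {}
    cov_rows = {}
    focal: dict[str, tuple[str, ...]] = {}
    plot_counter = 0
    for hab in config.habitats:
        clade = candidates[int(rng.integers(len(candidates)))]
        focal[hab.name] = clade
        in_clade = np.array([sp in clade for sp in species])
        base = config.inclusion_rate * hab.richness_multiplier
        for _ in range(hab.n_plots):
            plot_counter += 1
            plot = f"P{plot_counter:02d}"
            p_incl = np.clip(
                base * ((1.0 - hab.phi) + hab.phi * in_clade), 0.0, 1.0
            )
            included = rng.random(n) < p_incl
            counts = np.zeros(n, dtype=int)
            abund = rng.lognormal(
                config.abundance_log_mean, config.abundance_log_sd, size=n
            )
            counts[included] = np.maximum(1, np.round(abund[included])).astype(int)
            rows[plot] = counts
            cov_rows[plot] = {
                "habitat": hab.name,
                "altitude": rng.normal(*hab.altitude),
                "temperature": rng.normal(*hab.temperature),
                "ndmi": float(np.clip(rng.normal(*hab.ndmi), -1, 1)),
            }
    counts_df = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    # every species should be caught somewhere: seed absent ones into a
    # random plot with a single individual
    absent = counts_df.columns[counts_df.sum(axis=0) == 0]
    for sp in absent:
        counts_df.iloc[int(rng.integers(len(counts_df))), counts_df.columns.get_loc(sp)] = 1
    cov_df = pd.DataFrame.from_dict(cov_rows, orient="index")
    return CommunityTable(counts=counts_df, covariates=cov_df), focal


# ---------------------------------------------------------------------------
# one-call dataset

def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[SpecimenRecord], dict[str, LocusAlignment], dict[str, str], TruthBundle]:
    """Full synthetic inventory: tree, communities, specimens and labels.

    Returns ``(records, alignments, morph_labels, truth)``.  Specimen plot
    membership follows the simulated community abundances; morphospecies
    labels carry the configured error rates.  All randomness derives from
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_comm, s_sprout, s_morph = ss.spawn(4)
    tree = simulate_species_tree(
        config.n_species, config.birth_rate, np.random.default_rng(s_tree)
    )
    community, focal = simulate_communities(
        tree, config, np.random.default_rng(s_comm)
    )
    weights = {}
    for sp in community.otus:
        col = community.counts[sp]
        total = col.sum()
        if total > 0:
            weights[sp] = (list(community.counts.index), (col / total).tolist())
    records, alignments, truth = sprout_specimens(
        tree, config, np.random.default_rng(s_sprout), plot_weights=weights
    )
    labels = corrupt_morphospecies(
        truth.species_of, config.morph_error, np.random.default_rng(s_morph)
    )
    records = [
        replace(r, morphospecies=labels[r.specimen_id]) for r in records
    ]
    truth.community = community
    truth.focal_clades = focal
    return records, alignments, labels, truth
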