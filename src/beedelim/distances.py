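"""Pairwise genetic distances for aligned nucleotide data.

Three estimators are provided, matching the tiers commonly used in barcoding
work:

* :func:`k2p_distance` — Kimura two-parameter closed form, the barcoding
  standard for COI, separating transition (P) and transversion (Q)
  proportions.
* :func:`gtr_distance` — the closed-form general time-reversible estimator
  based on the matrix logarithm of the symmetrized divergence matrix.
* :func:`ml_distance_gtr_gamma` — a one-dimensional maximum-likelihood
  estimate of the pairwise branch length under GTR with invariant sites and
  discrete-gamma rate heterogeneity (the model typically selected for both
  a mitochondrial and a nuclear ribosomal locus).

Columns where either sequence carries a gap, ``N`` or an IUPAC ambiguity code
are removed pairwise before estimation.  Saturated pairs (where the closed
forms are undefined) are flagged rather than clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: transitions are A<->G and C<->T
_PURINES = {0, 2}

__all__ = [
    "GTRParams",
    "DistanceMatrix",
    "K2PResult",
    "encode_sequence",
    "k2p_distance",
    "gtr_distance",
    "ml_distance_gtr_gamma",
    "pairwise_matrix",
    "combine_loci",
    "discrete_gamma_rates",
]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as integers; anything but ACGT becomes -1.

    Gaps, ``N`` and IUPAC ambiguity codes are treated as missing for
    distance purposes (pairwise deletion) but are preserved on disk by the
    IO layer.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class GTRParams:
    """Parameters of a general time-reversible substitution model.

    ``exchangeabilities`` are the six symmetric rates in the order
    (AC, AG, AT, CG, CT, GT); ``base_frequencies`` are the stationary
    frequencies of A, C, G, T.  ``p_inv`` is the proportion of invariant
    sites and ``gamma_shape`` the discrete-gamma shape parameter (``None``
    disables rate heterogeneity).  The rate matrix is normalized so that
    the *overall* expected rate — including the invariant class — is one
    substitution per site per unit time, so branch lengths read directly
    as expected substitutions per site.
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.0
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6:
            raise ValueError("six exchangeabilities required (AC,AG,AT,CG,CT,GT)")
        if any(x < 0 for x in self.exchangeabilities):
            raise ValueError("exchangeabilities must be nonnegative")
        if len(self.base_frequencies) != 4:
            raise ValueError("four base frequencies required")
        pi = np.asarray(self.base_frequencies, dtype=float)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be positive and sum to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @classmethod
    def jc(cls, p_inv: float = 0.0, gamma_shape: float | None = None) -> "GTRParams":
        """Equal-rate, equal-frequency (Jukes-Cantor-like) parameters."""
        return cls(p_inv=p_inv, gamma_shape=gamma_shape)

    def rate_matrix(self) -> np.ndarray:
        """Normalized GTR rate matrix Q (zero row sums, mean rate 1).

        Normalization is over the variable sites only; combined with the
        site-rate distribution of :meth:`site_rates` (whose mean is one)
        the overall expected rate is one.
        """
        pi = np.asarray(self.base_frequencies, dtype=float)
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(pairs, self.exchangeabilities):
            s[i, j] = s[j, i] = x
        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.sum(pi * np.diag(q))
        if mu <= 0:
            raise ValueError("rate matrix is not stochastic (zero total rate)")
        return q / mu

    def site_rates(self, n_categories: int = 4) -> tuple[np.ndarray, np.ndarray]:
        """Site-rate categories ``(rates, weights)`` with overall mean 1.

        An invariant category of rate 0 carries weight ``p_inv``; the
        remaining weight is spread over ``n_categories`` discrete-gamma
        categories (mean-normalized, Yang's category-mean discretization),
        rescaled by ``1/(1 - p_inv)`` so the mixture mean stays at one.
        """
        if self.gamma_shape is None:
            rates = np.array([1.0])
            weights = np.array([1.0])
        else:
            rates = discrete_gamma_rates(self.gamma_shape, n_categories)
            weights = np.full(n_categories, 1.0 / n_categories)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], rates / (1.0 - self.p_inv)])
            weights = np.concatenate([[self.p_inv], weights * (1.0 - self.p_inv)])
        return rates, weights


def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Mean-normalized discrete-gamma category rates (category means).

    Categories are equal-probability quantile bins of a Gamma(shape, shape)
    distribution; each category's rate is the conditional mean within its
    bin, so the discretized distribution has mean exactly one.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    # conditional means via the regularized incomplete gamma of shape+1
    upper = gammainc(shape + 1, edges[1:] * shape)
    lower = gammainc(shape + 1, edges[:-1] * shape)
    return k * (upper - lower)


class K2PResult(NamedTuple):
    distance: float
    p_transition: float
    q_transversion: float
    n_sites: int
    saturated: bool


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a >= 0) & (b >= 0)


def k2p_distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> K2PResult:
    """Kimura two-parameter distance with pairwise deletion.

    Returns the distance, the transition and transversion proportions and
    the number of compared sites.  When ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0`` the estimator is undefined (saturation); the result is
    flagged and the distance reported as NaN.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned length")
    mask = _comparable(a, b)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    aa, bb = a[mask], b[mask]
    diff = aa != bb
    same_class = np.isin(aa, (0, 2)) == np.isin(bb, (0, 2))
    transitions = int(np.sum(diff & same_class))
    transversions = int(np.sum(diff & ~same_class))
    p = transitions / n
    q = transversions / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return K2PResult(float("nan"), p, q, n, True)
    d = -0.5 * np.log(arg1 * np.sqrt(arg2))
    return K2PResult(float(d), p, q, n, False)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    mask = _comparable(a, b)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    counts = np.zeros((4, 4))
    np.add.at(counts, (a[mask], b[mask]), 1.0)
    return counts, n


def gtr_distance(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    base_frequencies: Sequence[float] | None = None,
) -> tuple[float, int, bool]:
    """Closed-form GTR distance ``-tr(Π log(Π⁻¹ F̂))``.

    ``F̂`` is the symmetrized divergence-proportion matrix of the pair and
    ``Π`` the diagonal matrix of base frequencies (estimated from the
    pooled pair when not supplied).  Returns ``(distance, n_sites,
    saturated)``; a non-real or undefined matrix logarithm marks the pair
    saturated with a NaN distance.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned length")
    counts, n = _pair_counts(a, b)
    if counts.sum() - np.trace(counts) == 0:
        return 0.0, n, False
    fhat = (counts + counts.T) / (2.0 * n)
    if base_frequencies is None:
        pi = fhat.sum(axis=1)
    else:
        pi = np.asarray(base_frequencies, dtype=float)
    # bases absent from the pooled pair contribute nothing; restrict the
    # matrix logarithm to the observed states
    present = pi > 0
    pi = pi[present]
    fhat = fhat[np.ix_(present, present)]
    m = fhat / pi[:, np.newaxis]
    eigvals, eigvecs = np.linalg.eig(m)
    if np.any(np.abs(eigvals.imag) > 1e-10) or np.any(eigvals.real <= 0):
        return float("nan"), n, True
    log_m = (eigvecs * np.log(eigvals.real)) @ np.linalg.inv(eigvecs)
    if np.any(np.abs(log_m.imag) > 1e-8):
        return float("nan"), n, True
    d = -float(np.sum(pi * np.diag(log_m.real)))
    if not np.isfinite(d):
        return float("nan"), n, True
    return max(d, 0.0), n, False


def ml_distance_gtr_gamma(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    params: GTRParams,
    max_iter: int = 200,
    tol: float = 1e-8,
    t_max: float = 20.0,
) -> tuple[float, int]:
    """Maximum-likelihood pairwise distance under GTR+I+G.

    Maximizes the pairwise likelihood ``Σ_sites log Σ_cat w_c π_x P(t r_c)``
    over the branch length ``t >= 0`` by bounded Brent search.  Returns
    ``(t_hat, n_sites)``.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned length")
    counts, n = _pair_counts(a, b)
    if counts.sum() - np.trace(counts) == 0:
        return 0.0, n
    q = params.rate_matrix()
    pi = np.asarray(params.base_frequencies, dtype=float)
    rates, weights = params.site_rates()

    def neg_log_like(t: float) -> float:
        joint = np.zeros((4, 4))
        for r, w in zip(rates, weights):
            p_t = np.eye(4) if t * r == 0 else expm(q * (t * r))
            joint += w * (pi[:, np.newaxis] * p_t)
        joint = np.maximum(joint, 1e-300)
        return -float(np.sum(counts * np.log(joint)))

    res = minimize_scalar(
        neg_log_like,
        bounds=(0.0, t_max),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(
            f"ML distance failed to converge after {max_iter} iterations "
            f"(best t = {res.x:.6g})"
        )
    return float(res.x), n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts.

    ``values`` holds NaN for pairs that are not comparable (no shared
    sites/locus) and for saturated pairs, which are additionally marked in
    ``saturated``.  ``model`` records the estimator used.
    """

    ids: list[str]
    values: np.ndarray
    model: str
    sites_used: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate IDs in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError("value matrix shape does not match IDs")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        self.sites_used = np.asarray(self.sites_used)
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.values - self.values.T), initial=0.0) > 1e-12:
                raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def submatrix(self, subset: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(s) for s in subset]
        return DistanceMatrix(
            ids=list(subset),
            values=self.values[np.ix_(idx, idx)],
            model=self.model,
            sites_used=self.sites_used[np.ix_(idx, idx)],
            saturated=self.saturated[np.ix_(idx, idx)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")

    def write_phylip_lower(self, path) -> None:
        """PHYLIP-style lower-triangle output (names, then lower triangle)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{self.values[i, j]:.8f}" for j in range(i))
                fh.write(f"{name} {row}".rstrip() + "\n")

    @classmethod
    def read_csv(cls, path, model: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        ids = [str(x) for x in df.index]
        values = df.to_numpy(dtype=float)
        return cls(ids=ids, values=values, model=model,
                   sites_used=np.zeros_like(values, dtype=int))


def pairwise_matrix(
    alignment,
    method: str = "gtr",
    params: GTRParams | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix for one locus alignment.

    ``alignment`` is any object with ``sequences`` (mapping id -> string);
    ``method`` is one of ``k2p``, ``gtr``, ``gtr+g`` (the ML estimator,
    which requires fully specified ``params``).  IDs are sorted for a
    deterministic layout.  Saturated pairs are flagged and left NaN.
    """
    seqs: Mapping[str, str] = alignment.sequences
    ids = sorted(seqs)
    if len(ids) < 2:
        raise ValueError("at least two sequences required")
    encoded = {i: encode_sequence(seqs[i]) for i in ids}
    n = len(ids)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        sites[i, i] = int(np.sum(encoded[ids[i]] >= 0))
        for j in range(i + 1, n):
            a, b = encoded[ids[i]], encoded[ids[j]]
            if method == "k2p":
                res = k2p_distance(a, b)
                d, ns, s = res.distance, res.n_sites, res.saturated
            elif method == "gtr":
                d, ns, s = gtr_distance(a, b)
            elif method in ("gtr+g", "ml"):
                if params is None:
                    raise ValueError("ML distances require GTRParams")
                d, ns = ml_distance_gtr_gamma(a, b, params)
                s = False
            else:
                raise ValueError(f"unknown distance method: {method}")
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = ns
            sat[i, j] = sat[j, i] = s
    if sat.any():
        n_sat = int(sat.sum() // 2)
        logger.warning("%d saturated pair(s) flagged in %s matrix", n_sat, method)
    return DistanceMatrix(ids=ids, values=values, model=method,
                          sites_used=sites, saturated=sat)


def combine_loci(matrices: Iterable[DistanceMatrix]) -> DistanceMatrix:
    """Combine per-locus distances into one matrix, weighting by sites used.

    ``combined(i, j) = Σ_l sites_l(i, j) d_l(i, j) / Σ_l sites_l(i, j)``
    over the loci at which the pair is comparable.  A pair present at only
    one locus falls back to that locus' distance; a pair comparable at no
    locus is NaN.  This length-weighted rule approximates the distance a
    concatenated alignment would give.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to combine")
    all_ids = sorted(set().union(*(m.ids for m in matrices)))
    n = len(all_ids)
    pos = {s: k for k, s in enumerate(all_ids)}
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for m in matrices:
        idx = np.array([pos[s] for s in m.ids])
        valid = np.isfinite(m.values)
        w = np.where(valid, m.sites_used, 0).astype(float)
        contrib_num = np.where(valid, m.values, 0.0) * w
        num[np.ix_(idx, idx)] += contrib_num
        den[np.ix_(idx, idx)] += w
        sat[np.ix_(idx, idx)] |= m.saturated
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    np.fill_diagonal(values, 0.0)
    missing = int(np.sum(~np.isfinite(values[np.triu_indices(n, 1)])))
    if missing:
        logger.warning("%d pair(s) comparable at no locus in combined matrix", missing)
    return DistanceMatrix(ids=all_ids, values=values, model="combined",
                          sites_used=den.astype(int), saturated=sat)
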