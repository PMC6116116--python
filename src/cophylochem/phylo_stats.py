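"""Phylogenetic signal, ordination, and sampling-effort statistics.

* Blomberg's K with a tip-randomization p-value, measuring whether a
  continuous trait is more (K > 1) or less (K < 1) similar among close
  relatives than expected under Brownian motion on the tree.
* Principal coordinates analysis (classical metric scaling) used both
  to ordinate chemical similarity matrices and inside the ParaFit test.
* Patristic distances and the Brownian phylogenetic covariance matrix.
* Species-accumulation (random host ordering) and individual-based
  rarefaction curves for assessing sampling completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io_core import DistanceMatrix, IncidenceTable, Tree

__all__ = [
    "BlombergResult",
    "PCoAResult",
    "patristic_distances",
    "phylo_covariance",
    "blomberg_k",
    "pcoa",
    "accumulation_random",
    "rarefy",
    "mean_individuals_per_species",
]


def patristic_distances(tree: Tree) -> DistanceMatrix:
    """Tip-to-tip path lengths (sums of branch lengths)."""
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.tip_labels)
    label_to_taxon = {t.label: t for t in pdm.taxon_iter()}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(label_to_taxon[taxa[i]],
                                       label_to_taxon[taxa[j]])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(taxa, D, units=f"patristic ({tree.units})")


def phylo_covariance(tree: Tree, taxa: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Brownian covariance: C_ij = shared path length from root to MRCA(i, j).

    Computed as (depth_i + depth_j - patristic_ij) / 2; the diagonal
    holds root-to-tip depths.  Returns (taxa, C); C is PSD.
    """
    pat = patristic_distances(tree)
    depths = tree.root_distances()
    order = taxa if taxa is not None else pat.taxa
    pat = pat.submatrix(order)
    d = np.array([depths[t] for t in order])
    C = 0.5 * (d[:, None] + d[None, :] - pat.values)
    C[np.diag_indices_from(C)] = d
    return order, C


@dataclass
class BlombergResult:
    K: float
    p: float
    reps: int


def _k_statistic(x: np.ndarray, Cinv: np.ndarray,
                 denom_expected: float) -> float:
    n = x.size
    one = np.ones(n)
    a_hat = (one @ Cinv @ x) / (one @ Cinv @ one)
    r = x - a_hat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    return (mse0 / mse) / denom_expected


def blomberg_k(tree: Tree, trait: dict[str, float] | "np.ndarray",
               reps: int = 999, seed: int | None = None) -> BlombergResult:
    """Blomberg's K with a tip-shuffling randomization test.

    K = (MSE0/MSE) / E[MSE0/MSE | BM], with MSE0 the raw mean squared
    deviation of tip values from the GLS root estimate and MSE the
    phylogenetically corrected one.  The p-value is the add-one
    permutation probability that shuffled tip values yield K at least
    as large as observed.
    """
    taxa, C = phylo_covariance(tree)
    if isinstance(trait, dict):
        missing = set(taxa) - set(trait)
        if missing:
            raise ValueError(f"trait values missing for tips {sorted(missing)}")
        x = np.array([float(trait[t]) for t in taxa])
    else:
        x = np.asarray(trait, dtype=float)
        if x.size != len(taxa):
            raise ValueError("trait vector length does not match tip count")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.var(x) == 0:
        raise ValueError("trait is constant; K undefined")
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom_expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    k_obs = _k_statistic(x, Cinv, denom_expected)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        k_perm = _k_statistic(rng.permutation(x), Cinv, denom_expected)
        hits += k_perm >= k_obs
    p = (1 + hits) / (reps + 1)
    return BlombergResult(K=float(k_obs), p=float(p), reps=reps)


@dataclass
class PCoAResult:
    """Principal coordinates with axes ordered by decreasing eigenvalue."""

    objects: list[str]
    coordinates: np.ndarray        # n x k, columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray        # the k retained positive eigenvalues
    percent_variance: np.ndarray   # over positive eigenvalues, sums to 100
    negative_warning: bool = False

    def axis(self, k: int) -> np.ndarray:
        return self.coordinates[:, k]


def pcoa(dm: DistanceMatrix, eig_rel_tol: float = 1e-8) -> PCoAResult:
    """Classical metric scaling (Gower double-centering of -D^2/2).

    Axes with eigenvalue > ``eig_rel_tol`` x the largest are retained.
    Negative eigenvalues are dropped; percent variance is computed over
    the positive spectrum, and a flag is raised when the most negative
    eigenvalue exceeds 5% of the largest in magnitude.
    """
    D = dm.values
    if np.all(D == 0):
        raise ValueError("all distances are zero; ordination undefined")
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = 0.5 * (G + G.T)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eig_rel_tol * eigval[0]
    lam = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(lam)
    pos_sum = eigval[eigval > 0].sum()
    pct = 100.0 * lam / pos_sum
    neg_warn = bool(eigval[-1] < 0 and abs(eigval[-1]) > 0.05 * eigval[0])
    return PCoAResult(list(dm.taxa), coords, lam, pct, neg_warn)


def accumulation_random(incidence: IncidenceTable | np.ndarray,
                        n_perm: int = 100, seed: int | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Species-accumulation curve over random orderings of hosts.

    Returns (mean, sd) arrays of cumulative distinct-MOTU counts per
    number of hosts sampled; sd is the across-permutation standard
    deviation.
    """
    if isinstance(incidence, IncidenceTable):
        mat = incidence.binary_matrix().to_numpy()
    else:
        mat = np.asarray(incidence)
    n_hosts = mat.shape[0]
    if n_hosts < 1:
        raise ValueError("need at least one host")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, n_hosts))
    for p in range(n_perm):
        order = rng.permutation(n_hosts)
        seen = np.zeros(mat.shape[1], dtype=bool)
        for step, h in enumerate(order):
            seen |= mat[h].astype(bool)
            curves[p, step] = seen.sum()
    return curves.mean(axis=0), curves.std(axis=0, ddof=0)


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(abundance_counts: np.ndarray, n: int) -> tuple[float, float]:
    """Expected species richness (and sd) in a subsample of ``n`` individuals.

    Hypergeometric (sampling without replacement): E[S_n] = sum_i
    (1 - C(N-N_i, n)/C(N, n)), with the matching variance including
    pairwise co-absence terms.
    """
    counts = np.asarray(abundance_counts, dtype=int)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if not (1 <= n <= N):
        raise ValueError(f"subsample size must be in [1, {N}], got {n}")
    # q_i = P(species i absent from the subsample)
    with np.errstate(invalid="ignore"):
        log_q = np.where(N - counts >= n,
                         _log_choose(N - counts, n) - _log_choose(N, n),
                         -np.inf)
    q = np.exp(log_q)
    expected = float(np.sum(1.0 - q))
    var = float(np.sum(q * (1.0 - q)))
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            nij = N - counts[i] - counts[j]
            qij = np.exp(_log_choose(nij, n) - _log_choose(N, n)) if nij >= n else 0.0
            var += 2.0 * (qij - q[i] * q[j])
    var = max(var, 0.0)
    return expected, float(np.sqrt(var))


def mean_individuals_per_species(total_individuals: int, n_species: int) -> int:
    """Average individuals per species, rounded half away from zero."""
    if total_individuals <= 0 or n_species <= 0:
        raise ValueError("both totals must be positive")
    ratio = total_individuals / n_species
    return int(np.floor(ratio + 0.5))
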