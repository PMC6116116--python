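"""Permutation tests of cophylogenetic congruence (ParaFit).

The global statistic embeds the host and parasite distance matrices in
principal-coordinate space and measures the fourth-corner association
carried by the host-parasite link matrix: with B and C the host and
parasite coordinates and A the binary parasite x host link matrix,

    global = || C' A B ||^2  (sum of squares of the cross-product).

The null hypothesis of independent evolution is simulated by permuting
each parasite's host associations independently; p-values use the
add-one rule.  Per-link contributions (F1 = drop in the global
statistic when the link is removed; F2 = F1 scaled by the remaining
statistic) identify the individual associations driving congruence.

Substituting a chemogram's cophenetic distances for the host phylogeny
turns the same machinery into a test of whether parasite
diversification tracks host chemistry rather than host ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_similarity import Chemogram, chemogram_to_distance
from .io_core import DistanceMatrix, IncidenceTable, Tree
from .phylo_stats import patristic_distances, pcoa

__all__ = ["ParaFitResult", "parafit_global", "test_vs_chemistry"]


@dataclass
class ParaFitResult:
    global_stat: float
    p_global: float
    links: list[tuple[str, str]]           # (parasite, host)
    link_f1: np.ndarray
    link_f2: np.ndarray
    link_p: np.ndarray | None
    n_perm: int
    seed: int | None
    alpha: float = 0.05
    significant_links: list[tuple[str, str]] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "parasite": [p for p, _ in self.links],
            "host": [h for _, h in self.links],
            "F1": self.link_f1,
            "F2": self.link_f2,
        })
        if self.link_p is not None:
            df["p"] = self.link_p
            df["significant"] = df["p"] <= self.alpha
        return df


def _link_matrix(links: IncidenceTable | list[tuple[str, str]],
                 para_taxa: list[str], host_taxa: list[str]) -> np.ndarray:
    A = np.zeros((len(para_taxa), len(host_taxa)))
    if isinstance(links, IncidenceTable):
        mat = links.binary_matrix()
        pairs = [(m, h) for h in mat.index for m in mat.columns
                 if mat.loc[h, m] == 1]
    else:
        pairs = list(links)
    for para, host in pairs:
        if para not in para_taxa:
            raise ValueError(f"link parasite {para!r} not in parasite distances")
        if host not in host_taxa:
            raise ValueError(f"link host {host!r} not in host distances")
        A[para_taxa.index(para), host_taxa.index(host)] = 1
    if A.sum() < 2:
        raise ValueError("need at least 2 association links")
    return A


def _global_stat(C: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    D = C.T @ A @ B
    return float(np.sum(D * D))


def parafit_global(host_dm: DistanceMatrix, para_dm: DistanceMatrix,
                   links: IncidenceTable | list[tuple[str, str]],
                   n_perm: int = 999, seed: int | None = None,
                   test_links: bool = False, alpha: float = 0.05
                   ) -> ParaFitResult:
    """Global (and optionally per-link) ParaFit permutation test.

    ``links`` is either an incidence table or an explicit list of
    (parasite, host) pairs.  Each parasite's host set is permuted
    independently under the null.
    """
    B = pcoa(host_dm).coordinates
    C = pcoa(para_dm).coordinates
    host_taxa, para_taxa = list(host_dm.taxa), list(para_dm.taxa)
    A = _link_matrix(links, para_taxa, host_taxa)
    n_p, n_h = A.shape

    obs = _global_stat(C, A, B)
    link_idx = [(int(i), int(j)) for i, j in zip(*np.nonzero(A))]
    link_names = [(para_taxa[i], host_taxa[j]) for i, j in link_idx]

    def link_f1s(Amat: np.ndarray, total: float,
                 idx: list[tuple[int, int]]) -> np.ndarray:
        # stat without link (i,j) = total - 2 c_i' M b_j + |c_i|^2 |b_j|^2
        M = C.T @ Amat @ B
        f1 = np.empty(len(idx))
        for k, (i, j) in enumerate(idx):
            cross = C[i] @ M @ B[j]
            f1[k] = 2.0 * cross - (C[i] @ C[i]) * (B[j] @ B[j])
        return f1

    f1_obs = link_f1s(A, obs, link_idx)
    without = obs - f1_obs
    with np.errstate(divide="ignore", invalid="ignore"):
        f2_obs = np.where(without > 1e-300, f1_obs / without, np.inf)

    rng = np.random.default_rng(seed)
    hits_global = 0
    hits_link = np.zeros(len(link_idx))
    for _ in range(n_perm):
        perms = [rng.permutation(n_h) for _ in range(n_p)]
        Ap = np.empty_like(A)
        for i in range(n_p):
            Ap[i] = A[i, perms[i]]
        stat_p = _global_stat(C, Ap, B)
        hits_global += stat_p >= obs
        if test_links:
            # the k-th link follows its parasite's permutation
            idx_p = [(i, int(np.nonzero(perms[i] == j)[0][0]))
                     for i, j in link_idx]
            f1_p = link_f1s(Ap, stat_p, idx_p)
            hits_link += f1_p >= f1_obs
    p_global = (1 + hits_global) / (n_perm + 1)
    link_p = (1 + hits_link) / (n_perm + 1) if test_links else None
    significant = ([link_names[k] for k in range(len(link_names))
                    if link_p[k] <= alpha] if test_links else [])
    return ParaFitResult(
        global_stat=obs, p_global=float(p_global), links=link_names,
        link_f1=f1_obs, link_f2=f2_obs, link_p=link_p, n_perm=n_perm,
        seed=seed, alpha=alpha, significant_links=significant)


def test_vs_chemistry(host_chemogram: Chemogram, para_tree: Tree | DistanceMatrix,
                      links: IncidenceTable | list[tuple[str, str]],
                      n_perm: int = 999, seed: int | None = None,
                      test_links: bool = False) -> ParaFitResult:
    """ParaFit with the host chemogram's cophenetic distances in place of
    the host phylogeny."""
    host_dm = chemogram_to_distance(host_chemogram)
    if isinstance(para_tree, Tree):
        para_dm = patristic_distances(para_tree)
    else:
        para_dm = para_tree
    return parafit_global(host_dm, para_dm, links, n_perm=n_perm, seed=seed,
                          test_links=test_links)
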