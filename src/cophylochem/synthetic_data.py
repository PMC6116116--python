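"""Synthetic data with the statistical structure the analyses assume.

Every downstream stage of the pipeline is testable without field data:
birth-death species trees, Brownian traits (the null of the
phylogenetic-signal test), compound profiles gained and lost along a
tree (giving tunable phylogenetic signal in chemistry, with MS/MS
spectra whose cosine similarity mirrors compound ancestry), barcode
alignments with a controllable intra/inter-specific divergence gap, and
incidence matrices drawn from known variance components (the
generative twin of the variance-partitioning model).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .association_models import TERM_NAMES, TermCovariances, build_term_covariances
from .chem_similarity import (CompoundTable, SimilarityMatrix, Spectrum,
                              SpectrumSet, classify_compound)
from .io_core import AlignedSeqSet, IncidenceTable, Tree

__all__ = [
    "SimParams",
    "sim_bd_tree",
    "scale_tree_depth",
    "star_species_tree",
    "sim_bm_traits",
    "sim_chem_profiles",
    "sim_barcodes",
    "sim_barcode_fixture",
    "sim_incidence",
    "SimIncidence",
]


@dataclass
class SimParams:
    """Default study conditions for the synthetic community.

    Divergences are in expected substitutions per site; kappa is the
    transition/transversion rate ratio of the barcode substitution
    model; variance components are probit-scale variances.
    """

    n_host: int = 20
    n_parasite: int = 20
    birth: float = 1.0
    death: float = 0.0
    trait_sigma2: float = 1.0
    compound_gain: float = 12.0
    compound_loss: float = 0.4
    intra_div: float = 0.003
    inter_div: float = 0.05
    kappa: float = 1.47
    seq_len: int = 645
    variance_components: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth < 0 or self.death < 0:
            raise ValueError("rates must be nonnegative")
        if self.trait_sigma2 < 0:
            raise ValueError("Brownian rate must be nonnegative")
        if self.inter_div <= self.intra_div:
            raise ValueError("need inter_div > intra_div for a barcode gap")
        bad = set(self.variance_components) - set(TERM_NAMES)
        if bad:
            raise ValueError(f"unknown variance components {sorted(bad)}")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be nonnegative")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def sim_bd_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                seed: int | None = None, max_retries: int = 100) -> Tree:
    """Ultrametric birth-death tree with exactly ``n_tips`` extant tips."""
    from dendropy.model import birthdeath

    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = _pyrandom.Random(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            dtree = birthdeath.birth_death_tree(
                birth_rate=birth, death_rate=death,
                num_extant_tips=n_tips, rng=rng)
            break
        except Exception as err:  # total extinction; retry with the same rng
            last_err = err
    else:
        raise RuntimeError(f"birth-death simulation failed after "
                           f"{max_retries} retries: {last_err}")
    # the simulator stops exactly at the n-th birth, leaving a zero-length
    # cherry; extend every extant tip by the waiting time to the next event
    # so the tree stays ultrametric but has no duplicate tips
    extra = rng.expovariate(n_tips * (birth + death))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    dtree.seed_node.edge.length = 0.0
    tree = Tree(dtree, units="time")
    # guard against float drift in the simulator's depth accounting
    assert tree.is_ultrametric(rel_tol=1e-6)
    return tree


def scale_tree_depth(tree: Tree, target_depth: float) -> Tree:
    """Rescale all branch lengths so the maximum root-to-tip depth equals
    ``target_depth`` (e.g. to express a time tree in substitutions/site)."""
    if target_depth <= 0:
        raise ValueError("target depth must be positive")
    scaled = tree.clone()
    factor = target_depth / tree.depth()
    for edge in scaled.dendropy_tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    scaled.units = "substitutions/site"
    return scaled


def star_species_tree(n_species: int, tip_length: float) -> Tree:
    """Star (simultaneous radiation) tree: every pairwise divergence is
    exactly ``2 * tip_length``."""
    labels = [f"sp{i+1}" for i in range(n_species)]
    newick = "(" + ",".join(f"{l}:{tip_length:.10g}" for l in labels) + ");"
    return Tree.from_newick(newick)


# ---------------------------------------------------------------------------
# Brownian traits
# ---------------------------------------------------------------------------

def sim_bm_traits(tree: Tree, sigma2: float = 1.0, seed: int | None = None,
                  root_value: float = 0.0, name: str = "trait") -> pd.Series:
    """One Brownian-motion trait realization: tip values whose covariance
    is sigma2 times the shared root-to-MRCA path length."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if tree.depth() <= 0:
        raise ValueError("tree must have positive depth")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    dtree = tree.dendropy_tree
    out: dict[str, float] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            incr = rng.normal(0.0, np.sqrt(sigma2 * node.edge.length))
            values[id(node)] = values[id(node.parent_node)] + incr
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name=name)


# ---------------------------------------------------------------------------
# Chemistry
# ---------------------------------------------------------------------------

def _fresh_compound(rng: np.random.Generator, counter: list[int],
                    n_fragments: int) -> dict:
    cid = f"c{counter[0]}"
    counter[0] += 1
    mz = float(rng.uniform(150.0, 1200.0))
    rt = float(rng.uniform(1.0, 30.0))
    frags = np.sort(rng.uniform(50.0, max(mz - 1.0, 51.0), size=n_fragments))
    inten = rng.lognormal(0.0, 0.5, size=n_fragments)
    return {"id": cid, "mz": mz, "rt": rt,
            "cls": classify_compound(mz, rt),
            "frag_mz": frags, "frag_int": inten}


def _derived_compound(parent: dict, rng: np.random.Generator,
                      counter: list[int], n_fragments: int,
                      frag_inherit: float) -> dict:
    cid = f"c{counter[0]}"
    counter[0] += 1
    mz = float(np.clip(parent["mz"] + rng.normal(0.0, 30.0), 150.0, 1200.0))
    rt = float(np.clip(parent["rt"] + rng.normal(0.0, 1.5), 1.0, 30.0))
    n_inherit = int(round(frag_inherit * len(parent["frag_mz"])))
    take = rng.choice(len(parent["frag_mz"]), size=n_inherit, replace=False)
    # inherited fragments must still fit under the (possibly lighter) precursor
    keep = parent["frag_mz"][take] < mz - 1.0
    frags = list(parent["frag_mz"][take][keep])
    inten = list(parent["frag_int"][take][keep])
    while len(frags) < n_fragments:
        frags.append(float(rng.uniform(50.0, max(mz - 1.0, 51.0))))
        inten.append(float(rng.lognormal(0.0, 0.5)))
    order = np.argsort(frags)
    return {"id": cid, "mz": mz, "rt": rt,
            "cls": classify_compound(mz, rt),
            "frag_mz": np.asarray(frags)[order],
            "frag_int": np.asarray(inten)[order]}


def sim_chem_profiles(tree: Tree, n_compounds: int = 30, gain: float = 12.0,
                      loss: float = 0.4, seed: int | None = None,
                      n_fragments: int = 8, frag_inherit: float = 0.7,
                      abundance_concentration: float = 5.0
                      ) -> tuple[CompoundTable, SpectrumSet]:
    """Compound profiles evolving by gain/loss along a tree.

    The root carries ``n_compounds`` compounds.  Along each branch,
    gains arrive at rate ``gain`` per unit branch length and each
    present compound is lost at rate ``loss`` per unit branch length
    (so a compound survives a path of length T with probability
    exp(-loss T), and richness is stationary at gain/loss).  A gained
    compound derives from a randomly chosen compound present on that
    lineage, inheriting a fraction of its fragment m/z values, so
    structurally related compounds share MS/MS fragments and expected
    cosine similarity decays with divergence time.  Tip abundances are
    Dirichlet draws over the present compounds
    (``abundance_concentration = inf`` gives equal shares).  A tip
    that loses everything is reseeded with one fresh compound.
    """
    if gain < 0 or loss < 0:
        raise ValueError("gain and loss rates must be nonnegative")
    rng = np.random.default_rng(seed)
    counter = [0]
    catalog: dict[str, dict] = {}
    root_set = []
    for _ in range(n_compounds):
        c = _fresh_compound(rng, counter, n_fragments)
        catalog[c["id"]] = c
        root_set.append(c["id"])
    present: dict[int, list[str]] = {}
    tip_sets: dict[str, list[str]] = {}
    dtree = tree.dendropy_tree
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            present[id(node)] = list(root_set)
        else:
            cur = list(present[id(node.parent_node)])
            blen = node.edge.length or 0.0
            survive = rng.random(len(cur)) < np.exp(-loss * blen)
            cur = [cid for cid, s in zip(cur, survive) if s]
            # gains arrive uniformly along the branch and are themselves
            # exposed to loss for the remainder; the survivor count is a
            # thinned Poisson
            if loss > 0:
                gain_rate = gain * (1.0 - np.exp(-loss * blen)) / loss
            else:
                gain_rate = gain * blen
            n_gain = rng.poisson(gain_rate)
            for _ in range(n_gain):
                if cur:
                    parent_c = catalog[cur[rng.integers(len(cur))]]
                    c = _derived_compound(parent_c, rng, counter,
                                          n_fragments, frag_inherit)
                else:
                    c = _fresh_compound(rng, counter, n_fragments)
                catalog[c["id"]] = c
                cur.append(c["id"])
            present[id(node)] = cur
        if node.is_leaf():
            cur = present[id(node)]
            if not cur:
                c = _fresh_compound(rng, counter, n_fragments)
                catalog[c["id"]] = c
                cur = [c["id"]]
            tip_sets[node.taxon.label] = list(cur)
    observed = sorted({cid for s in tip_sets.values() for cid in s},
                      key=lambda c: int(c[1:]))
    species = list(tip_sets)
    rows = {cid: {"mz": catalog[cid]["mz"], "rt": catalog[cid]["rt"],
                  "cls": catalog[cid]["cls"],
                  **{sp: 0.0 for sp in species}} for cid in observed}
    for sp in species:
        ids = tip_sets[sp]
        if np.isinf(abundance_concentration):
            ab = np.full(len(ids), 1.0 / len(ids))
        else:
            ab = rng.dirichlet(np.full(len(ids), abundance_concentration))
        for cid, a in zip(ids, ab):
            rows[cid][sp] = float(a)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound"
    table = CompoundTable(df)
    spectra = SpectrumSet({
        cid: Spectrum(catalog[cid]["mz"],
                      np.column_stack([catalog[cid]["frag_mz"],
                                       catalog[cid]["frag_int"]]))
        for cid in observed})
    return table, spectra


# ---------------------------------------------------------------------------
# Barcodes (Kimura two-parameter process)
# ---------------------------------------------------------------------------

def _k80_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after expected divergence d."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def _evolve(seq: np.ndarray, d: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    if d <= 0:
        return seq.copy()
    p_ts, p_tv = _k80_probs(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    # codes 0=A,1=G,2=C,3=T: xor 1 = transition partner, xor 2/3 = transversions
    out[ts] ^= 1
    out[tv1] ^= 2
    out[tv2] ^= 3
    return out


_DECODE = np.array(list("AGCT"))


def sim_barcodes(species_tree: Tree, n_per_species: int = 4,
                 intra_div: float = 0.003, kappa: float = 1.47,
                 seed: int | None = None, seq_len: int = 645,
                 locus_name: str = "COI") -> AlignedSeqSet:
    """Barcodes evolved under a K2P process on a substitution-scaled
    species tree, plus a star-shaped intraspecific radiation.

    Within-species sequences diverge by an expected ``intra_div``
    substitutions/site (each individual sits on a private branch of
    length ``intra_div / 2`` off its species tip).  True species labels
    are recorded in ``species_label``.
    """
    if n_per_species < 1:
        raise ValueError("need at least one sequence per species")
    if intra_div < 0:
        raise ValueError("intra_div must be nonnegative")
    pat_max = 0.0
    from .phylo_stats import patristic_distances
    pat = patristic_distances(species_tree)
    pat_max = float(pat.values.max())
    if pat_max + intra_div > 0.75:
        raise ValueError(f"expected divergence {pat_max + intra_div:.2f} "
                         "exceeds 0.75; the K2P process is saturated")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_len).astype(np.uint8)
    tip_seqs: dict[str, np.ndarray] = {}
    seqs: dict[int, np.ndarray] = {}
    for node in species_tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = root_seq
        else:
            seqs[id(node)] = _evolve(seqs[id(node.parent_node)],
                                     node.edge.length or 0.0, kappa, rng)
        if node.is_leaf():
            tip_seqs[node.taxon.label] = seqs[id(node)]
    ids, out_seqs, labels = [], [], {}
    for sp in tip_seqs:
        for i in range(1, n_per_species + 1):
            s = _evolve(tip_seqs[sp], intra_div / 2.0, kappa, rng)
            sid = f"{sp}_{i}"
            ids.append(sid)
            out_seqs.append("".join(_DECODE[s]))
            labels[sid] = sp
    return AlignedSeqSet(ids, out_seqs, locus_name=locus_name,
                         species_label=labels)


def sim_barcode_fixture(n_species: int = 8, n_per_species: int = 4,
                        intra_div: float = 0.003, inter_div: float = 0.05,
                        kappa: float = 1.47, seed: int | None = None,
                        seq_len: int = 645) -> AlignedSeqSet:
    """Barcode set with a clean gap: a star species tree with every
    between-species divergence ``inter_div`` plus intraspecific
    star variation ``intra_div``."""
    tree = star_species_tree(n_species, inter_div / 2.0)
    return sim_barcodes(tree, n_per_species=n_per_species,
                        intra_div=intra_div, kappa=kappa, seed=seed,
                        seq_len=seq_len)


# ---------------------------------------------------------------------------
# Incidence from known variance components
# ---------------------------------------------------------------------------

@dataclass
class SimIncidence:
    table: IncidenceTable
    y: np.ndarray                    # (regions, sawflies, hosts)
    sigma2_true: dict[str, float]
    cov: TermCovariances
    threshold: float
    effort: np.ndarray


def _draw_kron_effect(term, sigma2: float, rng: np.random.Generator
                      ) -> np.ndarray:
    vals_s, vecs_s = np.linalg.eigh(term.factor_s)
    vals_h, vecs_h = np.linalg.eigh(term.factor_h)
    lam = np.outer(np.clip(vals_s, 0, None), np.clip(vals_h, 0, None))
    zeta = rng.standard_normal(lam.shape)
    return np.sqrt(sigma2) * (vecs_s @ (np.sqrt(lam) * zeta) @ vecs_h.T)


def sim_incidence(sawfly_tree: Tree, host_tree: Tree,
                  chem_similarity: SimilarityMatrix | np.ndarray | pd.DataFrame,
                  variance_components: dict[str, float],
                  effort: np.ndarray | dict[str, int] | None = None,
                  seed: int | None = None, threshold: float = 1.5,
                  regions: tuple[str, ...] = ("R1", "R2"),
                  effort_beta: float = 0.0) -> SimIncidence:
    """Incidence from the generative twin of the variance-partition model.

    The latent value for cell (sawfly, host, region) is the sum of
    Gaussian effects with covariances sigma2_k A_k (the named term
    structures), an optional effort effect, and unit probit noise;
    incidence is 1 where the latent value exceeds ``threshold``.  The
    true components are recorded alongside.
    """
    bad = set(variance_components) - set(TERM_NAMES)
    if bad:
        raise ValueError(f"unknown variance components {sorted(bad)}")
    if isinstance(chem_similarity, SimilarityMatrix):
        chem = pd.DataFrame(chem_similarity.values,
                            index=chem_similarity.names,
                            columns=chem_similarity.names)
    else:
        chem = chem_similarity
    cov = build_term_covariances(sawfly_tree, host_tree, chem, list(regions))
    rng = np.random.default_rng(seed)
    n_r, n_s, n_h = len(regions), cov.n_s, cov.n_h
    if effort is None:
        effort_arr = rng.integers(40, 81, size=n_h).astype(float)
    elif isinstance(effort, dict):
        effort_arr = np.array([effort[h] for h in cov.host_taxa], dtype=float)
    else:
        effort_arr = np.asarray(effort, dtype=float)
    eta = np.zeros((n_r, n_s, n_h))
    for name, sigma2 in variance_components.items():
        if sigma2 == 0:
            continue
        if name == "region":
            eta += (np.sqrt(sigma2)
                    * rng.standard_normal(n_r))[:, None, None]
        else:
            eta += _draw_kron_effect(cov.terms[name], sigma2, rng)[None]
    if effort_beta != 0.0:
        e = np.log(effort_arr)
        e = (e - e.mean()) / (e.std() if e.std() > 0 else 1.0)
        eta += effort_beta * e[None, None, :]
    eta += rng.standard_normal((n_r, n_s, n_h))
    y = (eta > threshold).astype(int)
    records = []
    for r, region in enumerate(regions):
        for s, motu in enumerate(cov.sawfly_taxa):
            for h, host in enumerate(cov.host_taxa):
                if y[r, s, h]:
                    records.append((motu, host, region, 1))
    rec_df = pd.DataFrame(records, columns=["motu", "host", "region", "count"])
    table = IncidenceTable(rec_df, regions=list(regions),
                           hosts=cov.host_taxa, motus=cov.sawfly_taxa,
                           effort=dict(zip(cov.host_taxa,
                                           effort_arr.astype(int))))
    truth = {t: float(variance_components.get(t, 0.0)) for t in TERM_NAMES}
    return SimIncidence(table=table, y=y, sigma2_true=truth, cov=cov,
                        threshold=threshold, effort=effort_arr)
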