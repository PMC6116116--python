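"""Species-level chemical similarity from metabolomic feature tables.

The pipeline scores pairs of compounds by the similarity of their MS/MS
fragmentation spectra (a modified cosine that also matches fragment
pairs shifted by the precursor mass difference), then scores pairs of
species by the abundance-weighted expected structural similarity of
their compound profiles.  Crediting structurally similar but unshared
compounds matters because a large fraction of plant secondary
metabolites occur in a single species and would otherwise contribute
nothing to between-species similarity.

Compound classes follow a chromatographic rule (saponins elute late and
heavy: RT > 18 min and precursor m/z > 580; the rest are phenolics);
class-wise similarity matrices are combined with equal weights,
optionally together with a tyrosine-overexpression similarity, and the
combined matrix is summarized as a bootstrap-supported UPGMA dendrogram
(the "chemogram").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .io_core import DistanceMatrix, Tree

__all__ = [
    "CompoundTable",
    "Spectrum",
    "SpectrumSet",
    "SimilarityMatrix",
    "Chemogram",
    "classify_compound",
    "match_shared_compounds",
    "modified_cosine",
    "build_compound_similarity",
    "species_similarity",
    "species_similarity_matrix",
    "combine_class_matrices",
    "build_chemogram",
    "chemogram_to_distance",
    "read_feature_csv",
    "read_mgf",
    "write_mgf",
]


def classify_compound(mz: float, rt: float) -> str:
    """Saponin iff RT > 18 min and precursor m/z > 580; else phenolic."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if rt < 0:
        raise ValueError("retention time must be nonnegative")
    return "saponin" if (rt > 18.0 and mz > 580.0) else "phenolic"


@dataclass
class CompoundTable:
    """Metabolomic features with per-species relative abundances.

    ``df`` is indexed by compound id with columns ``mz``, ``rt``,
    ``cls`` plus one abundance column per species.  Abundances are
    normalized to sum to 1 within each species.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("mz", "rt", "cls"):
            if col not in self.df.columns:
                raise ValueError(f"compound table missing column {col!r}")
        if (self.df["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.df["rt"] < 0).any():
            raise ValueError("retention times must be nonnegative")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate compound ids")
        ab = self.df[self.species]
        if (ab.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def species(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("mz", "rt", "cls")]

    @property
    def compounds(self) -> list[str]:
        return list(self.df.index)

    def normalized(self) -> "CompoundTable":
        """Rescale abundances so every species column sums to 1."""
        df = self.df.copy()
        for sp in self.species:
            total = df[sp].sum()
            if total <= 0:
                raise ValueError(f"species {sp!r} has no compounds")
            df[sp] = df[sp] / total
        return CompoundTable(df)

    def subset_class(self, cls: str) -> "CompoundTable":
        sub = self.df[self.df["cls"] == cls]
        if sub.empty:
            raise ValueError(f"no compounds of class {cls!r}")
        return CompoundTable(sub.copy())

    def abundance_matrix(self) -> np.ndarray:
        """Compounds x species abundance array."""
        return self.df[self.species].to_numpy(dtype=float)


@dataclass
class Spectrum:
    precursor_mz: float
    peaks: np.ndarray  # (n, 2): fragment m/z, intensity

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.peaks.shape[0] == 0:
            raise ValueError("empty spectrum")
        if np.any(self.peaks[:, 1] <= 0):
            raise ValueError("peak intensities must be positive")
        if np.any(self.peaks[:, 0] >= self.precursor_mz + 1.0):
            raise ValueError("fragment m/z at or above precursor m/z + 1")


class SpectrumSet:
    """MS/MS spectra keyed by compound id."""

    def __init__(self, spectra: Mapping[str, Spectrum]):
        self.spectra = dict(spectra)

    def __contains__(self, cid: str) -> bool:
        return cid in self.spectra

    def __getitem__(self, cid: str) -> Spectrum:
        return self.spectra[cid]

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.spectra)


@dataclass
class SimilarityMatrix:
    """Symmetric similarity in [0, 1] with unit diagonal over named objects."""

    names: list[str]
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("similarity diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def to_distance(self) -> DistanceMatrix:
        D = 1.0 - self.values
        np.fill_diagonal(D, 0.0)
        D = np.clip(0.5 * (D + D.T), 0.0, None)
        return DistanceMatrix(list(self.names), D, units="1 - similarity")


# ---------------------------------------------------------------------------
# Compound matching and spectral similarity
# ---------------------------------------------------------------------------

def match_shared_compounds(table_a: CompoundTable, table_b: CompoundTable,
                           mz_tol: float = 0.01, rt_tol: float = 0.25
                           ) -> list[tuple[str, str]]:
    """Greedy one-to-one matching of features by m/z then RT closeness.

    Candidate pairs within both tolerances are accepted in ascending
    (|dmz|, |drt|) order, each compound used at most once.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    cands = []
    for ca in table_a.compounds:
        mza, rta = table_a.df.loc[ca, "mz"], table_a.df.loc[ca, "rt"]
        for cb in table_b.compounds:
            dmz = abs(mza - table_b.df.loc[cb, "mz"])
            drt = abs(rta - table_b.df.loc[cb, "rt"])
            if dmz <= mz_tol and drt <= rt_tol:
                cands.append((dmz, drt, ca, cb))
    cands.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for _, _, ca, cb in cands:
        if ca not in used_a and cb not in used_b:
            pairs.append((ca, cb))
            used_a.add(ca)
            used_b.add(cb)
    return pairs


def modified_cosine(spec_a: Spectrum, spec_b: Spectrum,
                    frag_tol: float = 0.02) -> float:
    """Modified cosine similarity between two MS/MS spectra.

    Square-root intensities are L2-normalized; fragment pairs may match
    either directly (|dmz| <= tol) or shifted by the precursor mass
    difference (|dmz - dprecursor| <= tol).  Pairs are accepted
    greedily by descending intensity product, each peak used once; the
    score is the sum of matched products and lies in [0, 1].
    """
    shift = spec_a.precursor_mz - spec_b.precursor_mz
    wa = np.sqrt(spec_a.peaks[:, 1])
    wb = np.sqrt(spec_b.peaks[:, 1])
    wa = wa / np.linalg.norm(wa)
    wb = wb / np.linalg.norm(wb)
    mza, mzb = spec_a.peaks[:, 0], spec_b.peaks[:, 0]
    dm = mza[:, None] - mzb[None, :]
    allowed = (np.abs(dm) <= frag_tol) | (np.abs(dm - shift) <= frag_tol)
    ii, jj = np.nonzero(allowed)
    if ii.size == 0:
        return 0.0
    scores = wa[ii] * wb[jj]
    order = np.argsort(-scores, kind="stable")
    used_a = np.zeros(mza.size, dtype=bool)
    used_b = np.zeros(mzb.size, dtype=bool)
    total = 0.0
    for k in order:
        i, j = ii[k], jj[k]
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            total += scores[k]
    return float(min(total, 1.0))


def build_compound_similarity(spectra: SpectrumSet, frag_tol: float = 0.02,
                              score_floor: float = 0.2,
                              compounds: Sequence[str] | None = None
                              ) -> SimilarityMatrix:
    """Pairwise structural similarity matrix over compounds.

    Off-diagonal entries below ``score_floor`` are zeroed (network
    edge threshold); compounds without a spectrum score 0 against
    everything else but keep a unit diagonal.
    """
    if not (0 <= score_floor < 1):
        raise ValueError("score floor must be in [0, 1)")
    ids = list(compounds) if compounds is not None else spectra.compound_ids
    n = len(ids)
    eps = np.eye(n)
    for i in range(n):
        if ids[i] not in spectra:
            continue
        for j in range(i + 1, n):
            if ids[j] not in spectra:
                continue
            s = modified_cosine(spectra[ids[i]], spectra[ids[j]], frag_tol)
            if s >= score_floor:
                eps[i, j] = eps[j, i] = s
    return SimilarityMatrix(ids, eps, provenance="modified-cosine")


# ---------------------------------------------------------------------------
# Species similarity
# ---------------------------------------------------------------------------

def _raw_cross(a: np.ndarray, b: np.ndarray, eps: np.ndarray) -> float:
    return float(a @ eps @ b)


def _aligned_eps(eps: SimilarityMatrix, compounds: Sequence[str]) -> np.ndarray:
    """Compound similarity reindexed to a compound list; features missing
    from the matrix score 0 against everything else (no spectrum)."""
    if list(eps.names) == list(compounds):
        return eps.values
    E = pd.DataFrame(eps.values, index=eps.names, columns=eps.names) \
        .reindex(index=compounds, columns=compounds).fillna(0.0).to_numpy()
    np.fill_diagonal(E, 1.0)
    return E


def species_similarity(table: CompoundTable, eps: SimilarityMatrix,
                       species_a: str, species_b: str) -> float:
    """Abundance-weighted expected structural similarity of two species.

    raw(A, B) = sum_ij a_i b_j eps_ij over all compound pairs;
    S(A, B) = raw(A, B) / max(raw(A, A), raw(B, B)), and S(A, A) = 1.
    Unshared compounds thus still contribute through their structural
    similarity to the other species' compounds.
    """
    for sp in (species_a, species_b):
        if sp not in table.species:
            raise ValueError(f"species {sp!r} not in compound table")
    if species_a == species_b:
        return 1.0
    tab = table.normalized()
    E = _aligned_eps(eps, tab.compounds)
    a = tab.df[species_a].to_numpy(dtype=float)
    b = tab.df[species_b].to_numpy(dtype=float)
    raw_ab = _raw_cross(a, b, E)
    raw_aa = _raw_cross(a, a, E)
    raw_bb = _raw_cross(b, b, E)
    return float(np.clip(raw_ab / max(raw_aa, raw_bb), 0.0, 1.0))


def species_similarity_matrix(table: CompoundTable, eps: SimilarityMatrix,
                              provenance: str = "") -> SimilarityMatrix:
    """All-pairs species similarity for one compound class."""
    tab = table.normalized()
    sub = _aligned_eps(eps, tab.compounds)
    A = tab.abundance_matrix()  # compounds x species
    raw = A.T @ sub @ A
    self_raw = np.diag(raw)
    denom = np.maximum.outer(self_raw, self_raw)
    S = np.clip(raw / denom, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    S = 0.5 * (S + S.T)
    return SimilarityMatrix(tab.species, S, provenance=provenance)


def combine_class_matrices(class_matrices: Sequence[SimilarityMatrix],
                           tyrosine: Mapping[str, float] | None = None
                           ) -> SimilarityMatrix:
    """Equally weighted mean of per-class species similarity matrices.

    Tyrosine overexpression (percent leaf dry weight) enters as a third
    matrix, S_tyr(A, B) = 1 - |t_A - t_B| / max_pair |t_A - t_B|, when
    any species expresses tyrosine; entries are clipped to [0, 1].
    """
    if not class_matrices:
        raise ValueError("need at least one class matrix")
    species = class_matrices[0].names
    for m in class_matrices[1:]:
        if m.names != species:
            raise ValueError("class matrices cover different species sets")
    stack = [m.values for m in class_matrices]
    if tyrosine is not None and any(v > 0 for v in tyrosine.values()):
        missing = set(species) - set(tyrosine)
        if missing:
            raise ValueError(f"tyrosine values missing for {sorted(missing)}")
        t = np.array([float(tyrosine[s]) for s in species])
        diffs = np.abs(t[:, None] - t[None, :])
        dmax = diffs.max()
        S_tyr = np.ones_like(diffs) if dmax == 0 else 1.0 - diffs / dmax
        np.fill_diagonal(S_tyr, 1.0)
        stack.append(S_tyr)
    combined = np.clip(np.mean(stack, axis=0), 0.0, 1.0)
    np.fill_diagonal(combined, 1.0)
    return SimilarityMatrix(list(species), combined, provenance="equally-weighted")


# ---------------------------------------------------------------------------
# Chemogram
# ---------------------------------------------------------------------------

@dataclass
class Chemogram:
    """UPGMA dendrogram of species chemical similarity with bootstrap support."""

    species: list[str]
    linkage_matrix: np.ndarray
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    def clusters(self) -> list[frozenset[str]]:
        return _linkage_clusters(self.linkage_matrix, self.species)

    def to_tree(self) -> Tree:
        """Convert to a rooted ultrametric tree with merge-height branch
        lengths (node height = half the cophenetic distance)."""
        import dendropy

        n = len(self.species)
        taxon_namespace = dendropy.TaxonNamespace(self.species)
        nodes = {}
        heights = {}
        for i, sp in enumerate(self.species):
            node = dendropy.Node(taxon=taxon_namespace.get_taxon(sp))
            nodes[i] = node
            heights[i] = 0.0
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            parent = dendropy.Node()
            a, b = int(a), int(b)
            for child in (a, b):
                nodes[child].edge.length = h / 2.0 - heights[child]
                parent.add_child(nodes[child])
            nodes[n + k] = parent
            heights[n + k] = h / 2.0
        tree = dendropy.Tree(taxon_namespace=taxon_namespace,
                             seed_node=nodes[n + len(self.linkage_matrix) - 1])
        tree.is_rooted = True
        return Tree(tree, units="similarity height")


def _linkage_clusters(Z: np.ndarray, names: Sequence[str]) -> list[frozenset[str]]:
    n = len(names)
    members: dict[int, frozenset[str]] = {i: frozenset([names[i]]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        out.append(merged)
    return out


def _upgma(S: np.ndarray) -> np.ndarray:
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = np.clip(0.5 * (D + D.T), 0.0, None)
    return linkage(squareform(D, checks=False), method="average")


def build_chemogram(table: CompoundTable | None = None,
                    eps: SimilarityMatrix | None = None,
                    similarity: SimilarityMatrix | None = None,
                    tyrosine: Mapping[str, float] | None = None,
                    classes: Sequence[str] = ("phenolic", "saponin"),
                    n_boot: int = 0, seed: int | None = None) -> Chemogram:
    """UPGMA chemogram with compound-bootstrap cluster supports.

    Either pass a precomputed species ``similarity`` matrix (no
    bootstrap possible unless a table is also given), or a compound
    ``table`` plus compound similarity ``eps``; in the latter case the
    class-wise species matrices are built, equally weighted and
    combined, and cluster support is the fraction of ``n_boot``
    compound-resampled (with replacement) similarity matrices whose
    UPGMA tree contains the same tip set.
    """

    def combined_from(tab: CompoundTable, eps_use: SimilarityMatrix) -> SimilarityMatrix:
        mats = []
        for cls in classes:
            try:
                sub = tab.subset_class(cls)
            except ValueError:
                continue
            mats.append(species_similarity_matrix(sub, eps_use, provenance=cls))
        if not mats:
            raise ValueError("no compounds in any requested class")
        return combine_class_matrices(mats, tyrosine=tyrosine)

    if similarity is None:
        if table is None or eps is None:
            raise ValueError("need either a similarity matrix or table + eps")
        similarity = combined_from(table, eps)
    if len(similarity.names) < 3:
        raise ValueError("need at least 3 species for a chemogram")
    Z = _upgma(similarity.values)
    species = list(similarity.names)
    chemogram = Chemogram(species, Z)
    if n_boot >= 1:
        if table is None or eps is None:
            raise ValueError("bootstrap support requires the compound table")
        rng = np.random.default_rng(seed)
        targets = _linkage_clusters(Z, species)
        hits = {c: 0 for c in targets}
        ids = np.array(table.compounds)
        for _ in range(n_boot):
            take = rng.integers(0, len(ids), size=len(ids))
            boot_df = table.df.iloc[take].copy()
            boot_df.index = [f"b{i}" for i in range(len(take))]
            # carry compound similarity through the resampling
            eps_vals = _aligned_eps(eps, list(ids))[np.ix_(take, take)]
            # a compound drawn twice is identical to itself
            np.fill_diagonal(eps_vals, 1.0)
            boot_eps = SimilarityMatrix(list(boot_df.index), np.maximum(
                eps_vals, eps_vals.T), "bootstrap")
            try:
                boot_S = combined_from(CompoundTable(boot_df), boot_eps).values
            except ValueError:
                continue
            boot_clusters = set(_linkage_clusters(_upgma(boot_S), species))
            for c in targets:
                if c in boot_clusters:
                    hits[c] += 1
        chemogram.supports = {c: hits[c] / n_boot for c in targets}
    return chemogram


def chemogram_to_distance(chemogram: Chemogram) -> DistanceMatrix:
    """Cophenetic distances: the merge height at which two species join."""
    coph = cophenet(chemogram.linkage_matrix)
    D = squareform(coph)
    return DistanceMatrix(list(chemogram.species), D, units="cophenetic height")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_feature_csv(path: str | Path) -> CompoundTable:
    """Feature CSV: columns compound, mz, rt, [cls], then species columns.

    If ``cls`` is absent, classes are assigned with the RT/m-z rule.
    """
    df = pd.read_csv(path).set_index("compound")
    if "cls" not in df.columns:
        df["cls"] = [classify_compound(m, r) for m, r in zip(df["mz"], df["rt"])]
    return CompoundTable(df)


def read_mgf(path: str | Path) -> SpectrumSet:
    from pyteomics import mgf

    spectra = {}
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            cid = entry["params"]["title"]
            prec = float(entry["params"]["pepmass"][0])
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra[cid] = Spectrum(prec, peaks)
    return SpectrumSet(spectra)


def write_mgf(spectra: SpectrumSet, path: str | Path) -> None:
    from pyteomics import mgf

    entries = []
    for cid, spec in spectra.spectra.items():
        entries.append({
            "m/z array": spec.peaks[:, 0],
            "intensity array": spec.peaks[:, 1],
            "params": {"title": cid, "pepmass": spec.precursor_mz},
        })
    mgf.write(entries, str(path), file_mode="w")
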