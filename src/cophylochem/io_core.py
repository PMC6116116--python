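"""Shared domain types and readers/writers for the pipeline's file formats.

The analysis moves between five kinds of objects: aligned barcode
sequences, rooted trees, distance matrices, continuous trait tables and
host x herbivore incidence records.  Everything downstream (MOTU
delimitation, chemical similarity, phylogenetic statistics, the
association models) consumes and produces these types, so their
invariants are validated loudly here rather than deep in the analyses.

Trees are backed by dendropy; FASTA parsing by Bio.SeqIO; tabular data
by pandas.  All distances carry a ``units`` tag (substitutions/site,
patristic path length, or ``1 - similarity``) so that matrices from
different stages are not silently mixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedSeqSet",
    "Tree",
    "DistanceMatrix",
    "TraitTable",
    "IncidenceTable",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_incidence",
    "read_traits",
]

_DNA_ALPHABET = set("ACGT-N")


@dataclass
class AlignedSeqSet:
    """Equal-length uppercase DNA sequences with unique sample ids.

    ``species_label`` optionally maps each id to a known (true or
    hypothesised) species label; the synthetic generator records the
    simulated truth there so delimitation can be scored against it.
    """

    ids: list[str]
    seqs: list[str]
    locus_name: str = "COI"
    species_label: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(self.ids) == 0:
            raise ValueError("empty sequence set")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if self.length == 0:
            raise ValueError("alignment length is zero")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"sequence {sid!r} has non-DNA symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def sequence(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]


class Tree:
    """Rooted tree with nonnegative branch lengths over uniquely named tips.

    Thin wrapper around :class:`dendropy.Tree` that enforces the
    invariants the pipeline relies on and records the branch-length
    units.  Polytomies are accepted and treated as hard.
    """

    def __init__(self, dtree: dendropy.Tree, units: str = "substitutions/site"):
        dtree.is_rooted = True
        for edge in dtree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise ValueError("tree has an edge without a branch length")
            if edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValueError("tree has unnamed tips")
        if len(set(labels)) != len(labels):
            raise ValueError("tip names are not unique")
        self._dtree = dtree
        self.units = units

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, units: str = "substitutions/site",
                    midpoint_root: bool = False) -> "Tree":
        if "[&U]" in newick.upper().replace(" ", ""):
            if not midpoint_root:
                raise ValueError(
                    "tree is flagged unrooted; pass midpoint_root=True to "
                    "midpoint-root it"
                )
            dtree = dendropy.Tree.get(data=newick.replace("[&U]", "").replace("[&u]", ""),
                                      schema="newick")
            dtree.reroot_at_midpoint(update_bipartitions=False)
        else:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(dtree, units=units)

    # -- properties ----------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._dtree.leaf_nodes())

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return max(self.root_distances().values())

    def root_distances(self) -> dict[str, float]:
        self._dtree.calc_node_root_distances(
            return_leaf_distances_only=False)
        return {leaf.taxon.label: leaf.root_distance
                for leaf in self._dtree.leaf_node_iter()}

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = list(self.root_distances().values())
        span = max(d) - min(d)
        return span <= rel_tol * max(max(d), 1e-300)

    # -- serialization -------------------------------------------------
    def to_newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick",
            real_value_format_specifier=".10g",
            suppress_rooting=True,
        )
        return s.strip() + "\n"

    def clone(self) -> "Tree":
        return Tree(self._dtree.clone(depth=1), units=self.units)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix over named taxa with a units tag."""

    taxa: list[str]
    values: np.ndarray
    units: str = "substitutions/site"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("taxon names are not unique")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)], self.units)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, units: str = "") -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), units)


@dataclass
class TraitTable:
    """One row per species of named continuous traits; NaN marks missing."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate species in trait table")
        non_numeric = [c for c in self.df.columns
                       if not pd.api.types.is_numeric_dtype(self.df[c])]
        if non_numeric:
            raise ValueError(f"non-numeric trait columns: {non_numeric}")

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    def trait(self, name: str, dropna: bool = False) -> pd.Series:
        s = self.df[name]
        return s.dropna() if dropna else s


class IncidenceTable:
    """Host x herbivore incidence records with region and effort metadata.

    Records are (herbivore MOTU, host species, region, count >= 1); the
    derived matrix is binary: repeated records of the same link collapse
    to a single presence.  Hosts on which no herbivore was ever found
    are retained as all-zero rows (joint absences are informative for
    the occurrence models).
    """

    def __init__(self, records: pd.DataFrame,
                 regions: Iterable[str] | None = None,
                 hosts: Iterable[str] | None = None,
                 motus: Iterable[str] | None = None,
                 effort: Mapping[str, int] | None = None):
        required = {"motu", "host", "region", "count"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"incidence records missing columns {sorted(missing)}")
        records = records.copy()
        if (records["count"] < 1).any():
            bad = records[records["count"] < 1]
            raise ValueError(f"records with count < 1 are invalid:\n{bad}")
        declared = sorted(set(regions) if regions is not None
                          else set(records["region"]))
        unknown = set(records["region"]) - set(declared)
        if unknown:
            raise ValueError(
                f"unknown region labels {sorted(unknown)}; declared regions "
                f"are {declared}")
        self.records = records
        self.regions = declared
        self.hosts = sorted(set(hosts) if hosts is not None
                            else set(records["host"]))
        if not set(records["host"]) <= set(self.hosts):
            raise ValueError("records mention hosts outside the declared host list")
        self.motus = sorted(set(motus) if motus is not None
                            else set(records["motu"]))
        if not set(records["motu"]) <= set(self.motus):
            raise ValueError("records mention MOTUs outside the declared MOTU list")
        self.effort = dict(effort) if effort is not None else None
        if self.effort is not None:
            missing_effort = set(self.hosts) - set(self.effort)
            if missing_effort:
                raise ValueError(f"no sampling effort for hosts {sorted(missing_effort)}")

    def binary_matrix(self, region: str | None = None) -> pd.DataFrame:
        """Hosts x MOTUs presence/absence (optionally within one region)."""
        rec = self.records
        if region is not None:
            if region not in self.regions:
                raise ValueError(f"unknown region {region!r}; declared: {self.regions}")
            rec = rec[rec["region"] == region]
        mat = pd.DataFrame(0, index=self.hosts, columns=self.motus, dtype=int)
        for _, row in rec.iterrows():
            mat.loc[row["host"], row["motu"]] = 1
        return mat

    def motu_abundance(self) -> pd.Series:
        """Total individuals per MOTU (sum of record counts)."""
        return self.records.groupby("motu")["count"].sum().reindex(
            self.motus, fill_value=0)

    @property
    def n_links(self) -> int:
        return int(self.binary_matrix().to_numpy().sum())


@dataclass
class RunConfig:
    """Run-level plumbing: the seed and the stochastic-operation sizes."""

    seed: int = 0
    n_perm: int = 9999
    mcmc_iter: int = 50_000
    mcmc_burn: int = 5_000
    mcmc_thin: int = 45
    mz_tol: float = 0.01
    rt_tol: float = 0.25
    frag_tol: float = 0.02
    score_floor: float = 0.2
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("permutation count must be >= 1")

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return json.loads(json.dumps(d))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, locus_name: str = "COI") -> AlignedSeqSet:
    """Read an aligned FASTA file into an :class:`AlignedSeqSet`.

    Raises on ragged alignments, duplicate ids and empty files; record
    order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return AlignedSeqSet(
        ids=[r.id for r in records],
        seqs=[str(r.seq) for r in records],
        locus_name=locus_name,
    )


def write_fasta(seqset: AlignedSeqSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(seqset.ids, seqset.seqs):
            fh.write(f">{sid}\n{seq}\n")


def read_newick(path: str | Path, units: str = "substitutions/site",
                midpoint_root: bool = False) -> Tree:
    text = Path(path).read_text()
    return Tree.from_newick(text, units=units, midpoint_root=midpoint_root)


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())


def read_traits(path: str | Path, species_column: str | None = None) -> TraitTable:
    """Read a CSV of continuous traits, one row per species.

    The species column is the first column unless named explicitly.
    Empty cells become NaN (explicitly missing).
    """
    df = pd.read_csv(path)
    col = species_column or df.columns[0]
    df = df.set_index(col)
    return TraitTable(df)


def read_incidence(path: str | Path,
                   regions: Iterable[str] | None = None,
                   hosts: Iterable[str] | None = None,
                   effort_path: str | Path | None = None) -> IncidenceTable:
    """Read incidence records (CSV: motu, host, region, count).

    ``effort_path`` optionally points to a CSV with columns
    ``host, flushes_searched``.
    """
    records = pd.read_csv(path)
    effort = None
    if effort_path is not None:
        eff = pd.read_csv(effort_path)
        effort = dict(zip(eff["host"], eff["flushes_searched"].astype(int)))
        if hosts is None:
            hosts = list(effort)
    return IncidenceTable(records, regions=regions, hosts=hosts, effort=effort)
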