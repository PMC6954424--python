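"""Unique-molecule counting by edit-distance clustering of counting tags.

PCR duplication and sequencing substitutions turn each true 30-mer
counting tag into a small cloud of near-identical sequences.  Collapsing
that cloud back to one molecule is done here by greedy abundance-ordered
clustering, the standard rule in the UMI literature: distinct tags are
visited from most to least abundant (ties broken lexicographically) and
each joins the first existing cluster whose *representative* lies within
``distance`` of it, otherwise it seeds a new cluster.  With the default
``distance=2`` a tag carrying up to two substitutions relative to its
true molecule's tag is absorbed rather than counted as a new molecule.

The number of clusters for a protein is its molecule count.  A literal
O(n^2) re-implementation (:func:`brute_force_cluster`) is shipped as a
permanent test oracle, and a single-linkage variant is available for
sensitivity analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import edlib
import numpy as np
import pandas as pd

from .readio import UNASSIGNED, TagObservation
from .schema import BarcodeSchema, hamming

__all__ = [
    "ClusterParams",
    "MoleculeCluster",
    "MoleculeCountTable",
    "tag_distance",
    "cluster_tags",
    "brute_force_cluster",
    "count_molecules",
]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering parameters (defaults follow the assay's counting protocol)."""

    distance: int = 2
    fixed_base_number: int = 6
    random_base_number: int = 24
    metric: str = "hamming"  # or "levenshtein"
    linkage: str = "greedy"  # or "single"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.metric not in ("hamming", "levenshtein"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.linkage not in ("greedy", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")

    @property
    def tag_length(self) -> int:
        return self.fixed_base_number + self.random_base_number


@dataclass(frozen=True)
class MoleculeCluster:
    """One inferred molecule: a representative tag and its absorbed variants."""

    representative: str
    member_tags: tuple[tuple[str, int], ...]
    total_reads: int

    @property
    def n_member_tags(self) -> int:
        return len(self.member_tags)


def tag_distance(a: str, b: str, metric: str = "hamming") -> int:
    """Distance between two tags under the configured metric."""
    if metric == "hamming":
        return hamming(a, b)
    if metric == "levenshtein":
        return edlib.align(a, b, task="distance")["editDistance"]
    raise ValueError(f"unknown metric {metric!r}")


def _tag_counts(tags: Iterable[str] | Mapping[str, int]) -> Counter:
    if isinstance(tags, Mapping):
        counts = Counter()
        for tag, c in tags.items():
            if c < 0:
                raise ValueError("negative read count")
            if c:
                counts[tag] = c
        return counts
    return Counter(tags)


def _check_lengths(counts: Counter, params: ClusterParams) -> None:
    lengths = {len(t) for t in counts}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent tag lengths: {sorted(lengths)}")
    if params.metric == "hamming" and lengths and lengths != {params.tag_length}:
        raise ValueError(
            f"tag length {lengths.pop()} != fixed+random = {params.tag_length}"
        )


def _ordered(counts: Counter) -> list[tuple[str, int]]:
    # abundance-greedy visiting order: read count desc, lexicographic asc
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _finalize(
    groups: list[list[tuple[str, int]]],
) -> list[MoleculeCluster]:
    clusters = []
    for members in groups:
        # representative = most abundant member, ties lexicographic
        rep = min(members, key=lambda kv: (-kv[1], kv[0]))[0]
        clusters.append(
            MoleculeCluster(
                representative=rep,
                member_tags=tuple(members),
                total_reads=sum(c for _, c in members),
            )
        )
    clusters.sort(key=lambda cl: (-cl.total_reads, cl.representative))
    return clusters


def cluster_tags(
    tags: Iterable[str] | Mapping[str, int], params: ClusterParams = ClusterParams()
) -> list[MoleculeCluster]:
    """Collapse a multiset of counting tags into molecule clusters.

    Deterministic: the visiting order, the join rule (first cluster in
    creation order whose representative is within ``distance``) and the
    output order (total reads desc, representative asc) are all fully
    tie-broken.  ``tags`` may be a sequence of tags (one per read) or a
    mapping tag -> read count.
    """
    counts = _tag_counts(tags)
    _check_lengths(counts, params)
    if not counts:
        return []
    if params.linkage == "single":
        return _single_linkage(counts, params)
    reps: list[str] = []
    groups: list[list[tuple[str, int]]] = []
    for tag, c in _ordered(counts):
        for j, rep in enumerate(reps):
            if tag_distance(tag, rep, params.metric) <= params.distance:
                groups[j].append((tag, c))
                break
        else:
            reps.append(tag)
            groups.append([(tag, c)])
    return _finalize(groups)


def brute_force_cluster(
    tags: Iterable[str] | Mapping[str, int], params: ClusterParams = ClusterParams()
) -> list[MoleculeCluster]:
    """Literal O(n^2) reference of the greedy rule, via an explicit
    pairwise distance matrix.  Test oracle; guarded at 2000 distinct tags.
    """
    counts = _tag_counts(tags)
    _check_lengths(counts, params)
    if len(counts) > 2000:
        raise ValueError(f"brute-force oracle capped at 2000 distinct tags, got {len(counts)}")
    if not counts:
        return []
    ordered = _ordered(counts)
    n = len(ordered)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            dist[i, j] = tag_distance(ordered[i][0], ordered[j][0], params.metric)
    rep_idx: list[int] = []
    groups: list[list[tuple[str, int]]] = []
    for i in range(n):
        for g, r in enumerate(rep_idx):
            if dist[i, r] <= params.distance:
                groups[g].append(ordered[i])
                break
        else:
            rep_idx.append(i)
            groups.append([ordered[i]])
    return _finalize(groups)


def _single_linkage(counts: Counter, params: ClusterParams) -> list[MoleculeCluster]:
    # union-find over all tag pairs within `distance`; sensitivity-analysis
    # variant only — cluster members are chain-connected, so the
    # within-distance-of-representative invariant of the greedy rule may
    # not hold here.
    items = _ordered(counts)
    n = len(items)
    if n > 5000:
        raise ValueError("single-linkage variant capped at 5000 distinct tags")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if tag_distance(items[i][0], items[j][0], params.metric) <= params.distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups_by_root: dict[int, list[tuple[str, int]]] = {}
    for i in range(n):
        groups_by_root.setdefault(find(i), []).append(items[i])
    return _finalize(list(groups_by_root.values()))


@dataclass
class MoleculeCountTable:
    """Per-protein read tallies and unique-molecule counts.

    ``frame`` has one row per schema identifier (columns: protein, role,
    assigned_reads, filtered_reads, molecule_count).  Reads attributable
    to no identifier are tallied in ``unassigned_reads``; identifiers with
    role ``unused`` keep their own rows so the sequencing-noise floor can
    be estimated from them.
    """

    frame: pd.DataFrame
    total_reads: int
    unassigned_reads: int
    clusters: dict[str, list[MoleculeCluster]] = field(default_factory=dict)

    def row(self, protein: str) -> pd.Series:
        sub = self.frame[self.frame["protein"] == protein]
        if sub.empty:
            raise KeyError(f"no such protein in count table: {protein}")
        return sub.iloc[0]

    def reads_for(self, protein: str, on: str = "reads") -> int:
        """Signal used by calling rules: raw assigned reads (default) or molecules."""
        r = self.row(protein)
        return int(r["molecule_count"] if on == "molecules" else r["assigned_reads"])

    def unused_read_counts(self) -> np.ndarray:
        sub = self.frame[self.frame["role"] == "unused"]
        return sub["assigned_reads"].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_reads={self.total_reads}\n")
            fh.write(f"#unassigned_reads={self.unassigned_reads}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MoleculeCountTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, v = line[1:].strip().split("=")
                meta[k] = int(v)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh, sep="\t")
        return cls(
            frame=frame,
            total_reads=meta.get("total_reads", 0),
            unassigned_reads=meta.get("unassigned_reads", 0),
        )

    def clusters_frame(self) -> pd.DataFrame:
        rows = [
            (p, cl.representative, cl.total_reads, cl.n_member_tags)
            for p, cls_ in self.clusters.items()
            for cl in cls_
        ]
        return pd.DataFrame(
            rows, columns=["protein", "representative", "total_reads", "n_member_tags"]
        )


def count_molecules(
    observations: Iterable[TagObservation] | pd.DataFrame,
    schema: BarcodeSchema,
    params: ClusterParams = ClusterParams(),
    keep_clusters: bool = True,
) -> MoleculeCountTable:
    """Group filter-passing observations by protein and count molecules.

    Clustering is independent per protein; reads failing the fixed-base
    filter or unattributable to an identifier never enter clustering.
    """
    assigned = Counter()
    filtered_tags: dict[str, Counter] = {i.protein_name: Counter() for i in schema.identifiers}
    total = 0
    unassigned = 0

    if isinstance(observations, pd.DataFrame):
        rows: Iterator[tuple[str, str, bool]] = (
            (r.protein, r.counting_tag, bool(r.passed_filter))
            for r in observations.itertuples(index=False)
        )
    else:
        rows = ((o.protein_name, o.counting_tag, o.passed_filter) for o in observations)

    for protein, tag, passed in rows:
        total += 1
        if protein == UNASSIGNED or protein not in filtered_tags:
            unassigned += 1
            continue
        assigned[protein] += 1
        if passed:
            filtered_tags[protein][tag] += 1

    records = []
    clusters: dict[str, list[MoleculeCluster]] = {}
    for ident in schema.identifiers:
        name = ident.protein_name
        cls_ = cluster_tags(filtered_tags[name], params)
        if keep_clusters:
            clusters[name] = cls_
        records.append(
            (
                name,
                ident.role,
                int(assigned[name]),
                int(sum(filtered_tags[name].values())),
                len(cls_),
            )
        )
    frame = pd.DataFrame(
        records,
        columns=["protein", "role", "assigned_reads", "filtered_reads", "molecule_count"],
    )
    return MoleculeCountTable(
        frame=frame,
        total_reads=total,
        unassigned_reads=unassigned,
        clusters=clusters,
    )
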