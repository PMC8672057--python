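"""Greedy redundancy clustering and the mitogenome similarity network.

The redundancy filter follows the greedy incremental convention of
CD-HIT: genomes are visited longest-first, each is compared against the
representatives of existing clusters (not against their members), and it
joins the first cluster whose representative it matches at or above the
identity threshold, otherwise it founds a new cluster.  The identity used
is :func:`mitocomp.align.clustering_identity` (identical columns of the
best local alignment over the shorter sequence).

The all-vs-all network draws, for every genome pair that aligns at all,
exactly one undirected edge whose similarity index is the identity of the
*longest continuous alignment* between the pair — when a pair aligns in
several segments, the longest segment's identity wins even if a shorter
segment has higher identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from . import align
from .annotation_io import SequenceRecord


@dataclass
class Cluster:
    representative: str
    members: list[tuple[str, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    @property
    def ids(self) -> list[str]:
        return [self.representative] + [m for m, _ in self.members]


def _kmer_set(seq: str, k: int = 11) -> set[int]:
    fwd = align.kmer_codes(seq, k)
    rev = align.kmer_codes(align.reverse_complement(seq), k)
    codes = set(int(c) for c in fwd if c >= 0)
    codes.update(int(c) for c in rev if c >= 0)
    return codes


def greedy_cluster(
    genomes: Sequence[SequenceRecord],
    threshold: float = 0.90,
    scoring: align.ScoringScheme = align.DEFAULT_SCORING,
    prescreen_min_kmer_fraction: float = 0.01,
) -> list[Cluster]:
    """CD-HIT-style greedy clustering at an identity threshold.

    A cheap shared-11-mer prescreen (both strands) skips the alignment for
    pairs whose shared-word fraction is far below anything a clusterable
    pair could show; the prescreen only applies to sequences longer than
    the exact-alignment limit.  Set ``prescreen_min_kmer_fraction=0`` to
    disable it.
    """
    if not genomes:
        raise ValueError("greedy_cluster needs at least one genome")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(genomes, key=lambda g: (-len(g.seq), g.id))
    by_id = {g.id: g for g in ordered}
    rep_kmers: dict[str, set[int]] = {}
    clusters: list[Cluster] = []
    for g in ordered:
        g_codes = None
        placed = False
        for cl in clusters:
            rep = by_id[cl.representative]
            if prescreen_min_kmer_fraction > 0 and min(len(rep.seq), len(g.seq)) > 2000:
                if g_codes is None:
                    g_codes = _kmer_set(g.seq)
                if cl.representative not in rep_kmers:
                    rep_kmers[cl.representative] = _kmer_set(rep.seq)
                shared = len(g_codes & rep_kmers[cl.representative])
                if shared < prescreen_min_kmer_fraction * max(1, len(g_codes)):
                    continue
            ident = align.clustering_identity(
                rep.seq, g.seq, scoring, early_exit=threshold
            )
            if ident >= threshold:
                cl.members.append((g.id, ident))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=g.id))
    return clusters


def representatives(clusters: Sequence[Cluster]) -> list[str]:
    return [c.representative for c in clusters]


@dataclass
class SimilarityEdge:
    """One undirected edge: longest-HSP length and its identity."""

    u: str
    v: str
    hsp_len: int
    identity: float

    def __post_init__(self) -> None:
        if self.u > self.v:
            self.u, self.v = self.v, self.u
        if self.u == self.v:
            raise ValueError("self edges are not allowed")
        if not (0 <= self.identity <= 1):
            raise ValueError("identity must be in [0, 1]")


def build_network(
    genomes: Sequence[SequenceRecord],
    min_identity: float = 0.0,
    min_hsp_len: int = 0,
    rule: str = "longest",
    scoring: align.ScoringScheme = align.DEFAULT_SCORING,
) -> list[SimilarityEdge]:
    """All-vs-all similarity edges under the longest-alignment rule.

    ``rule="best_score"`` switches the edge index to the identity of the
    highest-scoring HSP instead of the length-maximal one.
    """
    if len(genomes) < 2:
        raise ValueError("build_network needs at least two genomes")
    edges = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            a, b = genomes[i], genomes[j]
            h = align.best_hsp(a.seq, b.seq, scoring, rule=rule)
            if h is None:
                continue
            ident = align.hsp_identity(h)
            if h.aln_len >= min_hsp_len and ident >= min_identity:
                edges.append(SimilarityEdge(a.id, b.id, int(h.aln_len), float(ident)))
    return edges


def components(
    edges: Iterable[SimilarityEdge], all_ids: Iterable[str] = ()
) -> list[set[str]]:
    """Connected components (singletons included from ``all_ids``)."""
    g = nx.Graph()
    g.add_nodes_from(all_ids)
    for e in edges:
        g.add_edge(e.u, e.v)
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# writers


def write_clstr(clusters: Sequence[Cluster], path: str | Path) -> None:
    """CD-HIT-style .clstr text output."""
    with open(path, "w") as fh:
        for ci, cl in enumerate(clusters):
            fh.write(f">Cluster {ci}\n")
            fh.write(f"0\t>{cl.representative}... *\n")
            for mi, (mid, ident) in enumerate(cl.members, start=1):
                fh.write(f"{mi}\t>{mid}... at {100 * ident:.2f}%\n")


def write_edges_tsv(edges: Sequence[SimilarityEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("u\tv\thsp_len\tidentity\n")
        for e in edges:
            fh.write(f"{e.u}\t{e.v}\t{e.hsp_len}\t{e.identity:.6f}\n")


def write_graphml(
    edges: Sequence[SimilarityEdge], path: str | Path, all_ids: Iterable[str] = ()
) -> None:
    g = nx.Graph()
    g.add_nodes_from(all_ids)
    for e in edges:
        g.add_edge(e.u, e.v, hsp_len=e.hsp_len, identity=e.identity)
    nx.write_graphml(g, str(path))
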