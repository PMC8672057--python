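"""Summary tables and the statistical machinery of the comparison.

Covers per-genome summaries (length, GC, census, genic/intergenic
accounting), Pearson correlation with a Student-t p-value, the
Wilcoxon/Mann-Whitney rank-sum test (exact enumeration for small
untied samples, normal approximation with tie and continuity
corrections otherwise), and patristic distance matrices from trees
with branch lengths.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation_io import AnnotatedGenome, gc_content
from .classify import CORE_ORDER, category_census, core_presence, normalize_name
from .intervals import genic_length, intergenic_length

SUMMARY_CATEGORIES = ("intron", "HEG", "uORF", "tRNA", "dpo", "rpo")


def summarize(
    genomes: Sequence[AnnotatedGenome],
    metadata: Mapping[str, Mapping] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per genome: identity, size, composition and accounting.

    Requires features to be classified already.  ``metadata`` supplies
    the phylum per genome id; a missing id is an error.
    """
    if isinstance(metadata, pd.DataFrame):
        metadata = metadata.set_index("id").to_dict("index")
    rows = []
    for g in genomes:
        if metadata is not None and g.id not in metadata:
            raise KeyError(f"metadata missing genome id {g.id!r}")
        meta = metadata.get(g.id, {}) if metadata else {}
        census = category_census(g)
        named = {normalize_name(f.name) for f in g.features}
        row = {
            "id": g.id,
            "phylum": meta.get("phylum", g.record.phylum or "unknown"),
            "length": len(g.record),
            "gc": gc_content(g.record.seq),
            "topology": g.record.topology,
            "genetic_code": g.record.genetic_code,
            "n_core_present": sum(1 for gene in CORE_ORDER if gene in named),
            "genic_length": genic_length(g),
            "intergenic_length": intergenic_length(g),
        }
        for cat in SUMMARY_CATEGORIES:
            row[f"n_{cat}"] = census[f"n_{cat}"]
            row[f"len_{cat}"] = census[f"len_{cat}"]
        for key in ("n_HEG_LAGLIDADG", "n_HEG_GIYYIG", "n_HEG_HNH"):
            row[key] = census[key]
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(summary: pd.DataFrame, by: str = "phylum") -> pd.DataFrame:
    """Mean +/- SD per group for the numeric summary columns."""
    numeric = summary.select_dtypes("number").columns
    return summary.groupby(by)[list(numeric)].agg(["mean", "std", "count"])


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    transform: str = "none"


def pearson(
    x: Sequence[float], y: Sequence[float], log10: bool = False
) -> CorrelationResult:
    """Product-moment correlation; two-sided p from the t transform
    ``t = r * sqrt((n-2) / (1-r^2))`` against Student-t with n-2 df.

    ``log10=True`` applies a log10 transform to both vectors first (used
    for the heavy-tailed uORF length correlations); zero or negative
    values are then an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("pearson requires n >= 3")
    if log10:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log10 transform requires strictly positive values")
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x), "log10" if log10 else "none")


def correlation_report(
    summary: pd.DataFrame,
    pairs: Sequence[tuple[str, str, bool]] = (
        ("length", "len_HEG", False),
        ("length", "len_intron", False),
        ("len_intron", "len_HEG", False),
        ("length", "len_uORF", True),
        ("len_intron", "len_uORF", True),
    ),
) -> pd.DataFrame:
    """Correlations between summary columns (the figure-series pairs).

    For log10 pairs, genomes with a zero value in either column are
    dropped (they have no such element to measure).
    """
    rows = []
    for xcol, ycol, use_log in pairs:
        sub = summary[[xcol, ycol]].dropna()
        if use_log:
            sub = sub[(sub[xcol] > 0) & (sub[ycol] > 0)]
        if len(sub) < 3 or sub[xcol].nunique() < 2 or sub[ycol].nunique() < 2:
            continue
        res = pearson(sub[xcol], sub[ycol], log10=use_log)
        rows.append(
            {
                "x": xcol, "y": ycol, "r": res.r, "p": res.p,
                "n": res.n, "transform": res.transform,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-sum test


def _ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values)  # midranks for ties


def wilcoxon_ranksum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 12
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    Exact p by enumeration of all rank assignments when
    ``len(x) + len(y) <= exact_limit`` and there are no ties; otherwise a
    normal approximation with midrank tie correction and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = _ranks(pooled)
    w = float(ranks[:nx].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= exact_limit and not has_ties:
        mean = nx * (n + 1) / 2
        dev = abs(w - mean)
        count = 0
        total = 0
        for combo in combinations(range(1, n + 1), nx):
            total += 1
            if abs(sum(combo) - mean) >= dev - 1e-9:
                count += 1
        return w, count / total

    mean = nx * (n + 1) / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = nx * ny / 12 * ((n + 1) - tie_term)
    if var == 0:
        return w, 1.0
    diff = abs(w - mean) - 0.5  # continuity correction
    z = max(diff, 0.0) / math.sqrt(var)
    return w, float(2 * sps.norm.sf(z))


# ---------------------------------------------------------------------------
# patristic distances


@dataclass
class PatristicMatrix:
    taxa: list[str]
    d: np.ndarray

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


def patristic_matrix(newick: str) -> PatristicMatrix:
    """Leaf-pair path-length sums from a newick tree with branch lengths."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves if lf.taxon is not None]
    if len(labels) != len(leaves):
        raise ValueError("every leaf must be labelled")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("tree has an edge without a branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in leaves}
    labels = sorted(labels)
    d = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[i, j] = d[j, i] = pdm.distance(taxa[a], taxa[b])
    return PatristicMatrix(labels, d)
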