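"""End-to-end orchestration: filter -> classify -> account -> correlate -> network.

The stage order mirrors how comparative mitogenome studies proceed: the
redundancy filter runs first and every downstream statistic is computed
on the non-redundant representative set.  Quality control precedes
clustering: genomes with more than ``max_n_fraction`` of N bases or
shorter than ``min_length`` are excluded with a logged reason.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    AnnotatedGenome,
    read_fasta,
    read_feature_table,
    read_metadata,
)
from .classify import (
    DomainHit,
    classify_genome,
    phylum_core_frequency,
    presence_matrix,
    share_missing_core,
)
from .intervals import overlap_report, pool_reports
from .similarity import (
    build_network,
    components,
    greedy_cluster,
    write_clstr,
    write_edges_tsv,
    write_graphml,
)
from .stats import correlation_report, patristic_matrix, summarize

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    features_dir: str
    outdir: str
    metadata: str | None = None
    domain_hits: str | None = None
    id_hits: str | None = None
    reference_dir: str | None = None
    newick: str | None = None
    cluster_threshold: float = 0.90
    absence_identity: float = 0.50
    triage_identity: float = 0.80
    e_value_cutoff: float = 0.01
    max_n_fraction: float = 0.20
    min_length: int = 2000
    network_min_identity: float = 0.0
    network_min_hsp_len: int = 0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for t in (self.cluster_threshold, self.absence_identity, self.triage_identity):
            if not (0 < t <= 1):
                raise ValueError("identity thresholds must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _load_hits_table(path: str | None, value_cols: list[str]) -> dict:
    """TSV -> {genome_id: {orf_id: [tuple of value columns]}}."""
    out: dict = {}
    if path is None:
        return out
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        out.setdefault(row["genome_id"], {}).setdefault(row["orf_id"], []).append(
            tuple(row[c] for c in value_cols)
        )
    return out


def _load_references(reference_dir: str | None) -> dict | None:
    if reference_dir is None:
        return None
    refs: dict = {}
    for fa in sorted(Path(reference_dir).glob("*.fasta")):
        gene = fa.stem
        refs[gene] = [r.seq for r in read_fasta(fa)]
    return refs


def run(cfg: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial_marker = outdir / "RUN.partial"
    partial_marker.write_text("run in progress\n")
    manifest: dict = {
        "package": "mitocomp",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "stages": {},
    }

    stage = "load"
    try:
        t0 = time.perf_counter()
        metadata = read_metadata(cfg.metadata) if cfg.metadata else None
        records = read_fasta(cfg.fasta, metadata=metadata)
        genomes = []
        for rec in records:
            ft = Path(cfg.features_dir) / f"{rec.id}.tsv"
            feats = (
                read_feature_table(ft, len(rec), rec.topology) if ft.exists() else []
            )
            genomes.append(AnnotatedGenome(record=rec, features=feats))
        manifest["stages"]["load"] = {
            "n_genomes": len(genomes), "seconds": time.perf_counter() - t0,
        }

        stage = "qc"
        t0 = time.perf_counter()
        kept, excluded = [], []
        for g in genomes:
            if len(g.record) < cfg.min_length:
                excluded.append((g.id, f"length {len(g.record)} < {cfg.min_length}"))
            elif g.record.n_fraction > cfg.max_n_fraction:
                excluded.append(
                    (g.id, f"N fraction {g.record.n_fraction:.3f} > {cfg.max_n_fraction}")
                )
            else:
                kept.append(g)
        pd.DataFrame(excluded, columns=["id", "reason"]).to_csv(
            outdir / "qc_exclusions.tsv", sep="\t", index=False
        )
        for gid, reason in excluded:
            log.info("QC excluded %s: %s", gid, reason)
        if not kept:
            raise ValueError("no genomes passed quality control")
        manifest["stages"]["qc"] = {
            "n_kept": len(kept), "n_excluded": len(excluded),
            "seconds": time.perf_counter() - t0,
        }

        stage = "cluster"
        t0 = time.perf_counter()
        clusters = greedy_cluster(
            [g.record for g in kept], threshold=cfg.cluster_threshold
        )
        write_clstr(clusters, outdir / "clusters.clstr")
        rep_ids = {c.representative for c in clusters}
        reps = [g for g in kept if g.id in rep_ids]
        (outdir / "nonredundant.txt").write_text(
            "".join(f"{g.id}\n" for g in reps)
        )
        manifest["stages"]["cluster"] = {
            "n_clusters": len(clusters),
            "n_members_total": sum(c.size for c in clusters),
            "seconds": time.perf_counter() - t0,
        }

        stage = "classify"
        t0 = time.perf_counter()
        domain_hits = {
            gid: {
                orf: [DomainHit(orf, d, sf, float(ev)) for d, sf, ev in hits]
                for orf, hits in per_orf.items()
            }
            for gid, per_orf in _load_hits_table(
                cfg.domain_hits, ["domain_name", "superfamily", "e_value"]
            ).items()
        }
        id_hits = _load_hits_table(cfg.id_hits, ["ref_class", "identity"])
        for g in reps:
            classify_genome(
                g,
                domain_hits.get(g.id),
                id_hits.get(g.id),
                triage_identity=cfg.triage_identity,
                e_value_cutoff=cfg.e_value_cutoff,
            )
        manifest["stages"]["classify"] = {
            "n_features": sum(len(g.features) for g in reps),
            "seconds": time.perf_counter() - t0,
        }

        stage = "presence"
        t0 = time.perf_counter()
        references = _load_references(cfg.reference_dir)
        pm = presence_matrix(reps, references, cfg.absence_identity)
        pm.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        phylum_of = {g.id: (g.record.phylum or "unknown") for g in reps}
        phylum_core_frequency(pm, phylum_of).to_csv(
            outdir / "phylum_core_frequency.tsv", sep="\t"
        )
        manifest["stages"]["presence"] = {
            "share_missing_core": share_missing_core(pm),
            "seconds": time.perf_counter() - t0,
        }

        stage = "account"
        t0 = time.perf_counter()
        summary = summarize(reps, metadata)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        reports = {"within": [], "overlap": []}
        for g in reps:
            rep_h = overlap_report(
                g.features_in_category("HEG"),
                g.features_in_category("intron"),
                len(g.record),
                g.record.topology,
            )
            rep_i = overlap_report(
                g.features_in_category("intron"),
                g.features_in_category("HEG"),
                len(g.record),
                g.record.topology,
            )
            reports["within"].append(rep_h)
            reports["overlap"].append(rep_i)
        pooled_h = pool_reports(reports["within"])
        pooled_i = pool_reports(reports["overlap"])
        with open(outdir / "overlap_report.tsv", "w") as fh:
            fh.write("a\tb\tmode\tn_a\tn_hit\tfraction\n")
            fh.write(
                f"HEG\tintron\twithin\t{pooled_h.n_a}\t{pooled_h.n_a_within_b}\t"
                f"{'' if pooled_h.frac_within is None else f'{pooled_h.frac_within:.6f}'}\n"
            )
            fh.write(
                f"intron\tHEG\toverlap\t{pooled_i.n_a}\t{pooled_i.n_a_overlapping_b}\t"
                f"{'' if pooled_i.frac_overlapping is None else f'{pooled_i.frac_overlapping:.6f}'}\n"
            )
        manifest["stages"]["account"] = {
            "n_rows": len(summary),
            "hegs_within_introns": pooled_h.frac_within,
            "introns_overlapping_hegs": pooled_i.frac_overlapping,
            "seconds": time.perf_counter() - t0,
        }

        stage = "stats"
        t0 = time.perf_counter()
        corr = correlation_report(summary)
        corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        if cfg.newick:
            pm_tree = patristic_matrix(Path(cfg.newick).read_text())
            pm_tree.to_frame().to_csv(outdir / "patristic.tsv", sep="\t")
        manifest["stages"]["stats"] = {
            "n_correlations": len(corr), "seconds": time.perf_counter() - t0,
        }

        stage = "network"
        t0 = time.perf_counter()
        edges = build_network(
            [g.record for g in reps],
            min_identity=cfg.network_min_identity,
            min_hsp_len=cfg.network_min_hsp_len,
        )
        write_edges_tsv(edges, outdir / "edges.tsv")
        write_graphml(edges, outdir / "network.graphml", [g.id for g in reps])
        comps = components(edges, [g.id for g in reps])
        with open(outdir / "components.tsv", "w") as fh:
            fh.write("component\tid\n")
            for ci, comp in enumerate(comps):
                for gid in sorted(comp):
                    fh.write(f"{ci}\t{gid}\n")
        manifest["stages"]["network"] = {
            "n_edges": len(edges), "n_components": len(comps),
            "seconds": time.perf_counter() - t0,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    partial_marker.unlink(missing_ok=True)
    return manifest
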