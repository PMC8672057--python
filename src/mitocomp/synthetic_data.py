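"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates the statistical regimes of curated fungal
mitogenome sets: lognormal genome lengths, mostly circular topology, a
mix of the four mitochondrial genetic codes, low GC, per-gene core
dropout, Poisson accessory loads (introns hosted inside core genes, HEGs
either embedded in introns or free-standing, uORFs, occasional
plasmid-derived dpo/rpo), and a coupling knob that makes accessory load
grow with genome length so that the length-vs-accessory correlations of
real datasets are reproducible on demand.

Genome lengths are scaled down ten-fold by default (the real 12-272 kbp
range becomes roughly 4-27 kbp; the lower bound is raised so that the
full core complement always fits) to keep exhaustive alignment oracles
fast.  Feature sequences are random DNA with planted start/stop codons —
classification downstream is name- and hit-driven, so sequence-level
homology realism is unnecessary, except where a test explicitly plants
it (e.g. copies of a gene or mutated whole-genome copies).

Everything is deterministic under the config seed, including the emitted
files (byte-identical FASTA and tables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    CIRCULAR,
    LINEAR,
    AnnotatedGenome,
    Feature,
    SequenceRecord,
    write_fasta,
    write_feature_table,
    write_metadata,
)
from .classify import (
    CORE_ORDER,
    CORE_PROTEIN_GENES,
    HEG_FAMILIES,
    INTRON_CLASSES,
    RRNA_GENES,
)

_TRNA_AAS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    """Study conditions for dataset generation (all randomness seeded).

    Count parameters are per-genome Poisson means at the median genome
    length; ``heg_length_coupling`` scales all accessory means by
    ``(L / length_median) ** (2 * coupling)`` so longer genomes carry
    more accessory load.
    """

    n_genomes: int = 50
    # genome length: lognormal, 10x scaled down
    length_median: int = 6400
    length_sigma: float = 0.5
    length_min: int = 4000
    length_max: int = 27200
    circular_fraction: float = 0.948
    genetic_code_weights: dict = field(
        default_factory=lambda: {1: 0.22, 3: 0.10, 4: 0.62, 16: 0.06}
    )
    gc_mean: float = 0.25
    gc_sd: float = 0.05
    # core complement
    core_dropout: float = 0.0317  # per-gene; ~36% of genomes miss >= 1 gene
    rps3_presence: float = 0.8
    trna_mean: float = 12.0
    # accessory load (per-genome means at median length)
    intron_mean: float = 8.0
    heg_mean: float = 8.0
    heg_embedding: float = 0.4346  # P(a HEG sits inside an intron)
    uorf_mean: float = 8.2
    dpo_mean: float = 0.4
    rpo_mean: float = 0.15
    other_domain_mean: float = 0.3
    heg_length_coupling: float = 0.5
    # per-HEG family frequencies (LAGLIDADG dominates, H-N-H rare)
    heg_family_weights: dict = field(
        default_factory=lambda: {"LAGLIDADG": 0.778, "GIY-YIG": 0.219, "H-N-H": 0.003}
    )
    intron_class_weights: dict = field(
        default_factory=lambda: {
            "IA": 0.15, "IB": 0.45, "IC1": 0.04, "IC2": 0.06, "ID": 0.10, "II": 0.20,
        }
    )
    rotate_circular: bool = True
    # families of near-identical genomes: list of (size, target_identity)
    family_structure: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.circular_fraction, self.core_dropout, self.rps3_presence,
            self.heg_embedding,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.length_min < 3600:
            raise ValueError(
                "length_min below 3600 bp cannot host the full core complement"
            )
        for m in (self.intron_mean, self.heg_mean, self.uorf_mean):
            if m < 0:
                raise ValueError("count means must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth, exactly matching the emitted annotations."""

    # id -> {"features": [...], "presence": {gene: bool}, "counts": {...},
    #        "n_hegs_embedded": int}
    genomes: dict = field(default_factory=dict)
    # id -> {feature name -> [[domain_name, superfamily, e_value], ...]}
    domain_hits: dict = field(default_factory=dict)
    # id -> {feature name -> [[ref_class, identity], ...]}
    id_hits: dict = field(default_factory=dict)
    family_of: dict = field(default_factory=dict)  # id -> family label
    target_identity: dict = field(default_factory=dict)  # id -> fraction

    def counts(self, genome_id: str) -> dict:
        return self.genomes[genome_id]["counts"]

    def presence_frame(self) -> pd.DataFrame:
        rows = {
            gid: info["presence"] for gid, info in self.genomes.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")[list(CORE_ORDER)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# sequence helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _weighted_choice(rng: np.random.Generator, weights: dict):
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


# ---------------------------------------------------------------------------
# per-genome layout

# scaled-down feature length samplers (bp)
def _len_core(rng) -> int:
    return 3 * int(rng.integers(25, 51))  # 75-150


def _len_heg(rng) -> int:
    return 3 * int(rng.integers(12, 29))  # 36-84


def _len_uorf(rng) -> int:
    return 3 * int(rng.integers(20, 51))  # 60-150


def _len_dpo(rng) -> int:
    return 3 * int(rng.integers(60, 111))


def _len_rpo(rng) -> int:
    return 3 * int(rng.integers(45, 91))


_LEN_RNL = 350
_LEN_RNS = 220
_LEN_RPS3 = 120


@dataclass
class _Item:
    """One top-level layout item; genes carry nested intron/HEG children."""

    name: str
    category: str
    subtype: str | None
    length: int
    coding: bool = False
    children: list = field(default_factory=list)  # nested _Item (introns)


def _plan_genome(
    cfg: GeneratorConfig, rng: np.random.Generator, length: int
) -> tuple[list[_Item], dict, int]:
    """Decide the feature inventory and nesting for one genome."""
    factor = (length / cfg.length_median) ** (2 * cfg.heg_length_coupling)

    presence = {}
    for gene in CORE_ORDER:
        presence[gene] = bool(rng.random() >= cfg.core_dropout)
    has_rps3 = bool(rng.random() < cfg.rps3_presence)

    genes: list[_Item] = []
    for gene in CORE_PROTEIN_GENES:
        if presence[gene]:
            genes.append(_Item(gene, "core_gene", gene, _len_core(rng), coding=True))
    if presence["rns"]:
        genes.append(_Item("rns", "rRNA", None, _LEN_RNS))
    if presence["rnl"]:
        genes.append(_Item("rnl", "rRNA", None, _LEN_RNL))
    if has_rps3:
        genes.append(_Item("rps3", "rps3", None, _LEN_RPS3, coding=True))

    orf_counter = 0

    def orf_name() -> str:
        nonlocal orf_counter
        orf_counter += 1
        return f"orf{orf_counter}"

    # introns (hosted inside genes; skipped when no host exists)
    n_introns = int(rng.poisson(cfg.intron_mean * factor))
    introns: list[_Item] = []
    for _ in range(n_introns):
        cls = _weighted_choice(rng, cfg.intron_class_weights)
        introns.append(_Item(f"intron_{cls}", "intron", cls, 0))

    # HEGs: embedded ones claim a host intron (created if necessary)
    n_hegs = int(rng.poisson(cfg.heg_mean * factor))
    free_items: list[_Item] = []
    n_embedded = 0
    free_intron_pool = list(introns)
    for _ in range(n_hegs):
        fam = _weighted_choice(rng, cfg.heg_family_weights)
        heg = _Item(orf_name(), "HEG", fam, _len_heg(rng), coding=True)
        if genes and rng.random() < cfg.heg_embedding:
            if free_intron_pool:
                host = free_intron_pool.pop(int(rng.integers(len(free_intron_pool))))
            else:  # force embedding even when the intron draw ran short
                cls = _weighted_choice(rng, cfg.intron_class_weights)
                host = _Item(f"intron_{cls}", "intron", cls, 0)
                introns.append(host)
            host.children.append(heg)
            n_embedded += 1
        else:
            free_items.append(heg)

    # size introns: own padding around any embedded HEG (an item's
    # `length` is its own extra extent; nested spans add up recursively)
    for intr in introns:
        intr.length = int(rng.integers(15, 46)) if intr.children else int(
            rng.integers(45, 106)
        )

    # attach introns to hosts
    if genes:
        for intr in introns:
            host = genes[int(rng.integers(len(genes)))]
            host.children.append(intr)
    else:
        introns = []  # no host gene anywhere: drop introns (and nested HEGs)
        free_items = [it for it in free_items]
        n_embedded = 0

    n_trna = int(rng.poisson(cfg.trna_mean))
    trnas = [
        _Item(
            f"trn{_TRNA_AAS[int(rng.integers(len(_TRNA_AAS)))]}{k + 1}",
            "tRNA",
            None,
            int(rng.integers(21, 28)),
        )
        for k in range(n_trna)
    ]

    for _ in range(int(rng.poisson(cfg.uorf_mean * factor))):
        free_items.append(_Item(orf_name(), "uORF", None, _len_uorf(rng), coding=True))
    for _ in range(int(rng.poisson(cfg.dpo_mean * factor))):
        free_items.append(_Item(orf_name(), "dpo", None, _len_dpo(rng), coding=True))
    for _ in range(int(rng.poisson(cfg.rpo_mean * factor))):
        free_items.append(_Item(orf_name(), "rpo", None, _len_rpo(rng), coding=True))
    for _ in range(int(rng.poisson(cfg.other_domain_mean))):
        free_items.append(
            _Item(orf_name(), "domain_orf", None, _len_uorf(rng), coding=True)
        )

    top = genes + trnas + free_items
    order = rng.permutation(len(top))
    top = [top[i] for i in order]
    return top, {"presence": presence, "rps3": has_rps3}, n_embedded


def _gene_span(item: _Item) -> int:
    return item.length + sum(_gene_span(ch) for ch in item.children)


def _layout(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    top: list[_Item],
    length: int,
    genome_id: str,
) -> list[Feature]:
    """Place top-level items left to right with Dirichlet-split gaps."""
    total = sum(_gene_span(it) for it in top)
    if total > length:
        raise ValueError(
            f"{genome_id}: planted features need {total} bp but the genome "
            f"is only {length} bp"
        )
    slack = length - total
    n_gaps = len(top) + 1
    if slack > 0 and n_gaps > 0:
        parts = rng.dirichlet(np.ones(n_gaps)) * slack
        gaps = np.floor(parts).astype(int)
        gaps[0] += slack - int(gaps.sum())
    else:
        gaps = np.zeros(n_gaps, dtype=int)

    features: list[Feature] = []
    cursor = 0
    for idx, item in enumerate(top):
        cursor += int(gaps[idx])
        span = _gene_span(item)
        start0 = cursor
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            Feature(
                name=item.name,
                start=start0 + 1,
                end=start0 + span,
                strand=strand,
                category=item.category,
                subtype=item.subtype,
            )
        )
        # nest children (introns, then HEGs inside introns) within the span
        if item.children:
            inner_cursor = start0
            inner_slack = span - sum(_gene_span(ch) for ch in item.children)
            inner_gaps = rng.dirichlet(np.ones(len(item.children) + 1)) * inner_slack
            inner_gaps = np.floor(inner_gaps).astype(int)
            inner_gaps[0] += inner_slack - int(inner_gaps.sum())
            for cidx, child in enumerate(item.children):
                inner_cursor += int(inner_gaps[cidx])
                cspan = _gene_span(child)
                features.append(
                    Feature(
                        name=child.name,
                        start=inner_cursor + 1,
                        end=inner_cursor + cspan,
                        strand=strand,
                        category=child.category,
                        subtype=child.subtype,
                    )
                )
                # grandchildren: a HEG inside an intron, centred in its pad
                gc_cursor = inner_cursor
                for gch in child.children:
                    pad = cspan - gch.length
                    off = int(rng.integers(0, pad + 1)) if pad > 0 else 0
                    features.append(
                        Feature(
                            name=gch.name,
                            start=gc_cursor + off + 1,
                            end=gc_cursor + off + gch.length,
                            strand=strand,
                            category=gch.category,
                            subtype=gch.subtype,
                        )
                    )
                inner_cursor += cspan
        cursor += span
    return features


def _plant_codons(
    seq: list[str], features: list[Feature], top: list[_Item]
) -> None:
    coding = {it.name for it in top if it.coding}
    for it in top:
        for ch in it.children:
            coding.update(g.name for g in ch.children if g.coding)
    for f in features:
        if f.name in coding and not f.wraps_origin:
            seq[f.start - 1 : f.start + 2] = list("ATG")
            seq[f.end - 3 : f.end] = list("TAA")  # stop in all four codes


def _rotate(features: list[Feature], seq: str, offset: int) -> tuple[list[Feature], str]:
    """Rotate a circular genome's origin; features may wrap afterwards."""
    L = len(seq)
    offset %= L
    new_seq = seq[L - offset :] + seq[: L - offset]
    out = []
    for f in features:
        ns = (f.start - 1 + offset) % L + 1
        ne = (f.end - 1 + offset) % L + 1
        out.append(
            Feature(
                name=f.name,
                start=ns,
                end=ne,
                strand=f.strand,
                wraps_origin=ns > ne,
                category=f.category,
                subtype=f.subtype,
            )
        )
    return out, new_seq


_CATEGORY_KEYS = (
    "core_gene", "rRNA", "rps3", "tRNA", "intron", "HEG", "uORF",
    "dpo", "rpo", "domain_orf", "other",
)


def _truth_counts(features: list[Feature]) -> dict:
    counts = {cat: 0 for cat in _CATEGORY_KEYS}
    for f in features:
        counts[f.category] += 1
    return counts


def _emit_hits(
    rng: np.random.Generator, features: list[Feature]
) -> tuple[dict, dict]:
    domain_hits: dict = {}
    id_hits: dict = {}
    for f in features:
        if f.category == "HEG":
            fam = f.subtype
            domain_hits[f.name] = [
                [f"{fam}_dom{int(rng.integers(1, 9))}", fam, float(10.0 ** -rng.uniform(5, 20))]
            ]
        elif f.category == "dpo":
            id_hits[f.name] = [["dpo", float(rng.uniform(0.85, 0.99))]]
        elif f.category == "rpo":
            id_hits[f.name] = [["rpo", float(rng.uniform(0.85, 0.99))]]
        elif f.category == "domain_orf":
            domain_hits[f.name] = [
                ["HAD_like", "HAD", float(10.0 ** -rng.uniform(3, 10))]
            ]
    return domain_hits, id_hits


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[AnnotatedGenome], SyntheticTruth]:
    """Generate annotated genomes plus their exact planted truth."""
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth()
    genomes: list[AnnotatedGenome] = []

    for g_idx in range(cfg.n_genomes):
        gid = f"SYN{g_idx + 1:04d}"
        length = int(
            np.clip(
                rng.lognormal(np.log(cfg.length_median), cfg.length_sigma),
                cfg.length_min,
                cfg.length_max,
            )
        )
        topology = CIRCULAR if rng.random() < cfg.circular_fraction else LINEAR
        code = _weighted_choice(rng, cfg.genetic_code_weights)
        gc = float(np.clip(rng.normal(cfg.gc_mean, cfg.gc_sd), 0.10, 0.60))

        top, meta, n_embedded = _plan_genome(cfg, rng, length)
        # the low tail of the length distribution may not fit the drawn
        # feature load; expand such genomes just enough (>=5% intergenic)
        required = sum(_gene_span(it) for it in top)
        length = max(length, int(np.ceil(required / 0.95)))
        features = _layout(cfg, rng, top, length, gid)
        seq = list(_random_dna(rng, length, gc))
        _plant_codons(seq, features, top)

        if topology == CIRCULAR and cfg.rotate_circular:
            offset = int(rng.integers(0, length))
            features, seq_str = _rotate(features, "".join(seq), offset)
        else:
            seq_str = "".join(seq)

        record = SequenceRecord(
            id=gid, seq=seq_str, topology=topology, genetic_code=int(code),
            phylum=_weighted_choice(
                rng,
                {"Ascomycota": 0.55, "Basidiomycota": 0.25, "Mucoromycota": 0.08,
                 "Chytridiomycota": 0.07, "Blastocladiomycota": 0.03,
                 "Zoopagomycota": 0.02},
            ),
        )
        genome = AnnotatedGenome(record=record, features=features)
        genomes.append(genome)

        d_hits, i_hits = _emit_hits(rng, features)
        presence = dict(meta["presence"])
        truth.genomes[gid] = {
            "features": [
                {
                    "name": f.name, "category": f.category, "subtype": f.subtype,
                    "start": f.start, "end": f.end, "strand": f.strand,
                    "wraps_origin": f.wraps_origin,
                }
                for f in features
            ],
            "presence": presence,
            "counts": _truth_counts(features),
            "n_hegs_embedded": n_embedded,
        }
        truth.domain_hits[gid] = d_hits
        truth.id_hits[gid] = i_hits

    return genomes, truth


# ---------------------------------------------------------------------------
# mutated copies and planted families


def mutate_copy(
    g: SequenceRecord, target_identity: float, seed: int, new_id: str | None = None
) -> SequenceRecord:
    """Copy of ``g`` diverged to approximately a target identity.

    The divergence budget ``1 - target_identity`` is spent 90% on
    substitutions and 10% on small indels (geometric lengths, mean 3 bp),
    so the realized clustering identity tracks the target to within a few
    percent on sequences of a few kbp.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rate = 1 - target_identity
    sub_rate, indel_rate = 0.9 * rate, 0.1 * rate
    bases = "ACGT"
    out: list[str] = []
    i = 0
    n = len(g.seq)
    while i < n:
        ch = g.seq[i]
        u = rng.random()
        if u < sub_rate:
            out.append(
                bases[(bases.index(ch) + int(rng.integers(1, 4))) % 4]
                if ch in bases
                else ch
            )
            i += 1
        elif u < sub_rate + indel_rate:
            size = int(rng.geometric(1 / 3))
            if rng.random() < 0.5:  # insertion after this base
                out.append(ch)
                out.extend(bases[int(rng.integers(4))] for _ in range(size))
                i += 1
            else:  # deletion of a block starting here
                i += size
        else:
            out.append(ch)
            i += 1
    return SequenceRecord(
        id=new_id or f"{g.id}_copy{seed}",
        seq="".join(out) if out else g.seq[:1],
        topology=g.topology,
        genetic_code=g.genetic_code,
        phylum=g.phylum,
    )


def plant_families(cfg: GeneratorConfig) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Dataset of genome families: one ancestor per family plus copies
    mutated to the family's target identity.

    ``cfg.family_structure`` is a list of ``(size, target_identity)``
    pairs; each family contributes one ancestor and ``size - 1`` copies.
    """
    if not cfg.family_structure:
        raise ValueError("cfg.family_structure must be non-empty")
    for size, ident in cfg.family_structure:
        if size < 1:
            raise ValueError("family sizes must be >= 1")
        if not (0 < ident <= 1):
            raise ValueError("target identities must be in (0, 1]")
    seedseq = np.random.SeedSequence(cfg.seed)
    child_seeds = seedseq.spawn(1 + len(cfg.family_structure))
    anc_cfg = GeneratorConfig(
        **{
            **{k: v for k, v in asdict(cfg).items() if k in GeneratorConfig.__dataclass_fields__},
            "n_genomes": len(cfg.family_structure),
            "family_structure": [],
            "seed": int(child_seeds[0].generate_state(1)[0] % (2**31)),
        }
    )
    ancestors, _ = generate_dataset(anc_cfg)
    records: list[SequenceRecord] = []
    truth = SyntheticTruth()
    for fam_idx, ((size, ident), anc) in enumerate(
        zip(cfg.family_structure, ancestors)
    ):
        fam = f"FAM{fam_idx + 1:03d}"
        base = SequenceRecord(
            id=f"{fam}_0", seq=anc.record.seq, topology=anc.record.topology,
            genetic_code=anc.record.genetic_code, phylum=anc.record.phylum,
        )
        records.append(base)
        truth.family_of[base.id] = fam
        truth.target_identity[base.id] = 1.0
        fam_rng = np.random.default_rng(
            int(child_seeds[fam_idx + 1].generate_state(1)[0] % (2**31))
        )
        for m in range(1, size):
            # keep the ancestor the longest family member, so that the
            # greedy length-descending pass makes it the representative
            # and member identities to the representative equal the
            # family target
            for _ in range(64):
                copy = mutate_copy(
                    base, ident, seed=int(fam_rng.integers(2**31)),
                    new_id=f"{fam}_{m}",
                )
                if ident == 1.0 or len(copy.seq) < len(base.seq):
                    break
            records.append(copy)
            truth.family_of[copy.id] = fam
            truth.target_identity[copy.id] = ident
    return records, truth


# ---------------------------------------------------------------------------
# on-disk dataset (same dialects annotation_io reads)


def write_dataset(
    genomes: Sequence[AnnotatedGenome], truth: SyntheticTruth, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([g.record for g in genomes], outdir / "genomes.fasta")
    write_metadata([g.record for g in genomes], outdir / "metadata.tsv")
    feat_dir = outdir / "features"
    feat_dir.mkdir(exist_ok=True)
    for g in genomes:
        write_feature_table(
            g.features, feat_dir / f"{g.id}.tsv", genome_length=len(g.record)
        )
    dh_rows = [
        {"genome_id": gid, "orf_id": orf, "domain_name": d, "superfamily": sf,
         "e_value": ev}
        for gid, hits in truth.domain_hits.items()
        for orf, hlist in hits.items()
        for d, sf, ev in hlist
    ]
    pd.DataFrame(
        dh_rows, columns=["genome_id", "orf_id", "domain_name", "superfamily", "e_value"]
    ).to_csv(outdir / "domain_hits.tsv", sep="\t", index=False)
    ih_rows = [
        {"genome_id": gid, "orf_id": orf, "ref_class": cls, "identity": ident}
        for gid, hits in truth.id_hits.items()
        for orf, hlist in hits.items()
        for cls, ident in hlist
    ]
    pd.DataFrame(
        ih_rows, columns=["genome_id", "orf_id", "ref_class", "identity"]
    ).to_csv(outdir / "id_hits.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
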