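"""Feature categorization and the core-gene presence/absence matrix.

Mitogenome features fall into a small set of categories: the conserved
core (14 protein-coding genes, the two rRNAs ``rns``/``rnl``, and the
optionally present ribosomal protein ``rps3``), tRNAs, self-splicing
introns (classes IA, IB, IC1, IC2, ID of group I plus group II), homing
endonuclease genes (families LAGLIDADG, GIY-YIG, H-N-H), plasmid-derived
DNA/RNA polymerases (``dpo``/``rpo``), ORFs with some other known protein
domain, and uORFs — ORFs with no known domain and no high-identity match
to any reference class.

The triage decision tree for an unnamed ORF is, in order of precedence:
annotated name -> intron class parsed from the name -> reference-panel
identity hit above the triage threshold (HEG/dpo/rpo) -> HEG-family
domain hit -> any other domain hit -> uORF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import align
from .annotation_io import AnnotatedGenome, Feature
from .intervals import canonicalize

log = logging.getLogger(__name__)

# categories
CORE_GENE = "core_gene"
RRNA = "rRNA"
RPS3 = "rps3"
TRNA = "tRNA"
INTRON = "intron"
HEG = "HEG"
UORF = "uORF"
DPO = "dpo"
RPO = "rpo"
DOMAIN_ORF = "domain_orf"
OTHER = "other"

CATEGORIES = (
    CORE_GENE, RRNA, RPS3, TRNA, INTRON, HEG, UORF, DPO, RPO, DOMAIN_ORF, OTHER,
)

CORE_PROTEIN_GENES = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNA_GENES = ("rns", "rnl")
#: fixed column order of the presence/absence matrix
CORE_ORDER = CORE_PROTEIN_GENES + RRNA_GENES

INTRON_CLASSES = ("IA", "IB", "IC1", "IC2", "ID", "II")
HEG_FAMILIES = ("LAGLIDADG", "GIY-YIG", "H-N-H")

# case-insensitive synonyms seen in annotation outputs
_NAME_SYNONYMS = {
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cox-1": "cox1", "cox-2": "cox2", "cox-3": "cox3",
    "nadl4": "nad4L", "nad4l": "nad4L",
    "atpase6": "atp6", "atpase8": "atp8", "atpase9": "atp9",
    "cytb": "cob", "cob1": "cob",
    "rrnl": "rnl", "rrns": "rns",
}

_CORE_LOOKUP = {g.lower(): g for g in CORE_PROTEIN_GENES}


def normalize_name(name: str) -> str:
    key = name.strip().lower()
    key = _NAME_SYNONYMS.get(key, key)
    if key in _CORE_LOOKUP:
        return _CORE_LOOKUP[key]
    return key


@dataclass
class DomainHit:
    """One conserved-domain hit for an ORF (CD-Search-style record)."""

    orf_id: str
    domain_name: str
    superfamily: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


def _heg_family_of(hit: DomainHit) -> str | None:
    text = f"{hit.domain_name} {hit.superfamily}".upper().replace("_", "-")
    if "LAGLIDADG" in text:
        return "LAGLIDADG"
    if "GIY-YIG" in text or "GIYYIG" in text.replace("-", ""):
        return "GIY-YIG"
    if "H-N-H" in text or "HNH" in text.replace("-", ""):
        return "H-N-H"
    return None


def _parse_intron_class(name: str) -> str | None:
    up = name.upper().replace("INTRON", " ").replace("_", " ").replace("-", " ")
    tokens = up.split()
    # longest labels first so IC1/IC2 are not shadowed by shorter matches
    for cls in ("IC1", "IC2", "IA", "IB", "ID", "II"):
        if cls in tokens:
            return cls
    return None


def classify_feature(
    feature: Feature,
    hits: Sequence[DomainHit] = (),
    id_hits: Sequence[tuple[str, float]] = (),
    triage_identity: float = 0.80,
    e_value_cutoff: float = 0.01,
) -> tuple[str, str | None]:
    """Assign (category, subtype) to one feature.

    ``hits`` are protein-domain hits for the feature's ORF; ``id_hits``
    are (reference class, identity) pairs from nucleotide comparison
    against reference panels, with class one of ``"HEG"``, ``"dpo"``,
    ``"rpo"`` (a HEG class may carry its family as ``"HEG:GIY-YIG"``).
    Identity must be strictly above ``triage_identity`` to count.
    """
    name = normalize_name(feature.name)

    if name in CORE_PROTEIN_GENES:
        return CORE_GENE, name
    if name in RRNA_GENES:
        return RRNA, None
    if name == "rps3":
        return RPS3, None
    if name.startswith("trn") or feature.name.lower().startswith("trna"):
        return TRNA, None
    if "intron" in name:
        return INTRON, _parse_intron_class(feature.name)

    good_hits = [h for h in hits if h.e_value <= e_value_cutoff]

    strong = [(cls, ident) for cls, ident in id_hits if ident > triage_identity]
    if strong:
        best_ident = max(ident for _, ident in strong)
        best = [cls for cls, ident in strong if ident == best_ident]
        base_classes = {cls.split(":")[0] for cls in best}
        if len(base_classes) > 1:
            warnings.warn(
                f"feature {feature.name!r}: tied identity hits to classes "
                f"{sorted(base_classes)}; classified as 'other'"
            )
            return OTHER, None
        cls = best[0]
        base, _, family = cls.partition(":")
        if base == "HEG":
            if not family:
                fams = [f for f in (_heg_family_of(h) for h in good_hits) if f]
                family = fams[0] if fams else None
            return HEG, family
        if base in (DPO, RPO):
            return base, None
        warnings.warn(
            f"feature {feature.name!r}: unknown reference class {base!r}"
        )
        return OTHER, None

    heg_fams = [f for f in (_heg_family_of(h) for h in good_hits) if f]
    if heg_fams:
        return HEG, heg_fams[0]
    if good_hits:
        return DOMAIN_ORF, None
    return UORF, None


def classify_genome(
    genome: AnnotatedGenome,
    domain_hits: Mapping[str, Sequence[DomainHit]] | None = None,
    id_hits: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    triage_identity: float = 0.80,
    e_value_cutoff: float = 0.01,
) -> AnnotatedGenome:
    """Classify every feature in place (hits keyed by feature name)."""
    domain_hits = domain_hits or {}
    id_hits = id_hits or {}
    for f in genome.features:
        f.category, f.subtype = classify_feature(
            f,
            domain_hits.get(f.name, ()),
            id_hits.get(f.name, ()),
            triage_identity=triage_identity,
            e_value_cutoff=e_value_cutoff,
        )
    return genome


# ---------------------------------------------------------------------------
# core-gene presence


def core_presence(
    genome: AnnotatedGenome,
    references: Mapping[str, Sequence[str]] | None = None,
    identity_threshold: float = 0.50,
    min_reference_coverage: float = 0.50,
) -> pd.Series:
    """Presence of the 16 core genes (14 protein-coding + rns + rnl).

    A gene is present if it is annotated by name, or — when nucleotide
    ``references`` are supplied — if a local alignment of the genome
    against any reference sequence of that gene reaches identity strictly
    above ``identity_threshold`` while covering at least
    ``min_reference_coverage`` of the reference length (the coverage
    requirement guards against rescuing a gene from a tiny high-identity
    HSP).
    """
    named = {
        normalize_name(f.name)
        for f in genome.features
    }
    present = {}
    for gene in CORE_ORDER:
        if gene in named or gene.lower() in named:
            present[gene] = True
            continue
        present[gene] = False
        if references is not None:
            if gene not in references or not references[gene]:
                raise ValueError(f"no reference sequences supplied for {gene!r}")
            for ref in references[gene]:
                h = align.best_hsp(genome.record.seq, ref)
                if (
                    h is not None
                    and align.hsp_identity(h) > identity_threshold
                    and h.aln_len >= min_reference_coverage * len(ref)
                ):
                    present[gene] = True
                    break
    return pd.Series(present, index=list(CORE_ORDER), dtype=bool)


def presence_matrix(
    genomes: Sequence[AnnotatedGenome],
    references: Mapping[str, Sequence[str]] | None = None,
    identity_threshold: float = 0.50,
) -> pd.DataFrame:
    """Boolean genomes x 16 core genes matrix (column order fixed)."""
    if not genomes:
        raise ValueError("presence_matrix needs at least one genome")
    rows = {
        g.id: core_presence(g, references, identity_threshold) for g in genomes
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(CORE_ORDER)]


def phylum_core_frequency(
    matrix: pd.DataFrame, phylum_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-phylum frequency of each core gene (column means by group)."""
    groups = pd.Series({gid: phylum_of.get(gid, "unknown") for gid in matrix.index})
    return matrix.groupby(groups).mean()


def share_missing_core(matrix: pd.DataFrame) -> float:
    """Fraction of genomes missing at least one of the 16 core genes."""
    return float((~matrix.all(axis=1)).mean())


# ---------------------------------------------------------------------------
# census


def category_census(genome: AnnotatedGenome) -> dict:
    """Counts and overlap-removed total lengths per category.

    A HEG nested inside an intron contributes to both categories (counts
    and lengths); lengths within one category are overlap-removed.
    """
    L = len(genome.record)
    topo = genome.record.topology
    census: dict = {"id": genome.id}
    for cat in CATEGORIES:
        feats = genome.features_in_category(cat)
        census[f"n_{cat}"] = len(feats)
        census[f"len_{cat}"] = canonicalize(feats, L, topo).covered_length
    for fam in HEG_FAMILIES:
        fam_key = fam.replace("-", "")
        census[f"n_HEG_{fam_key}"] = sum(
            1 for f in genome.features_in_category(HEG) if f.subtype == fam
        )
    census["n_features"] = len(genome.features)
    return census
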