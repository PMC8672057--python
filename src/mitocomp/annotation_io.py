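"""Sequence and annotation I/O for mitogenome datasets.

Genomes arrive as multi-record FASTA plus a per-genome feature table in
one of two dialects:

* a five-column tab-separated table with header
  ``name  start  end  size  strand`` (1-based inclusive coordinates, the
  GenBank/annotation-tool convention), or
* a GFF3 subset (seqid, source, type, start, end, score, strand, phase,
  attributes) where the feature label is taken from the ``Name``
  attribute (falling back to ``ID``, then the type column).

Both dialects encode an origin-spanning feature of a circular genome as a
single row with ``start > end``, meaning the feature runs ``start..L``
then ``1..end``.  Internally all interval arithmetic is done on 0-based
half-open segments (see :mod:`mitocomp.intervals`); the 1-based inclusive
coordinates are kept on the :class:`Feature` itself so files round-trip
bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .genetic_codes import SUPPORTED_CODES

CIRCULAR = "circular"
LINEAR = "linear"

# IUPAC nucleotide ambiguity codes collapsed to N on input (GC content and
# alignment treat them as unknowns).
_AMBIGUOUS = set("RYSWKMBDHV")
_VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One genome sequence with its topology and genetic code."""

    id: str
    seq: str
    topology: str = CIRCULAR
    genetic_code: int = 1
    phylum: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.topology not in (CIRCULAR, LINEAR):
            raise ValueError(f"record {self.id!r}: bad topology {self.topology!r}")
        if self.genetic_code not in SUPPORTED_CODES:
            raise ValueError(
                f"record {self.id!r}: unsupported genetic code {self.genetic_code!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_fraction(self) -> float:
        return self.seq.count("N") / len(self.seq)


@dataclass
class Feature:
    """One annotated element, in 1-based inclusive coordinates.

    ``wraps_origin`` is only legal on circular genomes and means the
    feature covers ``start..L`` followed by ``1..end``.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False
    category: str | None = None
    subtype: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"feature {self.name!r}: coordinates must be >= 1")
        if self.wraps_origin and self.start <= self.end:
            raise ValueError(
                f"feature {self.name!r}: wraps_origin requires start > end"
            )

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(
                f"feature {self.name!r} wraps the origin; genome length required"
            )
        return (genome_length - self.start + 1) + self.end

    def segments0(self, genome_length: int) -> list[tuple[int, int]]:
        """0-based half-open segments on the linearized axis."""
        if self.wraps_origin:
            return [(self.start - 1, genome_length), (0, self.end)]
        return [(self.start - 1, self.end)]

    def validate(self, genome_length: int, topology: str) -> None:
        if self.start > genome_length or self.end > genome_length:
            raise ValueError(
                f"feature {self.name!r}: coordinates ({self.start}, {self.end}) "
                f"exceed genome length {genome_length}"
            )
        if self.start > self.end and not self.wraps_origin:
            raise ValueError(
                f"feature {self.name!r}: start > end without origin wrap"
            )
        if self.wraps_origin and topology != CIRCULAR:
            raise ValueError(
                f"feature {self.name!r}: origin wrap on a {topology} genome"
            )


@dataclass
class AnnotatedGenome:
    """A sequence record bound to its (possibly empty) feature list."""

    record: SequenceRecord
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            f.validate(len(self.record), self.record.topology)

    @property
    def id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record)

    def features_in_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(record_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    out = []
    for pos, base in enumerate(seq, start=1):
        if base in _VALID_BASES:
            out.append(base)
        elif base in _AMBIGUOUS:
            out.append("N")
        else:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {base!r} at position {pos}"
            )
    return "".join(out)


def read_fasta(
    path: str | Path,
    metadata: Mapping[str, Mapping] | pd.DataFrame | None = None,
    default_topology: str = CIRCULAR,
    default_code: int = 1,
) -> list[SequenceRecord]:
    """Read a multi-record FASTA into :class:`SequenceRecord` objects.

    ``metadata`` (optional) supplies per-id topology / genetic_code /
    phylum, either as a mapping keyed by id or as the dataframe returned
    by :func:`read_metadata`.
    """
    if isinstance(metadata, pd.DataFrame):
        metadata = metadata.set_index("id").to_dict("index") if "id" in metadata else metadata.to_dict("index")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        meta = dict(metadata.get(rec.id, {})) if metadata else {}
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=_clean_sequence(rec.id, str(rec.seq)),
                topology=meta.get("topology", default_topology),
                genetic_code=int(meta.get("genetic_code", default_code)),
                phylum=meta.get("phylum"),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# metadata TSV (id, topology, genetic_code, phylum)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "topology", "genetic_code"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    if "phylum" not in df.columns:
        df["phylum"] = "unknown"
    return df


def write_metadata(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "topology": r.topology,
            "genetic_code": r.genetic_code,
            "phylum": r.phylum if r.phylum is not None else "unknown",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature tables

TSV_HEADER = ["name", "start", "end", "size", "strand"]


def _looks_like_gff3(first_line: str) -> bool:
    return first_line.startswith("##gff-version")


def _parse_gff_attributes(raw: str) -> dict:
    attrs = {}
    for part in raw.strip().split(";"):
        if not part or part == ".":
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _make_feature(
    name: str,
    start: int,
    end: int,
    strand: str,
    genome_length: int,
    topology: str,
    row_label: str,
    size: int | None = None,
    attributes: dict | None = None,
) -> Feature:
    if not (1 <= start <= genome_length and 1 <= end <= genome_length):
        raise ValueError(
            f"{row_label}: coordinates ({start}, {end}) outside genome "
            f"of length {genome_length}"
        )
    wraps = start > end
    if wraps and topology != CIRCULAR:
        raise ValueError(
            f"{row_label}: start > end is only valid on a circular genome"
        )
    feat = Feature(
        name=name,
        start=start,
        end=end,
        strand=strand,
        wraps_origin=wraps,
        attributes=attributes or {},
    )
    if size is not None and size != feat.length(genome_length):
        raise ValueError(
            f"{row_label}: size column {size} inconsistent with coordinates "
            f"(computed {feat.length(genome_length)})"
        )
    return feat


def read_feature_table(
    path: str | Path, genome_length: int, topology: str = CIRCULAR
) -> list[Feature]:
    """Read a feature table, auto-detecting the TSV vs GFF3 dialect."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    if _looks_like_gff3(lines[0]):
        return _read_gff3_lines(lines, genome_length, topology)
    return _read_tsv_lines(lines, genome_length, topology, str(path))


def _read_tsv_lines(
    lines: list[str], genome_length: int, topology: str, label: str
) -> list[Feature]:
    rows = list(csv.reader(lines, delimiter="\t"))
    header = [c.strip() for c in rows[0]]
    if header != TSV_HEADER:
        raise ValueError(
            f"{label}: expected header {TSV_HEADER}, found {header}"
        )
    features = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != 5:
            raise ValueError(f"{label} row {i}: expected 5 columns, got {len(row)}")
        name, start_s, end_s, size_s, strand = (c.strip() for c in row)
        size = None if size_s in (".", "") else int(size_s)
        features.append(
            _make_feature(
                name,
                int(start_s),
                int(end_s),
                strand,
                genome_length,
                topology,
                row_label=f"{label} row {i} ({name!r})",
                size=size,
            )
        )
    return features


def _read_gff3_lines(
    lines: list[str], genome_length: int, topology: str
) -> list[Feature]:
    features = []
    for i, ln in enumerate(lines, start=1):
        if ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GFF3 line {i}: expected 9 columns, got {len(cols)}")
        seqid, source, ftype, start_s, end_s, score, strand, phase, attr_raw = cols
        attrs = _parse_gff_attributes(attr_raw)
        name = attrs.get("Name") or attrs.get("ID") or ftype
        feat = _make_feature(
            name,
            int(start_s),
            int(end_s),
            strand if strand in ("+", "-") else "+",
            genome_length,
            topology,
            row_label=f"GFF3 line {i} ({name!r})",
            attributes={
                "seqid": seqid,
                "source": source,
                "type": ftype,
                "score": score,
                "phase": phase,
                "raw_attributes": attr_raw,
            },
        )
        features.append(feat)
    return features


def write_feature_table(
    features: Sequence[Feature],
    path: str | Path,
    genome_length: int,
    dialect: str = "tsv",
    seqid: str = ".",
) -> None:
    """Write features back out in either dialect (lossless round-trip)."""
    if dialect == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(TSV_HEADER)
            for f in features:
                w.writerow([f.name, f.start, f.end, f.length(genome_length), f.strand])
    elif dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in features:
                a = f.attributes
                raw = a.get("raw_attributes", f"Name={f.name}")
                fh.write(
                    "\t".join(
                        [
                            a.get("seqid", seqid),
                            a.get("source", "mitocomp"),
                            a.get("type", "region"),
                            str(f.start),
                            str(f.end),
                            a.get("score", "."),
                            f.strand,
                            a.get("phase", "."),
                            raw,
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# per-sequence metrics


def gc_content(seq: str) -> float:
    """GC fraction over non-N bases (N excluded from the denominator)."""
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    s = seq.upper()
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("gc_content undefined: sequence is all N")
    return (s.count("G") + s.count("C")) / denom
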