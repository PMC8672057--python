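"""NCBI translation tables used by fungal mitochondria.

Only four code tables are needed for this kingdom-wide setting:

* code 1  — the standard code,
* code 3  — the yeast mitochondrial code (``ATA``->Met, ``CTN``->Thr,
  ``TGA``->Trp),
* code 4  — the mold/protozoan/coelenterate mitochondrial code
  (``TGA``->Trp),
* code 16 — the chlorophycean mitochondrial code (``TAG``->Leu).

The tables are embedded verbatim (64-codon AA strings in the canonical
NCBI ``TCAG`` codon order) rather than looked up at run time, so that the
mapping in force is explicit and auditable.
"""

from __future__ import annotations

_BASES = "TCAG"
CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

# 64-character amino-acid strings, one per supported NCBI table id, in
# TTT, TTC, TTA, TTG, TCT, ... order ("*" marks a stop codon).
_AA_STRINGS = {
    1: "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    3: "FFLLSSSSYY**CCWWTTTTPPPPHHQQRRRRIIMMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    4: "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    16: "FFLLSSSSYY*LCC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
}

SUPPORTED_CODES = tuple(sorted(_AA_STRINGS))

CODON_TABLES: dict[int, dict[str, str]] = {
    code: dict(zip(CODONS, aas)) for code, aas in _AA_STRINGS.items()
}

STOP_CODONS: dict[int, frozenset[str]] = {
    code: frozenset(c for c, aa in table.items() if aa == "*")
    for code, table in CODON_TABLES.items()
}


def translate(seq: str, code_id: int = 1, frame_offset: int = 0) -> str:
    """Translate a DNA string codon-by-codon under an NCBI code table.

    Parameters
    ----------
    seq:
        DNA string (case-insensitive; ``U`` accepted as ``T``).
    code_id:
        NCBI translation table id; one of 1, 3, 4, 16.
    frame_offset:
        0, 1 or 2 — number of leading bases skipped before the first codon.

    Internal stop codons are rendered as ``"*"``; a trailing partial codon
    is dropped; codons containing ``N`` or other ambiguity codes yield
    ``"X"``.
    """
    if code_id not in CODON_TABLES:
        raise ValueError(
            f"unsupported genetic code {code_id!r}; supported: {SUPPORTED_CODES}"
        )
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    table = CODON_TABLES[code_id]
    s = seq.upper().replace("U", "T")
    out = []
    for i in range(frame_offset, len(s) - 2, 3):
        out.append(table.get(s[i : i + 3], "X"))
    return "".join(out)
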