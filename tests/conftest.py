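"""Shared fixtures and independent oracles.

The oracles deliberately avoid the implementation's code paths: interval
accounting is checked against per-base boolean arrays, alignment scores
against scikit-bio's C Smith-Waterman (a separate engine from the
Biopython one the package delegates to), and rank-sum p-values against
direct enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitocomp.annotation_io import CIRCULAR, Feature


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# per-base interval oracle


def coverage_mask(features, genome_length: int) -> np.ndarray:
    """Boolean per-base coverage by marking every covered position."""
    mask = np.zeros(genome_length, dtype=bool)
    for f in features:
        for s0, e0 in f.segments0(genome_length):
            mask[s0:e0] = True
    return mask


def feature_mask(f: Feature, genome_length: int) -> np.ndarray:
    mask = np.zeros(genome_length, dtype=bool)
    for s0, e0 in f.segments0(genome_length):
        mask[s0:e0] = True
    return mask


def random_features(
    rng: np.random.Generator,
    genome_length: int,
    n: int,
    topology: str = CIRCULAR,
    prefix: str = "f",
) -> list[Feature]:
    """Random features, including origin-wrapping ones on circular genomes."""
    feats = []
    for k in range(n):
        start = int(rng.integers(1, genome_length + 1))
        length = int(rng.integers(1, max(2, genome_length // 3)))
        end0 = start - 1 + length
        if end0 <= genome_length:
            feats.append(Feature(f"{prefix}{k}", start, end0))
        elif topology == CIRCULAR:
            feats.append(
                Feature(
                    f"{prefix}{k}", start, end0 - genome_length, wraps_origin=True
                )
            )
        else:
            feats.append(Feature(f"{prefix}{k}", start, genome_length))
    return feats


# ---------------------------------------------------------------------------
# Smith-Waterman oracle (independent engine)


def sw_oracle_score(a: str, b: str) -> float:
    """Optimal local affine-gap score under the default scoring scheme
    (match +1, mismatch -2, gap of length L costs 5 + 2L), computed by
    scikit-bio — an engine independent of the one the package uses."""
    from skbio.alignment import pair_align

    res = pair_align(
        a, b, mode="local", sub_score=(1.0, -2.0), gap_cost=(5.0, 2.0),
        max_paths=1,
    )
    return float(res.score)
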