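"""Deterministic synthetic data so every selection path is testable offline.

Two generators: a fixed 3-gene x 4-tissue demonstration matrix whose
three textbook slider selections each pick exactly one gene, and a
Dirichlet-based generator that plants features with a guaranteed minimum
contribution in a chosen facet against a tunable background.  Background
contribution vectors are symmetric-Dirichlet(alpha) draws — alpha = 1 is
uniform on the simplex, large alpha concentrates every feature near the
uninformative 100/K-per-facet profile.  Contribution rows are scaled by
a log-uniform sequencing depth so the raw matrices resemble tag counts
while the underlying percentages stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .errors import ValidationError
from .genomic import GenomicFeature, SNPRecord

#: fixed default seed for reproducible fixtures
DEFAULT_SEED = 1734

FIG_TISSUES = ("blood", "brain", "heart", "liver")


def make_fig1_fixture() -> ExpressionMatrix:
    """The fixed 3-gene demonstration matrix (TPM over four tissues).

    g1 is brain-dominant (85%), g2 splits evenly between blood and heart
    (40% each), g3 is liver-dominant (60%) with zero brain expression —
    so a [80,100] brain slider selects only g1, joint [30,45] blood and
    heart sliders select only g2, and brain [0,0] with liver [50,100]
    selects only g3.
    """
    values = pd.DataFrame(
        [[5.0, 85.0, 5.0, 5.0],
         [40.0, 10.0, 40.0, 10.0],
         [20.0, 0.0, 20.0, 60.0]],
        index=["g1", "g2", "g3"],
        columns=list(FIG_TISSUES),
    )
    return ExpressionMatrix(values, unit="TPM")


@dataclass(frozen=True)
class PlantedGroup:
    """feature_count features forced to >= min_contribution_pct in facet_id."""

    feature_count: int
    facet_id: str
    min_contribution_pct: float

    def __post_init__(self):
        if not (0.0 < self.min_contribution_pct <= 100.0):
            raise ValidationError(
                f"planted contribution must be in (0, 100], got "
                f"{self.min_contribution_pct}"
            )
        if self.feature_count < 0:
            raise ValidationError("planted feature_count must be >= 0")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic expression matrix with planted specificity."""

    n_features: int
    facets: tuple[str, ...]
    planted: tuple[PlantedGroup, ...] = ()
    noise_concentration: float = 1.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_features < 0:
            raise ValidationError("n_features must be >= 0")
        if self.noise_concentration <= 0:
            raise ValidationError("noise_concentration must be positive")
        if not self.facets:
            raise ValidationError("at least one facet required")
        for p in self.planted:
            if p.facet_id not in self.facets:
                raise ValidationError(f"planted facet {p.facet_id!r} not in facets")
        if sum(p.feature_count for p in self.planted) > self.n_features:
            raise ValidationError("planted feature counts exceed n_features")


def simulate_matrix(spec: FixtureSpec) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Draw a synthetic matrix; returns (matrix, planted_truth).

    ``planted_truth`` maps each planted feature id to its designated
    facet.  Planted rows put p ~ Uniform[min_pct, 100] percent in that
    facet and spread the remainder as a Dirichlet draw over the other
    facets; background rows are symmetric Dirichlet draws.  Rows are
    multiplied by a log-uniform depth in [10, 1e4] to produce raw
    "expression"; the same seed reproduces the matrix exactly.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.facets)
    pct = np.empty((spec.n_features, k))
    truth: dict[str, str] = {}
    ids = [f"f{i+1:05d}" for i in range(spec.n_features)]
    row = 0
    for group in spec.planted:
        j = spec.facets.index(group.facet_id)
        for _ in range(group.feature_count):
            target = rng.uniform(group.min_contribution_pct, 100.0)
            rest = rng.dirichlet(np.full(k - 1, spec.noise_concentration)) if k > 1 else np.array([])
            v = np.empty(k)
            v[j] = target
            others = [i for i in range(k) if i != j]
            v[others] = rest * (100.0 - target)
            pct[row] = v
            truth[ids[row]] = group.facet_id
            row += 1
    n_bg = spec.n_features - row
    if n_bg:
        pct[row:] = 100.0 * rng.dirichlet(
            np.full(k, spec.noise_concentration), size=n_bg
        )
    depth = 10.0 ** rng.uniform(1.0, 4.0, size=spec.n_features)
    raw = pct / 100.0 * depth[:, None]
    matrix = ExpressionMatrix(
        pd.DataFrame(raw, index=ids, columns=list(spec.facets)), unit="TPM"
    )
    return matrix, truth


def simulate_genomic(
    n_features: int,
    n_snps: int,
    chrom_length: int,
    seed: int = DEFAULT_SEED,
    chrom: str = "chrS",
) -> tuple[list[GenomicFeature], list[SNPRecord]]:
    """Uniform random intervals and SNP positions on one synthetic chromosome.

    Intervals are non-degenerate (length >= 1) and lie inside
    [0, chrom_length); deterministic under the seed.
    """
    if n_features < 0 or n_snps < 0 or chrom_length < 2:
        raise ValidationError("need non-negative sizes and chrom_length >= 2")
    rng = np.random.default_rng(seed)
    features = []
    for i in range(n_features):
        start = int(rng.integers(0, chrom_length - 1))
        length = int(rng.integers(1, max(2, min(2000, chrom_length - start))))
        features.append(
            GenomicFeature(f"e{i+1:04d}", chrom, start, start + length,
                           strand=rng.choice(["+", "-"]))
        )
    snps = [
        SNPRecord(f"rs{i+1:06d}", chrom, int(rng.integers(0, chrom_length)))
        for i in range(n_snps)
    ]
    return features, snps
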