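"""Expression data model and percentage-contribution normalization.

The engine never selects on absolute expression.  Raw evidence (CAGE tags
per million, RPKM, microarray intensity...) is first aggregated from
individual libraries to *facets* — named groups of samples of the same
cell type or tissue — and then each feature's row is rescaled to
percentages summing to 100 across the facets of one panel.  Those
percentage contributions are the only quantity the slider constraints
ever see, which makes selections comparable across features with very
different absolute expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MappingError, ValidationError

#: absolute tolerance for all percentage comparisons after normalization
PCT_TOL = 1e-9


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative feature x sample expression values with a unit label.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns.  Construction validates the container invariants: unique
    ids, no missing entries, no negative values.
    """

    values: pd.DataFrame
    unit: str = "arbitrary"

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value {arr[i, j]} at feature {v.index[i]!r}, "
                f"sample {v.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FacetMap:
    """Assignment of samples to facets for one slider panel.

    ``facet_order`` fixes the column order of the aggregated matrix; it
    defaults to first appearance order of the facets in ``mapping``.
    """

    panel_name: str
    mapping: Mapping[str, str]
    facet_order: tuple[str, ...] = ()

    def __post_init__(self):
        order = self.facet_order or tuple(dict.fromkeys(self.mapping.values()))
        object.__setattr__(self, "facet_order", tuple(order))
        seen = set(self.mapping.values())
        for facet in self.facet_order:
            if facet not in seen:
                raise ConfigurationError(
                    f"facet {facet!r} in facet_order has no member samples"
                )
        extra = seen - set(self.facet_order)
        if extra:
            raise ConfigurationError(
                f"facets {sorted(extra)} mapped but missing from facet_order"
            )

    @classmethod
    def identity(cls, sample_ids: Iterable[str], panel_name: str = "samples") -> "FacetMap":
        """Each sample is its own facet (sliders act on raw samples)."""
        ids = list(sample_ids)
        return cls(panel_name, {s: s for s in ids}, tuple(ids))

    def samples_of(self, facet_id: str) -> list[str]:
        return [s for s, f in self.mapping.items() if f == facet_id]


@dataclass(frozen=True)
class ContributionMatrix:
    """Per-feature percentage contributions over the facets of one panel.

    Rows with ``defined_mask`` True sum to 100 within :data:`PCT_TOL`.
    A feature whose total expression over the panel is zero carries no
    evidence; its row is stored as all zeros with ``defined_mask`` False
    and it is excluded from any selection that actually constrains a
    facet.
    """

    percentages: pd.DataFrame
    defined_mask: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.defined_mask is None:
            object.__setattr__(
                self,
                "defined_mask",
                pd.Series(True, index=self.percentages.index),
            )
        sums = self.percentages.to_numpy(dtype=float).sum(axis=1)
        defined = self.defined_mask.to_numpy(dtype=bool)
        bad = defined & (np.abs(sums - 100.0) > PCT_TOL)
        if bad.any():
            fid = self.percentages.index[np.argwhere(bad)[0][0]]
            raise ValidationError(
                f"contributions of feature {fid!r} sum to "
                f"{sums[np.argwhere(bad)[0][0]]!r}, expected 100"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.percentages.index)

    @property
    def facet_ids(self) -> list[str]:
        return list(self.percentages.columns)


def aggregate_facets(
    matrix: ExpressionMatrix,
    facets: FacetMap,
    method: Literal["sum", "mean"] = "sum",
) -> ExpressionMatrix:
    """Collapse sample columns to facet columns by sum (default) or mean.

    Sum preserves total tag counts, which keeps contribution percentages
    insensitive to how many libraries a facet happens to be split into.
    """
    if method not in ("sum", "mean"):
        raise ConfigurationError(f"unknown aggregation method {method!r}")
    unknown = [s for s in facets.mapping if s not in matrix.values.columns]
    if unknown:
        raise MappingError(
            f"facet map refers to unknown sample {unknown[0]!r} "
            f"(panel {facets.panel_name!r})"
        )
    cols = {}
    for facet in facets.facet_order:
        members = facets.samples_of(facet)
        if not members:
            raise ConfigurationError(f"facet {facet!r} has no member samples")
        block = matrix.values[members]
        cols[facet] = block.sum(axis=1) if method == "sum" else block.mean(axis=1)
    out = pd.DataFrame(cols, index=matrix.values.index)
    return ExpressionMatrix(out, unit=matrix.unit)


def normalize_contributions(matrix: ExpressionMatrix) -> ContributionMatrix:
    """Rescale each feature's row to percentages summing to 100.

    p_ij = 100 * x_ij / sum_j x_ij.  Zero-sum rows are undefined: stored
    as all zeros with the defined flag cleared.
    """
    arr = matrix.values.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    defined = totals > 0
    pct = np.zeros_like(arr)
    pct[defined] = 100.0 * arr[defined] / totals[defined, None]
    return ContributionMatrix(
        pd.DataFrame(pct, index=matrix.values.index, columns=matrix.values.columns),
        pd.Series(defined, index=matrix.values.index),
    )


@dataclass(frozen=True)
class Finding:
    """One machine-readable validation finding (reporting only)."""

    kind: str
    subject: str
    detail: str = ""


def validate_matrix(values: pd.DataFrame | ExpressionMatrix) -> list[Finding]:
    """Report problems in an expression table without modifying it.

    Accepts a raw DataFrame (pre-construction, so invalid content can be
    inspected) or an already-validated :class:`ExpressionMatrix`.
    Returns an empty list for a clean matrix.
    """
    v = values.values if isinstance(values, ExpressionMatrix) else values
    findings: list[Finding] = []
    for fid in v.index[v.index.duplicated()].unique():
        findings.append(Finding("duplicate id", str(fid), "feature id occurs twice"))
    for sid in v.columns[v.columns.duplicated()].unique():
        findings.append(Finding("duplicate id", str(sid), "sample id occurs twice"))
    arr = v.to_numpy(dtype=float)
    for i, j in np.argwhere(np.isnan(arr)):
        findings.append(
            Finding("missing value", str(v.index[i]), f"sample {v.columns[j]!r}")
        )
    with np.errstate(invalid="ignore"):
        for i, j in np.argwhere(arr < 0):
            findings.append(
                Finding(
                    "negative value",
                    str(v.index[i]),
                    f"value {arr[i, j]} in sample {v.columns[j]!r}",
                )
            )
    row_sums = np.nansum(arr, axis=1)
    for i in np.flatnonzero(row_sums == 0):
        findings.append(Finding("zero-sum feature", str(v.index[i])))
    col_sums = np.nansum(arr, axis=0)
    for j in np.flatnonzero(col_sums == 0):
        findings.append(Finding("zero-sum sample", str(v.columns[j])))
    return findings
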