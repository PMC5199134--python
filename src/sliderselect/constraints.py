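"""Slider constraints, panel logic and ordinal protein-level selection.

A *slider* is a closed percentage interval ``[min_pct, max_pct]`` on one
facet's contribution; ``[0, 100]`` is the default (no constraint).
Constraints within a panel combine conjunctively.  Panels (e.g. one for
primary cells, one for tissues) can be disabled, and enabled panels are
combined with AND (intersection) or OR (union), mirroring how slider
sets are used independently or jointly.

Protein abundance from immunohistochemical staining is ordinal, not a
percentage: the four-step scale None < Low < Medium < High gets its own
interval constraint type, and :func:`select_dual` conjoins RNA
percentage constraints with protein ordinal constraints over a shared
gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PCT_TOL, ContributionMatrix
from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger(__name__)

#: the ordered immunohistochemistry staining scale
ORDINAL_LEVELS = ("None", "Low", "Medium", "High")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(ORDINAL_LEVELS)}


@dataclass(frozen=True)
class SliderConstraint:
    """Closed interval [min_pct, max_pct] on one facet's contribution."""

    facet_id: str
    min_pct: float = 0.0
    max_pct: float = 100.0

    def __post_init__(self):
        if not (0.0 <= self.min_pct <= self.max_pct <= 100.0):
            raise ConfigurationError(
                f"invalid slider interval [{self.min_pct}, {self.max_pct}] "
                f"for facet {self.facet_id!r} (need 0 <= min <= max <= 100)"
            )

    @property
    def is_default(self) -> bool:
        return self.min_pct == 0.0 and self.max_pct == 100.0


@dataclass(frozen=True)
class ConstraintPanel:
    """One panel of sliders, keyed by facet; may be disabled entirely."""

    panel_name: str
    constraints: tuple[SliderConstraint, ...] = ()
    enabled: bool = True

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.constraints:
            if c.facet_id in seen:
                raise ConfigurationError(
                    f"panel {self.panel_name!r}: duplicate constraint on "
                    f"facet {c.facet_id!r}"
                )
            seen.add(c.facet_id)

    @classmethod
    def from_dict(
        cls,
        panel_name: str,
        intervals: Mapping[str, Sequence[float]],
        enabled: bool = True,
    ) -> "ConstraintPanel":
        """Build from ``{facet: (min_pct, max_pct)}``."""
        cons = tuple(
            SliderConstraint(f, float(lo), float(hi)) for f, (lo, hi) in intervals.items()
        )
        return cls(panel_name, cons, enabled)

    @property
    def active_constraints(self) -> tuple[SliderConstraint, ...]:
        return tuple(c for c in self.constraints if not c.is_default)


@dataclass(frozen=True)
class ConstraintSet:
    """Ordered panels plus the AND/OR combiner applied across enabled panels."""

    panels: tuple[ConstraintPanel, ...] = ()
    combiner: str = "AND"

    def __post_init__(self):
        if self.combiner not in ("AND", "OR"):
            raise ConfigurationError(f"combiner must be AND or OR, got {self.combiner!r}")
        names = [p.panel_name for p in self.panels]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate panel names in constraint set")

    @property
    def enabled_panels(self) -> tuple[ConstraintPanel, ...]:
        return tuple(p for p in self.panels if p.enabled)


@dataclass(frozen=True)
class OrdinalConstraint:
    """Closed interval on the None < Low < Medium < High staining scale."""

    facet_id: str
    min_level: str = "None"
    max_level: str = "High"

    def __post_init__(self):
        for lvl in (self.min_level, self.max_level):
            if lvl not in _LEVEL_RANK:
                raise FormatError(
                    f"unknown protein level {lvl!r}; expected one of {ORDINAL_LEVELS}"
                )
        if _LEVEL_RANK[self.min_level] > _LEVEL_RANK[self.max_level]:
            raise ConfigurationError(
                f"ordinal interval [{self.min_level}, {self.max_level}] is empty "
                f"for facet {self.facet_id!r}"
            )


@dataclass(frozen=True)
class SelectionResult:
    """Identifier set surviving all constraints, in input feature order."""

    selected_ids: tuple[str, ...]
    constraint_snapshot: object = None

    @property
    def count(self) -> int:
        return len(self.selected_ids)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in set(self.selected_ids)


# ---------------------------------------------------------------------------
# panel evaluation


def _panel_mask(contrib: ContributionMatrix, panel: ConstraintPanel) -> np.ndarray:
    """Boolean keep-mask over contrib's features for one panel."""
    n = len(contrib.percentages.index)
    if not panel.enabled:
        return np.ones(n, dtype=bool)
    active = panel.active_constraints
    for c in panel.constraints:
        if c.facet_id not in contrib.percentages.columns:
            raise ConfigurationError(
                f"panel {panel.panel_name!r}: constraint on unknown facet "
                f"{c.facet_id!r}"
            )
    if not active:
        # vacuous constraints select everything, including zero-sum features
        return np.ones(n, dtype=bool)
    mask = contrib.defined_mask.to_numpy(dtype=bool).copy()
    for c in active:
        p = contrib.percentages[c.facet_id].to_numpy(dtype=float)
        mask &= (p >= c.min_pct - PCT_TOL) & (p <= c.max_pct + PCT_TOL)
    return mask


def apply_panel(contrib: ContributionMatrix, panel: ConstraintPanel) -> SelectionResult:
    """Select the features whose contributions satisfy every slider of one panel.

    A feature with undefined contributions (zero total expression) is
    selected only when the panel imposes no actual constraint.
    """
    mask = _panel_mask(contrib, panel)
    ids = tuple(np.asarray(contrib.percentages.index, dtype=object)[mask])
    return SelectionResult(ids, panel)


def _common_universe(
    contrib_by_panel: Mapping[str, ContributionMatrix],
    panels: Sequence[ConstraintPanel],
    universe_mismatch: str,
) -> list[str]:
    """Feature ids shared by the required matrices, in first-panel order."""
    universes = []
    for p in panels:
        if p.panel_name not in contrib_by_panel:
            raise ConfigurationError(
                f"no contribution matrix supplied for enabled panel {p.panel_name!r}"
            )
        universes.append(list(contrib_by_panel[p.panel_name].percentages.index))
    first = universes[0]
    shared = set(first)
    union: set[str] = set()
    for u in universes:
        shared &= set(u)
        union |= set(u)
    if shared != union:
        diff = len(union - shared)
        if universe_mismatch == "error":
            raise DataError(
                f"feature universes differ between panels "
                f"(symmetric difference: {diff} features)"
            )
        logger.warning(
            "feature universes differ between panels; selecting on the "
            "intersection (%d features dropped)", diff,
        )
    return [f for f in first if f in shared]


def select(
    contrib_by_panel: Mapping[str, ContributionMatrix],
    cset: ConstraintSet,
    universe_mismatch: str = "intersect",
) -> SelectionResult:
    """Evaluate a full constraint set across its panels.

    AND intersects the per-panel selections, OR unions them; with zero
    enabled panels every feature is selected.  The result preserves
    input feature order.  When panels disagree on the feature universe
    the intersection is used with a warning, or a :class:`DataError` is
    raised with ``universe_mismatch="error"``.
    """
    enabled = cset.enabled_panels
    if not enabled:
        # no restriction at all: every feature of every supplied matrix
        ids: list[str] = []
        seen: set[str] = set()
        for cm in contrib_by_panel.values():
            for f in cm.percentages.index:
                if f not in seen:
                    seen.add(f)
                    ids.append(f)
        return SelectionResult(tuple(ids), cset)

    universe = _common_universe(contrib_by_panel, enabled, universe_mismatch)
    combined: np.ndarray | None = None
    for p in enabled:
        cm = contrib_by_panel[p.panel_name]
        mask_full = _panel_mask(cm, p)
        kept = {f for f, m in zip(cm.percentages.index, mask_full) if m}
        mask = np.fromiter((f in kept for f in universe), dtype=bool, count=len(universe))
        if combined is None:
            combined = mask
        elif cset.combiner == "AND":
            combined &= mask
        else:
            combined |= mask
    assert combined is not None
    return SelectionResult(tuple(f for f, m in zip(universe, combined) if m), cset)


def count_selected(
    contrib_by_panel: Mapping[str, ContributionMatrix],
    cset: ConstraintSet,
    universe_mismatch: str = "intersect",
) -> int:
    """Number of features the constraint set selects (the live count)."""
    return select(contrib_by_panel, cset, universe_mismatch).count


class ContributionIndex:
    """Per-facet sorted contribution arrays for fast repeated counting.

    One O(F·K log F) preprocessing pass; afterwards a single-slider
    count is two binary searches.  Intended for sweep scripts that
    emulate interactive slider movement with many count queries.
    Counts agree exactly with :func:`count_selected`.
    """

    def __init__(self, contrib: ContributionMatrix):
        self._contrib = contrib
        self._n = len(contrib.percentages.index)
        defined = contrib.defined_mask.to_numpy(dtype=bool)
        self._n_undefined = int((~defined).sum())
        self._sorted = {
            facet: np.sort(contrib.percentages[facet].to_numpy(dtype=float)[defined])
            for facet in contrib.percentages.columns
        }

    def count_single(self, constraint: SliderConstraint) -> int:
        """Count features satisfying one slider (all other sliders default)."""
        if constraint.facet_id not in self._sorted:
            raise ConfigurationError(f"unknown facet {constraint.facet_id!r}")
        if constraint.is_default:
            return self._n
        arr = self._sorted[constraint.facet_id]
        lo = np.searchsorted(arr, constraint.min_pct - PCT_TOL, side="left")
        hi = np.searchsorted(arr, constraint.max_pct + PCT_TOL, side="right")
        return int(hi - lo)

    def count_panel(self, panel: ConstraintPanel) -> int:
        """Count for a whole panel (falls back to a vectorized scan)."""
        active = panel.active_constraints
        if panel.enabled and len(active) == 1:
            for c in panel.constraints:  # still validate all named facets
                if c.facet_id not in self._sorted:
                    raise ConfigurationError(f"unknown facet {c.facet_id!r}")
            return self.count_single(active[0])
        return int(_panel_mask(self._contrib, panel).sum())


# ---------------------------------------------------------------------------
# ordinal (protein) selection


def _level_ranks(levels: pd.DataFrame) -> pd.DataFrame:
    """Map a gene x tissue table of level labels to integer ranks (NaN = missing)."""
    def rank(x):
        if pd.isna(x):
            return np.nan
        try:
            return float(_LEVEL_RANK[x])
        except KeyError:
            raise FormatError(
                f"unknown protein level {x!r}; expected one of {ORDINAL_LEVELS}"
            ) from None

    return levels.map(rank)


def apply_ordinal(
    levels: pd.DataFrame,
    constraints: Iterable[OrdinalConstraint],
) -> SelectionResult:
    """Select genes whose staining level falls in every ordinal interval.

    ``levels`` is a gene x tissue table of labels from
    :data:`ORDINAL_LEVELS`; missing entries (``NA``) fail any constraint
    on that tissue — absence of staining evidence must not satisfy an
    evidence requirement.
    """
    constraints = tuple(constraints)
    for c in constraints:
        if c.facet_id not in levels.columns:
            raise ConfigurationError(
                f"ordinal constraint on unknown tissue {c.facet_id!r}"
            )
    ranks = _level_ranks(levels)
    mask = np.ones(len(levels.index), dtype=bool)
    for c in constraints:
        r = ranks[c.facet_id].to_numpy(dtype=float)
        ok = (r >= _LEVEL_RANK[c.min_level]) & (r <= _LEVEL_RANK[c.max_level])
        ok &= ~np.isnan(r)
        mask &= ok
    return SelectionResult(
        tuple(np.asarray(levels.index, dtype=object)[mask]), constraints
    )


def select_dual(
    rna_contrib: ContributionMatrix,
    rna_cset: ConstraintSet,
    protein_levels: pd.DataFrame,
    protein_constraints: Iterable[OrdinalConstraint],
) -> SelectionResult:
    """Simultaneous RNA percentage and protein ordinal constraints.

    RNA and protein tables usually cover different gene universes; the
    conjunction is evaluated on their intersection, and an empty
    intersection is a :class:`DataError`.
    """
    rna_ids = list(rna_contrib.percentages.index)
    shared = set(rna_ids) & set(protein_levels.index)
    if not shared:
        raise DataError("RNA and protein tables share no gene identifiers")
    panel_name = rna_cset.panels[0].panel_name if rna_cset.panels else "rna"
    rna_sel = select({p.panel_name: rna_contrib for p in rna_cset.panels} or
                     {panel_name: rna_contrib}, rna_cset)
    prot_sel = apply_ordinal(protein_levels, protein_constraints)
    keep = set(rna_sel.selected_ids) & set(prot_sel.selected_ids) & shared
    ordered = tuple(f for f in rna_ids if f in keep)
    return SelectionResult(ordered, (rna_cset, tuple(protein_constraints)))


# ---------------------------------------------------------------------------
# JSON-config (de)serialization — defaults omitted


def constraint_set_to_config(cset: ConstraintSet) -> dict:
    """Round-trippable plain-dict form of a constraint set."""
    panels = {}
    for p in cset.panels:
        entry: dict = {}
        if not p.enabled:
            entry["enabled"] = False
        cons = {
            c.facet_id: [c.min_pct, c.max_pct] for c in p.constraints if not c.is_default
        }
        if cons:
            entry["constraints"] = cons
        panels[p.panel_name] = entry
    out: dict = {"panels": panels}
    if cset.combiner != "AND":
        out["combiner"] = cset.combiner
    return out


def constraint_set_from_config(config: Mapping) -> ConstraintSet:
    """Inverse of :func:`constraint_set_to_config`; validates as it builds."""
    panels = []
    for name, entry in config.get("panels", {}).items():
        if not isinstance(entry, Mapping):
            raise ConfigurationError(f"panel {name!r}: expected an object")
        intervals = entry.get("constraints", {})
        cons = []
        for facet, pair in intervals.items():
            if not isinstance(pair, Sequence) or len(pair) != 2:
                raise ConfigurationError(
                    f"panel {name!r}, facet {facet!r}: constraint must be [min, max]"
                )
            cons.append(SliderConstraint(facet, float(pair[0]), float(pair[1])))
        panels.append(
            ConstraintPanel(name, tuple(cons), bool(entry.get("enabled", True)))
        )
    return ConstraintSet(tuple(panels), config.get("combiner", "AND"))
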