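"""Cytokine-to-transcription-factor imputation maps and activation matrices.

Each cytokine activates a *primary* factor always (IL-2 and IL-15 → STAT5,
IL-12 → STAT4, IL-18 → NF-κB, IL-21 → STAT3) and may activate a set of
*secondary* factors drawn from a cytokine-specific pool: IL-2 from
{STAT1, STAT3, STAT4, NF-κB}, IL-18 from {STAT3}, IL-21 from {STAT1};
IL-12 and IL-15 contribute their primary alone.  An *imputation map* fixes
one secondary choice per cytokine, giving 16 x 1 x 1 x 2 x 2 = 64 maps.

A map converts a treatment condition into a binary *activation row* of
length 10: the presence of STAT1, STAT3, STAT4, STAT5, NF-κB during priming
(columns 1-5) and during PP-I (columns 6-10), obtained as the union of the
activated sets over the cytokines present in that phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .study_data import FACTOR_ORDER, Cytokine, CytokineCondition, Factor

__all__ = [
    "PRIMARY_FACTOR",
    "SECONDARY_POOL",
    "ImputationMap",
    "enumerate_maps",
    "reference_optimal_map",
    "minimal_map",
    "activation_matrix",
    "ActivationMatrix",
]

PRIMARY_FACTOR: dict[Cytokine, Factor] = {
    Cytokine.IL2: Factor.STAT5,
    Cytokine.IL12: Factor.STAT4,
    Cytokine.IL15: Factor.STAT5,
    Cytokine.IL18: Factor.NFKB,
    Cytokine.IL21: Factor.STAT3,
}

#: Allowed secondary factors per cytokine; order fixes the enumeration.
SECONDARY_POOL: dict[Cytokine, tuple[Factor, ...]] = {
    Cytokine.IL2: (Factor.STAT1, Factor.STAT3, Factor.STAT4, Factor.NFKB),
    Cytokine.IL12: (),
    Cytokine.IL15: (),
    Cytokine.IL18: (Factor.STAT3,),
    Cytokine.IL21: (Factor.STAT1,),
}


@dataclass(frozen=True)
class ImputationMap:
    """One hypothesized cytokine → activated-factor assignment.

    ``map_index`` is a 1-based position in the canonical enumeration
    (lexicographic over the IL-2 secondary bitmask, then the IL-18 and IL-21
    secondary bits).  Indices are artifacts of this ordering; all reporting
    should key on ``content_signature``, which is index-independent.
    """

    activated: Mapping[Cytokine, frozenset[Factor]]
    map_index: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "activated", {Cytokine(c): frozenset(fs) for c, fs in self.activated.items()}
        )
        for cyt in Cytokine:
            fs = self.activated.get(cyt)
            if fs is None:
                raise ValueError(f"map missing cytokine {cyt.value}")
            if PRIMARY_FACTOR[cyt] not in fs:
                raise ValueError(f"{cyt.value}: primary factor {PRIMARY_FACTOR[cyt].value} must be present")
            extras = fs - {PRIMARY_FACTOR[cyt]} - set(SECONDARY_POOL[cyt])
            if extras:
                raise ValueError(
                    f"{cyt.value}: factors {sorted(f.value for f in extras)} outside the allowed secondary pool"
                )

    @property
    def content_signature(self) -> str:
        """Sorted textual encoding, independent of enumeration order."""
        parts = []
        for cyt in Cytokine:
            facs = "+".join(sorted(f.value for f in self.activated[cyt]))
            parts.append(f"{cyt.value}:{facs}")
        return ";".join(parts)

    def factors(self, cytokines: frozenset[Cytokine] | set[Cytokine]) -> frozenset[Factor]:
        """Union of activated factors over a cytokine cocktail."""
        out: set[Factor] = set()
        for c in cytokines:
            out |= self.activated[Cytokine(c)]
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "map_index": self.map_index,
            "signature": self.content_signature,
            "activated": {c.value: sorted(f.value for f in fs) for c, fs in self.activated.items()},
        }


def enumerate_maps() -> list[ImputationMap]:
    """All 64 imputation maps in canonical order (1-based indices).

    The order is lexicographic over (IL-2 secondary subset as a bitmask over
    (STAT1, STAT3, STAT4, NF-κB), IL-18 STAT3 bit, IL-21 STAT1 bit), with
    the empty subset first.
    """
    il2_pool = SECONDARY_POOL[Cytokine.IL2]
    il2_subsets = [
        frozenset(sub) for r in range(len(il2_pool) + 1) for sub in combinations(il2_pool, r)
    ]
    # combinations() over increasing r is not bitmask-lexicographic; sort by mask.
    il2_subsets.sort(key=lambda s: sum(1 << i for i, f in enumerate(il2_pool) if f in s))
    maps = []
    idx = 1
    for il2_sec in il2_subsets:
        for il18_sec in (frozenset(), frozenset({Factor.STAT3})):
            for il21_sec in (frozenset(), frozenset({Factor.STAT1})):
                activated = {
                    Cytokine.IL2: frozenset({Factor.STAT5}) | il2_sec,
                    Cytokine.IL12: frozenset({Factor.STAT4}),
                    Cytokine.IL15: frozenset({Factor.STAT5}),
                    Cytokine.IL18: frozenset({Factor.NFKB}) | il18_sec,
                    Cytokine.IL21: frozenset({Factor.STAT3}) | il21_sec,
                }
                maps.append(ImputationMap(activated, idx))
                idx += 1
    return maps


def minimal_map() -> ImputationMap:
    """The primaries-only map (every secondary set empty)."""
    return enumerate_maps()[0]


def reference_optimal_map() -> ImputationMap:
    """The map selected as optimal for the day-9 study data.

    IL-2 → {STAT5, STAT4, STAT1}, IL-12 → {STAT4}, IL-15 → {STAT5},
    IL-18 → {NF-κB, STAT3}, IL-21 → {STAT3, STAT1}.  Exposed by content
    rather than by enumeration index, since indices depend on the
    enumeration order.
    """
    target = {
        Cytokine.IL2: frozenset({Factor.STAT5, Factor.STAT4, Factor.STAT1}),
        Cytokine.IL12: frozenset({Factor.STAT4}),
        Cytokine.IL15: frozenset({Factor.STAT5}),
        Cytokine.IL18: frozenset({Factor.NFKB, Factor.STAT3}),
        Cytokine.IL21: frozenset({Factor.STAT3, Factor.STAT1}),
    }
    for m in enumerate_maps():
        if m.activated == target:
            return m
    raise AssertionError("reference map not found in enumeration")  # pragma: no cover


@dataclass(frozen=True)
class ActivationMatrix:
    """Binary conditions x 10 matrix of induced factors under one map.

    Columns are the canonical factor order in priming then in PP-I; labels
    use S1, S3, S4, S5, Sb with a trailing '~' for PP-I.
    """

    values: np.ndarray
    condition_ids: tuple[int, ...]
    column_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.condition_ids), columns=list(self.column_labels))

    def row(self, condition_id: int) -> np.ndarray:
        return self.values[self.condition_ids.index(condition_id)]


_SHORT = {Factor.STAT1: "S1", Factor.STAT3: "S3", Factor.STAT4: "S4", Factor.STAT5: "S5", Factor.NFKB: "Sb"}


def factor_label(factor: Factor, phase: str) -> str:
    """Column label for a factor in a phase ('priming' or 'pp1')."""
    suffix = "~" if phase == "pp1" else ""
    return _SHORT[Factor(factor)] + suffix


ACTIVATION_COLUMNS: tuple[str, ...] = tuple(
    factor_label(f, phase) for phase in ("priming", "pp1") for f in FACTOR_ORDER
)


def activation_matrix(imap: ImputationMap, conditions: Sequence[CytokineCondition]) -> ActivationMatrix:
    """Translate (map, conditions) into the binary activation matrix M.

    Entry (condition, factor, phase) is 1 iff the factor lies in the union
    of the map's activated sets over the cytokines present in that phase.
    """
    rows = []
    for cond in conditions:
        if not cond.priming or not cond.pp1:
            raise ValueError(f"condition {cond.condition_id} has an empty phase cocktail")
        row = []
        for phase_set in (cond.priming, cond.pp1):
            active = imap.factors(phase_set)
            row.extend(1 if f in active else 0 for f in FACTOR_ORDER)
        rows.append(row)
    return ActivationMatrix(
        values=np.asarray(rows, dtype=int),
        condition_ids=tuple(c.condition_id for c in conditions),
        column_labels=ACTIVATION_COLUMNS,
    )
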