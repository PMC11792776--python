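"""Data model and I/O for NK-cell fold-expansion studies.

The experimental design this package models: purified NK cells from a panel
of donors are cultured under numbered cytokine-cocktail *conditions*.  Each
condition is a regimen with a 16-hour *priming* cocktail, a *post-priming I*
(PP-I, 16 h to day 3) cocktail and a *post-priming II* maintenance cocktail
(day 3 onward; never enters the regression).  Cell counts are taken on a
fixed day grid and expressed as *fold expansion* relative to day 0.

Donors are partitioned into groups that saw different condition subsets
(group A: conditions 1-6, group B: 7-8, group C: 9-12), so all cross-donor
statistics are computed within groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Cytokine",
    "Factor",
    "FACTOR_ORDER",
    "CytokineCondition",
    "DonorGroup",
    "FoldExpansionTable",
    "ALLOWED_DAYS",
    "SchemaError",
    "ValidationError",
    "ConfigurationError",
    "load_fold_expansion",
    "write_fold_expansion",
    "builtin_condition_registry",
    "load_condition_registry",
    "save_condition_registry",
    "default_donor_groups",
]


class Cytokine(str, Enum):
    """The five interleukins of the study design."""

    IL2 = "IL2"
    IL12 = "IL12"
    IL15 = "IL15"
    IL18 = "IL18"
    IL21 = "IL21"


class Factor(str, Enum):
    """STAT / NF-κB transcription factors, in the canonical column order."""

    STAT1 = "STAT1"
    STAT3 = "STAT3"
    STAT4 = "STAT4"
    STAT5 = "STAT5"
    NFKB = "NFKB"


#: Canonical factor ordering used for every matrix column layout.
FACTOR_ORDER: tuple[Factor, ...] = (
    Factor.STAT1,
    Factor.STAT3,
    Factor.STAT4,
    Factor.STAT5,
    Factor.NFKB,
)

#: Measurement schedule; other days are rejected at load time.
ALLOWED_DAYS: frozenset[int] = frozenset({0, 2, 4, 7, 9, 12, 14, 16})


class SchemaError(ValueError):
    """A required column cannot be resolved in an input file."""


class ValidationError(ValueError):
    """Input rows violate a table invariant."""


class ConfigurationError(ValueError):
    """A registry or config is incomplete for the requested operation."""


@dataclass(frozen=True)
class CytokineCondition:
    """One treatment regimen: per-phase cytokine cocktails.

    ``pp2`` is informational only; the modeling path uses priming and PP-I.
    ``placeholder`` marks conditions whose cocktails must be supplied by the
    user before they can enter the regression.
    """

    condition_id: int
    priming: frozenset[Cytokine]
    pp1: frozenset[Cytokine]
    pp2: frozenset[Cytokine] = frozenset()
    label: str = ""
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.condition_id <= 0:
            raise ValueError(f"condition_id must be positive, got {self.condition_id}")
        object.__setattr__(self, "priming", frozenset(Cytokine(c) for c in self.priming))
        object.__setattr__(self, "pp1", frozenset(Cytokine(c) for c in self.pp1))
        object.__setattr__(self, "pp2", frozenset(Cytokine(c) for c in self.pp2))
        if not self.placeholder and (not self.priming or not self.pp1):
            raise ValueError(
                f"condition {self.condition_id}: priming and pp1 must be non-empty "
                "for modeled conditions"
            )


@dataclass(frozen=True)
class DonorGroup:
    """A donor cohort sharing one condition subset."""

    group_id: str
    donor_ids: tuple[int, ...]
    condition_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "donor_ids", tuple(self.donor_ids))
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))


def default_donor_groups() -> tuple[DonorGroup, DonorGroup, DonorGroup]:
    """The study's three-group partition: 10 + 4 + 3 donors."""
    return (
        DonorGroup("A", tuple(range(1, 11)), (1, 2, 3, 4, 5, 6)),
        DonorGroup("B", tuple(range(11, 15)), (7, 8)),
        DonorGroup("C", tuple(range(15, 18)), (9, 10, 11, 12)),
    )


@dataclass
class FoldExpansionTable:
    """Long-format fold-expansion records with a donor-group partition.

    ``data`` holds columns ``donor_id``, ``condition_id``, ``day``,
    ``fold_expansion``; all fold expansions are positive ratios versus day 0.
    """

    data: pd.DataFrame
    groups: tuple[DonorGroup, ...] = field(default_factory=default_donor_groups)

    def __post_init__(self) -> None:
        self.data = _validate_records(self.data)
        self._check_partition()

    def _check_partition(self) -> None:
        donor_to_group: dict[int, str] = {}
        for g in self.groups:
            for d in g.donor_ids:
                if d in donor_to_group:
                    raise ValidationError(
                        f"donor {d} assigned to groups {donor_to_group[d]} and {g.group_id}"
                    )
                donor_to_group[d] = g.group_id
        cond_of_group = {g.group_id: set(g.condition_ids) for g in self.groups}
        for donor, cond in self.data[["donor_id", "condition_id"]].drop_duplicates().itertuples(index=False):
            gid = donor_to_group.get(donor)
            if gid is None:
                raise ValidationError(f"donor {donor} not assigned to any group")
            if cond not in cond_of_group[gid]:
                raise ValidationError(
                    f"observation (donor {donor}, condition {cond}) lies outside "
                    f"group {gid}'s condition list {sorted(cond_of_group[gid])}"
                )

    def group(self, group_id: str) -> DonorGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"no donor group {group_id!r}")

    def values(self, day: int, donors: Sequence[int], conditions: Sequence[int]) -> pd.DataFrame:
        """Donor x condition matrix of fold expansions at ``day``.

        Raises :class:`ValidationError` naming any missing cell.
        """
        sub = self.data[self.data["day"] == day]
        wide = sub.pivot(index="donor_id", columns="condition_id", values="fold_expansion")
        missing = [
            (d, c)
            for d in donors
            for c in conditions
            if d not in wide.index or c not in wide.columns or pd.isna(wide.loc[d, c])
        ]
        if missing:
            raise ValidationError(f"missing fold-expansion values at day {day}: {missing}")
        return wide.loc[list(donors), list(conditions)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoldExpansionTable):
            return NotImplemented
        a = self.data.sort_values(["donor_id", "condition_id", "day"]).reset_index(drop=True)
        b = other.data.sort_values(["donor_id", "condition_id", "day"]).reset_index(drop=True)
        return a.equals(b) and self.groups == other.groups


_REQUIRED = ("donor_id", "condition_id", "day", "fold_expansion")


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.loc[:, list(_REQUIRED)].copy()
    df["donor_id"] = df["donor_id"].astype(int)
    df["condition_id"] = df["condition_id"].astype(int)
    df["day"] = df["day"].astype(int)
    df["fold_expansion"] = df["fold_expansion"].astype(float)

    bad_day = sorted(set(df["day"]) - ALLOWED_DAYS)
    if bad_day:
        raise ValidationError(f"days outside the measurement schedule {sorted(ALLOWED_DAYS)}: {bad_day}")

    dupes = df[df.duplicated(subset=["donor_id", "condition_id", "day"], keep=False)]
    if not dupes.empty:
        keys = sorted(set(map(tuple, dupes[["donor_id", "condition_id", "day"]].values.tolist())))
        raise ValidationError(f"duplicate (donor, condition, day) keys: {keys}")

    nonpos = df[df["fold_expansion"] <= 0]
    if not nonpos.empty:
        keys = list(map(tuple, nonpos[["donor_id", "condition_id", "day"]].values.tolist()))
        raise ValidationError(f"non-positive fold expansion at keys: {keys}")

    day0 = df[(df["day"] == 0) & (df["fold_expansion"] != 1.0)]
    if not day0.empty:
        keys = list(map(tuple, day0[["donor_id", "condition_id", "day"]].values.tolist()))
        raise ValidationError(f"day-0 fold expansion must equal 1; offending keys: {keys}")
    return df.reset_index(drop=True)


def load_fold_expansion(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    groups: Iterable[DonorGroup] | None = None,
) -> FoldExpansionTable:
    """Read a fold-expansion CSV.

    ``schema`` maps the canonical column names to the file's column names,
    e.g. ``{"donor_id": "Donor"}``; unmapped names are used verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {}
    schema = dict(schema or {})
    for canon in _REQUIRED:
        src = schema.get(canon, canon)
        if src not in df.columns:
            raise SchemaError(f"column {src!r} (for {canon!r}) not found in {path.name}; have {list(df.columns)}")
        rename[src] = canon
    df = df.rename(columns=rename)
    table_groups = tuple(groups) if groups is not None else default_donor_groups()
    return FoldExpansionTable(df, table_groups)


def write_fold_expansion(table: FoldExpansionTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Condition registry


def builtin_condition_registry() -> list[CytokineCondition]:
    """The condition regimens that are known exactly, plus placeholders.

    Only five regimens are pinned down: condition 1 (IL-2 throughout),
    condition 2 (IL-12+15+18 priming, then IL-2), condition 3 (IL-12+15+18+21
    priming, then IL-2), condition 12 (IL-15+21 priming, IL-18 in PP-I) and
    the counterfactual condition 13 (condition 3's priming with IL-2+21 in
    PP-I).  Conditions 4-11 ship as placeholders that must be supplied by
    the user; requesting the modeled set with unresolved placeholders raises
    :class:`ConfigurationError`.
    """
    known = {
        1: CytokineCondition(1, {Cytokine.IL2}, {Cytokine.IL2}, label="IL-2 alone"),
        2: CytokineCondition(
            2,
            {Cytokine.IL12, Cytokine.IL15, Cytokine.IL18},
            {Cytokine.IL2},
            label="IL-12/15/18 priming, then IL-2",
        ),
        3: CytokineCondition(
            3,
            {Cytokine.IL12, Cytokine.IL15, Cytokine.IL18, Cytokine.IL21},
            {Cytokine.IL2},
            label="IL-12/15/18/21 priming, then IL-2",
        ),
        12: CytokineCondition(
            12,
            {Cytokine.IL15, Cytokine.IL21},
            {Cytokine.IL18},
            label="IL-15/21 priming, IL-18 post-priming",
        ),
        13: CytokineCondition(
            13,
            {Cytokine.IL12, Cytokine.IL15, Cytokine.IL18, Cytokine.IL21},
            {Cytokine.IL2, Cytokine.IL21},
            label="condition-3 priming with IL-2+21 post-priming (counterfactual)",
        ),
    }
    registry = []
    for cid in range(1, 14):
        if cid in known:
            registry.append(known[cid])
        else:
            registry.append(
                CytokineCondition(cid, frozenset(), frozenset(), label="user-must-supply", placeholder=True)
            )
    return registry


def modeled_conditions(
    registry: Sequence[CytokineCondition], condition_ids: Sequence[int] = tuple(range(1, 13))
) -> list[CytokineCondition]:
    """The conditions entering the regression, in condition-id order.

    Raises :class:`ConfigurationError` if any requested condition is still a
    placeholder.
    """
    by_id = {c.condition_id: c for c in registry}
    out = []
    unresolved = []
    for cid in condition_ids:
        cond = by_id.get(cid)
        if cond is None or cond.placeholder:
            unresolved.append(cid)
        else:
            out.append(cond)
    if unresolved:
        raise ConfigurationError(
            f"conditions {unresolved} are unresolved placeholders; supply their "
            "cytokine cocktails in the registry config"
        )
    return out


def _condition_to_dict(cond: CytokineCondition) -> dict:
    return {
        "condition_id": cond.condition_id,
        "priming": sorted(c.value for c in cond.priming),
        "pp1": sorted(c.value for c in cond.pp1),
        "pp2": sorted(c.value for c in cond.pp2),
        "label": cond.label,
        "placeholder": cond.placeholder,
    }


def save_condition_registry(registry: Sequence[CytokineCondition], path: str | Path) -> None:
    path = Path(path)
    payload = {"conditions": [_condition_to_dict(c) for c in registry]}
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_condition_registry(path: str | Path) -> list[CytokineCondition]:
    """Load a registry from YAML or JSON (keys: priming / pp1 / pp2)."""
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    out = []
    for entry in payload["conditions"]:
        out.append(
            CytokineCondition(
                condition_id=int(entry["condition_id"]),
                priming=frozenset(Cytokine(c) for c in entry.get("priming", [])),
                pp1=frozenset(Cytokine(c) for c in entry.get("pp1", [])),
                pp2=frozenset(Cytokine(c) for c in entry.get("pp2", [])),
                label=str(entry.get("label", "")),
                placeholder=bool(entry.get("placeholder", False)),
            )
        )
    return out
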