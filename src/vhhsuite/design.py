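"""Panning experiment design: conditions, roles, and read totals.

A phage-display campaign presents the target in several physical forms
("modalities": whole cells, membranes, proteoliposomes, recombinant
ectodomain, peptide) and carries each through two or three rounds of
selection.  Every (modality, round) pair is one sequenced condition;
each modality family has matched negative controls (untransfected cells,
empty liposomes, the MBP fusion partner alone, ...).  The design object
records which conditions are target-positive and which are controls, and
the per-condition sequencing depth used for counts-per-million scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

POSITIVE = "positive"
CONTROL = "control"


@dataclass(frozen=True)
class Condition:
    """One sequenced panning condition."""

    modality: str
    round: int
    role: str  # POSITIVE or CONTROL
    name: str = ""

    def __post_init__(self):
        if self.role not in (POSITIVE, CONTROL):
            raise ValueError(f"role must be 'positive' or 'control', got {self.role!r}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.modality}_r{self.round}")


@dataclass
class PanningDesign:
    """Declaration of all panning conditions and their sequencing totals."""

    conditions: list[Condition]
    totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        roles = {c.role for c in self.conditions}
        if POSITIVE not in roles or CONTROL not in roles:
            raise ValueError("design needs at least one positive and one control condition")

    @property
    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]

    @property
    def positive_names(self) -> list[str]:
        return [c.name for c in self.conditions if c.role == POSITIVE]

    @property
    def control_names(self) -> list[str]:
        return [c.name for c in self.conditions if c.role == CONTROL]

    @property
    def modalities(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c.modality, None)
        return list(seen)

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_totals(self, totals: Mapping[str, int]) -> "PanningDesign":
        unknown = set(totals) - set(self.condition_names)
        if unknown:
            raise KeyError(f"totals given for unknown conditions: {sorted(unknown)}")
        return PanningDesign(list(self.conditions), dict(totals))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {"modality": c.modality, "round": c.round, "role": c.role, "name": c.name}
                for c in self.conditions
            ],
            "totals": dict(self.totals),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanningDesign":
        conds = [
            Condition(
                modality=c["modality"],
                round=int(c["round"]),
                role=c["role"],
                name=c.get("name", ""),
            )
            for c in d["conditions"]
        ]
        return cls(conds, {k: int(v) for k, v in d.get("totals", {}).items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanningDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_design() -> PanningDesign:
    """The 12-condition design used throughout: 6 modality families with
    matched controls for proteoliposomes, cells, MBP and membranes, and
    R2/R3 rounds where a family was carried through both."""
    conds = [
        Condition("proteoliposomes_control", 3, CONTROL),
        Condition("proteoliposomes_fshr", 3, POSITIVE),
        Condition("cells_control", 3, CONTROL),
        Condition("cells_fshr", 2, POSITIVE),
        Condition("cells_fshr", 3, POSITIVE),
        Condition("mbp_control", 3, CONTROL),
        Condition("mbp_fshr", 2, POSITIVE),
        Condition("mbp_fshr", 3, POSITIVE),
        Condition("ecd_fshr", 2, POSITIVE),
        Condition("ecd_fshr", 3, POSITIVE),
        Condition("membranes_control", 3, CONTROL),
        Condition("membranes_fshr", 3, POSITIVE),
    ]
    return PanningDesign(conds)


def design_from_columns(columns: Iterable[str], round_default: int = 3) -> PanningDesign:
    """Build a design from report column names, inferring roles.

    Columns containing ``control`` become negative controls; a trailing
    ``_r<digit>`` suffix sets the round.  Totals are left unset (the
    caller decides the normalisation scale).
    """
    conds = []
    for col in columns:
        modality, rnd = col, round_default
        if len(col) > 3 and col[-3:-1] == "_r" and col[-1].isdigit():
            modality, rnd = col[:-3], int(col[-1])
        role = CONTROL if "control" in col else POSITIVE
        conds.append(Condition(modality, rnd, role, name=col))
    return PanningDesign(conds)
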