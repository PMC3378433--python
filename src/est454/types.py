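"""Core domain types shared across the pipeline.

The unit of data flowing through QC, assembly, and read counting is a
:class:`Read` tagged with its library of origin.  Libraries are organised by a
:class:`StageDesign`: ordered developmental stages within organ groups (flower
buds along a cold-acclimation time course measured in chill units, fruit along
a ripening series, and a single leaf sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Expression-pattern vocabulary used by the trend classifier.
TREND_LABELS = ("up", "down", "up_down", "down_up", "flat", "complex")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of ``seq`` in percent; 0.0 for an empty sequence."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass
class Read:
    """A sequence record tagged with its library of origin.

    ``meta`` carries simulation ground truth (source transcript, coordinates);
    the pipeline itself never reads it — it exists so tests can check planted
    truth.
    """

    id: str
    sequence: str
    library_id: str = ""
    quality: Optional[list[int]] = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class Stage:
    """A developmental stage with a numeric ordinate used for ordering."""

    label: str
    ordinate: float


@dataclass(frozen=True)
class StageDesign:
    """Ordered stages per organ group.

    Invariants: ordinates strictly increase within a group; any group meant to
    carry expression trends needs at least two stages.
    """

    groups: tuple[tuple[str, tuple[Stage, ...]], ...]

    def __post_init__(self) -> None:
        for name, stages in self.groups:
            if not stages:
                raise ValueError(f"group {name!r} has no stages")
            ords = [s.ordinate for s in stages]
            if any(b <= a for a, b in zip(ords, ords[1:])):
                raise ValueError(
                    f"stage ordinates must strictly increase in group {name!r}"
                )

    @property
    def group_names(self) -> list[str]:
        return [name for name, _ in self.groups]

    def stages(self, group: str) -> tuple[Stage, ...]:
        for name, stages in self.groups:
            if name == group:
                return stages
        raise KeyError(group)

    def trend_groups(self) -> list[str]:
        """Groups with >= 2 stages (the ones that can carry a trend)."""
        return [name for name, stages in self.groups if len(stages) >= 2]

    def library_id(self, group: str, stage: Stage | str) -> str:
        label = stage.label if isinstance(stage, Stage) else stage
        return f"{group}_{label}"

    def libraries(self) -> list[tuple[str, Stage, str]]:
        """All (group, stage, library_id) triples in design order."""
        out = []
        for name, stages in self.groups:
            for st in stages:
                out.append((name, st, self.library_id(name, st)))
        return out

    def library_ids(self, group: Optional[str] = None) -> list[str]:
        return [
            lib
            for g, _, lib in self.libraries()
            if group is None or g == group
        ]


def default_design() -> StageDesign:
    """The nine-library study design: four bud cold-acclimation time points
    (chill units accumulated), four fruit ripening stages, and leaves."""
    bud = tuple(Stage(str(cu), float(cu)) for cu in (0, 397, 789, 1333))
    fruit = tuple(
        Stage(lbl, float(i))
        for i, lbl in enumerate(["green", "white", "pink", "blue"])
    )
    leaf = (Stage("leaf", 0.0),)
    return StageDesign(groups=(("bud", bud), ("fruit", fruit), ("leaf", leaf)))
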