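"""Phase reference gene sets and GMT serialization.

A cell-cycle reference set maps each of the five expression-defined phases
(G1/S, S, G2, G2/M, M/G1) to a list of genes whose transcript levels peak in
that phase.  Reference lists of this kind derive from synchronized-culture
expression profiling; here the lists are either user-supplied (GMT) or
emitted by the synthetic generator together with the count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: Fixed phase order used everywhere (score columns, ideal patterns, ties).
PHASES: tuple[str, ...] = ("G1/S", "S", "G2", "G2/M", "M/G1")


@dataclass(frozen=True)
class PhaseGeneSets:
    """Mapping phase -> tuple of gene identifiers, in the fixed phase order.

    Invariants enforced at construction: all five phases present, every list
    non-empty, and no gene assigned to more than one phase.
    """

    genes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in PHASES if p not in self.genes]
        if missing:
            raise ValueError(f"phase gene sets missing phases: {missing}")
        extra = [p for p in self.genes if p not in PHASES]
        if extra:
            raise ValueError(f"unknown phases in gene sets: {extra}")
        seen: dict[str, str] = {}
        for phase in PHASES:
            members = tuple(self.genes[phase])
            if not members:
                raise ValueError(f"phase {phase!r} has an empty gene list")
            for g in members:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} assigned to both {seen[g]!r} and {phase!r}"
                    )
                seen[g] = phase
        # normalize to tuples in fixed order
        object.__setattr__(
            self, "genes", {p: tuple(self.genes[p]) for p in PHASES}
        )

    def __getitem__(self, phase: str) -> tuple[str, ...]:
        return self.genes[phase]

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(g for p in PHASES for g in self.genes[p])

    def subset(self, keep: Iterable[str]) -> "PhaseGeneSets":
        """Restrict every phase list to ``keep`` (order preserved).

        Raises if any phase would lose all of its genes.
        """
        keep = set(keep)
        out: dict[str, tuple[str, ...]] = {}
        for phase in PHASES:
            members = tuple(g for g in self.genes[phase] if g in keep)
            if not members:
                raise ValueError(f"phase {phase!r} lost all reference genes")
            out[phase] = members
        return PhaseGeneSets(out)

    def sizes(self) -> dict[str, int]:
        return {p: len(self.genes[p]) for p in PHASES}

    # -- GMT (one line per set: name, description, tab-separated genes) ----

    def to_gmt(self, path: str | Path) -> None:
        lines = []
        for phase in PHASES:
            lines.append("\t".join([phase, "cell cycle phase", *self.genes[phase]]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PhaseGeneSets":
        genes: dict[str, Sequence[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            genes[fields[0]] = tuple(fields[2:])
        return cls(genes)
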