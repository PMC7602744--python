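"""Taxonomic lineages and rank arithmetic.

A taxon is identified by its full lineage: an ordered sequence of rank
labels from kingdom down to genus, serialized as a semicolon-delimited
string (``Bacteria;Firmicutes;Clostridia;...``).  Aggregating a feature
table to a higher rank means grouping taxa that share a lineage prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The six ranks used throughout, from broadest to finest.
RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Separator used in serialized lineage strings.
SEP = ";"


def rank_depth(level: str) -> int:
    """Number of lineage labels a taxon carries at ``level`` (kingdom=1 ... genus=6)."""
    try:
        return RANKS.index(level) + 1
    except ValueError:
        raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}") from None


@dataclass(frozen=True)
class Lineage:
    """An ordered lineage of rank labels, truncated to some level.

    Labels for ranks that were not resolved by taxonomy assignment are
    conventionally rendered ``"unclassified <parent label>"`` so that they
    group deterministically when aggregating.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.labels) <= len(RANKS):
            raise ValueError(f"lineage must have 1..{len(RANKS)} labels, got {len(self.labels)}")
        if any(not lab or SEP in lab for lab in self.labels):
            raise ValueError(f"empty label or embedded {SEP!r} in lineage {self.labels!r}")

    @property
    def level(self) -> str:
        """The finest rank this lineage resolves."""
        return RANKS[len(self.labels) - 1]

    def truncate(self, level: str) -> "Lineage":
        """Lineage restricted to its first ranks, down to ``level`` (must be at or above)."""
        k = rank_depth(level)
        if k > len(self.labels):
            raise ValueError(
                f"cannot truncate a {self.level}-level lineage to the finer rank {level!r}"
            )
        return Lineage(self.labels[:k])

    def __str__(self) -> str:
        return SEP.join(self.labels)

    @classmethod
    def parse(cls, text: str, level: str | None = None) -> "Lineage":
        """Parse a semicolon-delimited lineage, optionally enforcing its level."""
        labels = tuple(part.strip() for part in text.split(SEP))
        lin = cls(labels)
        if level is not None and lin.level != level:
            raise ValueError(
                f"lineage {text!r} has {len(labels)} ranks ({lin.level}); expected {level}"
            )
        return lin
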