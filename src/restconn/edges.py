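"""Significant-edge lists shared by the correlation and causality analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["Edge", "SignificantEdgeList"]


@dataclass(frozen=True)
class Edge:
    """One edge surviving multiple-comparison correction.

    ``tier`` grades corrected significance: 1 (corrected p < .005),
    2 (< .001), 3 (< .0001) — higher tiers mean stronger evidence, the
    analogue of drawing a thicker line in a network plot.
    """

    source: str
    target: str
    weight: float
    sign: int
    p_corrected: float
    tier: int


@dataclass(frozen=True)
class SignificantEdgeList:
    """Edges surviving a Bonferroni-corrected family threshold.

    Undirected lists store each pair once, endpoints in sorted label
    order; directed lists key on the ordered (source, target) pair.
    """

    directed: bool
    edges: tuple[Edge, ...]
    family_alpha: float
    n_comparisons: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(self.edges))
        seen = set()
        for e in self.edges:
            key = (e.source, e.target)
            if not self.directed:
                if e.source > e.target:
                    raise ValueError(
                        f"undirected edge ({e.source}, {e.target}) not in "
                        "canonical label order"
                    )
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            if e.p_corrected >= self.family_alpha:
                raise ValueError(
                    f"edge {key} has corrected p {e.p_corrected:.3g} at or above "
                    f"the family threshold {self.family_alpha}"
                )

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}
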