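"""Item-set registry for the two ranking questions.

An :class:`ItemSet` describes one ranking question: the candidate items
(snake_case identifiers, stable across modules) and the *rank depth* K,
i.e. how many positions respondents fill in. Communication applications
are ranked completely (6 of 6) because a user eventually wants all of
them; mental strategies are ranked top-4-of-8 because a BCI user only
ever needs a few control strategies.

The rank-to-weight encoding hangs off the item set: the top-ranked item
receives weight K, the j-th ranked item K - j + 1, and unranked items 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

__all__ = [
    "ItemSet",
    "APPLICATIONS",
    "STRATEGIES",
    "BUILTIN_ITEM_SETS",
    "DISPLAY_NAMES",
]


@dataclass(frozen=True)
class ItemSet:
    """A ranking question: an ordered universe of items and a rank depth.

    Parameters
    ----------
    name
        Identifier of the item set (``"applications"``, ``"strategies"``).
    items
        Unique snake_case item identifiers, in canonical display order.
    rank_depth
        Number of positions K respondents rank (K <= len(items)).
    """

    name: str
    items: tuple[str, ...]
    rank_depth: int

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ParameterError(f"item set {self.name!r}: duplicate items")
        if not (1 <= self.rank_depth <= len(self.items)):
            raise ParameterError(
                f"item set {self.name!r}: rank_depth {self.rank_depth} "
                f"must be in [1, {len(self.items)}]"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    def weight_for_position(self, position: int) -> int:
        """Weight of the item ranked at 0-based ``position`` (best first)."""
        if not 0 <= position < self.rank_depth:
            raise ParameterError(
                f"position {position} outside [0, {self.rank_depth})"
            )
        return self.rank_depth - position

    def weight_multiset(self) -> tuple[int, ...]:
        """The multiset of weights one respondent distributes: K..1 plus
        zeros padding up to the number of items."""
        ranked = tuple(range(self.rank_depth, 0, -1))
        return ranked + (0,) * (self.n_items - self.rank_depth)

    def max_total_weight(self) -> int:
        """Sum of the nonzero weights, K(K+1)/2."""
        return self.rank_depth * (self.rank_depth + 1) // 2


#: Communication applications a cBCI could provide; ranked completely.
APPLICATIONS = ItemSet(
    name="applications",
    items=(
        "private_writing",
        "direct_communication",
        "environmental_control",
        "computer_use",
        "artistic_expression",
        "emotions_expression",
    ),
    rank_depth=6,
)

#: Mental strategies for generating a control signal; top 4 of 8 ranked.
STRATEGIES = ItemSet(
    name="strategies",
    items=(
        "attempted_hand",
        "attempted_body",
        "attempted_speech",
        "counting_backward",
        "visual_imagery",
        "visual_p300",
        "auditory_p300",
        "ssvep",
    ),
    rank_depth=4,
)

BUILTIN_ITEM_SETS: dict[str, ItemSet] = {
    APPLICATIONS.name: APPLICATIONS,
    STRATEGIES.name: STRATEGIES,
}

#: Human-readable display names for report output.
DISPLAY_NAMES: dict[str, str] = {
    "private_writing": "Private conversation and writing",
    "direct_communication": "Direct personal communication",
    "environmental_control": "Environmental control",
    "computer_use": "General computer use",
    "artistic_expression": "Artistic expression",
    "emotions_expression": "Emotions and facial expressions",
    "attempted_hand": "Attempted hand movement",
    "attempted_body": "Attempted body movement",
    "attempted_speech": "Attempted speech",
    "counting_backward": "Counting backward",
    "visual_imagery": "Visual imagery",
    "visual_p300": "Visual P300",
    "auditory_p300": "Auditory P300",
    "ssvep": "SSVEP",
}
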