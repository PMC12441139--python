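"""Childhood Trauma Questionnaire (CTQ) scoring and severity categorization.

The CTQ is a 25-item retrospective self-report instrument with five
subscales — emotional abuse (EA), physical abuse (PA), sexual abuse (SA),
emotional neglect (EN), physical neglect (PN) — each the sum of five items
rated 1..5, so subscale sums range 5..25 and the total 25..125.  Items are
assumed to be recoded already (reverse-keyed items flipped); the three
denial/minimization items of the 28-item form are not part of the scored set
and are ignored throughout.

Severity categorization follows the conventional subscale cutoff scheme: a
participant is in the *severe* extreme group when any subscale reaches its
severe cutoff, and in the *none-to-minimal* group when every subscale is at
or below the none-to-minimal upper bound; everyone else is *intermediate*
and excluded from extreme-group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

SUBSCALES = ("EA", "PA", "SA", "EN", "PN")

#: Default positional item→subscale map: items 1-5 EA, 6-10 PA, 11-15 SA,
#: 16-20 EN, 21-25 PN.  Real questionnaire layouts interleave subscales;
#: supply a custom map when scoring raw instrument exports.
DEFAULT_ITEM_MAP: dict[str, tuple[int, ...]] = {
    "EA": (1, 2, 3, 4, 5),
    "PA": (6, 7, 8, 9, 10),
    "SA": (11, 12, 13, 14, 15),
    "EN": (16, 17, 18, 19, 20),
    "PN": (21, 22, 23, 24, 25),
}

#: Conventional subscale severity bounds: upper bound of the
#: 'none to minimal' band and lower bound of the 'severe' band.
DEFAULT_NONE_UPPER = {"EA": 8, "PA": 7, "SA": 5, "EN": 9, "PN": 7}
DEFAULT_SEVERE_LOWER = {"EA": 16, "PA": 13, "SA": 13, "EN": 18, "PN": 13}

COMPOSITE_KINDS = ("ctq_sum", "abuse", "neglect", "ea", "pa", "sa", "en", "pn")


class CtqValidationError(ValueError):
    """Raised for out-of-range or structurally invalid CTQ input."""


class CtqMissingDataError(ValueError):
    """Raised when CTQ items are missing (such subjects are excluded upstream)."""


@dataclass(frozen=True)
class CtqScores:
    """Scored CTQ for one participant.

    ``subscale_sums`` maps EA/PA/SA/EN/PN to their 5..25 sums;
    ``total_sum`` is their sum (25..125); ``item_scores`` retains the raw
    items when the scores were computed from item level data.
    """

    subscale_sums: Mapping[str, int]
    total_sum: int
    item_scores: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if set(self.subscale_sums) != set(SUBSCALES):
            raise CtqValidationError(
                f"subscale_sums must have keys {SUBSCALES}, got {tuple(self.subscale_sums)}"
            )
        for key in SUBSCALES:
            s = self.subscale_sums[key]
            if not 5 <= s <= 25:
                raise CtqValidationError(f"subscale {key} sum {s} outside 5..25")
        if self.total_sum != sum(self.subscale_sums.values()):
            raise CtqValidationError(
                f"total_sum {self.total_sum} != sum of subscales "
                f"{sum(self.subscale_sums.values())}"
            )


@dataclass(frozen=True)
class SeverityCutoffs:
    """Per-subscale bounds delimiting 'none to minimal' and 'severe' bands."""

    none_upper: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_NONE_UPPER))
    severe_lower: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SEVERE_LOWER))

    def __post_init__(self) -> None:
        for key in SUBSCALES:
            if key not in self.none_upper or key not in self.severe_lower:
                raise CtqValidationError(f"cutoffs missing subscale {key}")
            if not self.none_upper[key] < self.severe_lower[key]:
                raise CtqValidationError(
                    f"subscale {key}: none_upper {self.none_upper[key]} must be "
                    f"< severe_lower {self.severe_lower[key]}"
                )


def score_ctq(
    items: Sequence[int | None],
    item_map: Mapping[str, Sequence[int]] = DEFAULT_ITEM_MAP,
) -> CtqScores:
    """Score 25 CTQ items (1..5 each) into subscale sums and the total.

    ``item_map`` maps each subscale to its five 1-based item positions.
    Raises :class:`CtqMissingDataError` on missing items (None/NaN) and
    :class:`CtqValidationError` on out-of-range values, naming the item.
    """
    if len(items) != 25:
        raise CtqValidationError(f"expected 25 items, got {len(items)}")
    clean: list[int] = []
    for idx, value in enumerate(items, start=1):
        if value is None or value != value:  # None or NaN
            raise CtqMissingDataError(f"item {idx} is missing")
        iv = int(value)
        if iv != value or not 1 <= iv <= 5:
            raise CtqValidationError(f"item {idx} value {value!r} outside 1..5")
        clean.append(iv)

    assigned = [pos for positions in item_map.values() for pos in positions]
    if sorted(assigned) != list(range(1, 26)):
        raise CtqValidationError("item_map must assign items 1..25 exactly once")
    if set(item_map) != set(SUBSCALES):
        raise CtqValidationError(f"item_map must cover subscales {SUBSCALES}")

    sums = {
        key: sum(clean[pos - 1] for pos in item_map[key]) for key in SUBSCALES
    }
    return CtqScores(
        subscale_sums=sums, total_sum=sum(sums.values()), item_scores=tuple(clean)
    )


def composite_predictor(scores: CtqScores, kind: str) -> int:
    """Return a maltreatment predictor value from scored CTQ data.

    ``ctq_sum`` is the total; ``abuse`` sums EA+PA+SA; ``neglect`` sums
    EN+PN; lower-case subscale names return that subscale's sum.
    """
    kind = kind.lower()
    s = scores.subscale_sums
    if kind == "ctq_sum":
        return scores.total_sum
    if kind == "abuse":
        return s["EA"] + s["PA"] + s["SA"]
    if kind == "neglect":
        return s["EN"] + s["PN"]
    if kind.upper() in SUBSCALES:
        return s[kind.upper()]
    raise CtqValidationError(
        f"unknown composite kind {kind!r}; expected one of {COMPOSITE_KINDS}"
    )


def assign_extreme_group(
    scores: CtqScores, cutoffs: SeverityCutoffs | None = None
) -> str:
    """Assign 'severe' / 'none_minimal' / 'intermediate' per subscale cutoffs.

    severe: any subscale at/above its severe lower bound;
    none_minimal: every subscale at/below its none-to-minimal upper bound;
    intermediate otherwise.
    """
    cutoffs = cutoffs or SeverityCutoffs()
    s = scores.subscale_sums
    if any(s[key] >= cutoffs.severe_lower[key] for key in SUBSCALES):
        return "severe"
    if all(s[key] <= cutoffs.none_upper[key] for key in SUBSCALES):
        return "none_minimal"
    return "intermediate"
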