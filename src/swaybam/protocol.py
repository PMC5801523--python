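"""The 6-condition quiet-standing balance protocol (BAM).

The protocol crosses support surface (firm / foam), foot placement
(feet together / tandem) and vision (eyes open / closed) into six 60 s
stances, ordered so that each eyes-open condition is immediately followed
by its eyes-closed counterpart.  A facilitator observes each attempt and
records one of six standardized failure events; failed attempts are
excluded from analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .exceptions import ConfigurationError


class Surface(str, Enum):
    FIRM = "firm"
    FOAM = "foam"


class Stance(str, Enum):
    FEET_TOGETHER = "feet_together"
    TANDEM = "tandem"


class Eyes(str, Enum):
    OPEN = "open"
    CLOSED = "closed"


class FailureReason(str, Enum):
    """Facilitator-recorded reasons an attempt is scored as failed."""

    ARMS_OFF_CHEST = "arms_off_chest"
    KNEES_BENT = "knees_bent"
    FEET_MOVED = "feet_moved"
    BENT_FORWARD = "bent_forward"
    EYES_OPENED = "eyes_opened"
    DECLINED = "declined"


@dataclass(frozen=True)
class StanceCondition:
    index: int
    surface: Surface
    stance: Stance
    eyes: Eyes
    duration_s: float = 60.0


@dataclass(frozen=True)
class ProtocolDefinition:
    """Ordered stance conditions plus the attempt count per condition."""

    conditions: tuple[StanceCondition, ...] = field(default_factory=tuple)
    n_attempts: int = 2

    def __post_init__(self) -> None:
        if len(self.conditions) != 6:
            raise ConfigurationError(
                f"protocol must define exactly 6 conditions, got {len(self.conditions)}"
            )
        if [c.index for c in self.conditions] != list(range(1, 7)):
            raise ConfigurationError("conditions must be indexed 1..6 in order")
        if self.n_attempts < 1:
            raise ConfigurationError("n_attempts must be >= 1")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def condition(self, index: int) -> StanceCondition:
        return self.conditions[index - 1]

    def eyes_pairs(self) -> list[tuple[int, int]]:
        """(eyes-open, eyes-closed) condition index pairs sharing surface+stance."""
        pairs = []
        by_key: dict[tuple[Surface, Stance], dict[Eyes, int]] = {}
        for c in self.conditions:
            by_key.setdefault((c.surface, c.stance), {})[c.eyes] = c.index
        for key in sorted(by_key, key=lambda k: by_key[k][Eyes.OPEN]):
            d = by_key[key]
            if Eyes.OPEN in d and Eyes.CLOSED in d:
                pairs.append((d[Eyes.OPEN], d[Eyes.CLOSED]))
        return pairs


BAM_PROTOCOL = ProtocolDefinition(
    conditions=(
        StanceCondition(1, Surface.FIRM, Stance.FEET_TOGETHER, Eyes.OPEN),
        StanceCondition(2, Surface.FIRM, Stance.FEET_TOGETHER, Eyes.CLOSED),
        StanceCondition(3, Surface.FOAM, Stance.FEET_TOGETHER, Eyes.OPEN),
        StanceCondition(4, Surface.FOAM, Stance.FEET_TOGETHER, Eyes.CLOSED),
        StanceCondition(5, Surface.FIRM, Stance.TANDEM, Eyes.OPEN),
        StanceCondition(6, Surface.FIRM, Stance.TANDEM, Eyes.CLOSED),
    ),
    n_attempts=2,
)
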