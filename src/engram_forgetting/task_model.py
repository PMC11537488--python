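"""Day-indexed schedule of the object-based memory task.

The experiment is represented on a whole-day grid ``t = 0..T`` (default
``T = 21``).  The familiar object is presented on the acquisition day
(``t = 0``), on the retrieval-test day, and on any reminder days; on every
other day it is absent.  Retention intervals map onto the grid as
24 hr = day 1, 1 week = day 7, 2 weeks = day 14, 3 weeks = day 21.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "DEFAULT_HORIZON",
    "InvalidScheduleError",
    "UnknownConditionError",
    "TaskSchedule",
    "build_schedule",
    "condition_presets",
    "ConditionPreset",
    "STANDARD_TEST_DAYS",
]

DEFAULT_HORIZON = 21

#: Between-subjects retention intervals used throughout: 24 hr, 1, 2, 3 weeks.
STANDARD_TEST_DAYS = (1, 7, 14, 21)


class InvalidScheduleError(ValueError):
    """Raised when test or reminder days fall outside the legal day grid."""


class UnknownConditionError(KeyError):
    """Raised when a condition label has no preset."""


@dataclass(frozen=True)
class TaskSchedule:
    """Object-presence sequence for one experimental condition.

    ``object_presence[t]`` is 1 when the familiar object is presented on
    day ``t`` (acquisition, test, reminders) and 0 otherwise.
    """

    condition_name: str
    test_day: int
    horizon_T: int = DEFAULT_HORIZON
    acquisition_day: int = 0
    reminder_days: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 <= self.acquisition_day < self.test_day <= self.horizon_T):
            raise InvalidScheduleError(
                f"need 0 <= acquisition ({self.acquisition_day}) < test "
                f"({self.test_day}) <= horizon ({self.horizon_T})"
            )
        for r in self.reminder_days:
            if not (self.acquisition_day < r < self.test_day):
                raise InvalidScheduleError(
                    f"reminder day {r} must lie strictly between acquisition "
                    f"day {self.acquisition_day} and test day {self.test_day}"
                )

    @property
    def object_presence(self) -> tuple[int, ...]:
        """o_t for t = 0..T: 1 on acquisition, reminder and test days."""
        event_days = {self.acquisition_day, self.test_day, *self.reminder_days}
        return tuple(1 if t in event_days else 0 for t in range(self.horizon_T + 1))

    def with_test_day(self, test_day: int) -> "TaskSchedule":
        """Same condition and reminders-relative layout at another test day."""
        return build_schedule(
            self.condition_name,
            test_day,
            reminder_days=[r for r in self.reminder_days if r < test_day],
            horizon_T=self.horizon_T,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "condition": self.condition_name,
            "test_day": self.test_day,
            "reminder_days": list(self.reminder_days),
            "horizon": self.horizon_T,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskSchedule":
        return build_schedule(
            str(d["condition"]),
            int(d["test_day"]),
            reminder_days=[int(r) for r in d.get("reminder_days", [])],
            horizon_T=int(d.get("horizon", DEFAULT_HORIZON)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TaskSchedule":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "TaskSchedule":
        return cls.from_dict(json.loads(text))


def build_schedule(
    condition_name: str,
    test_day: int,
    reminder_days: Sequence[int] | None = None,
    horizon_T: int = DEFAULT_HORIZON,
) -> TaskSchedule:
    """Build the day-indexed presence schedule for one condition.

    Acquisition is fixed at day 0.  ``test_day`` must lie in
    ``[1, horizon_T]`` and every reminder day strictly inside
    ``(0, test_day)``; violations raise :class:`InvalidScheduleError`.
    """
    return TaskSchedule(
        condition_name=condition_name,
        test_day=int(test_day),
        horizon_T=int(horizon_T),
        reminder_days=tuple(sorted(int(r) for r in (reminder_days or []))),
    )


@dataclass(frozen=True)
class ConditionPreset:
    """Generative parameter set plus schedule family for one condition.

    ``schedule_for(test_day)`` yields the condition's schedule at a given
    retention interval.  ``reminder_offset`` places a reminder session the
    given number of days before the test (the experimental reminder happens
    1 hr before testing; on the whole-day grid it is snapped to the
    preceding day).
    """

    name: str
    alpha_neg: float
    reminder_offset: int | None = None

    def schedule_for(self, test_day: int, horizon_T: int = DEFAULT_HORIZON) -> TaskSchedule:
        reminders: list[int] = []
        if self.reminder_offset is not None:
            r = test_day - self.reminder_offset
            if 0 < r < test_day:
                reminders.append(r)
        return build_schedule(self.name, test_day, reminders, horizon_T)


# Negative-prediction-error learning rates per condition: 0.07 standard
# housing (empirical fit), 0 enrichment (empirical fit; 0.01 simulation
# variant), 0.01 Rac1 inhibition, 0.5 Rac1 activation and context-only
# (simulation values), reminder condition re-uses the standard rate with a
# presence event the day before the test.
_PRESETS: dict[str, ConditionPreset] = {
    "standard": ConditionPreset("standard", alpha_neg=0.07),
    "enrichment": ConditionPreset("enrichment", alpha_neg=0.0),
    "enrichment_sim": ConditionPreset("enrichment_sim", alpha_neg=0.01),
    "rac1_inhibition": ConditionPreset("rac1_inhibition", alpha_neg=0.01),
    "rac1_activation": ConditionPreset("rac1_activation", alpha_neg=0.5),
    "context_only": ConditionPreset("context_only", alpha_neg=0.5),
    "reminder": ConditionPreset("reminder", alpha_neg=0.07, reminder_offset=1),
}


def condition_presets() -> dict[str, ConditionPreset]:
    """Mapping from condition label to its generative preset."""
    return dict(_PRESETS)


def get_preset(name: str) -> ConditionPreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise UnknownConditionError(
            f"unknown condition {name!r}; known: {sorted(_PRESETS)}"
        ) from None
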