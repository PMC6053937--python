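"""Coding of behavioural event logs from playback trials into response variables.

A playback trial yields a timestamped event log (as exported from video
annotation).  Response variables follow the field convention:

* ``responded`` — any new behaviour (head-up, scratch, other behavioural
  change) starting within 10 s after playback onset.  The window is the
  closed interval (onset, onset + 10]: an event at exactly +10 s counts.
  Resuming or continuing foraging is not a response; ``forage_start`` /
  ``forage_end`` and ``head_up_end`` are bookkeeping events.
* ``latency_s`` — time from onset to the first qualifying event.
* ``duration_s`` — time from onset to the start of the first post-onset
  foraging interval lasting at least 10 s ("foraging resumed").  Trials
  where foraging never resumes within the log are flagged censored, not
  imputed.
* ``n_head_ups`` / ``n_scratches`` — counts over the observation window.
* ``headlift_speed`` — consumed as a supplied measurement, not derived here.

All quantities are invariant to shifting the log's time origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONSE_EVENTS = {"head_up_start", "scratch", "other_behaviour_change"}
EVENT_KINDS = RESPONSE_EVENTS | {"head_up_end", "forage_start", "forage_end"}
RESPONSE_WINDOW_S = 10.0

__all__ = [
    "EventLog",
    "ResponseRecord",
    "code_binary_response",
    "code_continuous_response",
    "pretrial_relaxation_filter",
    "code_trials",
    "logs_from_frame",
]


@dataclass
class EventLog:
    """Timestamped behaviour log for one playback trial.

    ``events`` is a list of ``(time_s, kind)`` with non-decreasing times;
    kinds outside the known vocabulary raise at validation.  ``headlift_speed``
    is an optional externally measured angular speed.
    """

    trial_id: object
    onset: float
    events: list = field(default_factory=list)
    headlift_speed: float | None = None

    def validate(self) -> None:
        if self.onset < 0:
            raise ValueError(f"trial {self.trial_id}: onset must be >= 0")
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"trial {self.trial_id}: event times must be non-decreasing")
        bad = {k for _, k in self.events} - EVENT_KINDS
        if bad:
            raise ValueError(f"trial {self.trial_id}: unknown event kinds {sorted(bad)}")
        for kind in ("head_up", "forage"):
            depth = 0
            for _, k in self.events:
                if k == f"{kind}_start":
                    depth += 1
                elif k == f"{kind}_end":
                    depth -= 1
                if depth not in (0, 1):
                    raise ValueError(
                        f"trial {self.trial_id}: improperly nested {kind} intervals")


@dataclass
class ResponseRecord:
    """Coded response variables for one trial (NaN fields = undefined)."""

    trial_id: object
    responded: bool
    latency_s: float = np.nan
    duration_s: float = np.nan
    duration_censored: bool = False
    headlift_speed: float = np.nan
    n_head_ups: int = 0
    n_scratches: int = 0


def _forage_intervals(log: EventLog) -> list[tuple[float, float]]:
    """Closed forage intervals (start, end); an unclosed final interval ends at
    the last event time."""
    out, start = [], None
    last_t = log.onset
    for t, k in log.events:
        last_t = max(last_t, t)
        if k == "forage_start":
            start = t
        elif k == "forage_end" and start is not None:
            out.append((start, t))
            start = None
    if start is not None:
        out.append((start, last_t))
    return out


def code_binary_response(log: EventLog, window: float = RESPONSE_WINDOW_S) -> bool:
    """True iff a qualifying behaviour starts in (onset, onset + window]."""
    log.validate()
    return any(
        log.onset < t <= log.onset + window and k in RESPONSE_EVENTS
        for t, k in log.events
    )


def code_continuous_response(log: EventLog, window: float = RESPONSE_WINDOW_S,
                             min_forage: float = 10.0) -> ResponseRecord:
    """Full response coding for one trial.

    When ``responded`` is False, latency, duration and head-lift speed are
    undefined (NaN) and counts are taken over the post-onset window anyway
    (they will be zero for a truly undisturbed animal).
    """
    log.validate()
    responded = code_binary_response(log, window=window)
    rec = ResponseRecord(trial_id=log.trial_id, responded=responded)
    post = [(t, k) for t, k in log.events if t > log.onset]
    rec.n_head_ups = sum(1 for _, k in post if k == "head_up_start")
    rec.n_scratches = sum(1 for _, k in post if k == "scratch")
    if not responded:
        return rec
    rec.latency_s = min(
        t for t, k in post if k in RESPONSE_EVENTS and t <= log.onset + window
    ) - log.onset
    if log.headlift_speed is not None:
        rec.headlift_speed = float(log.headlift_speed)
    resumed = [
        (s, e) for s, e in _forage_intervals(log)
        if s > log.onset and e - s >= min_forage
    ]
    if resumed:
        rec.duration_s = resumed[0][0] - log.onset
    else:
        rec.duration_censored = True
    return rec


def pretrial_relaxation_filter(log: EventLog, min_forage: float = 20.0) -> bool:
    """True iff the animal foraged continuously for >= min_forage s up to onset.

    Used to screen trials: playbacks target relaxed, foraging animals.
    """
    log.validate()
    return any(
        s <= log.onset - min_forage and e >= log.onset
        for s, e in _forage_intervals(log)
    )


def code_trials(logs: list[EventLog]) -> pd.DataFrame:
    """Code a batch of logs; one ResponseRecord row per trial."""
    rows = [vars(code_continuous_response(log)) for log in logs]
    return pd.DataFrame(rows)


def logs_from_frame(events: pd.DataFrame, onsets: pd.Series,
                    headlift: pd.Series | None = None) -> list[EventLog]:
    """Assemble EventLogs from a tidy event table (trial_id, time_s, event)."""
    logs = []
    for trial_id, grp in events.groupby("trial_id", sort=False):
        grp = grp.sort_values("time_s", kind="stable")
        logs.append(EventLog(
            trial_id=trial_id,
            onset=float(onsets[trial_id]),
            events=list(zip(grp["time_s"].astype(float), grp["event"])),
            headlift_speed=(None if headlift is None or trial_id not in headlift
                            or pd.isna(headlift[trial_id])
                            else float(headlift[trial_id])),
        ))
    return logs
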