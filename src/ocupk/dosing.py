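"""Treatment regimens and instantaneous dose resets.

A :class:`Regimen` is an ordered list of :class:`TreatmentEvent` (drops,
drug-eluting lens insertion/removal, intravitreal injections) over a
simulation horizon.  Doses act instantaneously: a drop merges with the
tear film and mixes before the excess volume runs off; an injection adds
its drug amount to the (unchanged) vitreal volume; a lens pins the tear
drug concentration while worn.

Times are *global* simulation hours.  The governing equations see *local*
time, reset to zero at each drop because the tear-volume law depends on
the time since the last drop; the simulator handles that bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .model import EyeState
from .params import ParameterSet

__all__ = [
    "TreatmentEvent",
    "Regimen",
    "apply_drop",
    "apply_injection",
    "apply_lens",
    "build_standard_regimen",
]

EVENT_KINDS = ("drop", "injection", "lens_on", "lens_off")

HOURS_PER_DAY = 24.0
HOURS_PER_WEEK = 168.0


@dataclass(frozen=True)
class TreatmentEvent:
    """A single treatment action at a global time (h)."""

    time: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass(frozen=True)
class Regimen:
    """An ordered treatment schedule over ``[0, t_end]`` hours."""

    events: tuple[TreatmentEvent, ...]
    t_end: float

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: (e.time, EVENT_KINDS.index(e.kind))))
        object.__setattr__(self, "events", events)
        if events and self.t_end < events[-1].time:
            raise ValueError("t_end must not precede the last event time")
        self._validate()

    def _validate(self) -> None:
        last_drop = None
        lens_worn = False
        for ev in self.events:
            if ev.kind == "drop":
                if last_drop is not None and ev.time - last_drop < 0:
                    raise ValueError("drop events out of order")
                last_drop = ev.time
            elif ev.kind == "lens_on":
                if lens_worn:
                    raise ValueError("lens_on while a lens is already worn")
                lens_worn = True
            elif ev.kind == "lens_off":
                if not lens_worn:
                    raise ValueError("lens_off without a preceding lens_on")
                lens_worn = False

    def validate_drop_spacing(self, tau_loss: float) -> None:
        """Consecutive drops must be separated by at least ``tau_loss`` so
        the tear volume has returned to baseline before the next drop."""
        drops = [e.time for e in self.events if e.kind == "drop"]
        for a, b in zip(drops, drops[1:]):
            if b - a < tau_loss:
                raise ValueError(f"drops at {a} h and {b} h closer than tau_loss={tau_loss} h")

    def kinds(self) -> set[str]:
        return {e.kind for e in self.events}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"t_end_h": self.t_end, "events": [{"time_h": e.time, "kind": e.kind} for e in self.events]},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "Regimen":
        d = json.loads(text)
        return cls(tuple(TreatmentEvent(e["time_h"], e["kind"]) for e in d["events"]), d["t_end_h"])


# -- dose resets ----------------------------------------------------------


def apply_drop(state: EyeState, params: ParameterSet) -> EyeState:
    """Instantaneous tear-film reset on applying an eye drop.

    Human (in vivo): the drop merges and mixes with the normal tear film,
    so the new concentration is the volume-weighted average of the old
    film and the dose; the volume jumps to the reservoir volume and the
    excess runs off after mixing.  Ex vivo porcine: there is no resident
    film, so the tear takes the full drop volume at the dose concentration.
    """
    if params.species == "porcine":
        return state.replace(V_tear=params.V_drop, r_tear=params.r_dose)
    V_n, V_d = params.V_tear_norm, params.V_drop
    r_new = (state.r_tear * V_n + params.r_dose * V_d) / (V_n + V_d)
    return state.replace(V_tear=params.V_tear_res, r_tear=r_new)


def apply_injection(state: EyeState, params: ParameterSet) -> EyeState:
    """Intravitreal bolus: the dose equilibrates through the vitreous,
    raising the drug concentration by ``r_dose * V_drop / V_vit`` (the
    injected volume is negligible relative to the vitreous)."""
    return state.replace(r_vit=state.r_vit + params.r_dose * params.V_drop / params.V_vit)


def apply_lens(state: EyeState, params: ParameterSet, on: bool) -> EyeState:
    """Drug-eluting lens insertion (``on=True``) or removal.

    Insertion pins the tear concentration at ``r_tear_init`` (the lens
    elutes at the rate needed to hold it there); removal leaves the
    current concentration to decay freely.  The accompanying change of
    tear mode (held_constant vs depleting) is handled by the simulator.
    """
    if on:
        return state.replace(V_tear=params.V_tear_norm, r_tear=params.r_tear_init)
    return state.replace(V_tear=params.V_tear_norm)


# -- standard regimen builders -------------------------------------------


def daily_drops(n_drop: int, n_days: int, t_end: float) -> Regimen:
    """``n_drop`` drops per day for ``n_days`` days: the first drop of each
    day at 0 h, subsequent drops every ``16 / n_drop`` h (a 16-hour waking
    day)."""
    if not 1 <= n_drop <= 16:
        raise ValueError("n_drop must be in [1, 16]")
    spacing = 16.0 / n_drop
    events = [
        TreatmentEvent(day * HOURS_PER_DAY + k * spacing, "drop")
        for day in range(n_days)
        for k in range(n_drop)
    ]
    return Regimen(tuple(events), t_end)


def hourly_drops(n_days: int, t_end: float) -> Regimen:
    """One drop on the hour, every hour of the day (24 per day)."""
    events = [TreatmentEvent(float(h), "drop") for h in range(int(n_days * 24))]
    return Regimen(tuple(events), t_end)


def lens_cycles(n_day: int, n_cycles: int, t_end: float, start_day: float = 0.0) -> Regimen:
    """Lenses worn ``n_day`` days at a time with a 1-day break between
    them, the first inserted at ``start_day``."""
    if not 1 <= n_day <= 30:
        raise ValueError("n_day must be in [1, 30]")
    events = []
    for c in range(n_cycles):
        on = (start_day + c * (n_day + 1)) * HOURS_PER_DAY
        events.append(TreatmentEvent(on, "lens_on"))
        events.append(TreatmentEvent(on + n_day * HOURS_PER_DAY, "lens_off"))
    return Regimen(tuple(events), t_end)


def periodic_injections(interval_weeks: float, t_end: float, n_max: int | None = None) -> Regimen:
    """Injections every ``interval_weeks`` weeks, the first at the start of
    week 1 (global time 0)."""
    if not 1 <= interval_weeks <= 8:
        raise ValueError("interval_weeks must be in [1, 8]")
    events = []
    t = 0.0
    while t < t_end and (n_max is None or len(events) < n_max):
        events.append(TreatmentEvent(t, "injection"))
        t += interval_weeks * HOURS_PER_WEEK
    return Regimen(tuple(events), t_end)


def merge(a: Regimen, b: Regimen, t_end: float | None = None) -> Regimen:
    """Combine two schedules.  A drop and an injection at the same instant
    are both applied, drop first (they reset disjoint variables, so the
    order is a determinism convention only)."""
    t_end = max(a.t_end, b.t_end) if t_end is None else t_end
    return Regimen(a.events + b.events, t_end)


def weekly_lens_weeks(n_weeks: int, t_end: float) -> Regimen:
    """Lens worn 6 days a week (days 2-7 of each week), per week for
    ``n_weeks`` weeks -- the longest wear compatible with weekly
    injection days."""
    events = []
    for wk in range(n_weeks):
        on = wk * HOURS_PER_WEEK + 1 * HOURS_PER_DAY  # start of day 2
        events.append(TreatmentEvent(on, "lens_on"))
        events.append(TreatmentEvent(on + 6 * HOURS_PER_DAY, "lens_off"))
    return Regimen(tuple(events), t_end)


def build_standard_regimen(name: str, **options) -> Regimen:
    """Named treatment schedules used throughout the human predictions.

    ``drops_daily``
        ``n_drop`` drops/day (default 16) for ``n_days`` days (default 14),
        horizon ``t_end`` (default 21 days).
    ``lens_cycle``
        ``n_day``-day lenses (default 30) with 1-day breaks, ``n_cycles``
        (default 4), horizon default 152 days.
    ``injections``
        every ``interval_weeks`` (default 4) with default horizon 16 weeks.
    ``drops+injections``
        4-weekly injections plus ``n_drop`` drops/day throughout.
    ``lens+injections``
        injections plus 6-day lens weeks (lens on days 2-7).
    ``single_dose``
        one event of ``kind`` at t = 0, horizon ``t_end``.
    """
    if name == "drops_daily":
        n_drop = options.get("n_drop", 16)
        n_days = options.get("n_days", 14)
        t_end = options.get("t_end", 21 * HOURS_PER_DAY)
        return daily_drops(n_drop, n_days, t_end)
    if name == "lens_cycle":
        n_day = options.get("n_day", 30)
        n_cycles = options.get("n_cycles", 4)
        t_end = options.get("t_end", (n_cycles * (n_day + 1) + 28) * HOURS_PER_DAY)
        return lens_cycles(n_day, n_cycles, t_end, options.get("start_day", 0.0))
    if name == "injections":
        weeks = options.get("interval_weeks", 4)
        t_end = options.get("t_end", 16 * HOURS_PER_WEEK)
        return periodic_injections(weeks, t_end, options.get("n_max"))
    if name == "drops+injections":
        weeks = options.get("interval_weeks", 4)
        treated_weeks = options.get("treated_weeks", 16)
        t_end = options.get("t_end", (treated_weeks + 4) * HOURS_PER_WEEK)
        inj = periodic_injections(weeks, treated_weeks * HOURS_PER_WEEK)
        n_drop = options.get("n_drop", 16)
        drops = daily_drops(n_drop, treated_weeks * 7, t_end)
        return merge(drops, inj, t_end)
    if name == "lens+injections":
        weeks = options.get("interval_weeks", 4)
        treated_weeks = options.get("treated_weeks", 16)
        t_end = options.get("t_end", (treated_weeks + 4) * HOURS_PER_WEEK)
        inj = periodic_injections(weeks, treated_weeks * HOURS_PER_WEEK)
        lens = weekly_lens_weeks(treated_weeks, t_end)
        return merge(lens, inj, t_end)
    if name == "single_dose":
        kind = options.get("kind", "injection")
        t_end = options.get("t_end", 4 * HOURS_PER_WEEK)
        events = (TreatmentEvent(0.0, "lens_on"),) if kind == "lens" else (TreatmentEvent(0.0, kind),)
        return Regimen(events, t_end)
    raise ValueError(f"unknown regimen name {name!r}")
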