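"""Late fusion of the three component outputs into monthly alarms.

All ICF categories are weighted equally: the alarm is the logical OR of
the available components' change flags (C1 v C2 v C3). A component that
is unavailable for a resident (e.g. body functions for someone who does
not cook) is *skipped*, never treated as "no change" — absence of
evidence cannot suppress or cause an alarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import ComponentOutput, FuncmonError

ALL_COMPONENTS = (1, 2, 3)

#: ICF items produced by each component.
COMPONENT_ITEMS = {1: ("d450", "d460"), 2: ("b530",), 3: ("e115", "e245")}


@dataclass(frozen=True)
class AvailabilityMask:
    """Which components (hence ICF items) exist for one resident.

    Components 1 and 3 are installed for everyone; component 2 only for
    residents who prepare meals themselves.
    """

    components: frozenset = frozenset(ALL_COMPONENTS)

    def __post_init__(self) -> None:
        comps = frozenset(int(c) for c in self.components)
        if not comps <= set(ALL_COMPONENTS):
            raise ValueError(f"unknown components {sorted(comps - set(ALL_COMPONENTS))}")
        if not {1, 3} <= comps:
            raise ValueError("components 1 and 3 are always available")
        object.__setattr__(self, "components", comps)

    @property
    def icf_items(self) -> frozenset:
        return frozenset(i for c in self.components for i in COMPONENT_ITEMS[c])


def fuse_metric(
    c1: Optional[int], c2: Optional[int], c3: Optional[int]
) -> int:
    """Boolean OR over the *present* component flags; ``None`` = absent.

    Raises when every component is absent: an alarm decision needs at
    least one piece of evidence.
    """
    flags = [c for c in (c1, c2, c3) if c is not None]
    if not flags:
        raise FuncmonError("all components absent; fusion undefined")
    if any(f not in (0, 1) for f in flags):
        raise ValueError("component flags must be 0 or 1")
    return 1 if any(flags) else 0


@dataclass(frozen=True)
class MonthlyReport:
    """One assessment period's component outputs and the fused alarm."""

    participant: str
    period: tuple
    components: Mapping[int, Optional[ComponentOutput]]
    alarm: int

    def attributions(self) -> "list[str]":
        items: set = set()
        for out in self.components.values():
            if out is not None and out.available and out.flag:
                items |= out.icf_items
        return sorted(items)

    def to_dict(self) -> dict:
        comps = {}
        for c in ALL_COMPONENTS:
            out = self.components.get(c)
            if out is None or not out.available:
                comps[f"c{c}"] = None
            else:
                comps[f"c{c}"] = out.to_dict()
        return {
            "participant": self.participant,
            "period": list(self.period),
            "components": comps,
            "alarm": self.alarm,
        }


def build_report(
    outputs_by_period: Sequence[Mapping[int, Optional[ComponentOutput]]],
    mask: AvailabilityMask,
    participant: str = "participant",
) -> "list[MonthlyReport]":
    """Fuse per-period component outputs into monthly alarm reports.

    ``outputs_by_period`` holds, per consecutive period pair (T, T+1),
    the outputs of components 1..3 (missing/None allowed). Components
    outside the availability mask are dropped; component outputs marked
    unavailable are skipped by the fusion. Periods recorded on the
    outputs must agree with their position in the sequence.
    """
    reports = []
    for i, outs in enumerate(outputs_by_period):
        period = (i, i + 1)
        comps: dict = {}
        for c in ALL_COMPONENTS:
            out = outs.get(c)
            if out is not None and out.period[1] != period[1]:
                raise FuncmonError(
                    f"component {c} output for period {out.period} misaligned "
                    f"with report slot {period}"
                )
            if c not in mask.components:
                out = None
            comps[c] = out
        flags = {
            c: (out.flag if out is not None and out.available else None)
            for c, out in comps.items()
        }
        alarm = fuse_metric(flags[1], flags[2], flags[3])
        reports.append(
            MonthlyReport(participant=participant, period=period, components=comps, alarm=alarm)
        )
    return reports


def render_timeline(reports: Sequence[MonthlyReport]) -> str:
    """Plain-text month-by-month timeline of component flags and alarms."""
    lines = [f"Participant: {reports[0].participant}" if reports else "Participant: -"]
    header = f"{'period':>8} {'C1':>4} {'C2':>4} {'C3':>4} {'alarm':>6}  items"
    lines.append(header)
    lines.append("-" * len(header))
    for r in reports:
        cells = []
        for c in ALL_COMPONENTS:
            out = r.components.get(c)
            if out is None or not out.available:
                cells.append("-")
            else:
                cells.append(str(out.flag))
        items = ",".join(r.attributions()) or "-"
        lines.append(
            f"T{r.period[0]}-T{r.period[1]:<4} {cells[0]:>4} {cells[1]:>4} "
            f"{cells[2]:>4} {r.alarm:>6}  {items}"
        )
    return "\n".join(lines)
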