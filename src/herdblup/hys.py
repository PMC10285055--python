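"""Herd-year-season contemporary-group labels.

The season index is derived from the calving date: calendar quarters by default
(the paper-era default for seasonal grouping in these herds), with half-year and
monthly alternatives.  Labels are `herd|year|season` and deterministic.
"""

from __future__ import annotations

import datetime as _dt

__all__ = ["make_hys", "SEASON_RULES"]

SEASON_RULES = ("quarter", "half", "month")


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"unparseable ISO calving date {value!r}") from exc


def make_hys(herd: str, calving_date, season_rule: str = "quarter") -> str:
    """`herd|year|season` label for one record; ISO dates only."""
    if season_rule not in SEASON_RULES:
        raise ValueError(f"unknown season rule {season_rule!r}; choose from {SEASON_RULES}")
    d = _parse_date(calving_date)
    if season_rule == "quarter":
        season = (d.month - 1) // 3 + 1
    elif season_rule == "half":
        season = (d.month - 1) // 6 + 1
    else:
        season = d.month
    return f"{herd}|{d.year}|{season}"
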