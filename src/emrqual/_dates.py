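"""Anniversary (civil calendar) date arithmetic.

All study windows are half-open ``[start, end)`` at day granularity.
"One year" always means an anniversary year: the same month/day in the
following calendar year, with a Feb 29 start rolling forward to Mar 1 in
non-leap years.  Anniversary windows do not drift over long spans the way
fixed 365-day windows do.
"""

from __future__ import annotations

import datetime as dt

__all__ = ["add_years", "full_years_between", "DateWindow"]

DateWindow = tuple[dt.date, dt.date]


def add_years(d: dt.date, n: int) -> dt.date:
    """Return the n-th anniversary of *d* (n may be negative).

    Feb 29 anniversaries roll forward to Mar 1 in non-leap years.
    """
    try:
        return d.replace(year=d.year + n)
    except ValueError:  # Feb 29 in a non-leap target year
        return dt.date(d.year + n, 3, 1)


def full_years_between(start: dt.date, end: dt.date) -> int:
    """Number of complete anniversary years from *start* to *end*.

    Largest k >= 0 with ``add_years(start, k) <= end``; 0 if end < start.
    """
    if end < start:
        return 0
    k = end.year - start.year  # upper bound
    while k > 0 and add_years(start, k) > end:
        k -= 1
    return k
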