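"""Anomaly computation, kinetic energy, and time-slot slicing.

Monthly climatology (the mean of all Januaries, all Februaries, ...) is
removed first, then a per-cell ordinary-least-squares linear trend; the two
operations only commute approximately, so the order is fixed for
reproducibility.  Both are idempotent projections.
"""
from __future__ import annotations

import numpy as np

from .grid import GriddedField, TimeSlot

__all__ = [
    "deseasonalize", "detrend", "anomalies", "kinetic_energy",
    "slice_field", "make_timeslots",
]


def deseasonalize(field: GriddedField) -> GriddedField:
    """Subtract the per-cell monthly climatology.

    Requires at least 24 months so every calendar month has two samples.  A
    pure 12-month sinusoid (or any function of calendar month alone) maps to
    exactly zero.
    """
    if field.n_time < 24:
        raise ValueError(
            f"deseasonalize needs at least 2 full years (24 months), got {field.n_time}"
        )
    out = field.values.copy()
    months = field.months
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            out[sel] -= out[sel].mean(axis=0)
    return field.with_values(out)


def detrend(field: GriddedField) -> GriddedField:
    """Remove the per-cell OLS linear fit against the month index.

    The intercept (cell mean) is removed together with the slope, so an
    exactly linear series maps to zero.
    """
    if field.n_time < 3:
        raise ValueError("detrend needs at least 3 time points")
    T = field.n_time
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    flat = field.values.reshape(T, -1)
    mean = flat.mean(axis=0)
    slope = tc @ (flat - mean) / denom
    resid = flat - mean - np.outer(tc, slope)
    return field.with_values(resid.reshape(field.values.shape))


def anomalies(field: GriddedField) -> GriddedField:
    """Climatology removal followed by linear detrending."""
    return detrend(deseasonalize(field))


def kinetic_energy(u: GriddedField, v: GriddedField) -> GriddedField:
    """Kinetic energy per unit mass, 0.5 * (u^2 + v^2), in m2/s2."""
    if not u.congruent(v):
        raise ValueError("u and v are not on the same grid/time axis")
    return u.with_values(0.5 * (u.values**2 + v.values**2), units="m2 s-2")


def slice_field(field: GriddedField, slot: TimeSlot) -> GriddedField:
    """Restrict a field to the months of a time slot (12 * delta months)."""
    sel = slot.contains_years(field.years)
    n = int(sel.sum())
    if n != slot.n_months:
        raise ValueError(
            f"slot {slot} not fully inside the dataset span "
            f"({field.years.min()}-{field.years.max()}): found {n} of {slot.n_months} months"
        )
    return GriddedField(
        field.values[sel], field.time[sel], field.lat, field.lon, field.mask, field.units
    )


def make_timeslots(y0: int, y_last: int, delta: int, breakpoints=()) -> list:
    """All delta-year slots sliding yearly across [y0, y_last].

    ``breakpoints`` split the record into trend periods; a slot overlapping a
    period other than its home period (the one it shares most years with) by
    more than one year is excluded.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    bps = sorted(breakpoints)
    edges = [y0] + bps + [y_last + 1]
    periods = list(zip(edges[:-1], edges[1:]))
    slots = []
    for start in range(y0, y_last - delta + 2):
        slot = TimeSlot(start, delta)
        overlaps = sorted((slot.overlap_years(a, b) for a, b in periods), reverse=True)
        if len(overlaps) > 1 and overlaps[1] > 1:
            continue
        slots.append(slot)
    return slots
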