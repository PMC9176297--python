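"""Piecewise-constant rate maps along the genome.

A :class:`RateMap` assigns a non-negative per-unit, per-generation rate to
each interval of a genome of length ``L``.  It is the common currency for
recombination, gene-conversion initiation and mutation rates.
"""
from __future__ import annotations

import numpy as np

__all__ = ["RateMap"]


class RateMap:
    """Piecewise-constant rate over ``[0, sequence_length)``.

    Parameters
    ----------
    breakpoints:
        Ascending coordinates, starting at 0 and ending at the sequence
        length.  ``len(breakpoints) == len(rates) + 1``.
    rates:
        Per-unit, per-generation rates, one per interval; all ``>= 0``.
    """

    def __init__(self, breakpoints, rates):
        self.breakpoints = np.asarray(breakpoints, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.breakpoints.ndim != 1 or self.rates.ndim != 1:
            raise ValueError("breakpoints and rates must be 1-D")
        if len(self.breakpoints) != len(self.rates) + 1:
            raise ValueError("need len(breakpoints) == len(rates) + 1")
        if self.breakpoints[0] != 0:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        # cumulative mass at each breakpoint
        self._cum = np.concatenate(
            [[0.0], np.cumsum(self.rates * np.diff(self.breakpoints))]
        )

    @classmethod
    def uniform(cls, sequence_length, rate):
        return cls([0.0, float(sequence_length)], [float(rate)])

    @property
    def sequence_length(self) -> float:
        return float(self.breakpoints[-1])

    @property
    def total_mass(self) -> float:
        return float(self._cum[-1])

    def mass(self, left: float, right: float) -> float:
        """Integral of the rate over ``[left, right]``; 0 if right <= left."""
        if right <= left:
            return 0.0
        return self._cum_at(right) - self._cum_at(left)

    def _cum_at(self, x: float) -> float:
        x = min(max(x, 0.0), self.sequence_length)
        i = np.searchsorted(self.breakpoints, x, side="right") - 1
        i = min(i, len(self.rates) - 1)
        return float(self._cum[i] + self.rates[i] * (x - self.breakpoints[i]))

    def position_of_mass(self, left: float, m: float) -> float:
        """Position ``x >= left`` such that ``mass(left, x) == m``.

        Requires ``0 <= m <= mass(left, L)`` and a strictly positive rate
        over the relevant region (zero-rate stretches are skipped).
        """
        target = self._cum_at(left) + m
        i = int(np.searchsorted(self._cum, target, side="left")) - 1
        i = min(max(i, 0), len(self.rates) - 1)
        # skip zero-rate intervals
        while self.rates[i] == 0 and i < len(self.rates) - 1:
            i += 1
        if self.rates[i] == 0:
            raise ValueError("mass exceeds available rate mass")
        x = self.breakpoints[i] + (target - self._cum[i]) / self.rates[i]
        return float(min(x, self.sequence_length))

    def __eq__(self, other):
        return (
            isinstance(other, RateMap)
            and np.array_equal(self.breakpoints, other.breakpoints)
            and np.array_equal(self.rates, other.rates)
        )

    def __repr__(self):
        return f"RateMap({self.breakpoints.tolist()}, {self.rates.tolist()})"
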