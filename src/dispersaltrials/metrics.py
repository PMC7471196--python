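"""Point measures of passive dispersal and wind-regime bookkeeping.

A dispersal-tunnel trial starts with ``N`` individuals on a source patch.
After the trial, the individuals remaining on the source are recounted and
the dispersers are obtained by subtraction, ``D = N - remaining``.  An
unknown number of founders ``F`` settle on the target patch; after an
incubation period the colonizer population ``C`` on the target is counted.

Four quantities summarize the process:

* dispersal rate            q = D / N
* dispersal effectiveness   p = F / D
* population growth rate    r = log2(C / F + 1)
* colonization potential    k = C / D  =  p * (2**r - 1)

The growth rate is defined so that r = 1 means the population did not
change over the incubation, r > 1 it grew, r < 1 it shrank, and r = 0
means the colonizers went extinct (C = 0).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "TrialRecord",
    "WindRegime",
    "dispersal_rate",
    "dispersal_effectiveness",
    "population_growth_rate",
    "colonization_potential",
    "colonization_potential_from_effectiveness",
    "summarize_regime",
]


def _check_count(value, name: str) -> int:
    if isinstance(value, bool) or value != int(value):
        raise ValueError(f"{name} must be an integer count, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class TrialRecord:
    """Counts from a single dispersal-tunnel replicate.

    The disperser count is derived (``n_source - n_remaining``) because it
    is measured by subtraction; use :meth:`from_dispersers` to construct a
    record from a directly known disperser count (e.g. simulator output).
    """

    trial_id: str
    n_source: int
    n_remaining: int
    n_colonizers: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_source", _check_count(self.n_source, "n_source"))
        object.__setattr__(self, "n_remaining", _check_count(self.n_remaining, "n_remaining"))
        object.__setattr__(self, "n_colonizers", _check_count(self.n_colonizers, "n_colonizers"))
        if self.n_remaining > self.n_source:
            raise ValueError(
                f"trial {self.trial_id!r}: n_remaining ({self.n_remaining}) "
                f"exceeds n_source ({self.n_source})"
            )

    @classmethod
    def from_dispersers(
        cls, trial_id: str, n_source: int, dispersers: int, n_colonizers: int
    ) -> "TrialRecord":
        dispersers = _check_count(dispersers, "dispersers")
        if dispersers > n_source:
            raise ValueError(
                f"trial {trial_id!r}: dispersers ({dispersers}) exceed n_source ({n_source})"
            )
        return cls(trial_id, n_source, n_source - dispersers, n_colonizers)

    @property
    def dispersers(self) -> int:
        """Derived disperser count D = N - remaining."""
        return self.n_source - self.n_remaining


def dispersal_rate(dispersers: int, population: int) -> float:
    """Proportion of the source population that departed, q = D/N."""
    dispersers = _check_count(dispersers, "dispersers")
    population = _check_count(population, "population")
    if population == 0:
        raise ValueError("dispersal rate undefined for an empty source population")
    if dispersers > population:
        raise ValueError(
            f"dispersers ({dispersers}) cannot exceed population ({population})"
        )
    return dispersers / population


def dispersal_effectiveness(founders: int, dispersers: int) -> float:
    """Proportion of dispersers that founded the target population, p = F/D."""
    founders = _check_count(founders, "founders")
    dispersers = _check_count(dispersers, "dispersers")
    if dispersers == 0:
        raise ValueError("dispersal effectiveness undefined when no individuals dispersed")
    if founders > dispersers:
        raise ValueError(f"founders ({founders}) cannot exceed dispersers ({dispersers})")
    return founders / dispersers


def population_growth_rate(colonizers: int, founders: int) -> float:
    """Growth of the colonizing population, r = log2(C/F + 1).

    r = 1 means no change over the incubation; r = 0 means extinction.
    """
    colonizers = _check_count(colonizers, "colonizers")
    founders = _check_count(founders, "founders")
    if founders == 0:
        raise ValueError("growth rate undefined without founders")
    return math.log2(colonizers / founders + 1.0)


def colonization_potential(colonizers: int, dispersers: int) -> float:
    """Colonizers per disperser, k = C/D.

    Algebraically identical to ``p * (2**r - 1)`` with p = F/D and
    r = log2(C/F + 1) for any founder count 0 < F <= D.
    """
    colonizers = _check_count(colonizers, "colonizers")
    dispersers = _check_count(dispersers, "dispersers")
    if dispersers == 0:
        raise ValueError("colonization potential undefined when no individuals dispersed")
    return colonizers / dispersers


def colonization_potential_from_effectiveness(p: float, r: float) -> float:
    """Colonization potential from effectiveness and growth, k = p * (2**r - 1)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"effectiveness p must lie in [0, 1], got {p}")
    if r < 0:
        raise ValueError(f"growth rate r must be non-negative, got {r}")
    return p * (2.0**r - 1.0)


# --------------------------------------------------------------------------
# Wind-regime bookkeeping
# --------------------------------------------------------------------------

_TOKEN = re.compile(r"^(\d+(?:\.\d+)?)(?:/(\d+(?:\.\d+)?))?$")


@dataclass(frozen=True)
class WindRegime:
    """Ordered sequence of (minutes blowing, minutes still) phases.

    The final phase of an intermittent schedule may have no still segment;
    it is stored with ``off = 0``.
    """

    phases: tuple = field(default=())

    def __post_init__(self) -> None:
        norm = []
        for phase in self.phases:
            if isinstance(phase, (int, float)):
                on, off = float(phase), 0.0
            else:
                on = float(phase[0])
                off = float(phase[1]) if len(phase) > 1 and phase[1] is not None else 0.0
            if on < 0 or off < 0:
                raise ValueError(f"phase durations must be non-negative, got {phase!r}")
            norm.append((on, off))
        object.__setattr__(self, "phases", tuple(norm))

    @classmethod
    def parse(cls, text: str) -> "WindRegime":
        """Parse a token list such as ``"5/55 15/45 30/30 180"``.

        Each token is ``on/off`` minutes; a bare ``on`` token has no still
        segment (used for a trailing blowing phase).
        """
        phases = []
        for token in text.split():
            m = _TOKEN.match(token)
            if m is None:
                raise ValueError(f"malformed regime token {token!r}")
            on = float(m.group(1))
            off = float(m.group(2)) if m.group(2) is not None else 0.0
            phases.append((on, off))
        return cls(tuple(phases))


def summarize_regime(regime: WindRegime) -> dict:
    """Total blowing, still, and overall minutes of an intermittent schedule."""
    on_total = sum(on for on, _ in regime.phases)
    off_total = sum(off for _, off in regime.phases)
    return {
        "on_total": on_total,
        "off_total": off_total,
        "grand_total": on_total + off_total,
    }
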