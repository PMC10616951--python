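"""Stimulation-index analysis of T-cell proliferation assays.

Proliferation is read out as scintillation counts per minute (cpm) of
tritiated-thymidine incorporation, in triplicate wells, for each donor x
stimulus x day. The stimulation index (SI) is the mean cpm of stimulated
cultures divided by the mean cpm of the medium-only control for the same
donor and day; a donor is called a responder to a stimulus when SI exceeds
a threshold (strictly greater than 2 by convention, on day 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PairingError


@dataclass(frozen=True)
class ProliferationRecord:
    """Replicate cpm values for one donor x stimulus x day."""

    donor_id: str
    stimulus_id: str
    day: int
    cpm: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpm", tuple(float(c) for c in self.cpm))
        if len(self.cpm) < 1:
            raise ValueError("at least one replicate required")
        if any(c < 0 for c in self.cpm):
            raise ValueError(f"negative cpm in {self.cpm}")

    @property
    def mean_cpm(self) -> float:
        return float(np.mean(self.cpm))

    @property
    def cv(self) -> float:
        m = self.mean_cpm
        return float(np.std(self.cpm, ddof=1) / m) if m > 0 and len(self.cpm) > 1 else 0.0


@dataclass(frozen=True)
class SIResult:
    donor_id: str
    stimulus_id: str
    day: int
    si: float
    responder: bool
    threshold: float = 2.0


def stimulation_index(
    test: ProliferationRecord,
    control: ProliferationRecord,
    threshold: float = 2.0,
    max_cv: float | None = None,
) -> SIResult:
    """SI = mean(test cpm) / mean(medium-control cpm); responder iff SI > threshold.

    Replicates are aggregated by the arithmetic mean. The test and control
    records must come from the same donor and day. ``max_cv`` optionally
    raises when either record's replicate coefficient of variation exceeds
    the given value (a quality flag, off by default).
    """
    if test.donor_id != control.donor_id or test.day != control.day:
        raise PairingError(
            f"test ({test.donor_id}, day {test.day}) and control "
            f"({control.donor_id}, day {control.day}) are not paired"
        )
    if control.mean_cpm <= 0:
        raise ZeroDivisionError(
            f"control mean cpm must be positive, got {control.mean_cpm}"
        )
    if max_cv is not None:
        for name, rec in (("test", test), ("control", control)):
            if rec.cv > max_cv:
                raise ValueError(
                    f"{name} replicates CV {rec.cv:.2f} exceeds max_cv {max_cv}"
                )
    si = test.mean_cpm / control.mean_cpm
    return SIResult(
        donor_id=test.donor_id,
        stimulus_id=test.stimulus_id,
        day=test.day,
        si=si,
        responder=si > threshold,
        threshold=threshold,
    )


def percent_responders(results: list[SIResult]) -> float:
    """Percent of donors called responders for one stimulus.

    One result per donor; duplicates indicate an upstream pairing mistake
    and are rejected.
    """
    if not results:
        raise ValueError("percent_responders requires at least one result")
    stimuli = {r.stimulus_id for r in results}
    if len(stimuli) > 1:
        raise PairingError(f"results span stimuli {sorted(stimuli)}")
    donors = [r.donor_id for r in results]
    if len(donors) != len(set(donors)):
        dupes = sorted({d for d in donors if donors.count(d) > 1})
        raise PairingError(f"duplicate donors for stimulus: {dupes}")
    return 100.0 * sum(r.responder for r in results) / len(results)
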