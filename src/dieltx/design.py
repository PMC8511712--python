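"""Diel sampling design: evenly spaced times of day, repeated over days and replicates.

The study design this package targets samples a community every 4 h
(06:00, 10:00, 14:00, 18:00, 22:00, 02:00 local time) over 4 consecutive
days with duplicate samples, i.e. 48 samples and 8 observations per
time-of-day group.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SampleId:
    """One physical sample: (day, hour-of-day, replicate)."""

    day: int
    hour: float
    replicate: int

    def __str__(self) -> str:
        return f"d{self.day}_h{self.hour:05.2f}_r{self.replicate}"


@dataclass(frozen=True)
class SamplingDesign:
    """A diel sampling grid.

    Parameters
    ----------
    times_of_day:
        Sampling hours on a [0, 24) clock, strictly increasing and evenly
        spaced around the cycle (spacing = period_hours / n_times).
    n_days:
        Number of consecutive sampling days.
    n_replicates:
        Replicates collected at each (day, time) point.
    period_hours:
        Rhythm period; 24 for a diel study.
    """

    times_of_day: tuple[float, ...]
    n_days: int
    n_replicates: int
    period_hours: float = 24.0
    samples: tuple[SampleId, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "samples",
            tuple(
                SampleId(day, hour, rep)
                for day in range(1, self.n_days + 1)
                for hour in self.times_of_day
                for rep in range(1, self.n_replicates + 1)
            ),
        )

    @property
    def n_samples(self) -> int:
        return len(self.times_of_day) * self.n_days * self.n_replicates

    @property
    def n_per_group(self) -> int:
        """Observations per time-of-day group (days x replicates)."""
        return self.n_days * self.n_replicates

    @property
    def n_timepoints(self) -> int:
        """Distinct (day, hour) time points."""
        return len(self.times_of_day) * self.n_days

    @property
    def sample_names(self) -> list[str]:
        return [str(s) for s in self.samples]

    def group_index(self) -> dict[float, list[int]]:
        """Map each sampling hour to the positions of its samples."""
        idx: dict[float, list[int]] = {h: [] for h in self.times_of_day}
        for i, s in enumerate(self.samples):
            idx[s.hour].append(i)
        return idx


def make_design(
    times_of_day: list[float],
    n_days: int,
    n_replicates: int,
    period_hours: float = 24.0,
) -> SamplingDesign:
    """Validate and build a :class:`SamplingDesign`.

    Hours are normalized onto a [0, period) clock and sorted, so
    ``[6, 10, 14, 18, 22, 2]`` becomes ``[2, 6, 10, 14, 18, 22]``.
    Spacing must be even on the cyclic axis; n_days and n_replicates >= 1.
    """
    if len(times_of_day) < 2:
        # rhythm detection separately requires >= 3 groups; a 2-point grid is
        # still a valid sampling design (e.g. for ordination-only runs)
        raise ValueError("need at least 2 times of day")
    if n_days < 1 or n_replicates < 1:
        raise ValueError("n_days and n_replicates must be >= 1")
    if period_hours <= 0:
        raise ValueError("period_hours must be positive")

    hours = sorted(float(h) % period_hours for h in times_of_day)
    if len(set(hours)) != len(hours):
        raise ValueError(f"duplicate times of day after normalization: {hours}")

    expected = period_hours / len(hours)
    # cyclic gaps, including wrap-around from the last hour back to the first
    gaps = [hours[i + 1] - hours[i] for i in range(len(hours) - 1)]
    gaps.append(period_hours - hours[-1] + hours[0])
    for i, gap in enumerate(gaps):
        if abs(gap - expected) > 1e-9:
            a = hours[i]
            b = hours[(i + 1) % len(hours)]
            raise ValueError(
                f"uneven sampling: interval {a:g}h -> {b:g}h is {gap:g}h, "
                f"expected {expected:g}h"
            )

    return SamplingDesign(tuple(hours), n_days, n_replicates, period_hours)


def default_design() -> SamplingDesign:
    """The 6 x 4 x 2 field design (48 samples, n=8 per hour group)."""
    return make_design([6, 10, 14, 18, 22, 2], n_days=4, n_replicates=2)
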