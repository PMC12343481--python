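"""Per-pulse aggregation of cavitation area time series.

A laser event is summarized by the maxima of the PB and SC area series
inside one or more time windows. Reported A_PB / A_SC values are means of
those per-pulse maxima over many pulses (the acquisition protocol uses N > 30
pulses per condition). For the dual-pulse ASW modality, the maximum SC
area after the second pulse (A_SC 2nd pulse) is tracked as a function of
the inter-pulse delay t_d, producing a delay-sweep curve whose argmax is
the operationally optimal delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .detection import SegmentationResult
from .physics import delay_grid as default_delay_grid

__all__ = [
    "PulseRecord",
    "MaximaStats",
    "AggregatedMaxima",
    "SweepCurve",
    "pulse_maxima",
    "aggregate_maxima",
    "sweep_curve",
    "record_from_segmentation",
]

#: second-pulse window width W: the window [t_d, t_d + W) generalizes the
#: 360-560 µs example window seen for t_d = 360 µs.
DEFAULT_SECOND_WINDOW_US = 200.0


@dataclass
class PulseRecord:
    """Summary of one laser event (single USP pulse or ASW pulse pair)."""

    pulse_id: str
    modality: str
    pulse_energy_mJ: float
    a_pb_max_mm2: float
    a_sc_max_mm2: float
    t_d_us: float | None = None
    a_sc_max_2nd_mm2: float | None = None
    times_us: np.ndarray | None = None
    a_pb_mm2: np.ndarray | None = None
    a_sc_mm2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("USP", "ASW"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "ASW" and self.t_d_us is None:
            raise ValueError("ASW records require the inter-pulse delay t_d")
        if self.modality == "USP" and self.t_d_us is not None:
            raise ValueError("USP records carry no inter-pulse delay")


@dataclass(frozen=True)
class MaximaStats:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class AggregatedMaxima:
    pb: MaximaStats
    sc: MaximaStats


@dataclass
class SweepCurve:
    """A_SC(2nd pulse) vs inter-pulse delay, aggregated over pulses."""

    t_d_us: np.ndarray
    mean_mm2: np.ndarray
    sd_mm2: np.ndarray
    n: np.ndarray
    optimal_delay_us: float
    n_snapped: int = 0


def pulse_maxima(
    result: SegmentationResult, windows: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Maximum (A_PB, A_SC) inside each half-open time window [t0, t1) µs.

    Windows must be non-overlapping and non-inverted; a window containing
    no frames yields (0, 0).
    """
    checked = []
    for t_start, t_end in windows:
        if t_end <= t_start:
            raise ValueError(f"inverted window ({t_start}, {t_end})")
        checked.append((t_start, t_end))
    for (a0, a1), (b0, b1) in zip(sorted(checked), sorted(checked)[1:]):
        if b0 < a1:
            raise ValueError("windows overlap")

    out = []
    times = np.asarray(result.times_us, dtype=float)
    for t_start, t_end in windows:
        sel = (times >= t_start) & (times < t_end)
        if not sel.any():
            out.append((0.0, 0.0))
        else:
            out.append(
                (
                    float(np.max(np.asarray(result.a_pb_mm2)[sel])),
                    float(np.max(np.asarray(result.a_sc_mm2)[sel])),
                )
            )
    return out


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def aggregate_maxima(records: list[PulseRecord]) -> AggregatedMaxima:
    """Mean and sample SD (n-1 denominator) of per-pulse maxima.

    Warns, without failing, when fewer than the protocol's N > 30 pulses
    are aggregated.
    """
    if not records:
        raise ValueError("cannot aggregate an empty list of pulse records")
    n = len(records)
    if n <= 30:
        warnings.warn(
            f"aggregating only {n} pulses; the acquisition protocol uses N > 30",
            stacklevel=2,
        )
    pb = _mean_sd(np.array([r.a_pb_max_mm2 for r in records]))
    sc = _mean_sd(np.array([r.a_sc_max_mm2 for r in records]))
    return AggregatedMaxima(
        pb=MaximaStats(pb[0], pb[1], n), sc=MaximaStats(sc[0], sc[1], n)
    )


def sweep_curve(
    records: list[PulseRecord], grid: list[float] | None = None
) -> SweepCurve:
    """Delay-sweep curve of A_SC(2nd pulse) vs t_d from ASW pulse records.

    Records whose delay is off the grid are snapped to the nearest grid
    point and counted in ``n_snapped``. Pulses with no detected SC after
    the second pulse contribute 0 rather than being excluded. The optimal
    delay is the grid point with the largest mean (ties -> lowest delay).
    """
    asw = [r for r in records if r.modality == "ASW"]
    if not asw:
        raise ValueError("sweep_curve requires at least one ASW record")
    grid_arr = np.asarray(default_delay_grid() if grid is None else grid, dtype=float)

    groups: dict[float, list[float]] = {}
    n_snapped = 0
    for rec in asw:
        td = float(rec.t_d_us)  # type: ignore[arg-type]
        nearest = float(grid_arr[np.argmin(np.abs(grid_arr - td))])
        if nearest != td:
            n_snapped += 1
        value = rec.a_sc_max_2nd_mm2 if rec.a_sc_max_2nd_mm2 is not None else 0.0
        groups.setdefault(nearest, []).append(float(value))

    delays = np.array(sorted(groups), dtype=float)
    means = np.empty(len(delays))
    sds = np.empty(len(delays))
    ns = np.empty(len(delays), dtype=int)
    for i, td in enumerate(delays):
        means[i], sds[i] = _mean_sd(np.array(groups[td]))
        ns[i] = len(groups[td])
    if ns.min() <= 30:
        warnings.warn(
            "some delays aggregate <= 30 pulses; the protocol uses N > 30",
            stacklevel=2,
        )
    # argmax of the mean curve; np.argmax takes the first (lowest) delay on ties
    optimal = float(delays[int(np.argmax(means))])
    return SweepCurve(
        t_d_us=delays,
        mean_mm2=means,
        sd_mm2=sds,
        n=ns,
        optimal_delay_us=optimal,
        n_snapped=n_snapped,
    )


def record_from_segmentation(
    result: SegmentationResult,
    pulse_id: str,
    modality: str,
    pulse_energy_mJ: float,
    t_d_us: float | None = None,
    second_window_us: float = DEFAULT_SECOND_WINDOW_US,
) -> PulseRecord:
    """Build a PulseRecord from a segmented sequence.

    USP pulses use the whole series; ASW pairs split it into a first-pulse
    window [0, t_d) and a second-pulse window [t_d, t_d + W).
    """
    times = np.asarray(result.times_us, dtype=float)
    t_end = float(times[-1]) + 1.0
    if modality == "ASW":
        if t_d_us is None:
            raise ValueError("ASW records require t_d")
        (pb1, sc1), (_, sc2) = pulse_maxima(
            result, [(0.0, t_d_us), (t_d_us, t_d_us + second_window_us)]
        )
        return PulseRecord(
            pulse_id=pulse_id,
            modality="ASW",
            pulse_energy_mJ=pulse_energy_mJ,
            a_pb_max_mm2=pb1,
            a_sc_max_mm2=sc1,
            t_d_us=t_d_us,
            a_sc_max_2nd_mm2=sc2,
            times_us=times,
            a_pb_mm2=np.asarray(result.a_pb_mm2),
            a_sc_mm2=np.asarray(result.a_sc_mm2),
        )
    (pb, sc) = pulse_maxima(result, [(0.0, t_end)])[0]
    return PulseRecord(
        pulse_id=pulse_id,
        modality="USP",
        pulse_energy_mJ=pulse_energy_mJ,
        a_pb_max_mm2=pb,
        a_sc_max_mm2=sc,
        times_us=times,
        a_pb_mm2=np.asarray(result.a_pb_mm2),
        a_sc_mm2=np.asarray(result.a_sc_mm2),
    )
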