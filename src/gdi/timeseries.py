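"""Multichannel time-series container and spike-train binning.

A :class:`TimeSeriesSet` is the common currency of the package: a dense
``(T, R)`` matrix of ``T`` samples for ``R`` channels on a uniform sampling
grid.  Channels are either continuous-valued (voltages, rates) or binary
(binned spike trains, where 1 marks at least one spike in a bin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TimeSeriesSet", "bin_spike_trains"]


@dataclass
class TimeSeriesSet:
    """R-channel time series sampled every ``dt`` seconds.

    Parameters
    ----------
    values
        Array of shape ``(T, R)``; rows are time samples, columns channels.
    dt
        Sampling interval in seconds.  Purely metadata for continuous data;
        for binned spikes it equals the bin width.
    channel_names
        One identifier per channel.  Auto-numbered ``"1".."R"`` if omitted.
    kind
        ``"continuous"`` or ``"binary"``.  Binary sets may contain only
        values in {0, 1}.
    """

    values: np.ndarray
    dt: float = 1.0
    channel_names: list[str] = field(default_factory=list)
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x channel) array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.channel_names:
            self.channel_names = [str(i + 1) for i in range(self.values.shape[1])]
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names length must match channel count")
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary series may contain only 0/1 values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str | int) -> int:
        """Resolve a channel given by name or positional index."""
        if isinstance(name, (int, np.integer)):
            idx = int(name)
            if not 0 <= idx < self.n_channels:
                raise IndexError(f"channel index {idx} out of range")
            return idx
        try:
            return self.channel_names.index(str(name))
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


def bin_spike_trains(
    spikes: pd.DataFrame,
    bin_width: float,
    t_start: float,
    t_end: float,
    units: list | None = None,
) -> TimeSeriesSet:
    """Bin a (unit, time) spike table into a binary :class:`TimeSeriesSet`.

    Bins are half-open ``[t_start + b*w, t_start + (b+1)*w)``; a spike
    exactly on an edge falls in the later bin.  A bin with one or more
    spikes codes 1.  Spikes outside ``[t_start, t_end)`` are ignored
    (their count is logged).

    Parameters
    ----------
    spikes
        DataFrame with columns ``unit`` and ``time`` (seconds).  Extra
        columns are ignored.
    bin_width
        Bin width in seconds.
    t_start, t_end
        Analysis window; the number of bins is ``floor((t_end-t_start)/w)``.
    units
        Optional explicit channel order; unknown unit ids in the table
        create additional channels after these.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if not {"unit", "time"}.issubset(spikes.columns):
        raise ValueError("spike table needs 'unit' and 'time' columns")

    # tolerance guards float division (e.g. 0.105/0.035 -> 2.9999...)
    n_bins = int(np.floor((t_end - t_start) / bin_width + 1e-9))
    unit_order = list(units) if units is not None else []
    for u in pd.unique(spikes["unit"]):
        if u not in unit_order:
            unit_order.append(u)

    values = np.zeros((n_bins, len(unit_order)))
    t = spikes["time"].to_numpy(dtype=float)
    in_range = (t >= t_start) & (t < t_end)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("bin_spike_trains: ignored %d spikes outside [%g, %g)",
                    n_dropped, t_start, t_end)
    b = np.floor((t[in_range] - t_start) / bin_width).astype(int)
    keep = b < n_bins  # guard spikes in the trailing partial bin
    col = {u: i for i, u in enumerate(unit_order)}
    u_idx = spikes.loc[in_range, "unit"].map(col).to_numpy()[keep]
    values[b[keep], u_idx] = 1.0

    return TimeSeriesSet(values=values, dt=bin_width,
                         channel_names=[str(u) for u in unit_order],
                         kind="binary")
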