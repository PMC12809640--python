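"""One-pass incremental statistics and causal filters.

Every downstream stage (the TSW detector, the real-time loop emulator)
consumes current samples one at a time; this module provides the O(1)/O(log w)
primitives those stages are built from:

* :class:`RunningMoments` -- Welford mean/variance with an exact downdate, so
  fixed-length windows can maintain their statistics incrementally.
* :class:`MovingWindow` -- a bounded FIFO window with an O(log w) sliding
  median (dual heap, lazy deletion) and O(1) amortized min/max (monotonic
  deques).
* :func:`butter_design` / :class:`ButterworthFilter` -- a causal low-pass
  Butterworth cascade in second-order sections, streamable one sample at a
  time and sample-exact against offline application of the same coefficients.
* :func:`gaussian_lowpass` -- the zero-phase Gaussian FIR used by the
  simulators to band-limit synthetic traces (-3 dB at ``fc``).
"""

from __future__ import annotations

import heapq
import math
from collections import deque

import numpy as np
from scipy import signal


class RunningMoments:
    """Numerically stable one-pass mean/variance accumulator.

    Supports removal of previously ingested values (Welford downdate) so that
    a fixed-length window can keep its moments current in O(1) per sample.
    """

    __slots__ = ("count", "mean", "m2")

    def __init__(self) -> None:
        self.count = 0
        self.mean = 0.0
        self.m2 = 0.0

    def update(self, x: float) -> "RunningMoments":
        if not math.isfinite(x):
            raise ValueError(f"non-finite sample: {x!r}")
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (x - self.mean)
        return self

    def remove(self, x: float) -> "RunningMoments":
        """Downdate: inverse of :meth:`update` for a value still in the set."""
        if self.count < 1:
            raise ValueError("cannot remove from an empty accumulator")
        if self.count == 1:
            self.count = 0
            self.mean = 0.0
            self.m2 = 0.0
            return self
        n = self.count
        mean_prev = (n * self.mean - x) / (n - 1)
        self.m2 -= (x - mean_prev) * (x - self.mean)
        if self.m2 < 0.0:  # floating-point floor
            self.m2 = 0.0
        self.mean = mean_prev
        self.count = n - 1
        return self

    @property
    def variance(self) -> float:
        """Unbiased sample variance; requires count >= 2."""
        if self.count < 2:
            raise ValueError("variance needs at least two samples")
        return self.m2 / (self.count - 1)

    @property
    def std(self) -> float:
        return math.sqrt(self.variance)

    def get_mean(self) -> float:
        if self.count < 1:
            raise ValueError("mean of an empty accumulator is undefined")
        return self.mean


class MovingWindow:
    """Fixed-capacity FIFO window of current samples with streaming
    median/min/max.

    The median is maintained with two heaps (a max-heap for the lower half, a
    min-heap for the upper half) using lazy deletion keyed on the push
    sequence number: an element is dead once its sequence number has been
    evicted from the FIFO, and dead elements are discarded when they surface
    at a heap top. Cost is O(log capacity) amortized per push. Min/max use
    monotonic deques (O(1) amortized). Even-length median is the mean of the
    two central values.
    """

    def __init__(self, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._fifo: deque[tuple[float, int]] = deque()
        self._seq = 0
        self._evicted = 0
        # heaps store (value, seq); low is a max-heap via negation
        self._low: list[tuple[float, int]] = []
        self._high: list[tuple[float, int]] = []
        self._low_live = 0
        self._high_live = 0
        self._minq: deque[tuple[float, int]] = deque()
        self._maxq: deque[tuple[float, int]] = deque()

    def __len__(self) -> int:
        return len(self._fifo)

    @property
    def contents(self) -> list[float]:
        return [v for v, _ in self._fifo]

    # -- internal helpers ---------------------------------------------------

    def _dead(self, seq: int) -> bool:
        return seq < self._evicted

    def _purge_low(self) -> None:
        # low-heap entries are stored negated, so the sequence number is -ns
        while self._low and self._dead(-self._low[0][1]):
            heapq.heappop(self._low)

    def _purge_high(self) -> None:
        while self._high and self._dead(self._high[0][1]):
            heapq.heappop(self._high)

    def _low_top(self) -> tuple[float, int]:
        self._purge_low()
        nv, ns = self._low[0]
        return (-nv, -ns)

    def _high_top(self) -> tuple[float, int]:
        self._purge_high()
        return self._high[0]

    def _rebalance(self) -> None:
        # invariant: low_live == high_live or low_live == high_live + 1
        while self._low_live > self._high_live + 1:
            v, s = self._low_top()
            heapq.heappop(self._low)
            heapq.heappush(self._high, (v, s))
            self._low_live -= 1
            self._high_live += 1
        while self._high_live > self._low_live:
            v, s = self._high_top()
            heapq.heappop(self._high)
            heapq.heappush(self._low, (-v, -s))
            self._high_live -= 1
            self._low_live += 1

    # -- public API ---------------------------------------------------------

    def push(self, x: float) -> "MovingWindow":
        if not math.isfinite(x):
            raise ValueError(f"non-finite sample: {x!r}")
        if len(self._fifo) == self.capacity:
            v_old, s_old = self._fifo.popleft()
            # decide which heap holds (v_old, s_old) under (value, seq) order
            if self._low_live and (v_old, s_old) <= self._low_top():
                self._low_live -= 1
            else:
                self._high_live -= 1
            self._evicted = s_old + 1
        seq = self._seq
        self._seq += 1
        self._fifo.append((x, seq))
        if self._low_live == 0 or (x, seq) <= self._low_top():
            heapq.heappush(self._low, (-x, -seq))
            self._low_live += 1
        else:
            heapq.heappush(self._high, (x, seq))
            self._high_live += 1
        self._rebalance()
        # monotonic deques for min / max
        while self._minq and self._minq[-1][0] >= x:
            self._minq.pop()
        self._minq.append((x, seq))
        while self._minq[0][1] < self._evicted:
            self._minq.popleft()
        while self._maxq and self._maxq[-1][0] <= x:
            self._maxq.pop()
        self._maxq.append((x, seq))
        while self._maxq[0][1] < self._evicted:
            self._maxq.popleft()
        return self

    @property
    def median(self) -> float:
        n = len(self._fifo)
        if n == 0:
            raise ValueError("median of an empty window is undefined")
        lo = self._low_top()[0]
        if n % 2 == 1:
            return lo
        return 0.5 * (lo + self._high_top()[0])

    @property
    def min(self) -> float:
        if not self._fifo:
            raise ValueError("min of an empty window is undefined")
        return self._minq[0][0]

    @property
    def max(self) -> float:
        if not self._fifo:
            raise ValueError("max of an empty window is undefined")
        return self._maxq[0][0]


def butter_design(fc: float, fs: float, order: int = 4) -> np.ndarray:
    """Design a low-pass Butterworth filter as second-order sections.

    Parameters
    ----------
    fc : cutoff frequency in Hz (-3 dB point), 0 < fc < fs/2.
    fs : sampling rate in Hz.
    order : filter order (default 4, applied as cascaded biquads).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0.0 < fc < fs / 2.0:
        raise ValueError(f"fc must satisfy 0 < fc < fs/2 (got fc={fc}, fs={fs})")
    return signal.butter(order, fc, btype="low", fs=fs, output="sos")


class ButterworthFilter:
    """Causal streaming wrapper around a second-order-section cascade.

    Feeding samples one at a time (or chunk by chunk) is sample-exact against
    offline ``sosfilt`` of the same coefficients: the per-section delay
    registers are carried across calls.
    """

    def __init__(self, fc: float, fs: float, order: int = 4) -> None:
        self.sos = butter_design(fc, fs, order)
        self.zi = np.zeros((self.sos.shape[0], 2))

    def step(self, x: float) -> float:
        y, self.zi = signal.sosfilt(self.sos, np.asarray([x], float), zi=self.zi)
        return float(y[0])

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=float)
        if not np.all(np.isfinite(chunk)):
            raise ValueError("non-finite sample in input")
        y, self.zi = signal.sosfilt(self.sos, chunk, zi=self.zi)
        return y

    def reset(self) -> None:
        self.zi[:] = 0.0


def gaussian_kernel_sigma(fc: float, fs: float) -> float:
    """Kernel standard deviation in samples for a -3 dB point at ``fc``.

    The transfer function of a Gaussian kernel of width sigma_t is
    ``exp(-2 pi^2 f^2 sigma_t^2)``; solving for gain 1/sqrt(2) at ``fc``
    gives ``sigma_t = sqrt(ln 2) / (2 pi fc)``.
    """
    return fs * math.sqrt(math.log(2.0)) / (2.0 * math.pi * fc)


def gaussian_kernel(fc: float, fs: float) -> np.ndarray:
    sigma = gaussian_kernel_sigma(fc, fs)
    radius = max(1, int(math.ceil(4.0 * sigma)))  # ±4 sigma: <1e-4 amp error
    t = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def gaussian_lowpass(trace: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass (-3 dB at ``fc``), edge-padded.

    Offline-only: used by the simulators to band-limit synthetic traces the
    same way the acquisition chain band-limits real ones.
    """
    trace = np.asarray(trace, dtype=float)
    if not fc < fs / 2.0:
        raise ValueError("fc must be below the Nyquist frequency")
    k = gaussian_kernel(fc, fs)
    if k.size > trace.size:
        raise ValueError("kernel longer than trace")
    radius = (k.size - 1) // 2
    padded = np.pad(trace, radius, mode="edge")
    return np.convolve(padded, k, mode="valid")
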