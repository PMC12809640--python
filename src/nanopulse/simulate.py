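"""Synthetic resistive-pulse generators with exact ground truth.

Three protocols:

* :func:`simulate_square_trace` -- ideal square blockades (default 500 pA
  amplitude) in Gaussian baseline noise (default 50 pA sd), generated at a
  configurable event rate and band-limited with the zero-phase Gaussian
  low-pass (default fc = 50 kHz at fs = 500 kHz).
* :func:`simulate_modulated_trace` -- same, plus additional zero-mean
  Gaussian intraevent modulation (added before filtering) emulating the
  current fluctuations produced by a tumbling nonspherical particle.
* :func:`simulate_protein_trace` -- translocations of ellipsoidal proteins:
  each event follows a rotational Brownian walk of the symmetry axis, the
  orientation-dependent shape factor sets the instantaneous blockade, noise
  is added and the trace is band-limited.

Every generated trace is returned together with sample-accurate ground-truth
event boundaries (and class labels for mixtures); all detector accuracy
metrics in this package are computed against that truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .shape import effective_pore_volume, shape_factor_extremes
from .streaming import gaussian_lowpass


@dataclass
class SquarePulseSpec:
    fs: float = 500_000.0
    fc: float = 50_000.0
    amplitude: float = 500.0  # pA, blockade depth (current moves toward 0)
    baseline_noise_sd: float = 50.0
    event_rate: float = 1.0  # Hz
    dwell_s: float = 100e-6
    intraevent_sd: float = 0.0  # additional modulation, added pre-filter
    duration_s: float = 10.0
    baseline_pA: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.dwell_s < 1.0 / self.fs:
            raise ValueError("dwell must be at least one sample")
        if self.event_rate * self.dwell_s >= 1.0:
            raise ValueError("infeasible packing: event_rate * dwell >= 1")


@dataclass
class PoreSpec:
    diameter: float = 20.0  # nm
    length: float = 30.0  # nm
    open_current: float = -10_000.0  # pA
    noise_sd: float = 50.0  # pA, white, added before filtering

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("pore dimensions must be positive")


@dataclass
class ProteinSpec:
    m: float  # axis ratio b/a
    volume: float  # nm^3
    rot_diffusion: float = 16_667.0  # rad^2/s, tau_c ~ 30 us
    label: str = ""

    def __post_init__(self) -> None:
        if self.m <= 0 or self.volume <= 0:
            raise ValueError("m and volume must be positive")


def _place_pulses(
    n_samples: int,
    fs: float,
    rate: float,
    dwell_samples: Sequence[int],
    rng: np.random.Generator,
    warmup_samples: int,
) -> List[Tuple[int, int]]:
    """Deterministic count (rate x duration) with uniform jitter per slot.

    Pulses are placed one per 1/rate slot, jittered uniformly inside the
    slot while keeping a guard gap to the neighbours and the warm-up margin,
    so pulses never overlap and the detector windows can warm up first.
    """
    slot = int(round(fs / rate))
    n_pulses = max(n_samples // slot, 0)  # count = rate x duration
    base = warmup_samples  # slot grid starts after the warm-up margin
    out: List[Tuple[int, int]] = []
    if n_pulses == 0:
        return out
    # compress the slot grid into the post-warm-up span so the count is
    # preserved even when the warm-up margin eats into the first slot
    slot_eff = (n_samples - base) // n_pulses
    if slot_eff < 2:
        raise ValueError("infeasible packing of pulses at requested rate")
    prev_end = base
    for i in range(n_pulses):
        d = int(dwell_samples[i % len(dwell_samples)])
        lo = max(base + i * slot_eff + slot_eff // 10, prev_end + slot_eff // 10)
        hi = base + (i + 1) * slot_eff - d - slot_eff // 10
        if hi <= lo:
            raise ValueError("infeasible packing of pulses at requested rate")
        start = int(rng.integers(lo, hi))
        out.append((start, start + d))
        prev_end = start + d
    return out


def simulate_square_trace(
    spec: SquarePulseSpec,
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Square blockades in Gaussian noise, band-limited; returns the trace
    and the exact (start, end) sample indices of every pulse (end exclusive)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    d = max(1, int(round(spec.dwell_s * spec.fs)))
    warmup = max(int(0.03 * spec.fs), 2 * d)
    truth = _place_pulses(n, spec.fs, spec.event_rate, [d], rng, warmup)
    trace = np.full(n, spec.baseline_pA, dtype=np.float64)
    # blockade moves the current toward zero; for a zero baseline use a
    # negative-going pulse (the conventional -100 mV polarity)
    step = abs(spec.amplitude) if spec.baseline_pA < 0 else -abs(spec.amplitude)
    for s, e in truth:
        trace[s:e] += step
    if spec.intraevent_sd > 0:
        extra = math.sqrt(max(spec.intraevent_sd**2 - spec.baseline_noise_sd**2, 0.0))
        for s, e in truth:
            trace[s:e] += rng.normal(0.0, extra, e - s)
    trace += rng.normal(0.0, spec.baseline_noise_sd, n)
    trace = gaussian_lowpass(trace, spec.fc, spec.fs)
    return trace, truth


def simulate_modulated_trace(
    spec: SquarePulseSpec,
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Square blockades whose intraevent samples carry additional zero-mean
    Gaussian modulation of total sd ``intraevent_sd`` (>= baseline noise),
    added before filtering."""
    if spec.intraevent_sd < spec.baseline_noise_sd:
        raise ValueError("intraevent_sd must be >= baseline_noise_sd")
    return simulate_square_trace(spec)


def orientation_walk(
    rot_diffusion: float,
    n: int,
    dt: float,
    seed: int | np.random.Generator = 0,
    theta0: Optional[float] = None,
) -> np.ndarray:
    """Isotropic rotational Brownian walk of a symmetry axis on the sphere.

    Returns the polar angle theta(t) in [0, pi] between the axis and the pore
    axis. Per step, the axis receives independent Gaussian tangential
    displacements with variance ``2 * D_r * dt`` per tangent dimension and is
    renormalized; the stationary distribution of the axis is uniform on the
    sphere (density sin(theta) for theta).
    """
    if rot_diffusion < 0:
        raise ValueError("rot_diffusion must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if theta0 is None:
        c0 = rng.uniform(-1.0, 1.0)
        phi0 = rng.uniform(0.0, 2.0 * math.pi)
    else:
        c0 = math.cos(theta0)
        phi0 = 0.0
    s0 = math.sqrt(max(1.0 - c0 * c0, 0.0))
    u = np.array([s0 * math.cos(phi0), s0 * math.sin(phi0), c0])
    if rot_diffusion == 0.0:
        return np.full(n, math.acos(np.clip(u[2], -1, 1)))
    step_sd = math.sqrt(2.0 * rot_diffusion * dt)
    kicks = rng.normal(0.0, step_sd, size=(n, 2))
    theta = np.empty(n)
    from ._kernels import orientation_walk_kernel

    orientation_walk_kernel(np.ascontiguousarray(u), kicks, theta)
    return theta


@dataclass
class LabeledEvent:
    start: int
    end: int
    label: str
    m: float
    volume: float


def simulate_protein_trace(
    proteins: Sequence[ProteinSpec],
    pore: PoreSpec,
    fs: float = 500_000.0,
    fc: float = 50_000.0,
    dwell_sampler=None,
    event_rate: float = 10.0,
    duration_s: float = 10.0,
    seed: int = 0,
    mixture_weights: Optional[Sequence[float]] = None,
) -> Tuple[np.ndarray, List[LabeledEvent]]:
    """Translocations of a protein mixture through a cylindrical pore.

    Per event: a protein class is drawn, its symmetry axis performs a
    rotational Brownian walk, and the instantaneous blockade is
    ``I0 * gamma(m, theta(t)) * V / V_eff``; white Gaussian noise
    (``pore.noise_sd``) is added and the trace is Gaussian-filtered at
    ``fc``. Dwell times default to U(200 us, 600 us), long enough for
    orientation sampling at a 50 kHz bandwidth.
    """
    rng = np.random.default_rng(seed)
    if dwell_sampler is None:
        def dwell_sampler(r: np.random.Generator) -> float:
            return float(r.uniform(200e-6, 600e-6))
    n = int(round(duration_s * fs))
    i0 = pore.open_current
    v_eff = effective_pore_volume(pore.diameter, pore.length)
    weights = (
        np.full(len(proteins), 1.0 / len(proteins))
        if mixture_weights is None
        else np.asarray(mixture_weights, dtype=float) / np.sum(mixture_weights)
    )
    trace = np.full(n, i0, dtype=np.float64)
    truth: List[LabeledEvent] = []
    warmup = int(0.03 * fs)
    slot = int(round(fs / event_rate))
    n_events = max(n // slot, 0)  # count = rate x duration
    if n_events > 0:
        slot_eff = (n - warmup) // n_events
        if slot_eff < 2:
            raise ValueError("infeasible packing of events at requested rate")
    prev_end = warmup
    for i in range(n_events):
        d = max(2, int(round(dwell_sampler(rng) * fs)))
        lo = max(warmup + i * slot_eff + slot_eff // 10, prev_end + slot_eff // 10)
        hi = warmup + (i + 1) * slot_eff - d - slot_eff // 10
        if hi <= lo:
            raise ValueError("infeasible packing of events at requested rate")
        start = int(rng.integers(lo, hi))
        end = start + d
        k = int(rng.choice(len(proteins), p=weights))
        prot = proteins[k]
        g_par, g_perp = shape_factor_extremes(prot.m)
        theta = orientation_walk(prot.rot_diffusion, d, 1.0 / fs, rng)
        c2 = np.cos(theta) ** 2
        gamma = g_perp + (g_par - g_perp) * c2
        d_i = i0 * gamma * prot.volume / v_eff
        if np.any(np.abs(d_i) >= abs(i0)):
            raise ValueError("blockade exceeds the open-pore current")
        trace[start:end] -= d_i  # current magnitude drops by |dI|
        label = prot.label or f"protein_{k}"
        truth.append(LabeledEvent(start, end, label, prot.m, prot.volume))
        prev_end = end
    trace += rng.normal(0.0, pore.noise_sd, n)
    trace = gaussian_lowpass(trace, fc, fs)
    return trace, truth
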