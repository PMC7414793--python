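"""Forward model of time-domain NADH fluorescence decay.

Time-correlated single-photon counting (TCSPC) records, at every image
pixel, a histogram of photon arrival times relative to the laser pulse.
Intracellular NADH exists in two pools with distinct excited-state
lifetimes — free NADH (short component, ``tau1``) and protein-bound NADH
(long component, ``tau2``) — so the emission decay is modelled as a
bi-exponential

    d(t) = a1 * exp(-t / tau1) + (1 - a1) * exp(-t / tau2)

where ``a1`` is the fractional contribution of the free pool.  The
amplitude-weighted mean lifetime

    tau_m = a1 * tau1 + (1 - a1) * tau2

is the primary metabolic readout.  What the detector sees is this decay
convolved with the instrument response function (IRF) — the temporal blur
of the excitation pulse and detection chain, measured in practice from a
second-harmonic standard such as a urea crystal — sampled on a discrete
time axis, scaled to the expected photon count, and corrupted by Poisson
noise (noise is applied downstream, in the synthetic-data generator).

This module holds the acquisition/IRF/parameter types, the forward model
:func:`model_decay`, the lifetime algebra (:func:`mean_lifetime`,
:func:`solve_tau2`) and the phasor transform used as a fit-free
cross-check of the fitting engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainError",
    "GridMismatchError",
    "AcquisitionGrid",
    "IRFProfile",
    "BiExpParams",
    "DecayHistogram",
    "mean_lifetime",
    "solve_tau2",
    "model_decay",
    "phasor_transform",
]


class DomainError(ValueError):
    """A parameter lies outside its physical domain."""


class GridMismatchError(ValueError):
    """Two objects that must share an acquisition grid do not."""


# 80 MHz laser repetition -> 12.5 ns window; 256 ADC channels is the
# conventional resolution of SPC-150-class counting electronics.
DEFAULT_WINDOW_PS = 12500.0
DEFAULT_N_CHANNELS = 256


@dataclass(frozen=True)
class AcquisitionGrid:
    """Discrete space/time sampling of one FLIM acquisition.

    Parameters
    ----------
    n_time_channels:
        Number of TCSPC histogram channels (>= 16).
    channel_width:
        Temporal width of one channel, in picoseconds.
    height, width:
        Spatial pixel counts of the field of view.
    """

    n_time_channels: int = DEFAULT_N_CHANNELS
    channel_width: float = DEFAULT_WINDOW_PS / DEFAULT_N_CHANNELS
    height: int = 128
    width: int = 128

    def __post_init__(self) -> None:
        if self.n_time_channels < 16:
            raise DomainError("n_time_channels must be >= 16")
        if self.channel_width <= 0:
            raise DomainError("channel_width must be positive")
        if self.height < 1 or self.width < 1:
            raise DomainError("image dimensions must be positive")

    @property
    def time_axis(self) -> np.ndarray:
        """Channel start times in ps, shape ``(n_time_channels,)``."""
        return np.arange(self.n_time_channels) * self.channel_width

    @property
    def window(self) -> float:
        """Total temporal window in ps."""
        return self.n_time_channels * self.channel_width

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def check_window(self, max_lifetime: float) -> None:
        """Require the window to exceed 4x the largest simulated lifetime."""
        if self.window <= 4.0 * max_lifetime:
            raise DomainError(
                f"window {self.window:.0f} ps must exceed 4 x the largest "
                f"lifetime to be simulated ({max_lifetime:.0f} ps)"
            )


@dataclass(frozen=True)
class IRFProfile:
    """Normalized instrument response kernel on the acquisition time axis.

    The kernel is stored normalized to unit sum.  ``fwhm`` is informational
    (ps); ``peak_channel`` is the index of the kernel maximum and anchors
    the rise-region exclusion used during fitting.
    """

    kernel: np.ndarray
    fwhm: float | None = None
    peak_channel: int = field(default=-1)

    def __post_init__(self) -> None:
        kernel = np.asarray(self.kernel, dtype=float)
        if kernel.ndim != 1:
            raise DomainError("IRF kernel must be one-dimensional")
        if np.any(kernel < 0):
            raise DomainError("IRF kernel must be non-negative")
        total = kernel.sum()
        if total <= 0:
            raise DomainError("IRF kernel must have positive mass")
        object.__setattr__(self, "kernel", kernel / total)
        if self.peak_channel < 0:
            object.__setattr__(self, "peak_channel", int(np.argmax(kernel)))

    def __len__(self) -> int:
        return self.kernel.size

    @classmethod
    def gaussian(
        cls,
        grid: AcquisitionGrid,
        fwhm: float = 300.0,
        peak_channel: int = 10,
    ) -> "IRFProfile":
        """Gaussian stand-in for a measured (e.g. urea-SHG) IRF."""
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.channel_width
        ch = np.arange(grid.n_time_channels)
        kernel = np.exp(-0.5 * ((ch - peak_channel) / sigma) ** 2)
        return cls(kernel=kernel, fwhm=fwhm, peak_channel=peak_channel)

    @classmethod
    def delta(cls, grid: AcquisitionGrid, channel: int = 0) -> "IRFProfile":
        """Idealized instantaneous response (unit mass in one channel)."""
        kernel = np.zeros(grid.n_time_channels)
        kernel[channel] = 1.0
        return cls(kernel=kernel, fwhm=0.0, peak_channel=channel)

    def to_text(self, path) -> None:
        """Write the kernel as two-column text (channel index, weight)."""
        data = np.column_stack([np.arange(len(self)), self.kernel])
        header = json.dumps({"fwhm": self.fwhm, "peak_channel": self.peak_channel})
        np.savetxt(path, data, fmt=["%d", "%.10e"], header=header)

    @classmethod
    def from_text(cls, path) -> "IRFProfile":
        with open(path) as fh:
            first = fh.readline()
        meta = {}
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("# "))
            except json.JSONDecodeError:
                meta = {}
        data = np.loadtxt(path)
        return cls(
            kernel=data[:, 1],
            fwhm=meta.get("fwhm"),
            peak_channel=int(meta.get("peak_channel", -1)),
        )


@dataclass(frozen=True)
class BiExpParams:
    """Two-component decay parameters for one emitter (cell or pixel).

    ``a1`` is the free-NADH fraction; the bound fraction ``a2 = 1 - a1``
    is never stored independently.  The free component is the short one
    (``tau1 < tau2``).  ``amplitude`` is the expected total photon count
    of the noise-free curve; ``offset`` a constant background per channel.
    """

    a1: float
    tau1: float
    tau2: float
    amplitude: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a1 <= 1.0:
            raise DomainError(f"a1={self.a1} outside [0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise DomainError("lifetimes must be positive")
        if self.tau1 >= self.tau2:
            raise DomainError("tau1 (free) must be shorter than tau2 (bound)")
        if self.amplitude < 0 or self.offset < 0:
            raise DomainError("amplitude and offset must be non-negative")

    @property
    def a2(self) -> float:
        return 1.0 - self.a1

    @property
    def taum(self) -> float:
        return mean_lifetime(self.a1, self.tau1, self.tau2)


@dataclass(frozen=True)
class DecayHistogram:
    """Per-pixel photon counts across time channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise DomainError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise DomainError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())


def mean_lifetime(a1, tau1, tau2):
    """Amplitude-weighted mean lifetime ``tau_m = a1*tau1 + (1-a1)*tau2``.

    Accepts scalars or broadcastable arrays; the result always lies
    between ``tau1`` and ``tau2``.
    """
    a1 = np.asarray(a1, dtype=float)
    tau1 = np.asarray(tau1, dtype=float)
    tau2 = np.asarray(tau2, dtype=float)
    if np.any(a1 < 0) or np.any(a1 > 1):
        raise DomainError("a1 must lie in [0, 1]")
    if np.any(tau1 <= 0) or np.any(tau2 <= 0):
        raise DomainError("lifetimes must be positive")
    out = a1 * tau1 + (1.0 - a1) * tau2
    return float(out) if out.ndim == 0 else out


def solve_tau2(taum_target, a1, tau1):
    """Bound-component lifetime reproducing a target mean lifetime.

    Inverts ``tau_m = a1*tau1 + (1-a1)*tau2`` for ``tau2``; used to turn a
    published (tau_m, a1) pair into generative parameters given a free
    lifetime ``tau1``.
    """
    taum_target = np.asarray(taum_target, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    tau1 = np.asarray(tau1, dtype=float)
    if np.any(a1 < 0) or np.any(a1 >= 1):
        raise DomainError("a1 must lie in [0, 1) for the inverse to exist")
    if np.any(tau1 <= 0):
        raise DomainError("tau1 must be positive")
    if np.any(taum_target <= a1 * tau1):
        raise DomainError("taum_target must exceed a1*tau1")
    out = (taum_target - a1 * tau1) / (1.0 - a1)
    return float(out) if out.ndim == 0 else out


def model_decay(
    params: BiExpParams,
    irf: IRFProfile,
    grid: AcquisitionGrid,
    wrap: bool = False,
) -> np.ndarray:
    """Expected (noise-free) counts per channel for one emitter.

    The normalized bi-exponential is convolved with the IRF kernel and
    scaled so the sum over channels equals ``params.amplitude``, then the
    per-channel ``offset`` is added.  By default the convolution is linear
    (decay truncated at the window edge); ``wrap=True`` instead sums the
    decay periodically over repetition periods before a circular
    convolution, for windows that do not dwarf ``tau2``.
    """
    if len(irf) != grid.n_time_channels:
        raise GridMismatchError(
            f"IRF has {len(irf)} channels but grid expects {grid.n_time_channels}"
        )
    t = grid.time_axis
    if wrap:
        w = grid.window
        d = params.a1 * np.exp(-t / params.tau1) / -np.expm1(-w / params.tau1)
        d += (1.0 - params.a1) * np.exp(-t / params.tau2) / -np.expm1(-w / params.tau2)
        conv = np.real(np.fft.ifft(np.fft.fft(irf.kernel) * np.fft.fft(d)))
        conv = np.maximum(conv, 0.0)
    else:
        d = params.a1 * np.exp(-t / params.tau1)
        d += (1.0 - params.a1) * np.exp(-t / params.tau2)
        conv = np.convolve(irf.kernel, d)[: grid.n_time_channels]
    total = conv.sum()
    if params.amplitude > 0 and total > 0:
        curve = params.amplitude * conv / total
    else:
        curve = np.zeros_like(conv)
    return curve + params.offset


def phasor_transform(decay, grid: AcquisitionGrid, harmonic: int = 1):
    """First-harmonic phasor coordinates (g, s) of a decay histogram.

    Fourier projections of the normalized decay at angular frequency
    ``omega = 2*pi*harmonic / window``.  For a noise-free mono-exponential
    on a delta IRF, (g, s) lies on the universal semicircle
    ``g = 1/(1+(omega*tau)^2)``, ``s = omega*tau/(1+(omega*tau)^2)`` up to
    discretization error.  Fit-free, hence an independent cross-check of
    the fitting engine.
    """
    counts = decay.counts if isinstance(decay, DecayHistogram) else np.asarray(decay)
    total = counts.sum()
    if total <= 0:
        raise DomainError("phasor transform requires a non-empty histogram")
    if harmonic < 1:
        raise DomainError("harmonic must be a positive integer")
    omega = 2.0 * np.pi * harmonic / grid.window
    t = grid.time_axis
    g = float((counts * np.cos(omega * t)).sum() / total)
    s = float((counts * np.sin(omega * t)).sum() / total)
    return g, s
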