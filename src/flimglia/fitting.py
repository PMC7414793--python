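"""Per-pixel inversion of the decay model.

Mirrors the SPCImage-style workflow: spatial binning of neighbouring
pixels' histograms (factor ``b`` sums a ``(2b+1) x (2b+1)`` window), a
photon-count threshold to reject background, then a weighted
Levenberg-Marquardt fit of the IRF-convolved bi-exponential to every
remaining pixel, assessed by the reduced chi-squared.

The optimizer is batched: all pixels are iterated simultaneously with an
analytic Jacobian and per-pixel damping, which is what makes fitting a
whole experiment (hundreds of fields of view) tractable on one core.
The convolution of an exponential with the IRF kernel has the closed
form

    (k * e^{-t/tau})[n] = e^{-t_n/tau} * sum_{j<=n} k_j e^{+t_j/tau}

so each model evaluation costs one exponential over the time axis plus a
prefix sum over the (short) kernel support — no FFTs in the hot loop.
The curve amplitude is profiled out analytically each iteration
(variable projection) and its dependence on the nonlinear parameters is
folded into the Jacobian, leaving a1, tau1, tau2 (and optionally offset
and an IRF shift) as the iterated parameters.

Weighting.  Pure Neyman weights ``1/max(obs, 1)`` are the TCSPC
least-squares tradition but are known to bias two-component estimates at
realistic counts (low-count tail channels are mis-weighted).  The default
``weighting='model'`` therefore fits twice: a Neyman first pass, then a
refit with weights frozen at ``1/max(fit, 1)`` from the first-pass curve
— the classic two-pass scheme that removes the data-correlated weighting
bias without changing the least-squares character of the fit.  The
reported reduced chi-squared always uses the Neyman formula (or uniform,
if that weighting was requested), so goodness-of-fit stays comparable
across weightings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decay_model import (
    AcquisitionGrid,
    DecayHistogram,
    DomainError,
    GridMismatchError,
    IRFProfile,
)

__all__ = [
    "FitConfig",
    "PixelFitResult",
    "FlimMaps",
    "BelowThresholdError",
    "bin_stack",
    "threshold_pixels",
    "chi2_reduced",
    "fit_pixel",
    "fit_image",
]


class BelowThresholdError(ValueError):
    """A decay rejected by the photon-count threshold was passed to the fitter."""


# Coarse multi-start grid (also the enumeration oracle for the optimizer).
GRID_A1 = np.linspace(0.1, 0.9, 9)
GRID_TAU1 = np.array([200.0, 400.0, 600.0, 800.0])
GRID_TAU2 = np.array([900.0, 1400.0, 2200.0, 3200.0, 4000.0])

_MAP_PAGES = ("taum", "a1", "tau1", "tau2", "chi2_reduced", "total_photons", "valid_mask")


@dataclass(frozen=True)
class FitConfig:
    """Settings of the per-pixel fit.

    ``bin_factor`` follows the SPCImage convention: factor ``b`` sums the
    ``(2b+1) x (2b+1)`` neighbourhood.  ``min_photons`` applies to the
    post-binning per-pixel total.  ``weighting`` is one of ``'model'``
    (two-pass, default), ``'poisson'`` (Neyman, single pass) or
    ``'uniform'``.  Channels earlier than the IRF peak minus 3 are
    excluded from the residual when ``exclude_rise`` is set.
    """

    bin_factor: int = 2
    min_photons: float = 500.0
    a1_bounds: tuple[float, float] = (0.0, 1.0)
    tau1_bounds: tuple[float, float] = (100.0, 1000.0)
    tau2_bounds: tuple[float, float] = (800.0, 6000.0)
    offset_max_frac: float = 0.10  # offset bound, as a fraction of peak counts
    init_strategy: str = "moments"  # {"moments", "grid", "fixed"}
    fixed_init: tuple[float, float, float] = (0.7, 400.0, 1200.0)
    max_iterations: int = 40
    convergence_tol: float = 1e-4
    weighting: str = "model"  # {"model", "poisson", "uniform"}
    fit_offset: bool = False
    fit_shift: bool = False
    shift_bounds: tuple[float, float] = (-5.0, 5.0)  # channels
    exclude_rise: bool = True
    engine: str = "auto"  # {"auto", "numba", "numpy"}
    dtype: str = "float32"  # numpy-engine precision for image batches
    bounds_overlap: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.bin_factor < 0:
            raise DomainError("bin_factor must be >= 0")
        if self.min_photons < 0:
            raise DomainError("min_photons must be >= 0")
        lo, hi = self.a1_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise DomainError("a1 bounds must satisfy 0 <= lo < hi <= 1")
        if self.tau1_bounds[0] <= 0 or self.tau2_bounds[0] <= 0:
            raise DomainError("lifetime bounds must be positive")
        if self.init_strategy not in ("moments", "grid", "fixed"):
            raise DomainError(f"unknown init_strategy {self.init_strategy!r}")
        if self.weighting not in ("model", "poisson", "uniform"):
            raise DomainError(f"unknown weighting {self.weighting!r}")
        if self.engine not in ("auto", "numba", "numpy"):
            raise DomainError(f"unknown engine {self.engine!r}")
        # Overlapping tau windows are allowed but flagged: components may swap.
        object.__setattr__(
            self, "bounds_overlap", self.tau1_bounds[1] > self.tau2_bounds[0]
        )

    @property
    def n_free_params(self) -> int:
        """Fitted parameters: a1, tau1, tau2, amplitude (+offset, +shift)."""
        return 4 + int(self.fit_offset) + int(self.fit_shift)


@dataclass(frozen=True)
class PixelFitResult:
    """Fit of a single decay histogram."""

    a1: float
    tau1: float
    tau2: float
    taum: float
    amplitude: float
    offset: float
    shift: float
    chi2_reduced: float
    total_photons: float
    converged: bool
    n_iterations: int


@dataclass
class FlimMaps:
    """Per-pixel FLIM parameter images sharing one spatial grid.

    Pixels below the photon threshold or whose fit did not converge carry
    NaN and ``valid_mask=False``.
    """

    taum: np.ndarray
    a1: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    chi2_reduced: np.ndarray
    total_photons: np.ndarray
    valid_mask: np.ndarray
    grid: AcquisitionGrid | None = None

    def __post_init__(self) -> None:
        shapes = {getattr(self, name).shape for name in _MAP_PAGES}
        if len(shapes) != 1:
            raise GridMismatchError("all FLIM maps must share one spatial shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.taum.shape


def _box_sum(a: np.ndarray, radius: int, axis: int) -> np.ndarray:
    """Exact integer windowed sum of width ``2*radius+1``, truncated at edges."""
    n = a.shape[axis]
    # int32 is exact whenever the worst-case running sum fits; photon
    # counts are uint16 so this covers any realistic image size
    bound = int(np.max(a, initial=0)) * n if a.size else 0
    dtype = np.int32 if bound < 2**31 - 1 else np.int64
    c = np.cumsum(a, axis=axis, dtype=dtype)
    ca = np.moveaxis(c, axis, 0)
    out = np.empty_like(c)
    oa = np.moveaxis(out, axis, 0)
    r = min(radius, n - 1)
    oa[: n - r] = ca[r:]
    oa[n - r :] = ca[-1]
    oa[r + 1 :] -= ca[: n - r - 1]
    return out


def bin_stack(stack: np.ndarray, bin_factor: int) -> np.ndarray:
    """Sum each pixel's histogram over its ``(2b+1) x (2b+1)`` neighbourhood.

    ``stack`` is ``(n_time, height, width)``; spatial dimensions are
    unchanged and windows are truncated at image borders.  ``bin_factor=0``
    is the identity.
    """
    if bin_factor < 0:
        raise DomainError("bin_factor must be >= 0")
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise GridMismatchError("decay stack must be (n_time, height, width)")
    if bin_factor == 0:
        return stack.copy()
    out = _box_sum(stack, bin_factor, axis=1)
    out = _box_sum(out, bin_factor, axis=2)
    return out


def threshold_pixels(stack: np.ndarray, min_photons: float) -> np.ndarray:
    """Boolean image: per-pixel photon total >= ``min_photons``."""
    if min_photons < 0:
        raise DomainError("min_photons must be >= 0")
    stack = np.asarray(stack)
    return stack.sum(axis=0) >= min_photons


def chi2_reduced(
    observed,
    expected,
    n_free_params: int,
    weighting: str = "poisson",
    channel_mask: np.ndarray | None = None,
) -> float:
    """Reduced chi-squared of a fitted decay.

    Poisson (Neyman) weighting: ``sum (obs-exp)^2 / max(obs, 1)`` over the
    included channels, divided by ``n_included - n_free_params``.  Channels
    where both observed and expected are ~0 are excluded.
    """
    obs = observed.counts if isinstance(observed, DecayHistogram) else np.asarray(observed)
    obs = obs.astype(float)
    exp = np.asarray(expected, dtype=float)
    include = (exp > 1e-12) | (obs > 0)
    if channel_mask is not None:
        include &= np.asarray(channel_mask, dtype=bool)
    dof = int(include.sum()) - n_free_params
    if dof <= 0:
        raise DomainError("non-positive degrees of freedom")
    if weighting == "poisson":
        w = 1.0 / np.maximum(obs, 1.0)
    elif weighting == "uniform":
        w = np.ones_like(obs)
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    return float((((obs - exp) ** 2) * w)[include].sum() / dof)


class _IrfConvolver:
    """Closed-form convolution of exponentials with a (short) IRF kernel."""

    def __init__(self, kernel: np.ndarray, dt: float, dtype=np.float64):
        kernel = np.asarray(kernel, dtype=dtype)
        nz = int(np.nonzero(kernel > 1e-14)[0][-1]) + 1 if kernel.any() else 1
        self.n_channels = kernel.size
        self.dt = dt
        self.kj = kernel[:nz]
        self.tj = (np.arange(nz) * dt).astype(dtype)
        self.t = (np.arange(kernel.size) * dt).astype(dtype)
        self.dtype = dtype

    def exp_conv(self, tau: np.ndarray, kj: np.ndarray | None = None,
                 with_grad: bool = False):
        """conv[n] = sum_{j<=n} k_j exp(-(t_n - t_j)/tau) for tau (N, 1).

        Returns ``conv`` of shape (N, T) and, if requested, its derivative
        with respect to tau.  ``kj`` may override the kernel per pixel
        (shape (N, nz)) to express a fractional IRF shift.
        """
        tau = np.asarray(tau, dtype=self.dtype)
        if kj is None:
            kj = self.kj[None, :]
        E = kj * np.exp(self.tj[None, :] / tau)  # (N, nz)
        C = np.cumsum(E, axis=1)
        D = np.exp(-self.t[None, :] / tau)  # (N, T)
        nz = self.tj.size
        pad = self.n_channels - nz
        Cfull = np.concatenate(
            [C, np.broadcast_to(C[:, -1:], (C.shape[0], pad))], axis=1
        )
        conv = D * Cfull
        if not with_grad:
            return conv
        Q = np.cumsum(E * self.tj[None, :], axis=1)
        Qfull = np.concatenate(
            [Q, np.broadcast_to(Q[:, -1:], (Q.shape[0], pad))], axis=1
        )
        dconv = (self.t[None, :] * conv - D * Qfull) / tau**2
        return conv, dconv

    def shifted_kernel(self, shift: np.ndarray) -> np.ndarray:
        """Kernel linearly interpolated to a per-pixel fractional shift."""
        nz = self.kj.size
        base = np.concatenate([[0.0], self.kj, [0.0]]).astype(self.dtype)
        pos = np.arange(nz)[None, :] - shift  # sample original kernel here
        lo = np.floor(pos).astype(int)
        frac = (pos - lo).astype(self.dtype)
        lo = np.clip(lo + 1, 0, nz)  # +1 for the zero padding
        hi = np.clip(lo + 1, 0, nz + 1)
        return (1.0 - frac) * base[lo] + frac * base[hi]


def _shape_curves(op: _IrfConvolver, a1, tau1, tau2, shift=None):
    """Unnormalized model shapes a1*conv(tau1) + (1-a1)*conv(tau2)."""
    kj = op.shifted_kernel(shift) if shift is not None else None
    c1 = op.exp_conv(tau1, kj=kj)
    c2 = op.exp_conv(tau2, kj=kj)
    return a1 * c1 + (1.0 - a1) * c2


def _moments_init(y, op, config):
    """Centroid-based starting point: tau_m from the histogram centroid."""
    t = op.t
    total = np.maximum(y.sum(axis=1), 1e-12)
    tbar = (y * t[None, :]).sum(axis=1) / total
    tirf = float((op.kj * op.tj).sum())
    taum_est = tbar - tirf
    n = y.shape[0]
    a1_0 = np.full(n, 0.7)
    tau1_0 = np.full(n, np.clip(400.0, *config.tau1_bounds))
    with np.errstate(invalid="ignore"):
        tau2_0 = (taum_est - a1_0 * tau1_0) / (1.0 - a1_0)
    tau2_0 = np.where(np.isfinite(tau2_0), tau2_0, config.tau2_bounds[0])
    tau2_0 = np.clip(tau2_0, *config.tau2_bounds)
    return a1_0, tau1_0, tau2_0


def _grid_combos() -> np.ndarray:
    """Deterministic coarse grid, ordered a1-ascending for tie-breaking."""
    return np.array(
        [(a1, t1, t2) for a1 in GRID_A1 for t1 in GRID_TAU1 for t2 in GRID_TAU2]
    )


def _grid_search(y, w, op, config):
    """Best coarse-grid start per pixel (ties -> lowest a1 first)."""
    combos = _grid_combos()
    curves = _shape_curves(
        op, combos[:, 0:1], combos[:, 1:2], combos[:, 2:3]
    )  # (n_combo, T)
    num = (w * y) @ curves.T  # (N, n_combo)
    den = w @ (curves.T**2)
    A = np.maximum(num / np.maximum(den, 1e-30), 0.0)
    sq = (w * y * y).sum(axis=1, keepdims=True)
    chi2 = sq - 2.0 * A * num + A**2 * den
    best = np.argmin(chi2, axis=1)  # first minimum = lowest a1 on ties
    p = combos[best]
    return p[:, 0], p[:, 1], p[:, 2], chi2[np.arange(len(best)), best]


class _Problem:
    """One weighted least-squares problem over a batch of decays."""

    def __init__(self, y, w, op, config):
        self.y = y
        self.w = w
        self.op = op
        self.config = config
        self.off_hi = config.offset_max_frac * y.max(axis=1)
        self.lb = np.array(
            [config.a1_bounds[0], config.tau1_bounds[0], config.tau2_bounds[0]]
        )
        self.ub = np.array(
            [config.a1_bounds[1], config.tau1_bounds[1], config.tau2_bounds[1]]
        )

    def unpack(self, pm):
        cfg = self.config
        a1, tau1, tau2 = pm[:, 0:1], pm[:, 1:2], pm[:, 2:3]
        col = 3
        off = pm[:, col : col + 1] if cfg.fit_offset else 0.0
        col += int(cfg.fit_offset)
        sh = pm[:, col : col + 1] if cfg.fit_shift else None
        return a1, tau1, tau2, off, sh

    def clip(self, pm, rows):
        cfg = self.config
        pm[:, 0] = np.clip(pm[:, 0], self.lb[0], self.ub[0])
        pm[:, 1] = np.clip(pm[:, 1], self.lb[1], self.ub[1])
        pm[:, 2] = np.clip(pm[:, 2], self.lb[2], self.ub[2])
        col = 3
        if cfg.fit_offset:
            pm[:, col] = np.clip(pm[:, col], 0.0, self.off_hi[rows])
            col += 1
        if cfg.fit_shift:
            pm[:, col] = np.clip(pm[:, col], *cfg.shift_bounds)
        return pm

    def model(self, pm, rows):
        """Model curves with the amplitude profiled out; returns (model, A, c)."""
        y, w = self.y[rows], self.w[rows]
        a1, tau1, tau2, off, sh = self.unpack(pm)
        c = _shape_curves(self.op, a1, tau1, tau2, shift=sh)
        resid0 = y - off
        den = np.maximum((w * c * c).sum(axis=1), 1e-30)
        A = np.maximum((w * resid0 * c).sum(axis=1) / den, 0.0)
        return A[:, None] * c + off, A, c

    def chi2(self, pm, rows):
        y, w = self.y[rows], self.w[rows]
        model, A, _ = self.model(pm, rows)
        return (w * (y - model) ** 2).sum(axis=1), A


def _lm_pass(problem: _Problem, p: np.ndarray, max_iter: int):
    """Damped Gauss-Newton with per-pixel lambda and exact VarPro Jacobian."""
    cfg = problem.config
    op = problem.op
    n = p.shape[0]
    all_rows = np.arange(n)
    chi2, _ = problem.chi2(p, all_rows)
    lam = np.full(n, 1e-3)
    converged = np.zeros(n, dtype=bool)
    n_iter = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    eye = None
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        pa = p[idx]
        ya, wa = problem.y[idx], problem.w[idx]
        a1, tau1, tau2, off, sh = problem.unpack(pa)
        kj = op.shifted_kernel(sh) if sh is not None else None
        c1, d1 = op.exp_conv(tau1, kj=kj, with_grad=True)
        c2, d2 = op.exp_conv(tau2, kj=kj, with_grad=True)
        c = a1 * c1 + (1.0 - a1) * c2
        resid0 = ya - (off if cfg.fit_offset else 0.0)
        den = np.maximum((wa * c * c).sum(axis=1), 1e-30)
        A = np.maximum((wa * resid0 * c).sum(axis=1) / den, 0.0)
        model = A[:, None] * c + (off if cfg.fit_offset else 0.0)
        resid = ya - model

        # Shape derivatives; the amplitude's dependence on each parameter
        # (variable projection) is folded in so the Jacobian is exact.
        shapes = [c1 - c2, a1 * d1, (1.0 - a1) * d2]
        if cfg.fit_shift:
            eps = np.asarray(0.25, dtype=c.dtype)
            c_hi = _shape_curves(op, a1, tau1, tau2, shift=sh + eps)
            c_lo = _shape_curves(op, a1, tau1, tau2, shift=sh - eps)
            shape_sh = (c_hi - c_lo) / (2 * eps)
        cols = []
        for S in shapes:
            u = (wa * resid0 * S).sum(axis=1)
            v = (wa * c * S).sum(axis=1)
            dA = (u - 2.0 * A * v) / den
            cols.append(A[:, None] * S + dA[:, None] * c)
        if cfg.fit_offset:
            dA_off = -(wa * c).sum(axis=1) / den
            cols.append(1.0 + dA_off[:, None] * c)
        if cfg.fit_shift:
            u = (wa * resid0 * shape_sh).sum(axis=1)
            v = (wa * c * shape_sh).sum(axis=1)
            dA = (u - 2.0 * A * v) / den
            cols.append(A[:, None] * shape_sh + dA[:, None] * c)
        J = np.stack(cols, axis=2)  # (n_active, T, P)
        Jw = J * wa[:, :, None]
        JwT = Jw.transpose(0, 2, 1)
        JtJ = JwT @ J
        g = (JwT @ resid[:, :, None])[:, :, 0]
        diag = np.maximum(np.einsum("npp->np", JtJ), 1e-30)
        if eye is None or eye.shape[0] != J.shape[2]:
            eye = np.eye(J.shape[2], dtype=J.dtype)
        aug = JtJ + (lam[idx, None] * diag)[:, :, None] * eye
        try:
            delta = np.linalg.solve(aug, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            aug = aug + 1e-6 * eye
            delta = np.linalg.solve(aug, g[:, :, None])[:, :, 0]
        p_trial = problem.clip((pa + delta).astype(p.dtype, copy=False), idx)
        chi2_trial, _ = problem.chi2(p_trial, idx)
        improved = chi2_trial < chi2[idx]
        step = np.abs(p_trial - pa) / (np.abs(pa) + 1e-3)
        rel_gain = (chi2[idx] - chi2_trial) / np.maximum(chi2[idx], 1e-30)
        small = (step.max(axis=1) < cfg.convergence_tol) | (
            np.abs(rel_gain) < 1e-7
        )
        acc = idx[improved]
        p[acc] = p_trial[improved]
        chi2[acc] = chi2_trial[improved]
        lam[acc] = np.maximum(lam[acc] * 0.25, 1e-10)
        lam[idx[~improved]] *= 6.0
        n_iter[idx] += 1
        done = improved & small
        stalled = lam[idx] > 1e9
        # A stall at huge damping with a vanishing gain is a converged
        # pixel whose surface is flat, not a failure.
        flat = stalled & (np.abs(rel_gain) < 1e-8)
        converged[idx[done | flat]] = True
        active[idx] = ~(done | stalled)
    return p, chi2, converged, n_iter


def _fit_decays(
    counts: np.ndarray,
    irf: IRFProfile,
    grid: AcquisitionGrid,
    config: FitConfig,
) -> dict:
    """Batched Levenberg-Marquardt fit of ``(N, T)`` decay histograms."""
    dtype = np.dtype(config.dtype)
    y = np.asarray(counts, dtype=dtype)
    n_pix, n_ch = y.shape
    op = _IrfConvolver(irf.kernel, grid.channel_width, dtype=dtype)

    include = np.ones(n_ch, dtype=bool)
    if config.exclude_rise:
        include[: max(irf.peak_channel - 3, 0)] = False
    if config.weighting == "uniform":
        w1 = np.ones_like(y)
    else:  # Neyman weights for the (first) pass
        w1 = 1.0 / np.maximum(y, 1.0)
    w1[:, ~include] = 0.0

    if config.init_strategy == "moments":
        a1_0, tau1_0, tau2_0 = _moments_init(y, op, config)
    elif config.init_strategy == "grid":
        a1_0, tau1_0, tau2_0, _ = _grid_search(y, w1, op, config)
    else:
        a1_0 = np.full(n_pix, config.fixed_init[0])
        tau1_0 = np.full(n_pix, config.fixed_init[1])
        tau2_0 = np.full(n_pix, config.fixed_init[2])
    a1_0 = np.clip(a1_0, *config.a1_bounds)
    tau1_0 = np.clip(tau1_0, *config.tau1_bounds)
    tau2_0 = np.clip(tau2_0, *config.tau2_bounds)

    from ._speedups import NUMBA_AVAILABLE, fit_batch

    use_numba = (
        config.engine in ("auto", "numba")
        and NUMBA_AVAILABLE
        and not config.fit_offset
        and not config.fit_shift
    )
    if config.engine == "numba" and not use_numba:
        raise DomainError(
            "numba engine unavailable (missing numba or offset/shift fitting "
            "requested); use engine='numpy'"
        )
    if use_numba:
        return _fit_decays_numba(
            counts, irf, grid, config, np.column_stack([a1_0, tau1_0, tau2_0]),
            include, fit_batch,
        )
    p = np.column_stack([a1_0, tau1_0, tau2_0])
    for _ in range(int(config.fit_offset) + int(config.fit_shift)):
        p = np.column_stack([p, np.zeros(n_pix)])
    p = p.astype(dtype)

    def grid_fallback(prob_all, p, chi2, converged, n_iter):
        """Restart non-converged pixels from the best coarse-grid point."""
        retry = ~converged
        if not retry.any() or config.init_strategy == "grid":
            return p, chi2, converged, n_iter
        sub = np.nonzero(retry)[0]
        a1_g, t1_g, t2_g, _ = _grid_search(
            prob_all.y[sub], prob_all.w[sub], op, config
        )
        p_g = np.column_stack(
            [
                np.clip(a1_g, *config.a1_bounds),
                np.clip(t1_g, *config.tau1_bounds),
                np.clip(t2_g, *config.tau2_bounds),
            ]
        )
        for _ in range(p.shape[1] - 3):
            p_g = np.column_stack([p_g, np.zeros(len(sub))])
        p_g = p_g.astype(dtype)
        sub_prob = _Problem(prob_all.y[sub], prob_all.w[sub], op, config)
        p_g, chi2_g, conv_g, iter_g = _lm_pass(sub_prob, p_g, config.max_iterations)
        better = (chi2_g < chi2[sub]) | conv_g
        p[sub[better]] = p_g[better]
        chi2[sub[better]] = chi2_g[better]
        converged[sub] = conv_g | converged[sub]
        n_iter[sub] += iter_g
        return p, chi2, converged, n_iter

    prob = _Problem(y, w1, op, config)
    if config.weighting == "model":
        # First pass only has to pin down the weights: reduced budget,
        # no fallback; convergence is judged on the second pass.
        p, chi2, _, n_iter = _lm_pass(prob, p, min(config.max_iterations, 8))
        model1, _, _ = prob.model(p, np.arange(n_pix))
        w2 = 1.0 / np.maximum(model1, 1.0)
        w2[:, ~include] = 0.0
        prob2 = _Problem(y, w2.astype(dtype), op, config)
        p, chi2, converged, iter2 = _lm_pass(prob2, p, config.max_iterations)
        n_iter += iter2
        p, chi2, converged, n_iter = grid_fallback(prob2, p, chi2, converged, n_iter)
        final_prob = prob2
    else:
        p, chi2, converged, n_iter = _lm_pass(prob, p, config.max_iterations)
        p, chi2, converged, n_iter = grid_fallback(prob, p, chi2, converged, n_iter)
        final_prob = prob

    model, A, _ = final_prob.model(p, np.arange(n_pix))

    a1_f = p[:, 0].astype(float)
    tau1_f = p[:, 1].astype(float)
    tau2_f = p[:, 2].astype(float)
    swap = tau1_f > tau2_f
    if swap.any():  # relabel so the free component stays the short one
        a1_f[swap], tau1_f[swap], tau2_f[swap] = (
            1.0 - a1_f[swap],
            tau2_f[swap],
            tau1_f[swap],
        )

    dof = int(include.sum()) - config.n_free_params
    if dof <= 0:
        raise DomainError("non-positive degrees of freedom in the fit")
    # Goodness-of-fit is always reported on the Neyman (or uniform) scale.
    if config.weighting == "uniform":
        w_rep = np.ones_like(y)
    else:
        w_rep = 1.0 / np.maximum(y, 1.0)
    w_rep[:, ~include] = 0.0
    chi2_red = (w_rep * (y - model) ** 2).sum(axis=1).astype(float) / dof

    offset_arr = p[:, 3].astype(float) if config.fit_offset else np.zeros(n_pix)
    shift_arr = (
        p[:, 3 + int(config.fit_offset)].astype(float)
        if config.fit_shift
        else np.zeros(n_pix)
    )
    taum = a1_f * tau1_f + (1.0 - a1_f) * tau2_f
    return {
        "a1": a1_f,
        "tau1": tau1_f,
        "tau2": tau2_f,
        "taum": taum,
        "amplitude": A.astype(float),
        "offset": offset_arr,
        "shift": shift_arr,
        "chi2_reduced": chi2_red,
        "converged": converged,
        "n_iterations": n_iter,
        "total_photons": np.asarray(counts, dtype=float).sum(axis=1),
    }


def _fit_decays_numba(
    counts: np.ndarray,
    irf: IRFProfile,
    grid: AcquisitionGrid,
    config: FitConfig,
    p0: np.ndarray,
    include: np.ndarray,
    fit_batch,
) -> dict:
    """Dispatch the three-parameter fit to the fused per-pixel kernel."""
    y = np.ascontiguousarray(counts, dtype=np.float64)
    kernel = np.asarray(irf.kernel, dtype=np.float64)
    nz = int(np.nonzero(kernel > 1e-14)[0][-1]) + 1 if kernel.any() else 1
    kj = np.ascontiguousarray(kernel[:nz])
    inc0 = int(np.argmax(include))  # first included channel (prefix exclusion)
    lb = np.array([config.a1_bounds[0], config.tau1_bounds[0], config.tau2_bounds[0]])
    ub = np.array([config.a1_bounds[1], config.tau1_bounds[1], config.tau2_bounds[1]])
    params, chi2_rep, conv, iters, amp = fit_batch(
        y,
        np.ascontiguousarray(p0, dtype=np.float64),
        kj,
        float(grid.channel_width),
        inc0,
        lb,
        ub,
        float(config.convergence_tol),
        int(config.max_iterations),
        config.weighting == "model",
        config.weighting == "uniform",
        _grid_combos(),
    )
    a1_f = params[:, 0].copy()
    tau1_f = params[:, 1].copy()
    tau2_f = params[:, 2].copy()
    swap = tau1_f > tau2_f
    if swap.any():
        a1_f[swap], tau1_f[swap], tau2_f[swap] = (
            1.0 - a1_f[swap],
            tau2_f[swap],
            tau1_f[swap],
        )
    dof = int(include.sum()) - config.n_free_params
    if dof <= 0:
        raise DomainError("non-positive degrees of freedom in the fit")
    n_pix = y.shape[0]
    return {
        "a1": a1_f,
        "tau1": tau1_f,
        "tau2": tau2_f,
        "taum": a1_f * tau1_f + (1.0 - a1_f) * tau2_f,
        "amplitude": amp,
        "offset": np.zeros(n_pix),
        "shift": np.zeros(n_pix),
        "chi2_reduced": chi2_rep / dof,
        "converged": conv,
        "n_iterations": iters.astype(int),
        "total_photons": y.sum(axis=1),
    }


def fit_pixel(
    decay,
    irf: IRFProfile,
    grid: AcquisitionGrid,
    config: FitConfig | None = None,
) -> PixelFitResult:
    """Fit one decay histogram; raises :class:`BelowThresholdError` if the
    photon total is under ``config.min_photons``.

    Single decays are fit in double precision regardless of the batch
    engine dtype.
    """
    from dataclasses import replace

    config = config or FitConfig()
    if config.dtype != "float64":
        config = replace(config, dtype="float64")
    counts = decay.counts if isinstance(decay, DecayHistogram) else np.asarray(decay)
    if counts.size != grid.n_time_channels:
        raise GridMismatchError(
            f"decay has {counts.size} channels, grid expects {grid.n_time_channels}"
        )
    if len(irf) != grid.n_time_channels:
        raise GridMismatchError("IRF and grid channel counts differ")
    total = float(counts.sum())
    if total < config.min_photons:
        raise BelowThresholdError(
            f"decay holds {total:.0f} photons < threshold {config.min_photons:.0f}"
        )
    res = _fit_decays(counts[None, :], irf, grid, config)
    return PixelFitResult(
        a1=float(res["a1"][0]),
        tau1=float(res["tau1"][0]),
        tau2=float(res["tau2"][0]),
        taum=float(res["taum"][0]),
        amplitude=float(res["amplitude"][0]),
        offset=float(res["offset"][0]),
        shift=float(res["shift"][0]),
        chi2_reduced=float(res["chi2_reduced"][0]),
        total_photons=total,
        converged=bool(res["converged"][0]),
        n_iterations=int(res["n_iterations"][0]),
    )


def fit_image(
    stack: np.ndarray,
    irf: IRFProfile,
    grid: AcquisitionGrid,
    config: FitConfig | None = None,
) -> FlimMaps:
    """Bin, threshold and fit every valid pixel of a decay stack.

    Returns :class:`FlimMaps` on the stack's spatial grid; pixels below
    threshold or with non-converged fits are NaN with ``valid_mask=False``.
    Deterministic: no randomness enters the optimizer.
    """
    config = config or FitConfig()
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != grid.n_time_channels:
        raise GridMismatchError(
            f"stack shape {stack.shape} does not match grid "
            f"({grid.n_time_channels}, {grid.height}, {grid.width})"
        )
    if len(irf) != grid.n_time_channels:
        raise GridMismatchError("IRF and grid channel counts differ")
    binned = bin_stack(stack, config.bin_factor)
    totals = binned.sum(axis=0).astype(float)
    above = totals >= config.min_photons

    shape = stack.shape[1:]
    maps = {
        name: np.full(shape, np.nan)
        for name in ("taum", "a1", "tau1", "tau2", "chi2_reduced")
    }
    valid = np.zeros(shape, dtype=bool)
    if not above.any():
        warnings.warn("no pixel exceeds the photon threshold; returning empty maps")
        return FlimMaps(**maps, total_photons=totals, valid_mask=valid, grid=grid)
    ys = binned[:, above].T
    res = _fit_decays(ys, irf, grid, config)
    for name in maps:
        maps[name][above] = res[name]
    valid[above] = res["converged"]
    for name in maps:
        maps[name][above & ~valid] = np.nan
    return FlimMaps(**maps, total_photons=totals, valid_mask=valid, grid=grid)
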