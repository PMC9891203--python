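"""Well-tempered metadynamics on 1–2 collective variables.

The engine runs overdamped Langevin dynamics on an analytic free-energy
landscape U(s) in CV space while periodically depositing Gaussian bias
kernels whose height decays with the accumulated bias (well-tempering):

    w = w0 · exp(−V(s)/(kB·ΔT)),   ΔT = (γ − 1)·T

so that the converged bias satisfies V(s) = −(1 − 1/γ)·F(s) + const and the
free-energy surface is recovered as F(s) = −γ/(γ−1)·V(s), min-shifted to 0.
Basin free-energy differences are Boltzmann-weighted integrals of the FES
over disjoint CV-space regions, and their uncertainty is estimated from the
spread of ΔG recomputed at cumulative checkpoints over the second half of
the deposition history.

Dynamics are Euler–Maruyama: s' = s − (D·dt/kBT)·∇(U+V) + √(2·D·dt)·ξ with
reflective walls at the CV box (periodic wrap for angular CVs).  The run
loop integrates forces interpolated from the same grid on which the bias is
accumulated; :func:`langevin_step` exposes the per-step update with the
analytic landscape gradient for testing and custom integrators.

The deposition log serializes to a HILLS-like whitespace table readable by
standard metadynamics post-processing tools.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "KB",
    "Landscape",
    "MetaDParams",
    "BiasState",
    "KernelDeposit",
    "MetaDRun",
    "FreeEnergySurface",
    "BasinSpec",
    "langevin_step",
    "deposit",
    "bias_value",
    "run_wtmetad",
    "fes_from_bias",
    "basin_delta_g",
    "block_error",
    "write_hills",
    "read_hills",
    "bias_from_kernels",
]

KB = 0.0019872  # kcal/(mol·K)


@dataclass
class Landscape:
    """An analytic CV-space free-energy landscape U(s) in kcal/mol.

    ``energy`` and ``gradient`` take a CV vector (length ``dimension``);
    ``box`` is (dimension, 2) with per-CV (min, max); ``periodic`` flags
    angular CVs (period = box width).
    """

    dimension: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    box: np.ndarray
    periodic: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(self.dimension, 2)
        if not self.periodic:
            self.periodic = tuple(False for _ in range(self.dimension))
        if np.any(self.box[:, 0] >= self.box[:, 1]):
            raise ValueError("box minima must be below maxima")

    def check_gradient(self, rng: np.random.Generator, n: int = 20, eps: float = 1e-5,
                       rtol: float = 1e-4) -> None:
        """Finite-difference consistency check of gradient vs energy."""
        lo, hi = self.box[:, 0], self.box[:, 1]
        margin = 0.01 * (hi - lo)
        for _ in range(n):
            s = lo + margin + rng.random(self.dimension) * (hi - lo - 2 * margin)
            g = np.asarray(self.gradient(s), dtype=float)
            fd = np.empty_like(g)
            for d in range(self.dimension):
                sp, sm = s.copy(), s.copy()
                sp[d] += eps
                sm[d] -= eps
                fd[d] = (self.energy(sp) - self.energy(sm)) / (2 * eps)
            scale = max(1.0, float(np.max(np.abs(fd))))
            if np.max(np.abs(g - fd)) > rtol * scale:
                raise ValueError(f"gradient inconsistent with energy at {s}: {g} vs {fd}")


@dataclass
class MetaDParams:
    """Well-tempered metadynamics biasing parameters.

    Defaults: w0 = 0.3 kcal/mol initial Gaussian height, per-CV width sigma,
    a deposition every ``stride`` integrator steps, bias factor γ = 10 and
    T = 298 K.
    """

    sigma: np.ndarray | float = 1.0
    w0: float = 0.3
    stride: int = 500
    bias_factor: float = 10.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.w0 <= 0:
            raise ParameterError("w0 must be positive")
        if np.any(self.sigma <= 0):
            raise ParameterError("sigma must be positive")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if self.bias_factor <= 1:
            raise ParameterError("bias factor must be > 1")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")

    @property
    def kb_delta_t(self) -> float:
        """kB·ΔT = kB·(γ−1)·T, the tempering energy scale."""
        return KB * (self.bias_factor - 1.0) * self.temperature


@dataclass
class KernelDeposit:
    """One deposited Gaussian: time (step index), center and height."""

    time: float
    center: np.ndarray
    height: float


class BiasState:
    """Gaussian-kernel history plus the gridded bias it sums to.

    The grid stores the bias V and its gradient components so that force
    evaluation during a run is a cheap (bi)linear interpolation.  Gaussian
    support is truncated at 6σ; angular dimensions use minimum-image
    distances and wrapped grid windows.
    """

    def __init__(
        self,
        box: np.ndarray,
        sigma: np.ndarray | float,
        spacing: np.ndarray | float | None = None,
        periodic: Sequence[bool] | None = None,
        truncation: float = 6.0,
    ):
        self.box = np.asarray(box, dtype=float).reshape(-1, 2)
        self.dim = len(self.box)
        self.sigma = np.broadcast_to(np.atleast_1d(np.asarray(sigma, dtype=float)),
                                     (self.dim,)).copy()
        if spacing is None:
            spacing = self.sigma / 4.0
        self.spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing, dtype=float)),
                                       (self.dim,)).copy()
        if periodic is None:
            periodic = [False] * self.dim
        self.periodic = tuple(bool(p) for p in periodic)
        self.truncation = float(truncation)

        self.axes: list[np.ndarray] = []
        shape = []
        for d in range(self.dim):
            lo, hi = self.box[d]
            if self.periodic[d]:
                n = max(int(round((hi - lo) / self.spacing[d])), 4)
                ax = lo + (hi - lo) * np.arange(n) / n
                self.spacing[d] = (hi - lo) / n
            else:
                n = max(int(round((hi - lo) / self.spacing[d])) + 1, 4)
                ax = np.linspace(lo, hi, n)
                self.spacing[d] = ax[1] - ax[0]
            self.axes.append(ax)
            shape.append(len(ax))
        self.shape = tuple(shape)
        self.bias = np.zeros(self.shape)
        self.grads = [np.zeros(self.shape) for _ in range(self.dim)]
        self.kernels: list[tuple[np.ndarray, float]] = []

    # -- bookkeeping -----------------------------------------------------

    def in_box(self, s: np.ndarray) -> bool:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        for d in range(self.dim):
            if self.periodic[d]:
                continue
            if not (self.box[d, 0] <= s[d] <= self.box[d, 1]):
                return False
        return True

    def _check_in_box(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if len(s) != self.dim:
            raise ValueError(f"expected {self.dim}-dimensional CV vector")
        if not self.in_box(s):
            raise ValueError(f"point {s} outside the CV box {self.box.tolist()}")
        return s

    def _wrap(self, s: np.ndarray) -> np.ndarray:
        out = s.copy()
        for d in range(self.dim):
            lo, hi = self.box[d]
            if self.periodic[d]:
                out[d] = lo + (out[d] - lo) % (hi - lo)
        return out

    def _interp_weights(self, s: np.ndarray):
        """Lower grid index and fractional offset per dimension."""
        idx, frac = [], []
        for d in range(self.dim):
            n = self.shape[d]
            u = (s[d] - self.box[d, 0]) / self.spacing[d]
            if self.periodic[d]:
                i = int(np.floor(u)) % n
                f = u - np.floor(u)
            else:
                i = int(np.floor(u))
                i = min(max(i, 0), n - 2)
                f = u - i
                f = min(max(f, 0.0), 1.0)
            idx.append(i)
            frac.append(f)
        return idx, frac

    def _interp(self, arr: np.ndarray, s: np.ndarray) -> float:
        idx, frac = self._interp_weights(s)
        if self.dim == 1:
            i, f = idx[0], frac[0]
            j = (i + 1) % self.shape[0]
            return float(arr[i] * (1 - f) + arr[j] * f)
        i, fx = idx[0], frac[0]
        j, fy = idx[1], frac[1]
        i1 = (i + 1) % self.shape[0]
        j1 = (j + 1) % self.shape[1]
        return float(
            arr[i, j] * (1 - fx) * (1 - fy)
            + arr[i1, j] * fx * (1 - fy)
            + arr[i, j1] * (1 - fx) * fy
            + arr[i1, j1] * fx * fy
        )

    def value(self, s) -> float:
        """Interpolated bias V(s), kcal/mol."""
        s = self._wrap(self._check_in_box(s))
        return self._interp(self.bias, s)

    def gradient(self, s) -> np.ndarray:
        """Interpolated bias gradient ∇V(s)."""
        s = self._wrap(self._check_in_box(s))
        return np.array([self._interp(g, s) for g in self.grads])

    def kernel_sum(self, s) -> float:
        """Direct summation over the kernel history (oracle for the grid)."""
        s = self._wrap(self._check_in_box(s))
        total = 0.0
        for center, height in self.kernels:
            z = 0.0
            for d in range(self.dim):
                delta = s[d] - center[d]
                if self.periodic[d]:
                    width = self.box[d, 1] - self.box[d, 0]
                    delta = (delta + width / 2) % width - width / 2
                z += (delta / self.sigma[d]) ** 2
            total += height * math.exp(-0.5 * z)
        return total

    # -- deposition ------------------------------------------------------

    def _kernel_patch(self, center: np.ndarray, height: float):
        """Window indices plus bias/gradient increments for one Gaussian."""
        idx_arrays = []
        deltas = []
        for d in range(self.dim):
            n = self.shape[d]
            half = int(np.ceil(self.truncation * self.sigma[d] / self.spacing[d]))
            c = (center[d] - self.box[d, 0]) / self.spacing[d]
            i0 = int(np.floor(c)) - half
            i1 = int(np.ceil(c)) + half
            if self.periodic[d]:
                m = min(i1 - i0 + 1, n)
                raw = np.arange(i0, i0 + m)
                idx = raw % n
                coords = self.box[d, 0] + raw * self.spacing[d]
                delta = coords - center[d]
                width = self.box[d, 1] - self.box[d, 0]
                delta = (delta + width / 2) % width - width / 2
            else:
                i0 = max(i0, 0)
                i1 = min(i1, n - 1)
                idx = np.arange(i0, i1 + 1)
                delta = self.axes[d][idx] - center[d]
            idx_arrays.append(idx)
            deltas.append(delta)

        if self.dim == 1:
            g = height * np.exp(-0.5 * (deltas[0] / self.sigma[0]) ** 2)
            grad_patches = [-(deltas[0] / self.sigma[0] ** 2) * g]
        else:
            gx = np.exp(-0.5 * (deltas[0] / self.sigma[0]) ** 2)
            gy = np.exp(-0.5 * (deltas[1] / self.sigma[1]) ** 2)
            g = height * gx[:, None] * gy[None, :]
            grad_patches = [
                -(deltas[0][:, None] / self.sigma[0] ** 2) * g,
                -(deltas[1][None, :] / self.sigma[1] ** 2) * g,
            ]
        return idx_arrays, g, grad_patches

    def add_kernel(self, center, height: float):
        """Accumulate one Gaussian onto the grid; returns the patch so callers
        maintaining derived grids (e.g. total-force tables) can reuse it."""
        center = self._wrap(self._check_in_box(center))
        idx, g, grad_patches = self._kernel_patch(center, height)
        if self.dim == 1:
            self.bias[idx[0]] += g
            self.grads[0][idx[0]] += grad_patches[0]
        else:
            ix = np.ix_(idx[0], idx[1])
            self.bias[ix] += g
            for d in range(self.dim):
                self.grads[d][ix] += grad_patches[d]
        self.kernels.append((center.copy(), float(height)))
        return idx, g, grad_patches


def bias_value(bias: BiasState, s) -> float:
    """Interpolated bias at s (module-level convenience)."""
    return bias.value(s)


def deposit(bias: BiasState, s, params: MetaDParams) -> BiasState:
    """Deposit one well-tempered Gaussian at s and return the updated state.

    The height is w0·exp(−V(s)/kBΔT) with V(s) the pre-deposition bias, so
    the first kernel anywhere has height exactly w0 and heights at any
    revisited point are non-increasing.
    """
    v = bias.value(s)
    height = params.w0 * math.exp(-v / params.kb_delta_t)
    bias.add_kernel(s, height)
    return bias


def langevin_step(
    state,
    landscape: Landscape,
    bias: BiasState | None,
    dt: float,
    diffusion: float,
    temperature: float,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
):
    """One Euler–Maruyama step of overdamped Langevin dynamics on U + V.

    ``noise`` overrides the random draw (a zero vector gives the
    deterministic drift map used in tests).  Reflective boundaries at the
    box; periodic wrap for angular CVs.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if diffusion <= 0:
        raise ParameterError("diffusion coefficient must be positive")
    s = np.atleast_1d(np.asarray(state, dtype=float)).copy()
    g = np.asarray(landscape.gradient(s), dtype=float).copy()
    if bias is not None and bias.kernels:
        g = g + bias.gradient(s)
    if noise is None:
        if rng is None:
            raise ValueError("either rng or noise must be provided")
        noise = rng.standard_normal(len(s))
    s = s - (diffusion * dt / (KB * temperature)) * g + math.sqrt(2 * diffusion * dt) * np.asarray(noise)
    for d in range(landscape.dimension):
        lo, hi = landscape.box[d]
        if landscape.periodic[d]:
            s[d] = lo + (s[d] - lo) % (hi - lo)
        else:
            # reflect until inside (steps are small; loop rarely repeats)
            while s[d] < lo or s[d] > hi:
                if s[d] < lo:
                    s[d] = 2 * lo - s[d]
                if s[d] > hi:
                    s[d] = 2 * hi - s[d]
    return s


@dataclass
class MetaDRun:
    """Result bundle of one metadynamics run."""

    trajectory: np.ndarray  # (n_saved, dim) CV positions
    save_times: np.ndarray  # step index of each saved frame
    bias: BiasState
    log: list[KernelDeposit]
    params: MetaDParams
    seed: int


def run_wtmetad(
    landscape: Landscape,
    params: MetaDParams,
    n_steps: int,
    dt: float,
    diffusion: float,
    seed: int,
    initial: np.ndarray | None = None,
    grid_spacing: np.ndarray | float | None = None,
    traj_stride: int | None = None,
) -> MetaDRun:
    """Run well-tempered metadynamics with overdamped Langevin dynamics.

    Bit-reproducible for fixed seed and parameters.  Forces are interpolated
    from grids: the landscape gradient is tabulated once on the bias grid and
    each deposition patches both the bias and the total-force tables, so the
    per-step cost is independent of the kernel count.  One deposition occurs
    every ``params.stride`` steps; the trajectory is saved every
    ``traj_stride`` steps (default: the deposition stride).
    """
    if dt <= 0 or diffusion <= 0:
        raise ParameterError("dt and diffusion must be positive")
    dim = landscape.dimension
    sigma = np.broadcast_to(params.sigma, (dim,))
    bias = BiasState(landscape.box, sigma, spacing=grid_spacing, periodic=landscape.periodic)
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = landscape.box.mean(axis=1)
    s = np.atleast_1d(np.asarray(initial, dtype=float)).copy()
    if not bias.in_box(s):
        raise ValueError("initial state outside the CV box")
    if traj_stride is None:
        traj_stride = params.stride

    # total-force tables: landscape gradient sampled on the bias grid, to be
    # incremented in place by every kernel patch
    mesh = np.meshgrid(*bias.axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    base = np.stack([np.asarray(landscape.gradient(p), dtype=float) for p in pts])
    total = [base[:, d].reshape(bias.shape).copy() for d in range(dim)]

    mob = diffusion * dt / (KB * params.temperature)
    amp = math.sqrt(2.0 * diffusion * dt)
    stride = params.stride
    kb_dT = params.kb_delta_t
    w0 = params.w0

    traj = []
    save_times = []
    log: list[KernelDeposit] = []

    lo0, hi0 = bias.box[0]
    h0 = bias.spacing[0]
    n0 = bias.shape[0]
    per0 = bias.periodic[0]
    if dim == 2:
        lo1, hi1 = bias.box[1]
        h1 = bias.spacing[1]
        n1 = bias.shape[1]
        per1 = bias.periodic[1]
        T0, T1 = total[0], total[1]
        x, y = float(s[0]), float(s[1])
    else:
        T0 = total[0]
        x = float(s[0])

    step = 0
    while step < n_steps:
        chunk = min(stride, n_steps - step)
        xi = rng.standard_normal((chunk, dim))
        if dim == 1:
            for k in range(chunk):
                u = (x - lo0) / h0
                i = int(u)
                if per0:
                    f = u - i
                    i = i % n0
                    ip = (i + 1) % n0
                else:
                    if i > n0 - 2:
                        i = n0 - 2
                    elif i < 0:
                        i = 0
                    f = u - i
                    ip = i + 1
                g = T0[i] * (1.0 - f) + T0[ip] * f
                x = x - mob * g + amp * xi[k, 0]
                if per0:
                    x = lo0 + (x - lo0) % (hi0 - lo0)
                else:
                    while x < lo0 or x > hi0:
                        if x < lo0:
                            x = 2 * lo0 - x
                        if x > hi0:
                            x = 2 * hi0 - x
                if (step + k + 1) % traj_stride == 0:
                    traj.append((x,))
                    save_times.append(step + k + 1)
        else:
            for k in range(chunk):
                u = (x - lo0) / h0
                i = int(u)
                if per0:
                    fx = u - i
                    i = i % n0
                    ip = (i + 1) % n0
                else:
                    if i > n0 - 2:
                        i = n0 - 2
                    elif i < 0:
                        i = 0
                    fx = u - i
                    ip = i + 1
                v = (y - lo1) / h1
                j = int(v)
                if per1:
                    fy = v - j
                    j = j % n1
                    jp = (j + 1) % n1
                else:
                    if j > n1 - 2:
                        j = n1 - 2
                    elif j < 0:
                        j = 0
                    fy = v - j
                    jp = j + 1
                w00 = (1.0 - fx) * (1.0 - fy)
                w10 = fx * (1.0 - fy)
                w01 = (1.0 - fx) * fy
                w11 = fx * fy
                gx = T0[i, j] * w00 + T0[ip, j] * w10 + T0[i, jp] * w01 + T0[ip, jp] * w11
                gy = T1[i, j] * w00 + T1[ip, j] * w10 + T1[i, jp] * w01 + T1[ip, jp] * w11
                x = x - mob * gx + amp * xi[k, 0]
                y = y - mob * gy + amp * xi[k, 1]
                if per0:
                    x = lo0 + (x - lo0) % (hi0 - lo0)
                else:
                    while x < lo0 or x > hi0:
                        if x < lo0:
                            x = 2 * lo0 - x
                        if x > hi0:
                            x = 2 * hi0 - x
                if per1:
                    y = lo1 + (y - lo1) % (hi1 - lo1)
                else:
                    while y < lo1 or y > hi1:
                        if y < lo1:
                            y = 2 * lo1 - y
                        if y > hi1:
                            y = 2 * hi1 - y
                if (step + k + 1) % traj_stride == 0:
                    traj.append((x, y))
                    save_times.append(step + k + 1)
        step += chunk

        if chunk == stride:  # deposition boundary reached
            pos = np.array((x,) if dim == 1 else (x, y))
            v_here = bias.value(pos)
            height = w0 * math.exp(-v_here / kb_dT)
            idx, _g, grad_patches = bias.add_kernel(pos, height)
            if dim == 1:
                T0[idx[0]] += grad_patches[0]
            else:
                ix = np.ix_(idx[0], idx[1])
                T0[ix] += grad_patches[0]
                T1[ix] += grad_patches[1]
            log.append(KernelDeposit(time=float(step), center=pos, height=height))

    return MetaDRun(
        trajectory=np.asarray(traj, dtype=float),
        save_times=np.asarray(save_times, dtype=int),
        bias=bias,
        log=log,
        params=params,
        seed=seed,
    )


# --- FES reconstruction and basin thermodynamics ------------------------------

@dataclass
class FreeEnergySurface:
    """Gridded free energy over 1–2 CVs, min-shifted to 0."""

    axes: list[np.ndarray]
    F: np.ndarray
    gamma: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.F)):
            raise ValueError("free energy must be finite on the grid")

    @property
    def dim(self) -> int:
        return len(self.axes)

    def cell_volume(self) -> float:
        vol = 1.0
        for ax in self.axes:
            vol *= float(ax[1] - ax[0])
        return vol

    def to_text(self) -> str:
        """Two/three-column plain-text grid (coordinates then F)."""
        out = io.StringIO()
        out.write("#! FIELDS " + " ".join(f"cv{d+1}" for d in range(self.dim)) + " free_energy\n")
        if self.dim == 1:
            for xv, fv in zip(self.axes[0], self.F):
                out.write(f"{xv:.6f} {fv:.6f}\n")
        else:
            for i, xv in enumerate(self.axes[0]):
                for j, yv in enumerate(self.axes[1]):
                    out.write(f"{xv:.6f} {yv:.6f} {self.F[i, j]:.6f}\n")
        return out.getvalue()


def fes_from_bias(bias: BiasState, params: MetaDParams, provenance: str = "") -> FreeEnergySurface:
    """Reconstruct the FES from the accumulated bias: F = −γ/(γ−1)·V, shifted
    so that min F = 0."""
    if not bias.kernels:
        raise ValueError("cannot reconstruct an FES from an empty bias")
    gamma = params.bias_factor
    F = -(gamma / (gamma - 1.0)) * bias.bias
    F = F - F.min()
    return FreeEnergySurface(axes=[ax.copy() for ax in bias.axes], F=F, gamma=gamma,
                             provenance=provenance)


@dataclass
class BasinSpec:
    """A named CV-space region: a per-CV interval box or a center + radius."""

    name: str
    box: Sequence[tuple[float, float]] | None = None
    center: Sequence[float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if (self.box is None) == (self.center is None):
            raise ValueError("specify exactly one of box or center+radius")
        if self.center is not None and (self.radius is None or self.radius <= 0):
            raise ValueError("center-style basins need a positive radius")

    def mask(self, axes: Sequence[np.ndarray]) -> np.ndarray:
        mesh = np.meshgrid(*axes, indexing="ij")
        if self.box is not None:
            m = np.ones(mesh[0].shape, dtype=bool)
            for d, (lo, hi) in enumerate(self.box):
                m &= (mesh[d] >= lo) & (mesh[d] <= hi)
            return m
        r2 = np.zeros(mesh[0].shape)
        for d, c in enumerate(self.center):
            r2 += (mesh[d] - c) ** 2
        return r2 <= self.radius ** 2


def basin_delta_g(fes: FreeEnergySurface, a: BasinSpec, b: BasinSpec, temperature: float) -> float:
    """Free-energy difference ΔG_{a→b} = −kBT·ln(Z_b/Z_a) from Boltzmann sums
    of the FES over the two (disjoint) basin regions."""
    ma = a.mask(fes.axes)
    mb = b.mask(fes.axes)
    if not ma.any():
        raise ValueError(f"basin {a.name!r} contains no grid points")
    if not mb.any():
        raise ValueError(f"basin {b.name!r} contains no grid points")
    if (ma & mb).any():
        raise ValueError(f"basins {a.name!r} and {b.name!r} overlap")
    beta = 1.0 / (KB * temperature)
    vol = fes.cell_volume()
    za = float(np.sum(np.exp(-beta * fes.F[ma]))) * vol
    zb = float(np.sum(np.exp(-beta * fes.F[mb]))) * vol
    return float(-KB * temperature * math.log(zb / za))


@dataclass
class BlockErrorResult:
    """ΔG estimates at cumulative checkpoints and their spread."""

    estimates: np.ndarray
    error: float  # population standard deviation of the estimates
    delta_g: float  # estimate from the full deposition history


def block_error(
    log: Sequence[KernelDeposit],
    bias: BiasState,
    params: MetaDParams,
    basin_a: BasinSpec,
    basin_b: BasinSpec,
    n_blocks: int = 5,
) -> BlockErrorResult:
    """Uncertainty of a basin ΔG from cumulative checkpoints.

    The bias is replayed from the deposition log; ΔG is recomputed at
    ``n_blocks`` cumulative checkpoints spanning the second half of the run
    and the population standard deviation of those estimates is reported.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    n = len(log)
    if n < 2 * n_blocks:
        raise ValueError(f"deposition log too short ({n} kernels) for {n_blocks} blocks")
    checkpoints = np.unique(np.round(np.linspace(n // 2, n, n_blocks)).astype(int))
    replay = BiasState(bias.box, bias.sigma, spacing=bias.spacing, periodic=bias.periodic,
                       truncation=bias.truncation)
    estimates = []
    k = 0
    for cp in checkpoints:
        while k < cp:
            replay.add_kernel(log[k].center, log[k].height)
            k += 1
        fes = fes_from_bias(replay, params)
        estimates.append(basin_delta_g(fes, basin_a, basin_b, params.temperature))
    estimates = np.asarray(estimates)
    return BlockErrorResult(
        estimates=estimates,
        error=float(np.std(estimates)),
        delta_g=float(estimates[-1]),
    )


# --- HILLS-like serialization -------------------------------------------------

def write_hills(run: MetaDRun) -> str:
    """Serialize the deposition log as a HILLS-like whitespace table."""
    dim = run.bias.dim
    cols = [f"cv{d+1}" for d in range(dim)]
    header = "#! FIELDS time " + " ".join(cols) + " " + \
        " ".join(f"sigma_{c}" for c in cols) + " height biasf\n"
    lines = [header]
    sig = " ".join(f"{s:.6f}" for s in run.bias.sigma)
    for dep in run.log:
        center = " ".join(f"{c:.6f}" for c in dep.center)
        lines.append(f"{dep.time:.1f} {center} {sig} {dep.height:.9f} "
                     f"{run.params.bias_factor:.3f}\n")
    return "".join(lines)


def read_hills(text: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Parse a HILLS-like table back into (times, centers, sigmas, heights, biasf)."""
    rows = []
    dim = None
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            if line.startswith("#! FIELDS"):
                fields = line.split()[2:]
                dim = sum(1 for f in fields if f.startswith("cv") and not f.startswith("sigma"))
            continue
        rows.append([float(v) for v in line.split()])
    if not rows:
        raise ValueError("empty HILLS content")
    data = np.asarray(rows)
    if dim is None:
        dim = (data.shape[1] - 3) // 2
    times = data[:, 0]
    centers = data[:, 1:1 + dim]
    sigmas = data[:, 1 + dim:1 + 2 * dim]
    heights = data[:, 1 + 2 * dim]
    biasf = float(data[0, 2 + 2 * dim])
    return times, centers, sigmas, heights, biasf


def bias_from_kernels(
    centers: np.ndarray,
    heights: np.ndarray,
    sigma: np.ndarray | float,
    box: np.ndarray,
    spacing: np.ndarray | float | None = None,
    periodic: Sequence[bool] | None = None,
) -> BiasState:
    """Rebuild a gridded bias from an explicit kernel list (e.g. a HILLS file)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    bias = BiasState(box, sigma, spacing=spacing, periodic=periodic)
    for c, h in zip(centers, np.atleast_1d(heights)):
        bias.add_kernel(c, float(h))
    return bias
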