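"""Forward simulation of optical-trap transmission traces with known ground truth.

The generator mirrors the physics of the measurement in three layers:

1. A discrete-time Markov chain over conformational states (N/F/E for the
   monomer, C/O for the dimer) with one step per 100 ms recognition slice.
   Off-diagonal transition probabilities follow Kramers' viscous-limit form,
   ``P = const * exp(-E_A / k_BT)``, with the constants tied together by
   curvature ratios of the wells and barriers so that a single prefactor A
   remains free.
2. A per-sample voltage drawn around the occupied state's mean level.  With
   conformational breadth enabled (the default used by :func:`simulate_trace`)
   the within-state voltage is Gaussian with sd ``1/sqrt(omega_well)``, so the
   long-run voltage density is exactly the Gaussian-mixture Boltzmann density
   of a triple-well landscape — the landscape downstream modules try to
   recover.
3. Instrument effects: additive Gaussian point-spread noise, slow stage
   drift, and ADC quantization to a least-significant-bit grid.

Energies are in units of k_BT throughout; voltages in volts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core import StateSequence, TransmissionTrace, as_rng

__all__ = [
    "GroundTruthSpec",
    "AcquisitionSpec",
    "build_transition_matrix",
    "transition_matrix_from_params",
    "stationary_distribution",
    "simulate_chain",
    "render_trace",
    "simulate_trace",
    "mixture_density",
    "analytic_landscape",
    "design_three_state_spec",
    "design_two_state_spec",
]


@dataclass(frozen=True)
class GroundTruthSpec:
    """Ground-truth landscape and kinetics for a synthetic trapping trace.

    ``state_energies`` are the free-energy minima M_i (k_BT, relative to the
    first state) and ``barrier_energies`` the saddle values S_j between
    adjacent states, so activation energies are S_j - M_i.  Curvatures are
    second-derivative magnitudes of the landscape on the voltage coordinate
    (k_BT/V^2); only their ratios enter the kinetics, while well curvatures
    additionally set the conformational breadth 1/sqrt(omega) of each state.
    """

    state_levels: tuple[float, ...]
    state_energies: tuple[float, ...]
    barrier_energies: tuple[float, ...]
    well_curvatures: tuple[float, ...]
    barrier_curvatures: tuple[float, ...]
    prefactor_a: float = 0.9
    temperature: float = 310.0

    def __post_init__(self) -> None:
        for name in ("state_levels", "state_energies", "barrier_energies",
                     "well_curvatures", "barrier_curvatures"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        n = len(self.state_levels)
        if n not in (2, 3):
            raise ValueError("2 or 3 states required")
        if len(self.state_energies) != n or len(self.well_curvatures) != n:
            raise ValueError("state_energies/well_curvatures must match state count")
        if len(self.barrier_energies) != n - 1 or len(self.barrier_curvatures) != n - 1:
            raise ValueError("need one barrier per adjacent state pair")
        if any(np.diff(self.state_levels) <= 0):
            raise ValueError("state_levels must be strictly increasing "
                             "(expansion increases transmission)")
        for j, s in enumerate(self.barrier_energies):
            if s <= self.state_energies[j] or s <= self.state_energies[j + 1]:
                raise ValueError("every barrier must exceed both adjacent minima")
        if any(w <= 0 for w in self.well_curvatures + self.barrier_curvatures):
            raise ValueError("curvatures must be positive")
        if not 0.0 < self.prefactor_a < 1.0:
            raise ValueError("prefactor_a must lie in (0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_states(self) -> int:
        return len(self.state_levels)

    @property
    def activation_energies(self) -> np.ndarray:
        """Array of (E_fwd, E_rev) per barrier: (S_j - M_j, S_j - M_{j+1})."""
        out = []
        for j, s in enumerate(self.barrier_energies):
            out.append((s - self.state_energies[j], s - self.state_energies[j + 1]))
        return np.asarray(out)

    @property
    def well_sigmas(self) -> np.ndarray:
        """Boltzmann breadth of each well on the voltage axis: 1/sqrt(omega)."""
        return 1.0 / np.sqrt(np.asarray(self.well_curvatures))

    def with_prefactor(self, a: float) -> "GroundTruthSpec":
        return replace(self, prefactor_a=a)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Instrument model: sampling, noise, drift, quantization, seeding."""

    duration: float = 100.0
    sampling_rate: float = 100_000.0
    slice_duration: float = 0.1
    noise_sigma: float = 0.0134     # PSF width in volts
    lsb: float = 0.002441           # ADC least significant bit in volts
    drift_model: str = "segment"    # none | segment | linear | random_walk
    drift_scale: float = 0.005      # V per 20 s drift segment
    drift_segment_duration: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0 or self.slice_duration <= 0:
            raise ValueError("duration, sampling_rate and slice_duration must be positive")
        spp = self.sampling_rate * self.slice_duration
        if abs(spp - round(spp)) > 1e-9 or round(spp) < 1:
            raise ValueError("sampling_rate x slice_duration must be a positive integer")
        if self.noise_sigma < 0 or self.lsb < 0:
            raise ValueError("noise_sigma and lsb must be non-negative")
        if self.drift_model not in ("none", "segment", "linear", "random_walk"):
            raise ValueError(f"unknown drift_model {self.drift_model!r}")

    @property
    def samples_per_slice(self) -> int:
        return int(round(self.sampling_rate * self.slice_duration))

    @property
    def n_slices(self) -> int:
        return int(self.duration / self.slice_duration)


def transition_matrix_from_params(
    activation: np.ndarray,
    well_curvatures: Sequence[float],
    barrier_curvatures: Sequence[float],
    prefactor_a: float,
) -> np.ndarray:
    """Per-step stochastic matrix from activation energies and curvature ratios.

    ``activation[j] = (E_fwd, E_rev)`` for the barrier between states j and
    j+1 (k_BT).  The nearest-neighbour off-diagonals are

        P(j -> j+1) = c_fwd * exp(-E_fwd),   P(j+1 -> j) = c_rev * exp(-E_rev)

    with the proportionality constants chained from the single prefactor A by
    curvature ratios: for the first barrier c_fwd = A and c_rev = A*w1/w0; for
    the second barrier the barrier-curvature ratio enters as well,
    c_rev(E->F) = A*(wb1/wb0)*(w1/w2) and c_fwd(F->E) = A*(wb1/wb0)*(w2/w1).
    Direct N<->E hops are forbidden.  Diagonals complete each row to one.
    """
    w = np.asarray(well_curvatures, dtype=float)
    wb = np.asarray(barrier_curvatures, dtype=float)
    act = np.asarray(activation, dtype=float)
    n = w.size
    a = float(prefactor_a)
    p = np.zeros((n, n))
    # constants: A for N->F; B = A*wF/wN for F->N; for the second barrier
    # C = A*(wFE/wNF)*(wF/wE) for E->F and D = A*(wFE/wNF)*(wE/wF) for F->E.
    p[0, 1] = a * math.exp(-act[0, 0])
    p[1, 0] = a * (w[1] / w[0]) * math.exp(-act[0, 1])
    if n == 3:
        ratio = wb[1] / wb[0]
        p[1, 2] = a * ratio * (w[2] / w[1]) * math.exp(-act[1, 0])
        p[2, 1] = a * ratio * (w[1] / w[2]) * math.exp(-act[1, 1])
    for i in range(n):
        exit_p = p[i].sum()
        if exit_p > 1.0 + 1e-12:
            raise ValueError(
                f"per-step exit probability {exit_p:.4f} from state {i} exceeds 1; "
                "prefactor A is too large for this landscape at this step size"
            )
        if np.any(p[i] < 0) or np.any(p[i] > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        p[i, i] = 1.0 - exit_p
    return p


def build_transition_matrix(spec: GroundTruthSpec) -> np.ndarray:
    """Per-step transition matrix over the spec's states (see module docs)."""
    return transition_matrix_from_params(
        spec.activation_energies, spec.well_curvatures,
        spec.barrier_curvatures, spec.prefactor_a,
    )


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Left eigenvector of a row-stochastic matrix, normalized to sum 1."""
    matrix = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eig(matrix.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_chain(
    matrix: np.ndarray,
    n_steps: int,
    initial_state: int | None = None,
    seed: int | np.random.Generator | None = None,
    slice_duration: float = 0.1,
) -> StateSequence:
    """Simulate a Markov trajectory; one step per recognition slice.

    Dwells in each state are geometric with that state's per-step exit
    probability.  ``initial_state=None`` draws the start from the stationary
    distribution so long traces are equilibrium traces from the first slice.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9) or matrix.min() < -1e-12:
        raise ValueError("matrix must be row-stochastic")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = as_rng(seed)
    n = matrix.shape[0]
    if initial_state is None:
        initial_state = int(rng.choice(n, p=stationary_distribution(matrix)))
    if not 0 <= initial_state < n:
        raise ValueError("initial_state out of range")
    cum = matrix.cumsum(axis=1)
    cum[:, -1] = 1.0  # guard rounding in searchsorted
    u = rng.random(n_steps)
    labels = np.empty(n_steps, dtype=np.int64)
    # plain python loop over rows of a tiny matrix; lists beat ndarray indexing here
    cum_rows = [row.tolist() for row in cum]
    state = int(initial_state)
    uu = u.tolist()
    for i in range(n_steps):
        row = cum_rows[state]
        x = uu[i]
        s = 0
        while row[s] <= x:
            s += 1
        state = s
        labels[i] = s
    return StateSequence(labels, slice_duration, n_states=n)


def _drift_offsets(acq: AcquisitionSpec, n_samples: int, rng: np.random.Generator):
    """Per-sample drift array (or 0.0) plus the per-segment offset record."""
    if acq.drift_model == "none" or acq.drift_scale == 0.0:
        return 0.0, np.zeros(0)
    seg_len = int(round(acq.drift_segment_duration * acq.sampling_rate))
    n_seg = max(1, math.ceil(n_samples / seg_len))
    if acq.drift_model == "segment":
        seg = rng.normal(0.0, acq.drift_scale, n_seg)
    elif acq.drift_model == "random_walk":
        seg = np.cumsum(rng.normal(0.0, acq.drift_scale, n_seg))
    else:  # linear ramp, drift_scale volts per segment duration
        seg = acq.drift_scale * np.arange(n_seg, dtype=float)
    drift = np.repeat(seg, seg_len)[:n_samples]
    return drift, seg


def quantize(samples: np.ndarray, lsb: float) -> np.ndarray:
    """Round to the nearest LSB multiple, halves away from zero (ADC model)."""
    if lsb <= 0:
        return samples
    return np.sign(samples) * np.floor(np.abs(samples) / lsb + 0.5) * lsb


def render_trace(
    states: StateSequence,
    acq: AcquisitionSpec,
    levels: Sequence[float],
    state_sigmas: Sequence[float] | None = None,
    temperature: float = 310.0,
    rng: int | np.random.Generator | None = None,
) -> TransmissionTrace:
    """Expand a state sequence into a sampled voltage trace.

    Each slice becomes ``samples_per_slice`` samples at its state's mean
    level; optional per-state conformational breadth (``state_sigmas``) and
    the PSF noise are added, then drift, then LSB quantization.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size != states.n_states or np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be strictly increasing, one per state")
    if abs(acq.slice_duration - states.slice_duration) > 1e-12:
        raise ValueError("acquisition slice_duration must match the state sequence")
    rng = as_rng(acq.seed if rng is None else rng)
    spp = acq.samples_per_slice
    n = states.n_slices * spp
    volts = np.repeat(levels[states.labels], spp)
    if state_sigmas is not None:
        sig = np.asarray(state_sigmas, dtype=float)
        if sig.size != states.n_states or np.any(sig < 0):
            raise ValueError("state_sigmas must be non-negative, one per state")
        if np.any(sig > 0):
            volts += np.repeat(sig[states.labels], spp) * rng.standard_normal(n)
    if acq.noise_sigma > 0:
        volts += acq.noise_sigma * rng.standard_normal(n)
    drift, seg_offsets = _drift_offsets(acq, n, rng)
    if np.ndim(drift) > 0 or drift != 0.0:
        volts += drift
    volts = quantize(volts, acq.lsb)
    meta = {
        "noise_sigma": acq.noise_sigma,
        "lsb": acq.lsb,
        "seed": acq.seed,
        "levels": levels.tolist(),
        "drift_model": acq.drift_model,
        "drift_offsets": np.asarray(seg_offsets).tolist(),
        "drift_segment_duration": acq.drift_segment_duration,
        "slice_duration": acq.slice_duration,
    }
    return TransmissionTrace(volts, acq.sampling_rate, temperature, meta)


def simulate_trace(
    spec: GroundTruthSpec,
    acq: AcquisitionSpec,
    seed: int | np.random.Generator | None = None,
) -> tuple[TransmissionTrace, StateSequence]:
    """Full forward model: chain -> conformational breadth -> instrument.

    Returns the rendered trace and the ground-truth state sequence.  The
    long-run (drift-free) voltage density is the Gaussian mixture
    ``sum_i pi_i N(level_i, 1/omega_i + noise_sigma^2)`` where pi is the
    chain's stationary distribution.
    """
    rng = as_rng(acq.seed if seed is None else seed)
    matrix = build_transition_matrix(spec)
    states = simulate_chain(matrix, acq.n_slices, seed=rng,
                            slice_duration=acq.slice_duration)
    trace = render_trace(states, acq, spec.state_levels,
                         state_sigmas=spec.well_sigmas,
                         temperature=spec.temperature, rng=rng)
    trace.metadata["ground_truth"] = {
        "state_energies": list(spec.state_energies),
        "barrier_energies": list(spec.barrier_energies),
        "prefactor_a": spec.prefactor_a,
    }
    return trace, states


# ---------------------------------------------------------------------------
# Analytic (oracle) landscape realized by the generator
# ---------------------------------------------------------------------------

def mixture_density(spec: GroundTruthSpec, grid: np.ndarray) -> np.ndarray:
    """Long-run pre-PSF voltage density realized by :func:`simulate_trace`."""
    pi = stationary_distribution(build_transition_matrix(spec))
    grid = np.asarray(grid, dtype=float)
    dens = np.zeros_like(grid)
    for p, mu, s in zip(pi, spec.state_levels, spec.well_sigmas):
        dens += p * np.exp(-0.5 * ((grid - mu) / s) ** 2) / (s * math.sqrt(2 * math.pi))
    return dens


def analytic_landscape(
    spec: GroundTruthSpec, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact energy landscape (k_BT, min 0) the generator realizes.

    This is the oracle for recovery tests: the Boltzmann inversion of the
    stationary Gaussian-mixture density, evaluated on ``grid`` (a dense
    default grid spanning the wells if omitted).
    """
    if grid is None:
        lv = np.asarray(spec.state_levels)
        s = spec.well_sigmas
        lo = lv[0] - 5 * s[0]
        hi = lv[-1] + 5 * s[-1]
        grid = np.linspace(lo, hi, 6001)
    u = -np.log(mixture_density(spec, grid))
    return grid, u - u.min()


# ---------------------------------------------------------------------------
# Designers: solve for a spec whose realized landscape hits requested values
# ---------------------------------------------------------------------------

def _realized(levels, pis, sigma):
    """Extremum scan of -log of an equal-sigma Gaussian mixture."""
    lv = np.asarray(levels, dtype=float)
    grid = np.linspace(lv[0] - 5 * sigma, lv[-1] + 5 * sigma, 8001)
    dens = np.zeros_like(grid)
    for p, mu in zip(pis, lv):
        dens += p * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    u = -np.log(dens)
    mins, sads = [], []
    for j, mu in enumerate(lv):
        lo = grid[0] if j == 0 else 0.5 * (lv[j - 1] + mu)
        hi = grid[-1] if j == len(lv) - 1 else 0.5 * (mu + lv[j + 1])
        m = (grid >= lo) & (grid <= hi)
        i = np.argmin(u[m])
        mins.append((grid[m][i], u[m][i]))
    for j in range(len(lv) - 1):
        m = (grid >= mins[j][0]) & (grid <= mins[j + 1][0])
        i = np.argmax(u[m])
        sads.append((grid[m][i], u[m][i]))
    return grid, u, mins, sads


def _curvature_at(grid, u, x0):
    h = grid[1] - grid[0]
    i = int(np.argmin(np.abs(grid - x0)))
    i = min(max(i, 1), grid.size - 2)
    return (u[i - 1] - 2 * u[i] + u[i + 1]) / h**2


def design_three_state_spec(
    delta_g_nf: float = 1.0,
    delta_g_fe: float = 0.5,
    barrier_nf: float = 3.5,
    barrier_fe: float = 3.0,
    well_sigma: float = 0.025,
    base_level: float = 0.30,
    prefactor_a: float = 0.9,
    temperature: float = 310.0,
) -> GroundTruthSpec:
    """Three-state spec whose *realized* mixture landscape hits the targets.

    ``delta_g_nf``/``delta_g_fe`` are M_F - M_N and M_E - M_F (k_BT);
    ``barrier_nf`` is S_1 - M_N and ``barrier_fe`` is S_2 - M_F.  Mixture
    weights follow from the Gibbs factors; the level spacings are solved so
    the -log density saddle heights equal the requested barriers.  Equal
    well curvatures (sd ``well_sigma``) make the chain's stationary
    distribution coincide with the mixture weights (detailed balance).
    """
    pis = np.array([1.0, math.exp(-delta_g_nf), math.exp(-delta_g_nf - delta_g_fe)])
    pis /= pis.sum()
    s = float(well_sigma)
    d1, d2 = 5.0 * s, 5.0 * s

    def b1_err(d, d2_):
        _, _, mins, sads = _realized([0.0, d, d + d2_], pis, s)
        return (sads[0][1] - mins[0][1]) - barrier_nf

    def b2_err(d, d1_):
        _, _, mins, sads = _realized([0.0, d1_, d1_ + d], pis, s)
        return (sads[1][1] - mins[1][1]) - barrier_fe

    for _ in range(4):
        d1 = brentq(lambda d: b1_err(d, d2), 2.2 * s, 12.0 * s, xtol=1e-6 * s)
        d2 = brentq(lambda d: b2_err(d, d1), 2.2 * s, 12.0 * s, xtol=1e-6 * s)

    levels = np.array([base_level, base_level + d1, base_level + d1 + d2])
    grid, u, mins, sads = _realized(levels, pis, s)
    m_e = [m[1] - mins[0][1] for m in mins]
    s_e = [sd[1] - mins[0][1] for sd in sads]
    well_c = [abs(_curvature_at(grid, u, m[0])) for m in mins]
    barr_c = [abs(_curvature_at(grid, u, sd[0])) for sd in sads]
    return GroundTruthSpec(
        state_levels=tuple(levels),
        state_energies=tuple(m_e),
        barrier_energies=tuple(s_e),
        well_curvatures=tuple(well_c),
        barrier_curvatures=tuple(barr_c),
        prefactor_a=prefactor_a,
        temperature=temperature,
    )


def design_two_state_spec(
    delta_g: float = 0.7,
    barrier: float = 3.0,
    well_sigma: float = 0.025,
    base_level: float = 0.30,
    prefactor_a: float = 0.9,
    temperature: float = 310.0,
) -> GroundTruthSpec:
    """Two-state (dimer closed/open) analogue of :func:`design_three_state_spec`."""
    pis = np.array([1.0, math.exp(-delta_g)])
    pis /= pis.sum()
    s = float(well_sigma)

    def b_err(d):
        _, _, mins, sads = _realized([0.0, d], pis, s)
        return (sads[0][1] - mins[0][1]) - barrier

    d = brentq(b_err, 2.2 * s, 12.0 * s, xtol=1e-6 * s)
    levels = np.array([base_level, base_level + d])
    grid, u, mins, sads = _realized(levels, pis, s)
    return GroundTruthSpec(
        state_levels=tuple(levels),
        state_energies=(0.0, mins[1][1] - mins[0][1]),
        barrier_energies=(sads[0][1] - mins[0][1],),
        well_curvatures=tuple(abs(_curvature_at(grid, u, m[0])) for m in mins),
        barrier_curvatures=(abs(_curvature_at(grid, u, sads[0][0])),),
        prefactor_a=prefactor_a,
        temperature=temperature,
    )
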