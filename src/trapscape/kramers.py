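"""Kramers-rate Markov model connecting the landscape to the kinetics.

In the viscous (overdamped) limit, the forward flux over a barrier is

    J = (omega_well / 2 pi) * (omega_barrier / zeta) * exp(-E_A / k_BT),

so with friction absorbed into a single free prefactor A the per-step
transition probabilities of a slice-resolution Markov chain are Boltzmann
factors of the landscape's activation energies, with prefactors chained by
curvature ratios.  A is fitted to the measured mean residence times and the
resulting chain is simulated to validate the landscape kinetically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import as_rng
from .landscape import LandscapeFeatures
from .states import DwellStatistics, equilibrium_from_residence, residence_statistics
from .synthetic import simulate_chain, stationary_distribution, transition_matrix_from_params

__all__ = [
    "kramers_flux",
    "KramersModel",
    "model_from_features",
    "optimize_prefactor",
    "PrefactorFit",
    "validate_kinetics",
    "KineticsReport",
]

#: below this activation energy (k_BT) the saddle is barely a barrier and the
#: Kramers picture is dubious; the model warns rather than refusing
LOW_BARRIER_KT = 0.5


def kramers_flux(omega_well: float, omega_barrier: float, zeta: float,
                 activation_kt: float) -> float:
    """Kramers escape rate (1/s) in the viscous damping limit.

    ``activation_kt`` is the activation energy already expressed in k_BT, so
    the Boltzmann factor is exp(-activation_kt) directly.
    """
    if omega_well <= 0 or omega_barrier <= 0 or zeta <= 0:
        raise ValueError("curvatures and friction must be positive")
    return (omega_well / (2 * math.pi)) * (omega_barrier / zeta) * math.exp(-activation_kt)


@dataclass
class KramersModel:
    """Per-step transition matrix built from landscape features plus one A."""

    features: LandscapeFeatures
    prefactor_a: float
    step_duration: float
    matrix: np.ndarray
    low_barrier_warnings: list[str] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def exit_probability(self) -> np.ndarray:
        return 1.0 - np.diag(self.matrix)

    @property
    def mean_residence_time(self) -> np.ndarray:
        """Analytic mean dwell per state: step / exit probability (s)."""
        return self.step_duration / self.exit_probability

    @property
    def stationary(self) -> np.ndarray:
        return stationary_distribution(self.matrix)

    @property
    def normalized_prefactor(self) -> float:
        """A / (omega_N * omega_NF): the cross-temperature invariant."""
        return self.prefactor_a / (self.features.well_curvature[0]
                                   * self.features.barrier_curvature[0])


def model_from_features(features: LandscapeFeatures, prefactor_a: float,
                        step_duration: float = 0.1) -> KramersModel:
    """Build the slice-resolution Kramers-Markov model from a landscape."""
    matrix = transition_matrix_from_params(
        features.activation_energies(), features.well_curvature,
        features.barrier_curvature, prefactor_a)
    warnings = []
    for (e_fwd, e_rev), j in zip(features.activation_energies(),
                                 range(features.n_states - 1)):
        for name, e in (("forward", e_fwd), ("reverse", e_rev)):
            if e < LOW_BARRIER_KT:
                warnings.append(
                    f"barrier {j} {name} activation energy {e:.2f} k_BT lacks a "
                    "pronounced barrier; Kramers' theory may not apply")
    return KramersModel(features, float(prefactor_a), step_duration, matrix,
                        warnings)


@dataclass
class PrefactorFit:
    prefactor_a: float
    objective: float                  # sum of squared log-tau residuals
    residuals: np.ndarray             # ln tau_model - ln tau_target per state
    se_log_a: float                   # sampling s.e. of ln A from dwell counts
    converged: bool


def optimize_prefactor(
    features: LandscapeFeatures,
    target_taus: np.ndarray,
    step_duration: float = 0.1,
    dwell_counts: np.ndarray | None = None,
) -> PrefactorFit:
    """Fit the single free prefactor A to measured mean residence times.

    Minimizes sum_s (ln tau_model(s) - ln tau_target(s))^2 over ln A with an
    unconstrained quasi-Newton search (the log parametrization keeps A > 0
    structurally; residence times span orders of magnitude across states,
    hence the log residuals).  If ``dwell_counts`` is given, the sampling
    standard error of ln A is propagated from the targets as
    sqrt(sum 1/n_s) / n_states.
    """
    target = np.asarray(target_taus, dtype=float)
    if target.size != features.n_states:
        raise ValueError("one target residence time per state required")
    if np.any(~np.isfinite(target)) or np.any(target <= 0):
        raise ValueError("target residence times must be positive and finite")
    if np.any(target < step_duration):
        raise ValueError("targets shorter than one step are unresolvable")

    # exit probability scales linearly in A: tau(s) = step / (A q_s)
    ref = model_from_features(features, 1e-6, step_duration)
    q = ref.exit_probability / 1e-6
    log_tau_unit = np.log(step_duration / q)     # ln tau at A = 1

    def objective(x):
        r = (log_tau_unit - x[0]) - np.log(target)
        return float(np.dot(r, r))

    res = minimize(objective, x0=np.array([0.0]), method="BFGS")
    a = float(np.exp(res.x[0]))
    r = (log_tau_unit - res.x[0]) - np.log(target)
    # validity: the fitted A must yield a proper stochastic matrix
    model_from_features(features, a, step_duration)
    se = float("nan")
    if dwell_counts is not None:
        n = np.maximum(np.asarray(dwell_counts, dtype=float), 1.0)
        se = float(np.sqrt(np.sum(1.0 / n)) / n.size)
    return PrefactorFit(a, float(res.fun), r, se, bool(res.success))


@dataclass
class KineticsReport:
    """Measured-vs-simulated comparison behind the kinetic validation."""

    model: KramersModel
    simulated_dwells: DwellStatistics
    tau_simulated: np.ndarray
    tau_simulated_se: np.ndarray
    tau_analytic: np.ndarray
    tau_target: np.ndarray | None
    k_simulated: np.ndarray           # occupancy-ratio K per adjacent pair
    k_landscape: np.ndarray           # exp(-dG) from the model's features
    se_log_k_simulated: np.ndarray

    def tau_zscores(self) -> np.ndarray:
        """(tau_sim - tau_target) / se per state (against targets if given)."""
        ref = self.tau_analytic if self.tau_target is None else self.tau_target
        return (self.tau_simulated - ref) / self.tau_simulated_se


def validate_kinetics(
    model: KramersModel,
    duration: float = 1000.0,
    seed: int | np.random.Generator | None = None,
    target_taus: np.ndarray | None = None,
) -> KineticsReport:
    """Simulate the fitted chain and compare dwell statistics and K routes.

    Runs a ``duration``-second trajectory at the model's step, computes the
    simulated mean residence times and occupancy-ratio equilibrium constants,
    and reports them next to the analytic values, the (optional) measured
    targets, and the landscape-route Gibbs factors.
    """
    n_steps = int(round(duration / model.step_duration))
    seq = simulate_chain(model.matrix, n_steps, seed=as_rng(seed),
                         slice_duration=model.step_duration)
    dwells = residence_statistics(seq)
    eq = equilibrium_from_residence(dwells)
    k_land = np.array([model.features.keq(j)
                       for j in range(model.features.n_states - 1)])
    return KineticsReport(
        model=model,
        simulated_dwells=dwells,
        tau_simulated=dwells.mean_dwell,
        tau_simulated_se=dwells.sem_dwell,
        tau_analytic=model.mean_residence_time,
        tau_target=None if target_taus is None else np.asarray(target_taus, float),
        k_simulated=eq.k_total,
        k_landscape=k_land,
        se_log_k_simulated=eq.se_log_k,
    )
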