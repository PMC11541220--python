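"""State recognition and dwell-time kinetics.

The trace is reduced to 100 ms slice means, classified into discrete
conformational states by deterministic one-dimensional k-means (two
hierarchical two-state splits for the three-state monomer), and run-length
encoded into dwells.  Ratios of total residence times give the kinetic-route
equilibrium constants that cross-check the landscape route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StateSequence, TransmissionTrace

__all__ = [
    "slice_means",
    "kmeans_two_state",
    "classify_three_state",
    "classify_trace",
    "residence_statistics",
    "equilibrium_from_residence",
    "DwellStatistics",
    "ResidenceEquilibrium",
]


def slice_means(trace: TransmissionTrace | np.ndarray,
                slice_duration: float = 0.1,
                sampling_rate: float | None = None) -> np.ndarray:
    """Non-overlapping slice averages; a final partial slice is discarded."""
    if isinstance(trace, TransmissionTrace):
        samples = trace.samples
        sampling_rate = trace.sampling_rate
    else:
        samples = np.asarray(trace, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare array")
    spp = int(round(sampling_rate * slice_duration))
    if spp < 1 or samples.size < spp:
        raise ValueError("trace shorter than one slice")
    n = samples.size // spp
    return samples[: n * spp].reshape(n, spp).mean(axis=1)


def kmeans_two_state(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D two-means by threshold enumeration.

    One-dimensional two-cluster k-means is separable: the optimum is a
    threshold split of the sorted values, so enumerating the n-1 splits and
    picking the minimum within-cluster sum of squares is both exact and
    deterministic (no seeds, no restarts).  Ties break toward the lower
    cluster.  Returns (labels, centers) with centers ascending.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if np.ptp(values) == 0:
        raise ValueError("constant input has no two-cluster partition")
    order = np.argsort(values, kind="stable")
    x = values[order]
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    n = x.size
    k = np.arange(1, n)                      # size of the lower cluster
    left = csq[:-1] - csum[:-1] ** 2 / k
    right = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - k)
    wcss = left + right
    split = int(np.argmin(wcss)) + 1         # argmin takes the first (lower-cluster) tie
    labels = np.zeros(n, dtype=np.int64)
    labels[order[split:]] = 1
    centers = np.array([x[:split].mean(), x[split:].mean()])
    return labels, centers


def _pooled_sd(values: np.ndarray, labels: np.ndarray) -> float:
    dev = np.concatenate([values[labels == g] - values[labels == g].mean()
                          for g in (0, 1)])
    return float(np.sqrt(np.mean(dev**2)))


def classify_three_state(
    values: np.ndarray,
    slice_duration: float = 0.1,
    resolvability: float = 3.0,
) -> StateSequence:
    """Hierarchical two-pass k-means classification of slice means.

    The first pass makes a coarse two-way split; the second splits one of the
    two groups further.  Which group is split is decided by the total
    within-cluster sum of squares of the resulting three-way partition (the
    first threshold can land between either state pair, depending on
    occupancies).  If the winning second split's center separation is below
    ``resolvability`` times its pooled within-cluster sd the split is judged
    spurious (the rarely visited third state is absent) and the result
    collapses to two states.  Labels are ascending in voltage.
    """
    values = np.asarray(values, dtype=float)
    labels1, centers1 = kmeans_two_state(values)

    def try_split(side: int):
        group = values[labels1 == side]
        if group.size < 4 or np.ptp(group) == 0:
            return None
        labels2, centers2 = kmeans_two_state(group)
        if min(np.sum(labels2 == 0), np.sum(labels2 == 1)) == 0:
            return None
        other = values[labels1 == 1 - side]
        wcss = (((group[labels2 == 0] - centers2[0]) ** 2).sum()
                + ((group[labels2 == 1] - centers2[1]) ** 2).sum()
                + ((other - other.mean()) ** 2).sum())
        ratio = (centers2[1] - centers2[0]) / max(_pooled_sd(group, labels2), 1e-300)
        return wcss, ratio, labels2, centers2

    options = {side: r for side in (0, 1) if (r := try_split(side)) is not None}
    if options:
        side = min(options, key=lambda s: options[s][0])
        wcss, ratio, labels2, centers2 = options[side]
        if ratio >= resolvability:
            labels = np.empty_like(labels1)
            if side == 1:     # upper group split into F and E
                labels[labels1 == 0] = 0
                labels[labels1 == 1] = 1 + labels2
                centers = np.array([centers1[0], centers2[0], centers2[1]])
            else:             # lower group split into N and F
                labels[labels1 == 0] = labels2
                labels[labels1 == 1] = 2
                centers = np.array([centers2[0], centers2[1], centers1[1]])
            return StateSequence(labels, slice_duration, n_states=3, centers=centers)
    return StateSequence(labels1, slice_duration, n_states=2, centers=centers1)


def classify_trace(trace: TransmissionTrace, slice_duration: float = 0.1,
                   resolvability: float = 3.0) -> StateSequence:
    """Slice-average a trace and classify it (convenience composition)."""
    return classify_three_state(slice_means(trace, slice_duration),
                                slice_duration, resolvability)


@dataclass
class DwellStatistics:
    """Per-state residence statistics from a state sequence.

    ``mean_dwell`` averages *complete* dwells only (the censored first and
    last runs have unknown true length); ``total_time`` includes them so
    occupancies conserve the trace duration exactly.
    """

    slice_duration: float
    n_states: int
    dwell_durations: list[np.ndarray]          # complete dwells per state, seconds
    total_time: np.ndarray                     # includes censored dwells
    n_dwells: np.ndarray                       # complete dwells per state
    censored_time: np.ndarray = field(default=None)  # time in censored dwells

    @property
    def mean_dwell(self) -> np.ndarray:
        """Mean residence time tau per state (s); nan where no complete dwell."""
        return np.array([d.mean() if d.size else np.nan
                         for d in self.dwell_durations])

    @property
    def sem_dwell(self) -> np.ndarray:
        """Standard error of the mean residence time per state."""
        out = np.full(self.n_states, np.nan)
        for i, d in enumerate(self.dwell_durations):
            if d.size > 1:
                out[i] = d.std(ddof=1) / np.sqrt(d.size)
        return out

    @property
    def occupancy(self) -> np.ndarray:
        """Fraction of the trace spent in each state."""
        return self.total_time / self.total_time.sum()


def residence_statistics(states: StateSequence) -> DwellStatistics:
    """Run-length encode a state sequence into dwells.

    Maximal runs of equal labels are dwells of duration run-length x
    slice_duration.  The first and last runs are censored: counted toward
    total occupancy but excluded from the complete-dwell lists.
    """
    lab = states.labels
    dt = states.slice_duration
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [lab.size]))
    run_state = lab[starts]
    run_len = ends - starts
    n = states.n_states
    total = np.zeros(n)
    censored = np.zeros(n)
    np.add.at(total, run_state, run_len * dt)
    durations: list[list[float]] = [[] for _ in range(n)]
    for k in range(run_state.size):
        if k == 0 or k == run_state.size - 1:
            censored[run_state[k]] += run_len[k] * dt
            continue
        durations[run_state[k]].append(run_len[k] * dt)
    return DwellStatistics(
        slice_duration=dt,
        n_states=n,
        dwell_durations=[np.asarray(d) for d in durations],
        total_time=total,
        n_dwells=np.array([len(d) for d in durations]),
        censored_time=censored,
    )


@dataclass
class ResidenceEquilibrium:
    """Kinetic-route equilibrium constants between adjacent states.

    ``k_total[j]`` is the ratio of total residence times of state j+1 over
    state j (the definition used for K_NF = tau_F/tau_N and K_FE =
    tau_E/tau_F); ``k_mean_dwell`` is the mean-complete-dwell variant kept
    for comparison.  ``se_log_k`` is the approximate standard error of
    ln K_total, sqrt(1/n_j + 1/n_{j+1}) from the complete-dwell counts
    (relative error of a mean of n near-geometric dwells is ~1/sqrt(n)).
    """

    k_total: np.ndarray
    k_mean_dwell: np.ndarray
    se_log_k: np.ndarray

    @property
    def k_nf(self) -> float:
        return float(self.k_total[0])

    @property
    def k_fe(self) -> float:
        return float(self.k_total[1]) if self.k_total.size > 1 else np.nan


def equilibrium_from_residence(dwells: DwellStatistics) -> ResidenceEquilibrium:
    """Equilibrium constants from ratios of total residence times."""
    n = dwells.n_states
    k_tot, k_md, se = [], [], []
    for j in range(n - 1):
        lo, hi = dwells.total_time[j], dwells.total_time[j + 1]
        if lo <= 0:
            raise ValueError(
                f"state {j} has zero occupancy; K between states {j} and {j+1} "
                "is undefined (the state may be absent from this trace)")
        k_tot.append(hi / lo)
        md = dwells.mean_dwell
        k_md.append(md[j + 1] / md[j] if md[j] and np.isfinite(md[j]) else np.nan)
        n_lo = max(int(dwells.n_dwells[j]), 1)
        n_hi = max(int(dwells.n_dwells[j + 1]), 1)
        se.append(np.sqrt(1.0 / n_lo + 1.0 / n_hi))
    return ResidenceEquilibrium(np.asarray(k_tot), np.asarray(k_md), np.asarray(se))
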