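"""Energy-landscape reconstruction by histogram, deconvolution and inversion.

The voltage histogram of a long trace estimates the stationary probability
density p(V).  Translational/rotational motion of the trapped protein blurs
every conformational level with a Gaussian point-spread function C(V), so the
conformational density P(V) is recovered by iterative Lucy-Richardson
deconvolution,

    P^(k+1) = P^(k) * [ (p / (P^(k) (*) C)) (*) C~ ],      P^(1) = p,

(circular convolutions on the zero-padded 128-bin grid, C~ the mirrored
kernel), followed by Boltzmann inversion U(V) = -ln P(V) in units of k_BT.
Landscape features — state minima, saddle maxima, activation energies,
extremum curvatures and equilibrium constants — are then read off U.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import TransmissionTrace

log = logging.getLogger(__name__)

__all__ = [
    "PdfEstimate",
    "PsfKernel",
    "EnergyLandscape",
    "LandscapeFeatures",
    "histogram_pdf",
    "lucy_richardson",
    "energy_from_pdf",
    "extract_features",
    "fit_curvature",
    "landscape_from_curve",
    "FeatureExtractionError",
]

#: bins whose probability falls below this fraction of the total are left out
#: of the landscape support (guards -ln 0; below one count in any real trace)
PROBABILITY_FLOOR = 1e-6


class FeatureExtractionError(ValueError):
    """Raised when a landscape does not expose the expected extremum pattern."""


@dataclass
class PdfEstimate:
    """Binned probability density on an (optionally zero-padded) voltage grid."""

    bin_centers: np.ndarray
    probabilities: np.ndarray
    bin_width: float
    pad_count: int = 0
    n_samples: int | None = None   # histogram counts behind the estimate, if any

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_centers.shape != self.probabilities.shape:
            raise ValueError("bin_centers and probabilities must align")
        if np.any(self.probabilities < 0) or not np.all(np.isfinite(self.probabilities)):
            raise ValueError("probabilities must be finite and non-negative")


@dataclass
class PsfKernel:
    """Discrete Gaussian point-spread function on the histogram bin grid.

    ``kernel`` is stored in circulant layout (element 0 at zero lag) so that
    FFT products implement circular convolution directly.
    """

    sigma: float          # volts
    bin_width: float
    kernel: np.ndarray    # circulant layout, sums to 1

    @classmethod
    def gaussian(cls, sigma: float, bin_width: float, n_bins: int = 128) -> "PsfKernel":
        if sigma <= 0 or bin_width <= 0:
            raise ValueError("sigma and bin_width must be positive")
        lags = np.fft.fftfreq(n_bins, d=1.0 / n_bins)  # 0, 1, ..., -1 in bins
        k = np.exp(-0.5 * (lags * bin_width / sigma) ** 2)
        return cls(sigma=sigma, bin_width=bin_width, kernel=k / k.sum())

    @property
    def sigma_bins(self) -> float:
        return self.sigma / self.bin_width

    @property
    def mirrored(self) -> np.ndarray:
        """Kernel of the adjoint (correlation) step, C(-V)."""
        return np.roll(self.kernel[::-1], 1)


def histogram_pdf(
    trace: TransmissionTrace | np.ndarray,
    n_bins: int = 100,
    padded_len: int = 128,
) -> PdfEstimate:
    """Equal-width histogram over [min, max], normalized, zero-padded.

    The 100-bin histogram is padded evenly with zeros on both sides (14 per
    side by default) to a power-of-two length, extending the voltage grid at
    the same bin width so circular convolution wraparound acts only on
    near-zero mass.
    """
    samples = trace.samples if isinstance(trace, TransmissionTrace) else np.asarray(trace)
    if samples.size == 0:
        raise ValueError("empty trace")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if padded_len < n_bins or (padded_len - n_bins) % 2:
        raise ValueError("padded_len must be >= n_bins with an even difference")
    lo, hi = float(samples.min()), float(samples.max())
    if hi == lo:
        raise ValueError("constant trace has zero-width voltage range")
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    bw = (hi - lo) / n_bins
    pad = (padded_len - n_bins) // 2
    probs = np.zeros(padded_len)
    probs[pad: pad + n_bins] = counts / counts.sum()
    centers = (np.arange(padded_len) - pad + 0.5) * bw + lo
    return PdfEstimate(centers, probs, bw, pad_count=pad, n_samples=int(samples.size))


def _circ(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(kernel)))


def lucy_richardson(
    pdf: PdfEstimate,
    psf: PsfKernel,
    iterations: int = 51,
    damping: float = math.sqrt(0.0001),
    floor: float = 1e-12,
) -> PdfEstimate:
    """Damped Lucy-Richardson deconvolution of a binned PDF.

    The multiplicative update preserves non-negativity; the output is
    renormalized to unit mass.  The damping threshold suppresses the per-bin
    correction (factor replaced by 1) wherever the reblur residual is below
    ``damping`` *counts* — it exists to stop amplification of counting noise,
    so the residual is compared on the counts scale when the estimate carries
    a sample count and damping is inactive for analytic (noise-free) PDFs.
    Division by near-empty reblur bins is floored at ``floor`` (logged).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if psf.kernel.size != pdf.probabilities.size:
        raise ValueError("pdf and psf must share one grid")
    p = pdf.probabilities
    total = p.sum()
    if total <= 0:
        raise ValueError("pdf carries no mass")
    p = p / total
    thresh = damping / pdf.n_samples if (damping > 0 and pdf.n_samples) else 0.0
    est = p.copy()
    mirrored = psf.mirrored
    floored = 0
    for _ in range(iterations):
        reblur = _circ(est, psf.kernel)
        floored += int(np.count_nonzero((reblur < floor) & (p > 0)))
        ratio = p / np.maximum(reblur, floor)
        corr = _circ(ratio, mirrored)
        if thresh > 0:
            corr = np.where(np.abs(p - reblur) < thresh, 1.0, corr)
        est = np.clip(est * corr, 0.0, None)
    if floored:
        log.debug("lucy_richardson floored %d near-empty reblur bins", floored)
    return PdfEstimate(pdf.bin_centers, est / est.sum(), pdf.bin_width,
                       pad_count=pdf.pad_count, n_samples=pdf.n_samples)


@dataclass
class EnergyLandscape:
    """Free energy (k_BT, minimum 0 on support) along the voltage coordinate."""

    bin_centers: np.ndarray
    energy: np.ndarray          # +inf outside the support
    support_mask: np.ndarray
    temperature: float
    bin_width: float

    @property
    def support_slice(self) -> slice:
        """Largest contiguous run of supported bins."""
        idx = np.flatnonzero(self.support_mask)
        if idx.size == 0:
            raise ValueError("empty support")
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [idx.size]))
        k = int(np.argmax(ends - starts))
        return slice(int(idx[starts[k]]), int(idx[ends[k] - 1]) + 1)


def energy_from_pdf(pdf: PdfEstimate, temperature: float,
                    floor: float = PROBABILITY_FLOOR) -> EnergyLandscape:
    """Boltzmann inversion U = -ln P in k_BT units.

    Bins below the probability floor are excluded from the support and carry
    infinite energy; the supported minimum is shifted to zero for reporting.
    Conversion to kcal/mol happens only in the thermo layer so temperature
    enters the energy scale exactly once.
    """
    p = pdf.probabilities / pdf.probabilities.sum()
    mask = p >= floor
    if not np.any(mask):
        raise ValueError("no bins above the probability floor")
    energy = np.full(p.size, np.inf)
    energy[mask] = -np.log(p[mask])
    energy[mask] -= energy[mask].min()
    return EnergyLandscape(pdf.bin_centers.copy(), energy, mask,
                           temperature=temperature, bin_width=pdf.bin_width)


def fit_curvature(landscape: EnergyLandscape, extremum_bin: int,
                  window_bins: int = 7, kind: str = "auto") -> float:
    """Curvature magnitude at an extremum by local quadratic least squares.

    Fits U ~ a(V-V0)^2 + b(V-V0) + c over a window centered on the extremum,
    clipped to the monotone flanks so neighbouring features do not leak in;
    returns omega = 2|a| (k_BT/V^2).  A fitted ``a`` whose sign contradicts
    the extremum type signals a mislocated extremum and raises.
    """
    u = landscape.energy
    i0 = int(extremum_bin)
    if not landscape.support_mask[i0]:
        raise ValueError("extremum bin outside the landscape support")
    if kind == "auto":
        left = u[i0 - 1] if i0 > 0 else np.inf
        right = u[i0 + 1] if i0 + 1 < u.size else np.inf
        kind = "min" if min(left, right) >= u[i0] else "max"
    sgn = 1.0 if kind == "min" else -1.0
    half = max(window_bins // 2, 2)
    lo = i0
    while (lo > 0 and i0 - lo < half and landscape.support_mask[lo - 1]
           and np.isfinite(u[lo - 1]) and sgn * (u[lo - 1] - u[lo]) >= 0):
        lo -= 1
    hi = i0
    while (hi + 1 < u.size and hi - i0 < half and landscape.support_mask[hi + 1]
           and np.isfinite(u[hi + 1]) and sgn * (u[hi + 1] - u[hi]) >= 0):
        hi += 1
    if hi - lo + 1 < 3:
        raise ValueError("window too small for a quadratic fit")
    x = landscape.bin_centers[lo: hi + 1] - landscape.bin_centers[i0]
    a, b, c = np.polyfit(x, u[lo: hi + 1], 2)
    if sgn * a <= 0:
        raise ValueError(
            f"curvature sign at bin {i0} contradicts a {kind}imum; "
            "the extremum is probably mislocated")
    return float(2.0 * abs(a))


@dataclass
class LandscapeFeatures:
    """Thermodynamic features of an energy landscape.

    States are ordered by voltage (N, F, E for the monomer).  Activation
    energies follow E_N = S1-M_N, E_NF = S1-M_F, E_FE = S2-M_F, E_F = S2-M_E;
    equilibrium constants are Gibbs factors of the minima differences.
    """

    minima_energy: np.ndarray
    minima_position: np.ndarray
    minima_bins: np.ndarray
    saddle_energy: np.ndarray
    saddle_position: np.ndarray
    saddle_bins: np.ndarray
    well_curvature: np.ndarray
    barrier_curvature: np.ndarray
    temperature: float

    @property
    def n_states(self) -> int:
        return self.minima_energy.size

    def delta_g(self, j: int = 0) -> float:
        """M_{j+1} - M_j in k_BT (ΔG of the j-th transition)."""
        return float(self.minima_energy[j + 1] - self.minima_energy[j])

    def activation_energies(self) -> np.ndarray:
        """(E_fwd, E_rev) per barrier: (S_j - M_j, S_j - M_{j+1})."""
        out = [(self.saddle_energy[j] - self.minima_energy[j],
                self.saddle_energy[j] - self.minima_energy[j + 1])
               for j in range(self.n_states - 1)]
        return np.asarray(out)

    def keq(self, j: int = 0) -> float:
        """Landscape-route equilibrium constant exp(-(M_{j+1} - M_j))."""
        return float(np.exp(-self.delta_g(j)))

    @property
    def barrier_heights(self) -> np.ndarray:
        """S_j - M_0: saddle energies above the global reference minimum."""
        return self.saddle_energy - self.minima_energy[0]


def _smooth3(u: np.ndarray) -> np.ndarray:
    padded = np.concatenate(([u[0]], u, [u[-1]]))
    return np.convolve(padded, np.ones(3) / 3, mode="valid")


def extract_features(
    landscape: EnergyLandscape,
    expected_states: int = 3,
    curvature_window: int = 7,
) -> LandscapeFeatures:
    """Locate minima and saddles and derive all thermodynamic features.

    Extremum *localization* uses a lightly smoothed copy (3-bin moving
    average) of the landscape to suppress single-bin noise; energies are
    always read from the raw landscape at the located bins.  The
    ``expected_states`` deepest local minima (ordered by voltage) become the
    state minima; each saddle is the raw maximum between adjacent minima.
    """
    if expected_states not in (2, 3):
        raise ValueError("expected_states must be 2 or 3")
    sl = landscape.support_slice
    u = landscape.energy[sl]
    if u.size < 5:
        raise FeatureExtractionError("support too small")
    us = _smooth3(u)
    interior = np.arange(1, u.size - 1)
    is_min = (us[interior] < us[interior - 1]) & (us[interior] <= us[interior + 1])
    cand = interior[is_min]
    if cand.size < expected_states:
        raise FeatureExtractionError(
            f"found {cand.size} local minima, expected {expected_states}; "
            "retry with expected_states=2 if the third state is absent")
    deepest = cand[np.argsort(u[cand])[:expected_states]]
    mins = np.sort(deepest)
    # smoothing can shift an extremum by a bin; re-anchor on the raw curve
    mins = np.array([max(1, min(u.size - 2, b - 1 + int(np.argmin(u[b - 1:b + 2]))))
                     for b in mins])
    if np.unique(mins).size < mins.size:
        raise FeatureExtractionError("minima collapse onto one bin")
    sads = []
    for a, b in zip(mins[:-1], mins[1:]):
        sads.append(a + int(np.argmax(u[a:b + 1])))
    sads = np.asarray(sads)
    for j, s in enumerate(sads):
        if u[s] < max(u[mins[j]], u[mins[j + 1]]):
            raise FeatureExtractionError("saddle below an adjacent minimum: "
                                         "non-alternating extremum order")
    mins_abs = mins + sl.start
    sads_abs = sads + sl.start
    well_c = np.array([fit_curvature(landscape, b, curvature_window, "min")
                       for b in mins_abs])
    barr_c = np.array([fit_curvature(landscape, b, curvature_window, "max")
                       for b in sads_abs])
    return LandscapeFeatures(
        minima_energy=landscape.energy[mins_abs],
        minima_position=landscape.bin_centers[mins_abs],
        minima_bins=mins_abs,
        saddle_energy=landscape.energy[sads_abs],
        saddle_position=landscape.bin_centers[sads_abs],
        saddle_bins=sads_abs,
        well_curvature=well_c,
        barrier_curvature=barr_c,
        temperature=landscape.temperature,
    )


def landscape_from_curve(bin_centers: np.ndarray, energy: np.ndarray,
                         temperature: float = 310.0) -> EnergyLandscape:
    """Wrap an analytic energy curve (e.g. the generator oracle) for extraction."""
    bin_centers = np.asarray(bin_centers, dtype=float)
    energy = np.asarray(energy, dtype=float)
    return EnergyLandscape(
        bin_centers=bin_centers,
        energy=energy - energy.min(),
        support_mask=np.isfinite(energy),
        temperature=temperature,
        bin_width=float(bin_centers[1] - bin_centers[0]),
    )
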