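"""Display helpers.

The 10 Hz low-pass exists *only* here: filtering before analysis squeezes
the signal toward the landscape minima and biases every extracted parameter,
so the analysis modules always consume raw samples.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import TransmissionTrace
from .landscape import EnergyLandscape, PdfEstimate


def lowpass_for_display(trace: TransmissionTrace, cutoff_hz: float = 10.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of the samples (display only)."""
    nyq = trace.sampling_rate / 2
    sos = signal.butter(4, cutoff_hz / nyq, output="sos")
    return signal.sosfiltfilt(sos, trace.samples)


def plot_trace(trace: TransmissionTrace, ax=None, cutoff_hz: float = 10.0,
               max_points: int = 200_000):
    """Raw trace (decimated for drawing) with its low-passed overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    step = max(1, trace.samples.size // max_points)
    t = np.arange(0, trace.samples.size, step) / trace.sampling_rate
    ax.plot(t, trace.samples[::step], lw=0.3, alpha=0.4, label="raw")
    ax.plot(t, lowpass_for_display(trace, cutoff_hz)[::step], lw=1.0,
            label=f"{cutoff_hz:g} Hz low-pass (display)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("transmission (V)")
    ax.legend(frameon=False)
    return ax


def plot_landscape(scape: EnergyLandscape, pdf: PdfEstimate | None = None, ax=None):
    """Energy landscape over its support, optionally with the deconvolved PDF."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    m = scape.support_mask
    ax.plot(scape.bin_centers[m], scape.energy[m], "o-", ms=3)
    ax.set_xlabel("transmission (V)")
    ax.set_ylabel(r"free energy ($k_BT$)")
    if pdf is not None:
        ax2 = ax.twinx()
        ax2.fill_between(pdf.bin_centers, pdf.probabilities, alpha=0.2, color="gray")
        ax2.set_ylabel("probability")
    return ax
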