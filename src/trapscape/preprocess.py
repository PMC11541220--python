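"""Trace conditioning: LSB dithering, segment-wise drift correction, RMSD.

Stage drift is slow relative to the conformational kinetics, so the trace is
split into 20 s segments, states are recognized within each segment, and the
segments are re-spliced with offsets that hold the reference-state (F) mean
constant across the whole series.  Dithering adds sub-LSB uniform noise to
decorrelate ADC rounding from the histogram binning downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import TransmissionTrace, as_rng
from .states import classify_three_state, slice_means

log = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "dither", "correct_drift", "normalized_rmsd"]


@dataclass(frozen=True)
class PreprocessConfig:
    lsb: float = 0.002441            # dither amplitude, volts
    segment_duration: float = 20.0   # drift-correction segment, seconds
    rmsd_window: int = 5000          # samples per RMSD window
    rmsd_portion: float = 5.0        # seconds of trace used for the RMSD
    slice_duration: float = 0.1
    reference_state: int | None = None  # None: middle state (3), majority (2)
    dither_seed: int | None = None

    def __post_init__(self) -> None:
        if self.lsb < 0 or self.segment_duration <= 0:
            raise ValueError("lsb must be >= 0 and segment_duration > 0")
        if self.rmsd_window < 2:
            raise ValueError("rmsd_window must be >= 2")


def dither(trace: TransmissionTrace, lsb: float = 0.002441,
           seed: int | np.random.Generator | None = None) -> TransmissionTrace:
    """Add independent uniform noise on [-lsb/2, +lsb/2) to every sample.

    ``lsb = 0`` is the identity.  The added noise has zero mean and sd
    lsb/sqrt(12), small against the PSF width but enough to repopulate
    histogram bins emptied by quantization.
    """
    if lsb < 0:
        raise ValueError("lsb must be non-negative")
    if lsb == 0:
        return trace.copy_with(trace.samples.copy(), dithered=False)
    rng = as_rng(seed)
    noisy = trace.samples + rng.uniform(-lsb / 2, lsb / 2, trace.samples.size)
    return trace.copy_with(noisy, dithered=True, dither_lsb=lsb)


def _reference_label(seq, reference_state: int | None) -> int | None:
    """Pick the alignment state: configured label, middle of 3, majority of 2."""
    if reference_state is not None:
        return reference_state if reference_state < seq.n_states else None
    if seq.n_states == 3:
        return 1
    counts = np.bincount(seq.labels, minlength=2)
    return int(np.argmax(counts))


def correct_drift(
    trace: TransmissionTrace,
    config: PreprocessConfig | None = None,
    recognizer=None,
) -> tuple[TransmissionTrace, np.ndarray]:
    """Align segments so the reference-state mean is constant over the trace.

    Per segment: recognize states on the slice means, take the mean voltage
    of the reference state (F for the three-state monomer), and subtract the
    difference to the first segment's reference mean from every sample of the
    segment.  Segments where the reference state cannot be identified (state
    recognition collapses below three states when three are expected) inherit
    the previous segment's offset.  Returns the corrected trace and the
    per-segment offsets that were removed.
    """
    config = config or PreprocessConfig()
    recognizer = recognizer or classify_three_state
    spp_slice = int(round(trace.sampling_rate * config.slice_duration))
    if trace.samples.size < spp_slice:
        raise ValueError("trace shorter than one recognition slice")
    seg_len = int(round(config.segment_duration * trace.sampling_rate))
    n_seg = max(1, int(np.ceil(trace.samples.size / seg_len)))
    if n_seg == 1:
        return trace.copy_with(trace.samples.copy(), drift_offsets=[0.0]), np.zeros(1)

    classified: list = [None] * n_seg
    for g in range(n_seg):
        seg = trace.samples[g * seg_len: (g + 1) * seg_len]
        if seg.size < 2 * spp_slice:
            continue
        values = slice_means(seg, config.slice_duration, trace.sampling_rate)
        try:
            classified[g] = (values, recognizer(values, config.slice_duration))
        except ValueError:
            continue
    found = [c[1].n_states for c in classified if c is not None]
    if not found:
        raise ValueError("state recognition failed in every segment")
    expected_states = max(found)
    # a globally consistent majority label for two-state (dimer) traces
    if expected_states == 2 and config.reference_state is None:
        counts = np.zeros(2)
        for c in classified:
            if c is not None:
                counts += np.bincount(c[1].labels, minlength=2)
        majority = int(np.argmax(counts))
    else:
        majority = None
    ref_means = np.full(n_seg, np.nan)
    for g, c in enumerate(classified):
        if c is None:
            continue
        values, seq = c
        if seq.n_states < expected_states:
            continue  # reference state unresolved in this segment
        ref = majority if majority is not None else \
            _reference_label(seq, config.reference_state)
        if ref is None or not np.any(seq.labels == ref):
            continue
        ref_means[g] = values[seq.labels == ref].mean()

    if not np.any(np.isfinite(ref_means)):
        raise ValueError("reference state not found in any segment")
    anchor = ref_means[np.flatnonzero(np.isfinite(ref_means))[0]]
    offsets = np.zeros(n_seg)
    last = 0.0
    for g in range(n_seg):
        if np.isfinite(ref_means[g]):
            last = ref_means[g] - anchor
        else:
            log.warning("segment %d lacks the reference state; reusing offset", g)
        offsets[g] = last
    corrected = trace.samples - np.repeat(offsets, seg_len)[: trace.samples.size]
    out = trace.copy_with(corrected, drift_offsets=offsets.tolist())
    return out, offsets


def normalized_rmsd(
    trace: TransmissionTrace,
    window: int = 5000,
    portion: float = 5.0,
    start_time: float = 0.0,
) -> float:
    """Mean-normalized root-mean-square deviation of the trapped signal.

    Takes ``portion`` seconds starting at ``start_time``, partitions it into
    consecutive windows of ``window`` samples (final partial window
    discarded), computes each window's RMS deviation about its own mean,
    divides by the global mean of the portion, and averages the windows.
    Scale invariant; zero for a constant trace.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    i0 = int(round(start_time * trace.sampling_rate))
    n = int(round(portion * trace.sampling_rate))
    seg = trace.samples[i0: i0 + n]
    if seg.size < window:
        raise ValueError("trace shorter than the requested RMSD portion")
    mean = seg.mean()
    if mean == 0:
        raise ValueError("zero-mean portion: normalized RMSD undefined")
    m = seg.size // window
    win = seg[: m * window].reshape(m, window)
    rmsd = np.sqrt(((win - win.mean(axis=1, keepdims=True)) ** 2).mean(axis=1))
    return float(np.mean(rmsd / abs(mean)))
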