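"""Time-Frequency-Topography (TFT) and intertrial (iTFT) map construction.

A TFT map condenses the per-sample cluster labels into a bands x windows
grid of scalp maps: within each non-overlapping window of ``upsilon``
samples, each channel is assigned its modal cluster label, but only when
that label occurs in strictly more than ``rho`` percent of the window
(ties and sub-threshold modes yield the all-zero "unassigned" word, which
avoids bimodal or multimodal cells).  The intertrial variant first takes
the modal label across epochs at every within-epoch sample (the intertrial
cluster modes, ITCM) — the label-domain analogue of a grand average — and
then windows that array the same way.

Epoch segmentation slices the labeled record; labels are never recomputed,
so identical labels mean identical clusters across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcps import ClusterRecord
from .sim_eeg import FlashSchedule
from .tf_phase import FrequencyGrid, PowerTensor

__all__ = [
    "EpochStack",
    "TFTMap",
    "segment_epochs",
    "windowed_modes",
    "build_tft",
    "intertrial_modes",
    "build_itft",
    "tf_power_map",
]

UNASSIGNED = 0  # the all-zero label word


@dataclass
class EpochStack:
    """Labeled epochs of one condition: bands x epochs x channels x samples."""

    labels: np.ndarray  # uint32, (n_bands, n_epochs, n_channels, epoch_len)
    condition: str
    window: tuple[int, int]  # sample offsets relative to event onset

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[1]

    @property
    def epoch_length(self) -> int:
        return self.labels.shape[3]


@dataclass
class TFTMap:
    """Bands x windows grid of per-channel modal cluster labels."""

    labels: np.ndarray  # uint32, (n_bands, n_windows, n_channels)
    upsilon: int
    rho: float
    fs: float
    grid: FrequencyGrid

    @property
    def n_windows(self) -> int:
        return self.labels.shape[1]

    def window_ms(self) -> float:
        """Duration of one window in milliseconds."""
        return 1000.0 * self.upsilon / self.fs


def segment_epochs(
    record: ClusterRecord, schedule: FlashSchedule
) -> dict[str, EpochStack]:
    """Slice a labeled record into per-condition epoch stacks.

    Every epoch window must lie inside the record.  Overlapping epochs are
    permitted and share the underlying labels.  Segmentation happens after
    labeling, so label words are directly comparable across conditions.
    """
    start_off, end_off = schedule.epoch_window
    ep_len = end_off - start_off
    out: dict[str, EpochStack] = {}
    for condition in schedule.conditions:
        onsets = schedule.onsets(condition)
        stack = np.empty(
            (record.n_bands, len(onsets), record.n_channels, ep_len),
            dtype=record.labels.dtype,
        )
        for e, onset in enumerate(onsets):
            lo, hi = onset + start_off, onset + end_off
            if lo < 0 or hi > record.n_samples:
                raise ValueError(
                    f"epoch [{lo}, {hi}) at onset {onset} exceeds record bounds"
                )
            stack[:, e] = record.labels[:, :, lo:hi]
        out[condition] = EpochStack(
            labels=stack, condition=condition, window=schedule.epoch_window
        )
    return out


def _strict_mode(values: np.ndarray, denominator: int, rho: float) -> int:
    """Modal value if unimodal and above the strict rho% majority, else 0."""
    uniq, counts = np.unique(values, return_counts=True)
    top = counts.max()
    if (counts == top).sum() != 1:
        return UNASSIGNED
    if top * 100.0 <= rho * denominator:
        return UNASSIGNED
    return int(uniq[np.argmax(counts)])


def windowed_modes(labels: np.ndarray, upsilon: int, rho: float) -> np.ndarray:
    """Per-channel modal labels over consecutive non-overlapping windows.

    ``labels`` is channels x samples; the output is channels x windows.  A
    label is assigned only when its count exceeds ``rho`` percent of the
    window strictly; ties among equally frequent labels are unassigned.  A
    trailing partial window is dropped.
    """
    if upsilon < 1:
        raise ValueError("window size upsilon must be >= 1")
    if not 0 <= rho < 100:
        raise ValueError("mode threshold rho must be in [0, 100)")
    labels = np.atleast_2d(labels)
    n_ch, n_samp = labels.shape
    n_win = n_samp // upsilon
    if n_win == 0:
        raise ValueError("window size exceeds the segment length")
    out = np.zeros((n_ch, n_win), dtype=labels.dtype)
    for j in range(n_ch):
        for w in range(n_win):
            out[j, w] = _strict_mode(
                labels[j, w * upsilon : (w + 1) * upsilon], upsilon, rho
            )
    return out


def build_tft(
    record: ClusterRecord, upsilon: int = 16, rho: float = 50.0,
    start: int = 0, stop: int | None = None,
) -> TFTMap:
    """Window a labeled record (or a slice of it) into a TFT map.

    At 256 Hz the default 16-sample window spans 62.5 ms, so a 1000 ms
    segment tiles into 16 windows per band.
    """
    seg = record.labels[:, :, start: record.n_samples if stop is None else stop]
    modes = np.stack(
        [windowed_modes(seg[k], upsilon, rho) for k in range(record.n_bands)]
    )
    # (bands, channels, windows) -> (bands, windows, channels)
    return TFTMap(
        labels=modes.transpose(0, 2, 1),
        upsilon=upsilon,
        rho=rho,
        fs=record.fs,
        grid=record.grid,
    )


def intertrial_modes(stack: EpochStack, rho: float = 50.0) -> np.ndarray:
    """Modal label across epochs at each band, channel and sample (ITCM).

    The across-epoch analogue of a grand average, with the same strict
    majority rule: the modal label must occur in strictly more than
    ``rho`` percent of the epochs, ties are unassigned.
    """
    if stack.n_epochs < 1:
        raise ValueError("epoch stack is empty")
    n_bands, n_ep, n_ch, ep_len = stack.labels.shape
    out = np.zeros((n_bands, n_ch, ep_len), dtype=stack.labels.dtype)
    for k in range(n_bands):
        for j in range(n_ch):
            col = stack.labels[k, :, j, :]
            for n in range(ep_len):
                out[k, j, n] = _strict_mode(col[:, n], n_ep, rho)
    return out


def build_itft(
    stack: EpochStack, upsilon: int = 16, rho: float = 50.0,
    fs: float = 256.0, grid: FrequencyGrid | None = None,
) -> TFTMap:
    """Intertrial TFT map: ITCM first, then windowed modes over epoch time.

    Invariant to epoch order and to duplicating the full epoch set.
    """
    itcm = intertrial_modes(stack, rho)
    modes = np.stack(
        [windowed_modes(itcm[k], upsilon, rho) for k in range(itcm.shape[0])]
    )
    return TFTMap(
        labels=modes.transpose(0, 2, 1), upsilon=upsilon, rho=rho, fs=fs, grid=grid
    )


def tf_power_map(
    pw: PowerTensor, channel: int, upsilon: int = 16,
    start: int = 0, stop: int | None = None,
) -> np.ndarray:
    """Mean wavelet power of one channel per band and window.

    Complements the label maps: bands x windows, same tiling as the TFT.
    """
    seg = pw.values[channel, start: pw.values.shape[1] if stop is None else stop, :]
    n_win = seg.shape[0] // upsilon
    if n_win == 0:
        raise ValueError("window size exceeds the segment length")
    trimmed = seg[: n_win * upsilon].reshape(n_win, upsilon, -1)
    return trimmed.mean(axis=1).T  # (bands, windows)
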