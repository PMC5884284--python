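"""Synthetic multichannel EEG by instantaneous linear source mixing.

The forward model is deliberately simple: ``N_s`` sources located inside a
unit-sphere head are mixed instantaneously into ``N_ch`` scalp electrodes,
with gains following the inverse-square law of the electrode-to-source
distance (homogeneous, isotropic volume conduction).  One source is a
Gaussian-windowed, downward-chirped visual evoked potential (VEP) repeated
identically in every epoch; the remaining sources are harmonic, white
Gaussian, or colored (1/f^alpha) Gaussian noise, optionally moving along
linear or circular trajectories.

A P300-matrix-speller-like flash schedule (6x6 character grid, row/column
flashes) is provided for epoch segmentation into ERP / no-ERP conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "ElectrodeMontage",
    "FixedTrajectory",
    "LinearTrajectory",
    "RotationalTrajectory",
    "SourceSpec",
    "SimulatedRecord",
    "FlashSchedule",
    "standard_montage",
    "mixing_weights",
    "vep_waveform",
    "generate_sources",
    "simulate_record",
    "speller_schedule",
    "snr_db",
    "default_seeg_sources",
]

#: canonical channel orders; these fix the bit order of hexadecimal labels
CHANNELS_8 = ("Fz", "Cz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")
CHANNELS_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

DISTANCE_FLOOR = 1e-3  # unit-sphere units; clamps inverse-square gains


@dataclass
class ElectrodeMontage:
    """Ordered scalp electrode set with unit-sphere coordinates.

    The channel order is canonical for a whole analysis: it defines the bit
    order of hexadecimal cluster labels and the row order of every record.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("montage channel names must be unique")
        if self.positions.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms <= 0) or np.any(norms > 1.05):
            raise ValueError("electrode position norms must lie in (0, 1.05]")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def n_bits(self) -> int:
        """Label width in bits: channel count padded to a multiple of 4."""
        return 4 * math.ceil(self.n_channels / 4)

    @property
    def label_width(self) -> int:
        """Hexadecimal label width in digits."""
        return self.n_bits // 4

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None


@lru_cache(maxsize=None)
def _standard_positions(names: tuple[str, ...]) -> tuple[tuple[float, float, float], ...]:
    import warnings

    import mne  # deferred: slow import, only needed to build montages

    with warnings.catch_warnings():
        # montage alias naming is in flux across mne versions
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    out = []
    for name in names:
        p = np.asarray(ch_pos[name], dtype=float)
        out.append(tuple(p / np.linalg.norm(p)))
    return tuple(out)


def standard_montage(layout: str) -> ElectrodeMontage:
    """Return a standard montage projected onto the unit sphere.

    Parameters
    ----------
    layout
        ``"10-20-19ch"`` — the classic 19-electrode 10-20 set; or
        ``"10-10-8ch"`` — the 8-electrode 10-10 set
        (Fz, Cz, Pz, Oz, P3, P4, PO7, PO8) in exactly that order.
    """
    if layout == "10-10-8ch":
        names = CHANNELS_8
    elif layout == "10-20-19ch":
        names = CHANNELS_19
    else:
        raise ValueError(f"unknown montage layout {layout!r}")
    return ElectrodeMontage(names, np.array(_standard_positions(names)))


# --------------------------------------------------------------------------
# source specifications and trajectories

@dataclass(frozen=True)
class FixedTrajectory:
    position: tuple[float, float, float]

    def positions(self, t: np.ndarray) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.position, float), (len(t), 3)).copy()


@dataclass(frozen=True)
class LinearTrajectory:
    """Straight-line drift: position(t) = start + velocity * t (t in seconds)."""

    start: tuple[float, float, float]
    velocity: tuple[float, float, float]

    def positions(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(self.start, float) + np.outer(t, np.asarray(self.velocity, float))


@dataclass(frozen=True)
class RotationalTrajectory:
    """Circular orbit in a horizontal plane around ``center``.

    ``angular_rate`` is in rad/s; the orbit lies in the plane z = center_z.
    """

    center: tuple[float, float, float]
    radius: float
    angular_rate: float
    initial_angle: float = 0.0

    def positions(self, t: np.ndarray) -> np.ndarray:
        ang = self.initial_angle + self.angular_rate * t
        out = np.tile(np.asarray(self.center, float), (len(t), 1))
        out[:, 0] += self.radius * np.cos(ang)
        out[:, 1] += self.radius * np.sin(ang)
        return out


@dataclass(frozen=True)
class SourceSpec:
    """One simulated source.

    kind
        ``"vep"`` — the evoked-potential wave packet, identical in every
        epoch; ``"harmonic"`` — a pure sinusoid with fixed amplitude,
        frequency and initial phase; ``"white"`` — i.i.d. Gaussian noise;
        ``"colored"`` — Gaussian noise with a 1/f^alpha amplitude spectrum.
    amplitude
        Peak (harmonic/vep) or standard-deviation (noise) scale factor.
    frequency
        Oscillation frequency in Hz (harmonic) or the VEP carrier in Hz
        (default 10 for the vep kind).
    """

    kind: str
    amplitude: float = 1.0
    frequency: float | None = None
    initial_phase: float = 0.0
    alpha: float = 1.0
    trajectory: FixedTrajectory | LinearTrajectory | RotationalTrajectory = field(
        default_factory=lambda: FixedTrajectory((0.0, 0.0, 0.0))
    )

    def __post_init__(self) -> None:
        if self.kind not in {"vep", "harmonic", "white", "colored"}:
            raise ValueError(f"unsupported source kind {self.kind!r}")
        if self.kind == "harmonic" and (self.frequency is None or self.frequency <= 0):
            raise ValueError("harmonic sources need frequency > 0")


def mixing_weights(
    montage: ElectrodeMontage,
    source_positions: Sequence[Sequence[float]],
    floor: float = DISTANCE_FLOOR,
) -> np.ndarray:
    """Inverse-square-distance gain matrix, channels x sources.

    ``w_ji = 1 / max(d(c_j, s_i), floor)**2`` with the distance floor
    preventing a singular gain when a source coincides with an electrode.
    """
    if floor <= 0:
        raise ValueError("distance floor must be positive")
    src = np.atleast_2d(np.asarray(source_positions, dtype=float))
    if src.size == 0:
        raise ValueError("source position list is empty")
    d = np.linalg.norm(montage.positions[:, None, :] - src[None, :, :], axis=2)
    return 1.0 / np.maximum(d, floor) ** 2


def vep_waveform(
    N: int,
    f: float = 10.0,
    mu: float | None = None,
    sigma2: float | None = None,
    fs: float = 256.0,
) -> np.ndarray:
    """Gaussian-windowed, downward-chirped evoked-potential wave packet.

    ``v(n) = (1/sqrt(2*pi)) * exp(-((n-mu)/sigma)**2 / 2)
    * sin(2*pi*f*(n/N)*gamma(n))`` for n = 1..N, with
    ``gamma(n) = (N - 0.5*n)/N`` and ``sigma = sqrt(sigma2)``.

    Defaults place the envelope peak mid-epoch (``mu = 0.5*N``) with
    ``sigma2 = 0.125*N`` samples^2.  The chirp sweeps the instantaneous
    frequency down as ``fs*f*(1 - n/N)/N`` Hz, so with N = 768 and f = 10
    the packet oscillates near 1.67 Hz at its peak.
    """
    if N <= 0:
        raise ValueError("epoch length N must be positive")
    mu = 0.5 * N if mu is None else mu
    sigma2 = 0.125 * N if sigma2 is None else sigma2
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    n = np.arange(1, N + 1, dtype=float)
    sigma = math.sqrt(sigma2)
    envelope = np.exp(-0.5 * ((n - mu) / sigma) ** 2) / math.sqrt(2.0 * math.pi)
    gamma = (N - 0.5 * n) / N
    return envelope * np.sin(2.0 * math.pi * f * (n / N) * gamma)


def _colored_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^alpha power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    scale[0] = 0.0  # remove DC: the shaping law diverges there
    out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_sources(
    specs: Sequence[SourceSpec],
    n_samples: int,
    fs: float,
    seed: int,
    epoch_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Realize source time courses and their per-sample positions.

    Returns ``(S, P)`` with ``S`` of shape (n_sources, n_samples) and ``P``
    of shape (n_sources, n_samples, 3).  All randomness is drawn from a
    single generator seeded with ``seed``, in spec order, so identical seeds
    yield bit-identical sources.  The VEP kind is deterministic (noise seeds
    never alter it) and requires ``epoch_length`` to tile its wave packet.
    """
    if not specs:
        raise ValueError("at least one source spec is required")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    S = np.empty((len(specs), n_samples))
    P = np.empty((len(specs), n_samples, 3))
    for i, spec in enumerate(specs):
        if spec.kind == "harmonic":
            S[i] = spec.amplitude * np.sin(
                2.0 * math.pi * spec.frequency * t + spec.initial_phase
            )
        elif spec.kind == "white":
            S[i] = spec.amplitude * rng.standard_normal(n_samples)
        elif spec.kind == "colored":
            S[i] = spec.amplitude * _colored_noise(rng, n_samples, spec.alpha)
        elif spec.kind == "vep":
            if epoch_length is None:
                raise ValueError("vep sources need epoch_length")
            if n_samples % epoch_length:
                raise ValueError("n_samples must be a multiple of epoch_length")
            wave = vep_waveform(epoch_length, f=spec.frequency or 10.0, fs=fs)
            S[i] = spec.amplitude * np.tile(wave, n_samples // epoch_length)
        P[i] = spec.trajectory.positions(t)
        if np.any(np.linalg.norm(P[i], axis=1) > 1.0 + 1e-9):
            raise ValueError(f"source {i} trajectory leaves the unit sphere")
    return S, P


@dataclass
class SimulatedRecord:
    """A simulated multichannel record plus per-source ground truth.

    ``contributions[i]`` is the channels x samples mixture of source ``i``
    alone; ``data`` is their sum.  Keeping the per-source mixtures allows
    SNR reporting and source-recovery checks downstream.
    """

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    epoch_length: int
    n_epochs: int
    montage: ElectrodeMontage
    specs: tuple[SourceSpec, ...]
    contributions: np.ndarray  # (n_sources, n_channels, n_samples)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def simulate_record(
    montage: ElectrodeMontage,
    specs: Sequence[SourceSpec],
    n_epochs: int = 30,
    epoch_seconds: float = 3.0,
    fs: float = 256.0,
    seed: int = 0,
    floor: float = DISTANCE_FLOOR,
) -> SimulatedRecord:
    """Mix sources into electrodes: C = W S, with W re-evaluated per sample
    for moving sources.

    The default epoch structure (30 epochs of 3 s at 256 Hz) carries one
    evoked wave packet per epoch, identical across epochs.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    specs = tuple(specs)
    epoch_length = int(round(epoch_seconds * fs))
    n_samples = n_epochs * epoch_length
    S, P = generate_sources(specs, n_samples, fs, seed, epoch_length=epoch_length)
    n_ch = montage.n_channels
    contributions = np.empty((len(specs), n_ch, n_samples))
    for i in range(len(specs)):
        pos = P[i]
        if np.ptp(pos, axis=0).max() == 0.0:  # static source: one weight column
            w = mixing_weights(montage, pos[:1], floor)[:, 0]
            contributions[i] = np.outer(w, S[i])
        else:
            d = np.linalg.norm(
                montage.positions[:, None, :] - pos[None, :, :], axis=2
            )
            contributions[i] = S[i][None, :] / np.maximum(d, floor) ** 2
    data = contributions.sum(axis=0)
    return SimulatedRecord(
        data=data,
        fs=fs,
        epoch_length=epoch_length,
        n_epochs=n_epochs,
        montage=montage,
        specs=specs,
        contributions=contributions,
    )


def snr_db(record: SimulatedRecord) -> float:
    """Broadband SNR in dB: VEP-mixture power over residual power,
    averaged across channels.  Returns ``inf`` for a noiseless record.
    """
    vep_idx = [i for i, s in enumerate(record.specs) if s.kind == "vep"]
    if not vep_idx:
        raise ValueError("record has no vep source in its ground truth")
    signal = record.contributions[vep_idx].sum(axis=0)
    noise = record.data - signal
    p_noise = float(np.mean(noise**2))
    if p_noise == 0.0:
        return float("inf")
    return 10.0 * math.log10(float(np.mean(signal**2)) / p_noise)


# --------------------------------------------------------------------------
# speller-like event schedule

@dataclass(frozen=True)
class FlashSchedule:
    """Ordered stimulus events with ERP / no-ERP condition labels.

    ``events`` holds ``(onset_sample, condition)`` pairs with strictly
    increasing onsets spaced by the interstimulus interval;
    ``epoch_window`` gives (start, end) sample offsets relative to onset.
    """

    events: tuple[tuple[int, str], ...]
    isi_ms: float
    epoch_window: tuple[int, int]

    def __post_init__(self) -> None:
        onsets = [o for o, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def onsets(self, condition: str | None = None) -> list[int]:
        return [o for o, c in self.events if condition is None or c == condition]

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, c in self.events:
            seen.setdefault(c)
        return tuple(seen)


def speller_schedule(
    n_characters: int,
    sequences_per_character: int,
    isi_ms: float = 125.0,
    fs: float = 256.0,
    epoch_ms: float = 1000.0,
    first_onset: int = 0,
) -> FlashSchedule:
    """Row/column flash schedule of a 6x6 matrix speller.

    Each stimulation sequence flashes the 6 rows then the 6 columns; exactly
    two of the twelve flashes intersect the target character (its row and
    its column) and are labeled ``ERP``, the other ten ``noERP``.  Onsets
    are spaced by ``round(isi_ms * fs / 1000)`` samples, giving the exact
    1:5 ERP:noERP ratio of the paradigm.
    """
    if min(n_characters, sequences_per_character) < 1 or isi_ms <= 0 or fs <= 0:
        raise ValueError("all schedule counts and rates must be positive")
    step = int(round(isi_ms * fs / 1000.0))
    window = (0, int(round(epoch_ms * fs / 1000.0)))
    events: list[tuple[int, str]] = []
    onset = first_onset
    for char in range(n_characters):
        target_row = char % 6
        target_col = (char // 6) % 6
        for _ in range(sequences_per_character):
            for flash in range(12):
                if flash < 6:
                    hit = flash == target_row
                else:
                    hit = flash - 6 == target_col
                events.append((onset, "ERP" if hit else "noERP"))
                onset += step
    return FlashSchedule(tuple(events), isi_ms, window)


#: initial phase of the frontal delta-band harmonic that places it in
#: antiphase with the VEP's in-band phase at the epoch midpoint (band
#: centered near 1.57 Hz, 4-cycle Morlet, 3 s epochs at 256 Hz)
FRONTAL_ANTIPHASE = 4.7329


def default_seeg_sources(
    montage: ElectrodeMontage, vep_amplitude: float = 12.0
) -> list[SourceSpec]:
    """Default source configuration for synthetic-EEG experiments.

    The planted spatial structure: one occipital VEP source close to the
    scalp, and one frontal delta-band harmonic (5/3 Hz, epoch-periodic,
    fixed initial phase in antiphase with the VEP wave packet at the epoch
    midpoint) that keeps frontal electrodes desynchronized from the
    occipital cluster — without such an out-of-phase far source, "far
    electrodes outside the evoked cluster" would not be a recoverable
    ground truth.  Scattered harmonic / white / colored sources (one
    drifting, one orbiting) add broadband noise; the 8 Hz harmonic mimics
    a steady-state stimulation artifact.  Amplitude rationale is in the
    methods note.
    """
    def _direction(prefixes: tuple[str, ...]) -> np.ndarray:
        rows = [
            montage.positions[i]
            for i, n in enumerate(montage.names)
            if n.startswith(prefixes)
        ]
        v = np.mean(rows, axis=0)
        return v / np.linalg.norm(v)

    occipital = _direction(("O",))
    frontal = _direction(("Fp", "F")) if any(
        n.startswith("Fp") for n in montage.names
    ) else _direction(("F",))
    return [
        SourceSpec("vep", amplitude=vep_amplitude, frequency=10.0,
                   trajectory=FixedTrajectory(tuple(0.8 * occipital))),
        SourceSpec("harmonic", amplitude=0.035 * vep_amplitude, frequency=5.0 / 3.0,
                   initial_phase=FRONTAL_ANTIPHASE,
                   trajectory=FixedTrajectory(tuple(0.7 * frontal))),
        SourceSpec("harmonic", amplitude=2.0, frequency=8.0, initial_phase=0.7,
                   trajectory=FixedTrajectory((0.5, 0.1, 0.2))),
        SourceSpec("harmonic", amplitude=2.0, frequency=5.0, initial_phase=2.1,
                   trajectory=FixedTrajectory((-0.5, 0.1, 0.2))),
        SourceSpec("white", amplitude=1.2,
                   trajectory=FixedTrajectory((0.0, 0.2, 0.45))),
        SourceSpec("white", amplitude=1.2,
                   trajectory=LinearTrajectory((-0.3, -0.3, 0.3), (0.006, 0.006, 0.0))),
        SourceSpec("colored", amplitude=1.5, alpha=1.0,
                   trajectory=RotationalTrajectory((0.0, 0.0, 0.4), 0.3, 0.1)),
    ]
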