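"""Multivariate phase-synchrony clustering by circular variance.

At every time sample and frequency band the instantaneous phases of the
``N_ch`` channels are points on the unit circle.  A candidate channel set
is coherent when the magnitude of its mean resultant vector

    Rbar = | mean_j exp(i * theta_j) |

is close to 1.  Fuzzy (overlapping) clusters are grown greedily from every
channel as a seed, adding at each step the channel that maximizes Rbar of
the enlarged set and stopping before any addition would drop Rbar below
the threshold ``r``.  The overlapping candidates are then reduced to a
disjoint (hard) partition by repeatedly accepting the candidate with the
highest Rbar (ties: larger set, then smaller encoded label) and stripping
its members from the survivors, whose Rbar is recomputed on the reduced
sets.  Channels never accepted into a multi-channel cluster end up as
singletons, whose Rbar is 1 by definition.

Cluster identity is carried as an integer bitmask over the canonical
channel order (most significant bit = first channel, padded to a multiple
of four bits) so that identical channel sets compare equal across samples;
the :mod:`phasetopo.labeling` module renders these masks as hexadecimal
words.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tf_phase import FrequencyGrid, PhaseTensor

__all__ = [
    "FuzzyCluster",
    "HardPartition",
    "ClusterRecord",
    "mean_resultant",
    "create_fuzzy_clusters",
    "convert_to_hard",
    "cluster_sample",
    "cluster_series",
]


def n_label_bits(n_channels: int) -> int:
    """Label width in bits: channel count padded up to a multiple of 4."""
    return 4 * math.ceil(n_channels / 4)


def members_to_mask(members: Iterable[int], n_channels: int) -> int:
    """Bitmask of a channel-index set, MSB-first in montage order."""
    bits = n_label_bits(n_channels)
    return sum(1 << (bits - 1 - j) for j in members)


def mask_to_members(mask: int, n_channels: int) -> frozenset[int]:
    bits = n_label_bits(n_channels)
    return frozenset(j for j in range(n_channels) if mask >> (bits - 1 - j) & 1)


def mean_resultant(angles: Sequence[float] | np.ndarray) -> float:
    """Magnitude of the mean resultant vector of a set of angles, in [0, 1].

    Equals 1 for perfectly aligned angles and 0 for balanced (e.g.
    antipodal) configurations; a singleton always scores 1.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("mean_resultant of an empty angle set")
    return float(np.abs(np.mean(np.exp(1j * angles))))


@dataclass(frozen=True)
class FuzzyCluster:
    """A candidate channel set with its mean-resultant magnitude."""

    members: frozenset[int]
    rbar: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("fuzzy cluster must be non-empty")


@dataclass(frozen=True)
class HardPartition:
    """Disjoint channel sets covering all channels, with per-cluster Rbar."""

    clusters: tuple[frozenset[int], ...]
    rbars: tuple[float, ...]
    n_channels: int

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for c in self.clusters:
            if covered & c:
                raise ValueError("hard clusters must be pairwise disjoint")
            covered |= c
        if covered != set(range(self.n_channels)):
            raise ValueError("hard clusters must cover all channels")

    def cluster_of(self, channel: int) -> frozenset[int]:
        for c in self.clusters:
            if channel in c:
                return c
        raise KeyError(channel)

    def labels(self) -> np.ndarray:
        """Per-channel cluster bitmask, in canonical channel order."""
        out = np.zeros(self.n_channels, dtype=np.uint32)
        for c in self.clusters:
            mask = members_to_mask(c, self.n_channels)
            for j in c:
                out[j] = mask
        return out


def create_fuzzy_clusters(phases: np.ndarray, r: float) -> list[FuzzyCluster]:
    """Grow one greedy candidate cluster from every channel seed.

    Each seed set is enlarged by the channel whose inclusion maximizes the
    mean resultant magnitude; growth stops before any addition would drop
    it below ``r``.  Duplicate member sets are merged, so the result may
    hold fewer candidates than channels; candidates may overlap.
    """
    if not 0 < r < 1:
        raise ValueError("threshold r must satisfy 0 < r < 1")
    phases = np.asarray(phases, dtype=float)
    n_ch = phases.size
    E = np.exp(1j * phases)
    seen: dict[frozenset[int], float] = {}
    for seed in range(n_ch):
        members = [seed]
        z = E[seed]
        rbar = 1.0
        free = set(range(n_ch)) - {seed}
        while free:
            cand = np.array(sorted(free))
            cand_r = np.abs(z + E[cand]) / (len(members) + 1)
            best = int(np.argmax(cand_r))
            if cand_r[best] < r:
                break
            z = z + E[cand[best]]
            members.append(int(cand[best]))
            rbar = float(cand_r[best])
            free.discard(int(cand[best]))
        seen.setdefault(frozenset(members), rbar)
    return [FuzzyCluster(m, rb) for m, rb in seen.items()]


def _hard_masks(
    candidates: dict[int, float], E: np.ndarray, n_ch: int, r: float
) -> list[tuple[int, float]]:
    """Greedy overlap elimination on bitmask candidates.

    ``candidates`` maps bitmask -> Rbar.  Returns accepted
    ``(mask, rbar)`` clusters; uncovered channels are appended as
    singletons.
    """
    bits = n_label_bits(n_ch)
    bit_of = [1 << (bits - 1 - j) for j in range(n_ch)]
    cand = dict(candidates)
    accepted: list[tuple[int, float]] = []
    covered = 0
    while cand:
        best_mask = min(
            cand, key=lambda m: (-cand[m], -m.bit_count(), m)
        )
        best_r = cand.pop(best_mask)
        if best_mask.bit_count() > 1 and best_r < r:
            continue  # reduced below threshold: its channels fall through
        accepted.append((best_mask, best_r))
        covered |= best_mask
        reduced: dict[int, float] = {}
        for mask in cand:
            new = mask & ~best_mask
            if new == 0 or new in reduced:
                continue
            if new == mask:
                reduced[new] = cand[mask]
            elif new.bit_count() == 1:
                reduced[new] = 1.0
            else:
                idx = [j for j in range(n_ch) if new & bit_of[j]]
                reduced[new] = float(np.abs(np.mean(E[idx])))
        cand = reduced
    for j in range(n_ch):
        if not covered & bit_of[j]:
            accepted.append((bit_of[j], 1.0))
    return accepted


def convert_to_hard(
    fuzzy: Sequence[FuzzyCluster], phases: np.ndarray, r: float
) -> HardPartition:
    """Reduce overlapping candidates to a disjoint covering partition.

    ``phases`` must be the same phase vector the candidates were grown
    from: survivors' Rbar is recomputed on their reduced member sets after
    every acceptance.
    """
    phases = np.asarray(phases, dtype=float)
    n_ch = phases.size
    E = np.exp(1j * phases)
    candidates = {
        members_to_mask(fc.members, n_ch): fc.rbar for fc in fuzzy
    }
    accepted = _hard_masks(candidates, E, n_ch, r)
    clusters = tuple(mask_to_members(m, n_ch) for m, _ in accepted)
    rbars = tuple(rb for _, rb in accepted)
    return HardPartition(clusters=clusters, rbars=rbars, n_channels=n_ch)


def cluster_sample(phases: np.ndarray, r: float) -> HardPartition:
    """Fuzzy generation followed by hard conversion for one phase vector."""
    return convert_to_hard(create_fuzzy_clusters(phases, r), phases, r)


@dataclass
class ClusterRecord:
    """Per band, a channels x samples grid of cluster bitmask labels.

    ``labels[k, j, n]`` is the bitmask of the hard cluster containing
    channel ``j`` at sample ``n`` in band ``k``; at every (n, k) the masks
    define a valid disjoint covering partition.
    """

    labels: np.ndarray  # uint32, (n_bands, n_channels, n_samples)
    grid: FrequencyGrid
    fs: float
    r: float

    @property
    def n_bands(self) -> int:
        return self.labels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.labels.shape[1]

    @property
    def n_samples(self) -> int:
        return self.labels.shape[2]


def _fuzzy_masks_band(theta: np.ndarray, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized greedy growth across all samples of one band.

    Returns ``(masks, rbars)`` of shape (n_channels_seeds, n_samples): the
    candidate grown from each seed at each sample, as bitmask and Rbar.
    """
    n_ch, n_samp = theta.shape
    bits = n_label_bits(n_ch)
    weights = (1 << (bits - 1 - np.arange(n_ch, dtype=np.uint64))).astype(np.uint64)
    E = np.exp(1j * theta)  # (n_ch, n_samp)
    masks = np.empty((n_ch, n_samp), dtype=np.uint64)
    rbars = np.empty((n_ch, n_samp))
    cols = np.arange(n_samp)
    for seed in range(n_ch):
        member = np.zeros((n_ch, n_samp), dtype=bool)
        member[seed] = True
        z = E[seed].copy()
        size = np.ones(n_samp)
        active = np.ones(n_samp, dtype=bool)
        for _ in range(n_ch - 1):
            cand_r = np.abs(z[None, :] + E) / (size + 1.0)
            cand_r[member] = -1.0
            best = np.argmax(cand_r, axis=0)
            best_r = cand_r[best, cols]
            grow = active & (best_r >= r)
            if not grow.any():
                break
            z = np.where(grow, z + E[best, cols], z)
            size = np.where(grow, size + 1.0, size)
            member[best[grow], cols[grow]] = True
            active = grow
        masks[seed] = (member * weights[:, None]).sum(axis=0)
        # singletons score exactly 1 (|exp(i theta)| may round below 1)
        rbars[seed] = np.where(size == 1.0, 1.0, np.abs(z) / size)
    return masks, rbars


def cluster_series(phase: PhaseTensor, r: float) -> ClusterRecord:
    """Run the clustering independently at every sample of every band.

    Deterministic for a fixed input: the greedy growth, ordering and
    tie-breaking involve no randomness.
    """
    if not 0 < r < 1:
        raise ValueError("threshold r must satisfy 0 < r < 1")
    n_ch, n_samp, n_bands = phase.values.shape
    labels = np.zeros((n_bands, n_ch, n_samp), dtype=np.uint32)
    bits = n_label_bits(n_ch)
    bit_of = [1 << (bits - 1 - j) for j in range(n_ch)]
    for k in range(n_bands):
        theta = phase.values[:, :, k]
        masks, rbars = _fuzzy_masks_band(theta, r)
        E = np.exp(1j * theta)
        for n in range(n_samp):
            cand: dict[int, float] = {}
            for s in range(n_ch):
                m = int(masks[s, n])
                if m not in cand:
                    cand[m] = float(rbars[s, n])
            col = labels[k, :, n]
            for mask, rb in _hard_masks(cand, E[:, n], n_ch, r):
                for j in range(n_ch):
                    if mask & bit_of[j]:
                        col[j] = mask
    return ClusterRecord(labels=labels, grid=phase.grid, fs=phase.fs, r=r)
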