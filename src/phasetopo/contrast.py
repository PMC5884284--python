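"""Levenshtein-distance contrast between condition label maps (TFL maps).

Cluster labels are fixed-width binary words over the alphabet {0, 1}, one
bit per channel.  Their dissimilarity under two conditions is an edit
distance with unit costs; because the labels always have equal length and
each bit position carries the identity of one channel, the comparison is
restricted to position-wise substitutions, so the distance equals the
number of differing bits, bounded by the channel count (the extreme case:
no channel assigned versus all channels assigned).  The unrestricted
dynamic program over insertions, deletions and substitutions is provided
as :func:`levenshtein` for general strings; note that allowing shifts can
undercut the substitution count even on equal-length words, which would
break the channel-wise reading of the contrast — hence the restricted
:func:`label_distance` is what TFL maps use.  A TFL map collects these
distances per channel over the bands x windows grid shared by two TFT
maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labeling import mask_to_hex
from .maps import TFTMap
from .mcps import n_label_bits

__all__ = ["TFLMap", "levenshtein", "label_distance", "tfl_map"]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two strings (full dynamic program).

    Implements the general insert/delete/substitute recurrence even though
    equal-length label words only exercise substitutions.
    """
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            curr.append(
                min(
                    prev[j] + 1,  # deletion
                    curr[j - 1] + 1,  # insertion
                    prev[j - 1] + (ca != cb),  # substitution / match
                )
            )
        prev = curr
    return prev[-1]


def label_distance(a: str, b: str) -> int:
    """Edit distance between equal-length label words, substitutions only.

    With insertions and deletions ruled out (each bit position belongs to
    one channel, so bits must stay aligned), the dynamic program reduces
    to its diagonal and the distance is the number of differing positions.
    """
    if len(a) != len(b):
        raise ValueError("label words must have equal length")
    return sum(ca != cb for ca, cb in zip(a, b))


@dataclass
class TFLMap:
    """Per-channel bands x windows grid of label edit distances."""

    distances: np.ndarray  # int, (n_bands, n_windows)
    channel: int
    upsilon: int
    rho: float


def tfl_map(map_a: TFTMap, map_b: TFTMap, channel: int, n_channels: int) -> TFLMap:
    """Edit distance between one channel's labels under two conditions.

    Both maps must share the band grid, window tiling and montage.  Labels
    are expanded to their binary bit strings before the distance is taken,
    so each cell lies in [0, n_channels]; cells where both conditions agree
    are exactly 0 and the map is symmetric in its two inputs.
    """
    if map_a.labels.shape != map_b.labels.shape:
        raise ValueError("TFT maps have mismatched band/window/channel grids")
    if map_a.upsilon != map_b.upsilon:
        raise ValueError("TFT maps have mismatched window sizes")
    bits = n_label_bits(n_channels)
    n_bands, n_win, _ = map_a.labels.shape
    out = np.zeros((n_bands, n_win), dtype=int)
    for k in range(n_bands):
        for w in range(n_win):
            wa = format(int(map_a.labels[k, w, channel]), f"0{bits}b")
            wb = format(int(map_b.labels[k, w, channel]), f"0{bits}b")
            out[k, w] = label_distance(wa, wb)
    return TFLMap(
        distances=out, channel=channel, upsilon=map_a.upsilon, rho=map_a.rho
    )


def _hex_grid(m: TFTMap, n_channels: int) -> list[list[list[str]]]:
    """Hex-word view of a TFT label grid (helper for serialization)."""
    return [
        [
            [mask_to_hex(int(m.labels[k, w, j]), n_channels) for j in range(m.labels.shape[2])]
            for w in range(m.n_windows)
        ]
        for k in range(m.labels.shape[0])
    ]
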