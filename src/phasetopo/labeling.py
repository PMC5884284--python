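"""Hexadecimal cluster labels and their colormap.

A cluster's identity is the set of channels it contains.  That set is
encoded as a fixed-width hexadecimal word: one bit per channel, most
significant bit first in canonical montage order, padded with trailing
zero bits up to a multiple of four.  On the 8-channel montage
(Fz Cz Pz Oz P3 P4 PO7 PO8) the set {Fz, Pz, P3, P4} is the bit pattern
``10101100`` and hence the word ``"AC"``; the all-channel cluster is
``"FF"`` and the singleton {PO8} is ``"01"``.  Identical channel sets
therefore carry identical labels at every sample, band and condition.

Colors interpolate linearly between dark blue (the ``"01"`` endpoint) and
bright yellow (the all-channel endpoint) by the rank of the label's
encoded integer among the labels observed in a run; the all-zero
"unassigned" word renders as neutral gray.
"""

from __future__ import annotations

from typing import Iterable

from .mcps import mask_to_members, members_to_mask, n_label_bits
from .sim_eeg import ElectrodeMontage

__all__ = [
    "encode_label",
    "decode_label",
    "mask_to_hex",
    "hex_to_mask",
    "label_bits",
    "label_color",
    "DARK_BLUE",
    "BRIGHT_YELLOW",
    "UNASSIGNED_GRAY",
]

DARK_BLUE = (0, 0, 139)
BRIGHT_YELLOW = (255, 255, 0)
UNASSIGNED_GRAY = (128, 128, 128)


def mask_to_hex(mask: int, n_channels: int) -> str:
    """Render an integer membership bitmask as a fixed-width hex word."""
    width = n_label_bits(n_channels) // 4
    if mask < 0 or mask >= 1 << (4 * width):
        raise ValueError(f"mask {mask} out of range for {n_channels} channels")
    return format(mask, f"0{width}X")


def hex_to_mask(word: str, n_channels: int) -> int:
    width = n_label_bits(n_channels) // 4
    if len(word) != width:
        raise ValueError(
            f"label {word!r} must have {width} hex digits for {n_channels} channels"
        )
    return int(word, 16)


def label_bits(word: str, n_channels: int) -> str:
    """Binary expansion of a hex label, one character per bit (MSB first)."""
    return format(hex_to_mask(word, n_channels), f"0{n_label_bits(n_channels)}b")


def encode_label(members: Iterable[str], montage: ElectrodeMontage) -> str:
    """Encode a channel-name set as its hexadecimal cluster word."""
    idx = {montage.index(name) for name in members}
    return mask_to_hex(members_to_mask(idx, montage.n_channels), montage.n_channels)


def decode_label(word: str, montage: ElectrodeMontage) -> frozenset[str]:
    """Exact inverse of :func:`encode_label`."""
    mask = hex_to_mask(word, montage.n_channels)
    pad = montage.n_bits - montage.n_channels
    if pad and mask & ((1 << pad) - 1):
        raise ValueError(f"label {word!r} sets padding bits")
    members = mask_to_members(mask, montage.n_channels)
    return frozenset(montage.names[j] for j in members)


def label_color(
    word: str, universe: Iterable[str], n_channels: int = 8
) -> tuple[int, int, int]:
    """RGB color for a label given the set of labels seen in a run.

    The singleton-of-the-last-channel word (integer 1) is pinned to dark
    blue and the all-channel word to bright yellow; every other observed
    label is placed linearly between them by the rank of its encoded
    integer.  The all-zero word is unassigned and renders gray.
    """
    mask = hex_to_mask(word, n_channels)
    if mask == 0:
        return UNASSIGNED_GRAY
    full = members_to_mask(range(n_channels), n_channels)
    seen = {hex_to_mask(w, n_channels) for w in universe} | {1, full, mask}
    ordered = sorted(seen - {0})
    t = ordered.index(mask) / (len(ordered) - 1) if len(ordered) > 1 else 0.0
    return tuple(
        int(round(lo + t * (hi - lo))) for lo, hi in zip(DARK_BLUE, BRIGHT_YELLOW)
    )
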