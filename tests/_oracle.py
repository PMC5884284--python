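"""Exhaustive set-partition oracle for small channel counts."""

import numpy as np

from phasetopo.mcps import mean_resultant


def all_partitions(items):
    """All set partitions (Bell-number enumeration; small n only)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def oracle_partition(phases, r):
    """Best feasible partition by exhaustive search.

    Feasible: every multi-channel block has mean resultant >= r.  Best:
    lexicographically largest multiset of block sizes (prefer the largest
    coherent blocks) — unambiguous for rigid planted groups separated by
    more than pi/2.
    """
    phases = np.asarray(phases)
    best, best_key = None, None
    for part in all_partitions(range(len(phases))):
        if any(
            len(b) > 1 and mean_resultant(phases[list(b)]) < r for b in part
        ):
            continue
        key = tuple(sorted((len(b) for b in part), reverse=True))
        if best_key is None or key > best_key:
            best, best_key = part, key
    return {frozenset(b) for b in best}
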