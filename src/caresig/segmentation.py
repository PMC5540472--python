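"""Three-way record segmentation shared by both feature extractors.

A record is split into k contiguous, order-preserving chunks whose sizes
differ by at most one; when the length is not divisible by k, the
earlier chunks take the remainder (10 frames → 4, 3, 3).
"""

from __future__ import annotations

from .exceptions import InputError


def segment_sizes(n: int, k: int = 3) -> list[int]:
    """Chunk sizes for splitting ``n`` items into ``k`` ordered chunks."""
    if n < k:
        raise InputError(f"cannot split {n} items into {k} nonempty segments")
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def segment_slices(n: int, k: int = 3) -> list[slice]:
    """Index slices partitioning ``range(n)`` into ``k`` ordered chunks."""
    sizes = segment_sizes(n, k)
    slices, start = [], 0
    for s in sizes:
        slices.append(slice(start, start + s))
        start += s
    return slices
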