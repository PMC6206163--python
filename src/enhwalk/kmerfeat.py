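"""k-mer composition features.

All 4^k words for k = 1..6 (4 + 16 + ... + 4096 = 5460 features) counted
as raw overlapping occurrences, in a fixed canonical order: grouped by
ascending k, alphabetical within each k. Counting is strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np

from .errors import EnhwalkError
from .seqio import SequenceRecord

K_MIN, K_MAX = 1, 6
N_KMER_FEATURES = sum(4**k for k in range(K_MIN, K_MAX + 1))  # 5460

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class KmerVector:
    counts: np.ndarray  # int64, one entry per k-mer in canonical order
    order: tuple[str, ...]


@lru_cache(maxsize=8)
def kmer_order(k_min: int = K_MIN, k_max: int = K_MAX) -> tuple[str, ...]:
    """The canonical k-mer name list: ascending k, alphabetical within k."""
    if not 1 <= k_min <= k_max:
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    if k_max > 12:
        raise ValueError(f"k_max={k_max} refused: 4^{k_max} k-mers is combinatorially excessive")
    names: list[str] = []
    for k in range(k_min, k_max + 1):
        names.extend("".join(p) for p in product("ACGT", repeat=k))
    return tuple(names)


def count_kmers(seq: SequenceRecord | str, k_min: int = K_MIN, k_max: int = K_MAX) -> KmerVector:
    """Count overlapping k-mer occurrences for all k in [k_min, k_max].

    Single pass with a rolling 2-bit code per k; for a clean length-L
    sequence the 4^k counts at each k sum to L - k + 1.
    """
    bases = seq.bases if isinstance(seq, SequenceRecord) else seq
    order = kmer_order(k_min, k_max)
    if len(bases) < k_max:
        raise EnhwalkError(
            f"sequence length {len(bases)} < k_max={k_max}: largest k-mer block undefined"
        )
    codes = _BASE_CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        pos = int(np.flatnonzero(codes < 0)[0])
        raise EnhwalkError(f"non-ACGT character at position {pos + 1}")

    blocks: list[np.ndarray] = []
    word = codes.copy()  # 2-bit code of the k-mer ending rule: word[i] codes bases[i-k+1 : i+1]
    for k in range(1, k_max + 1):
        if k > 1:
            word = word[:-1] * 4 + codes[k - 1 :]
        if k >= k_min:
            blocks.append(np.bincount(word, minlength=4**k))
    return KmerVector(counts=np.concatenate(blocks).astype(np.int64), order=order)
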