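"""The purine/pyrimidine DNA walk.

Each base contributes one step: pyrimidines (C, T) step +1, purines
(A, G) step -1. The cumulative sum of steps is the walk, a 1-D series
whose dynamics (long-range correlation, entropy, scaling) carry
composition information beyond k-mer counts. The walk has no leading
zero: ``walk[0] == steps[0]``, and the final value equals
(#C + #T) - (#A + #G).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EncodingError
from .seqio import SequenceRecord

# pyrimidine -> +1, purine -> -1
_STEP = {"C": 1, "T": 1, "A": -1, "G": -1}
_STEP_LUT = np.full(128, 0, dtype=np.int8)
for _b, _s in _STEP.items():
    _STEP_LUT[ord(_b)] = _s


@dataclass(frozen=True)
class DNAWalk:
    """Step series (values in {+1, -1}) and its cumulative walk."""

    steps: np.ndarray
    walk: np.ndarray

    @property
    def length(self) -> int:
        return len(self.steps)


def build_walk(seq: SequenceRecord | str) -> DNAWalk:
    """Encode a normalized ACGT sequence as its DNA walk."""
    bases = seq.bases if isinstance(seq, SequenceRecord) else seq
    if not bases:
        raise EncodingError("cannot build a walk from an empty sequence")
    codes = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    steps = _STEP_LUT[codes].astype(np.int64)
    bad = np.flatnonzero(steps == 0)
    if bad.size:
        raise EncodingError(
            f"non-ACGT character {bases[bad[0]]!r} at position {int(bad[0]) + 1}"
        )
    return DNAWalk(steps=steps, walk=np.cumsum(steps))


def write_walk_csv(walk: DNAWalk, path: str | Path) -> None:
    """Export (position, step, walk) triples, e.g. for plotting."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "step", "walk"])
        for i, (s, v) in enumerate(zip(walk.steps, walk.walk), start=1):
            w.writerow([i, int(s), int(v)])
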