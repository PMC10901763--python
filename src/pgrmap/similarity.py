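"""Pairwise sequence-identity predicate shared by the clustering steps.

Identity follows the -c semantics of classic greedy nucleotide clusterers:
the shorter sequence is aligned end-to-end within the longer one (infix
edit distance via edlib) on either strand, and identity is
``1 - distance / len(shorter)``.
"""

from __future__ import annotations

import edlib

from .model import revcomp


def global_identity(shorter: str, longer: str) -> float:
    """Best either-strand identity of ``shorter`` aligned within ``longer``."""
    if len(shorter) > len(longer):
        shorter, longer = longer, shorter
    best = 0.0
    for q in (shorter, revcomp(shorter)):
        d = edlib.align(q, longer, mode="HW", task="distance")["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(shorter))
    return best
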