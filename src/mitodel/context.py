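"""Sequence context of deletion junctions: terminal microhomology (TMH).

TMH is the total length of identical sequence shared between one deletion
terminus and the flank of the other terminus -- the direct repeat at the
junction. It is computed as the sum of two exact extensions and is by
construction agnostic to which strand or direction a deletion mechanism
acted on:

* rightward: compare the sequence starting at the first deleted base
  (``ls5``) with the sequence starting at the first retained base after
  the deletion (``hs5 + 1``);
* leftward: compare the sequence ending at the last retained base before
  the deletion (``ls5 - 1``) with the sequence ending at the last deleted
  base (``hs5``).

The sum is invariant under the choice of equivalent junction
representation, so annotating left-aligned calls loses nothing. Only
perfect identity counts; a deletion whose TMH reaches its own span length
removes one unit of a perfect local repeat (homopolymer-run contractions
being the common case).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quant import FrequencyTable
from .refmap import CircularReference, DeletionSpan, span_length

#: extensions are capped here; biological TMH is over an order of
#: magnitude shorter
MAX_TMH = 100

TMH_BINS = [str(i) for i in range(10)] + [">=10"]


def tmh_length(span: DeletionSpan, ref: CircularReference,
               max_ext: int = MAX_TMH) -> int:
    """Total direct-repeat length at the junction (leftward + rightward
    exact extensions, circular indexing)."""
    r = 0
    while r < max_ext and ref.base(span.ls5 + r) == ref.base(span.hs5 + 1 + r):
        r += 1
    l = 0
    while l < max_ext and ref.base(span.ls5 - 1 - l) == ref.base(span.hs5 - l):
        l += 1
    return r + l


def repeat_tract_flag(span: DeletionSpan, ref: CircularReference) -> bool:
    """True when the deletion removes one unit of a perfect local repeat."""
    return tmh_length(span, ref) >= span_length(span, ref)


def tmh_bin(tmh: int) -> str:
    return str(tmh) if tmh < 10 else ">=10"


def deletion_class(tmh: int) -> int:
    """Convenience mechanistic class: 1 = little/no homology (blunt
    ligation-like, TMH <= 3), 2 = extensive homology (primer
    slippage-like, TMH >= 10), 3 = the residue. The classes are heuristic
    labels, not a partition the data defines sharply."""
    if tmh >= 10:
        return 2
    if tmh <= 3:
        return 1
    return 3


def annotate(freqs: FrequencyTable, ref: CircularReference) -> pd.DataFrame:
    """Per-deletion context annotations joined to the frequency rows.

    Adds tmh, in_repeat_tract, tmh_bin and deletion_class columns.
    """
    rows = freqs.rows
    tmh = np.zeros(len(rows), dtype=int)
    tract = np.zeros(len(rows), dtype=bool)
    for j, r in enumerate(rows.itertuples(index=False)):
        span = DeletionSpan(int(r.ls5), int(r.hs5), bool(r.wraps))
        tmh[j] = tmh_length(span, ref)
        tract[j] = tmh[j] >= int(r.length)
    out = rows.copy()
    out["tmh"] = tmh
    out["in_repeat_tract"] = tract
    out["tmh_bin"] = [tmh_bin(t) for t in tmh]
    out["deletion_class"] = [deletion_class(t) for t in tmh]
    return out


def tmh_spectrum(annotated: pd.DataFrame, min_span: int = 20) -> dict:
    """Background-subtracted frequency mass per TMH bin for deletions of
    at least ``min_span`` bp, plus the fraction of (unique) deletions with
    any TMH."""
    sel = annotated[annotated["length"] >= min_span]
    spectrum = {b: 0.0 for b in TMH_BINS}
    for r in sel.itertuples(index=False):
        spectrum[tmh_bin(int(r.tmh))] += float(r.f_i_bg)
    frac_with_tmh = float((sel["tmh"] >= 1).mean()) if len(sel) else float("nan")
    return {"spectrum": spectrum, "fraction_with_tmh": frac_with_tmh,
            "n_deletions": int(len(sel))}
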