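"""Split-read deletion detection on a circular reference.

Reads are aligned to two tandem copies of the reference so that alignments
and junctions crossing the coordinate origin need no special casing; all
reported coordinates are folded back onto ``[1, L]``. A deletion junction
is called when the two ends of one read anchor at distinct reference loci
on the same strand with a positive reference gap. Junction representations
are then left-aligned (shifted to the smallest equivalent ``ls5``) so that
every deletant sequence has exactly one canonical (ls5, hs5) key, and mate
pairs are reconciled: a junction supported by one mate is dropped for that
pair when the other mate contiguously covers the junction locus, which is
incompatible with the deletion.

The aligner is a deliberately small exact-k-mer-seed / ungapped-extension
scheme (default k = 16, at most 2 mismatches per anchor, 20 bp minimum
anchor). On a 16.6-kb genome with near-unique 16-mers this is sufficient to
realize the detection contract; it is not a general-purpose read mapper.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .refmap import CircularReference, DeletionSpan, canonicalize, span_length

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

#: spans longer than this are retained but flagged: on a circular reference
#: their split reads are indistinguishable from large insertions
POSSIBLE_INSERTION_BP = 15000


class AmbiguousJunctionError(ValueError):
    """Anchors overlap on the reference after canonicalization."""


class UndefinedLoadError(ZeroDivisionError):
    """Deletion load is undefined when no reads mapped."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Anchor:
    """An ungapped match: read interval [read_start, read_end) (0-based,
    half-open) against doubled-reference interval [ref_start, ref_end]
    (1-based, inclusive)."""

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class SplitAlignment:
    """Exactly two same-strand anchors with a positive reference gap."""

    left: Anchor
    right: Anchor

    @property
    def gap(self) -> int:
        return self.right.ref_start - self.left.ref_end - 1


@dataclass(frozen=True)
class AlignmentResult:
    kind: str  # "split" | "contig"
    anchors: tuple[Anchor, ...]
    split: SplitAlignment | None = None


class ReadAligner:
    """Exact-seeded, mismatch-tolerant anchoring aligner on the doubled
    reference.

    Seeds are exact k-mers taken from the read ends (with fallback offsets
    to step over sequencing errors); anchors are extended ungapped in both
    directions tolerating at most ``max_mismatch`` mismatches and trimmed
    back to their last matching base, so junction coordinates are never
    shifted by a terminal mismatch.
    """

    def __init__(self, ref: CircularReference, k: int = 16,
                 min_anchor: int = 20, max_mismatch: int = 2) -> None:
        self.ref = ref
        self.L = ref.length
        self.k = k
        self.min_anchor = min_anchor
        self.max_mismatch = max_mismatch
        doubled = ref.doubled().encode()
        self.darr = np.frombuffer(doubled, dtype=np.uint8)
        index: dict[bytes, list[int]] = {}
        for i in range(self.L):
            index.setdefault(doubled[i : i + k], []).append(i)
        self.index = index

    # -- extension helpers (0-based doubled-reference coordinates) ---------

    def _extend_right(self, arr: np.ndarray, rpos: int, dpos: int) -> int:
        """Length of rightward extension from (rpos, dpos), trailing
        mismatches trimmed."""
        n = min(len(arr) - rpos, 2 * self.L - dpos)
        if n <= 0:
            return 0
        cmp = arr[rpos : rpos + n] != self.darr[dpos : dpos + n]
        mism = np.flatnonzero(cmp)
        end = n if len(mism) <= self.max_mismatch else int(mism[self.max_mismatch])
        while end > 0 and cmp[end - 1]:
            end -= 1
        return end

    def _extend_left(self, arr: np.ndarray, rpos: int, dpos: int) -> int:
        """Length of leftward extension ending just before (rpos, dpos)."""
        n = min(rpos, dpos)
        if n <= 0:
            return 0
        cmp = arr[rpos - n : rpos][::-1] != self.darr[dpos - n : dpos][::-1]
        mism = np.flatnonzero(cmp)
        end = n if len(mism) <= self.max_mismatch else int(mism[self.max_mismatch])
        while end > 0 and cmp[end - 1]:
            end -= 1
        return end

    def _seed_hits(self, kmer: bytes) -> list[int]:
        return self.index.get(kmer, [])

    def _anchor_from_left(self, raw: bytes, arr: np.ndarray) -> Anchor | None:
        best: Anchor | None = None
        for off in (0, self.k, 2 * self.k):
            if off + self.k > len(arr):
                break
            hits = self._seed_hits(raw[off : off + self.k])
            for p in hits:
                lext = self._extend_left(arr, off, p)
                rext = self._extend_right(arr, off, p)
                a = Anchor(off - lext, off + rext, p - lext + 1, p + rext)
                if best is None or a.read_end > best.read_end or (
                    a.read_end == best.read_end and a.length > best.length
                ):
                    best = a
            if best is not None and best.read_start <= 3:
                return best
        return best

    def _anchor_from_right(self, raw: bytes, arr: np.ndarray) -> Anchor | None:
        best: Anchor | None = None
        n = len(arr)
        for back in (0, self.k, 2 * self.k):
            off = n - self.k - back
            if off < 0:
                break
            hits = self._seed_hits(raw[off : off + self.k])
            for p0 in hits:
                # prefer the second-copy placement so right anchors sit to
                # the right of left anchors even across the origin
                for p in (p0, p0 + self.L):
                    if p + self.k > 2 * self.L:
                        continue
                    lext = self._extend_left(arr, off, p)
                    rext = self._extend_right(arr, off, p)
                    a = Anchor(off - lext, off + rext, p - lext + 1, p + rext)
                    if best is None or a.read_start < best.read_start or (
                        a.read_start == best.read_start and a.length > best.length
                    ):
                        best = a
            if best is not None and best.read_end >= n - 3:
                return best
        return best

    def _optimal_split(self, arr: np.ndarray, d1: int, d2: int
                       ) -> tuple[int, int] | None:
        """Best junction read-offset between diagonals d1 (left) and d2
        (right), minimizing total mismatches; ties go to the smallest
        offset (the leftmost equivalent placement inside a homology run).

        A diagonal d maps read position i to 0-based doubled-reference
        position d + i. Returns (t, cost) or None when out of bounds.
        """
        n = len(arr)
        m = self.min_anchor
        if d1 < 0 or d2 + n > 2 * self.L or n < 2 * m:
            return None
        a = (arr != self.darr[d1 : d1 + n]).astype(np.int32)
        b = (arr != self.darr[d2 : d2 + n]).astype(np.int32)
        ca = np.concatenate([[0], np.cumsum(a)])   # mism in read[0:t] on d1
        cb = np.concatenate([[0], np.cumsum(b)])   # mism in read[0:t] on d2
        ts = np.arange(m, n - m + 1)
        cost = ca[ts] + (cb[n] - cb[ts])
        j = int(np.argmin(cost))  # first minimum -> smallest t
        t = int(ts[j])
        left_mism = int(ca[t])
        right_mism = int(cb[n] - cb[t])
        if left_mism > self.max_mismatch or right_mism > self.max_mismatch:
            return None
        return t, int(cost[j])

    def _align_oriented(self, read: str) -> AlignmentResult | None:
        raw = read.encode()
        arr = np.frombuffer(raw, dtype=np.uint8)
        n = len(arr)
        left = self._anchor_from_left(raw, arr)
        if left is None:
            return None
        if left.read_end >= n - 3:
            return AlignmentResult("contig", (left,))
        right = self._anchor_from_right(raw, arr)
        if right is None:
            # no usable second anchor: report the partial contiguous match
            return AlignmentResult("contig", (left,))
        d1 = left.ref_start - 1 - left.read_start
        d2 = right.ref_start - 1 - right.read_start
        if d2 <= d1:
            # same locus, or a gap crossing the origin: lift to second copy
            if d2 + self.L + n <= 2 * self.L and d2 + self.L > d1:
                d2 += self.L
            else:
                return AlignmentResult("contig", (left,))
        if d2 - d1 >= self.L:
            return AlignmentResult("contig", (left,))
        placed = self._optimal_split(arr, d1, d2)
        if placed is None:
            return AlignmentResult("contig", (left,))
        t, _cost = placed
        la = Anchor(0, t, d1 + 1, d1 + t, left.strand)
        ra = Anchor(t, n, d2 + t + 1, d2 + n, right.strand)
        split = SplitAlignment(la, ra)
        if split.gap <= 0:
            return AlignmentResult("contig", (left,))
        return AlignmentResult("split", (la, ra), split)

    def align(self, read: str) -> AlignmentResult | None:
        """Align one read; tries the forward orientation, then the reverse
        complement. All coordinates are on the forward reference axis."""
        if len(read) < 2 * self.min_anchor:
            return None
        fwd = self._align_oriented(read)
        if fwd is not None and (
            fwd.kind == "split" or fwd.anchors[0].length >= 0.9 * len(read)
        ):
            return fwd
        rev = self._align_oriented(revcomp(read))
        if rev is None:
            return fwd
        if fwd is None:
            return rev
        # keep whichever orientation explains more of the read
        fb = sum(a.length for a in fwd.anchors)
        rb = sum(a.length for a in rev.anchors)
        return fwd if fb >= rb else rev


# ---------------------------------------------------------------------------
# junction calling and normalization
# ---------------------------------------------------------------------------


def call_junction(split: SplitAlignment, ref: CircularReference) -> DeletionSpan:
    """Convert a two-anchor split into last-missing-base coordinates."""
    L = ref.length
    p_end = split.left.ref_end
    q_start = split.right.ref_start
    gap = q_start - p_end - 1
    if gap <= 0:
        raise AmbiguousJunctionError(
            f"anchors overlap on reference (gap {gap})"
        )
    if gap >= L:
        raise AmbiguousJunctionError(f"gap {gap} spans the whole reference")
    ls5 = canonicalize(p_end + 1 if p_end + 1 <= 2 * L else p_end + 1 - L, L)
    hs5 = canonicalize(q_start - 1, L)
    wraps = ls5 > hs5
    return DeletionSpan(ls5, hs5, wraps)


def left_align(span: DeletionSpan, ref: CircularReference) -> DeletionSpan:
    """Shift a junction to its leftmost equivalent representation.

    (ls5 - 1, hs5 - 1) removes the same sequence whenever the base just
    left of the deletion equals the last deleted base; iterate until that
    fails. Junctions inside a perfect repeat spanning the whole circle are
    degenerate and returned after one full revolution.
    """
    L = ref.length
    ls5, hs5 = span.ls5, span.hs5
    for _ in range(L):
        if ref.base(ls5 - 1) != ref.base(hs5):
            break
        ls5 = ls5 - 1 if ls5 > 1 else L
        hs5 = hs5 - 1 if hs5 > 1 else L
    wraps = ls5 > hs5
    return DeletionSpan(ls5, hs5, wraps)


# ---------------------------------------------------------------------------
# FASTQ streaming and quality filtering
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def read_pairs(fq1: str | Path, fq2: str | Path) -> Iterator[tuple[str, tuple[str, str], tuple[str, str]]]:
    """Yield (id, (seq1, qual1), (seq2, qual2)) from paired FASTQ files."""
    with _open_text(fq1) as h1, _open_text(fq2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            yield t1.split()[0], (s1, q1), (s2, q2)


def mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.frombuffer(qual.encode(), dtype=np.uint8).mean()) - 33.0


def quality_filter(pairs: Iterable[tuple[str, tuple[str, str], tuple[str, str]]],
                   min_mean_q: float = 20.0) -> Iterator[tuple[str, tuple[str, str], tuple[str, str]]]:
    """Drop a pair when either mate's mean Phred score is below threshold."""
    for rid, m1, m2 in pairs:
        if mean_quality(m1[1]) >= min_mean_q and mean_quality(m2[1]) >= min_mean_q:
            yield rid, m1, m2


# ---------------------------------------------------------------------------
# mate reconciliation
# ---------------------------------------------------------------------------


def _circ_covers(anchor: Anchor, w_lo: int, w_hi: int, L: int) -> bool:
    """Does a contiguous anchor cover window [w_lo, w_hi] circularly?

    Window coordinates are 1-based on [1, L] (w_lo may exceed w_hi only via
    callers normalizing first); anchor coordinates live on the doubled axis.
    """
    w_lo = ((w_lo - 1) % L) + 1
    w_hi = ((w_hi - 1) % L) + 1
    if w_lo > w_hi:  # window itself crosses the origin
        w_hi += L
    for t in (0, L):
        if anchor.ref_start <= w_lo + t and w_hi + t <= anchor.ref_end:
            return True
    return False


def mate_contradicts(span: DeletionSpan, other: AlignmentResult | None,
                     L: int, margin: int = 20) -> bool:
    """True when the other mate contiguously spans a junction terminus.

    A contiguous alignment covering ``margin`` bases on both sides of a
    deleted terminus demonstrates the molecule retained that sequence; the
    margin guards against contiguous alignments that merely extend into the
    deleted region through junction microhomology.
    """
    if other is None or other.kind != "contig":
        return False
    a = other.anchors[0]
    return _circ_covers(a, span.ls5 - margin, span.ls5 + margin - 1, L) or \
        _circ_covers(a, span.hs5 - margin + 1, span.hs5 + margin, L)


def reconcile_mates(
    junctions: list[tuple[int, DeletionSpan]],
    results: tuple[AlignmentResult | None, AlignmentResult | None],
    L: int,
    margin: int = 20,
) -> list[DeletionSpan]:
    """Per-pair junction reconciliation.

    ``junctions`` lists (mate_index, span) calls from this pair; a call
    survives unless the *other* mate contiguously spans its junction locus.
    Each surviving supporting read contributes one count.
    """
    kept = []
    for mate_idx, span in junctions:
        other = results[1 - mate_idx]
        if not mate_contradicts(span, other, L, margin):
            kept.append(span)
    return kept


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


@dataclass
class DeletionCatalog:
    """Per-sample deletion calls plus the depth profile and read totals.

    ``calls`` columns: ls5, hs5, length, x_i, wraps, possible_insertion.
    ``r_t`` is the effective number of mapped reads, ``L_r`` the mean
    aligned read length.
    """

    calls: pd.DataFrame
    depth: np.ndarray
    r_t: int
    L_r: float
    sample_id: str = ""
    min_anchor: int = 20
    stats: dict = field(default_factory=dict)

    @property
    def total_junction_reads(self) -> int:
        return int(self.calls["x_i"].sum()) if len(self.calls) else 0

    def write(self, outdir: str | Path, prefix: str = "catalog") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.calls.to_csv(outdir / f"{prefix}_calls.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"pos": np.arange(1, len(self.depth) + 1), "depth": self.depth}
        ).to_csv(outdir / f"{prefix}_depth.tsv", sep="\t", index=False)
        summary = {
            "sample_id": self.sample_id,
            "r_t": int(self.r_t),
            "L_r": float(self.L_r),
            "min_anchor": int(self.min_anchor),
            **{k: (int(v) if isinstance(v, (int, np.integer)) else v)
               for k, v in self.stats.items()},
        }
        (outdir / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "catalog") -> "DeletionCatalog":
        outdir = Path(outdir)
        calls = pd.read_csv(outdir / f"{prefix}_calls.tsv", sep="\t")
        depth = pd.read_csv(outdir / f"{prefix}_depth.tsv", sep="\t")["depth"].to_numpy(float)
        summary = json.loads((outdir / f"{prefix}_summary.json").read_text())
        return cls(
            calls=calls,
            depth=depth,
            r_t=int(summary["r_t"]),
            L_r=float(summary["L_r"]),
            sample_id=summary.get("sample_id", ""),
            min_anchor=int(summary.get("min_anchor", 20)),
        )


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["ls5", "hs5", "length", "x_i", "wraps", "possible_insertion"]
    ).astype({"ls5": int, "hs5": int, "length": int, "x_i": int,
              "wraps": bool, "possible_insertion": bool})


def _add_depth(depth: np.ndarray, a: Anchor, L: int) -> None:
    s0 = (a.ref_start - 1) % L
    n = a.length
    if s0 + n <= L:
        depth[s0 : s0 + n] += 1
    else:
        depth[s0:] += 1
        depth[: (s0 + n) - L] += 1


def build_catalog(
    fq1: str | Path,
    fq2: str | Path,
    ref: CircularReference,
    sample_id: str = "",
    min_mean_q: float = 20.0,
    k: int = 16,
    min_anchor: int = 20,
    max_mismatch: int = 2,
    aligner: ReadAligner | None = None,
) -> DeletionCatalog:
    """Run the full detection chain on one paired-end FASTQ sample.

    quality filter -> split alignment -> junction calling -> left
    alignment -> mate reconciliation, accumulating the per-position depth
    profile and the read totals that the frequency math consumes.
    """
    if aligner is None:
        aligner = ReadAligner(ref, k=k, min_anchor=min_anchor, max_mismatch=max_mismatch)
    L = ref.length
    depth = np.zeros(L, dtype=np.int64)
    counts: dict[tuple[int, int, bool], int] = {}
    r_t = 0
    aligned_bases = 0
    n_pairs = n_kept = n_suppressed = 0

    for rid, (s1, _q1), (s2, _q2) in quality_filter(read_pairs(fq1, fq2), min_mean_q):
        n_pairs += 1
        results = (aligner.align(s1), aligner.align(s2))
        junctions: list[tuple[int, DeletionSpan]] = []
        for idx, res in enumerate(results):
            if res is None:
                continue
            r_t += 1
            aligned_bases += sum(a.length for a in res.anchors)
            for a in res.anchors:
                _add_depth(depth, a, L)
            if res.kind == "split":
                try:
                    span = left_align(call_junction(res.split, ref), ref)
                except AmbiguousJunctionError:
                    continue
                junctions.append((idx, span))
        kept = reconcile_mates(junctions, results, L, margin=min_anchor)
        n_suppressed += len(junctions) - len(kept)
        for span in kept:
            key = (span.ls5, span.hs5, span.wraps)
            counts[key] = counts.get(key, 0) + 1
            n_kept += 1

    if counts:
        rows = []
        for (ls5, hs5, wraps), x in sorted(counts.items()):
            length = span_length(DeletionSpan(ls5, hs5, wraps), ref)
            rows.append((ls5, hs5, length, x, wraps, length > POSSIBLE_INSERTION_BP))
        calls = pd.DataFrame(
            rows, columns=["ls5", "hs5", "length", "x_i", "wraps", "possible_insertion"]
        )
    else:
        calls = _empty_calls()

    L_r = aligned_bases / r_t if r_t else 0.0
    return DeletionCatalog(
        calls=calls,
        depth=depth,
        r_t=r_t,
        L_r=L_r,
        sample_id=sample_id,
        min_anchor=min_anchor,
        stats={
            "pairs_after_quality_filter": n_pairs,
            "junction_reads_kept": n_kept,
            "junction_reads_suppressed": n_suppressed,
        },
    )


def deletion_load(catalog: DeletionCatalog) -> dict[str, float]:
    """Deletion load: junction reads per Mbp mapped, plus the per-read ratio."""
    if catalog.r_t <= 0:
        raise UndefinedLoadError("no mapped reads; deletion load undefined")
    total_x = catalog.total_junction_reads
    per_mbp = total_x / (catalog.r_t * catalog.L_r) * 1e6
    return {"per_mbp": per_mbp, "per_read": total_x / catalog.r_t}
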