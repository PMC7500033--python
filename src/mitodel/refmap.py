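"""Circular reference genome, coordinate arithmetic, and the feature map.

Everything downstream works in 1-based coordinates that are inclusive at
both ends. A deletion is identified by the positions of the last missing
bases in the light-strand 5' direction (``ls5``) and the heavy-strand 5'
direction (``hs5``); for the canonical human mtDNA "common deletion" that
convention gives (8471, 13447) and a span of 4977 bp.

Positions on the tandem-doubled reference used by the split-read aligner
are folded back onto ``[1, L]`` with :func:`canonicalize`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

FEATURE_CATEGORIES = {
    "origin",
    "control_region",
    "gene",
    "tRNA",
    "rRNA",
    "promoter",
    "terminator",
    "arc",
}


class CoordinateError(ValueError):
    """A position or span falls outside the circular coordinate system."""


@dataclass(frozen=True)
class CircularReference:
    """A circular genome: name, uppercase sequence, and its length."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("reference sequence must be non-empty")
        if set(seq) - VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise ValueError(f"non-DNA characters in reference: {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at a 1-based position; positions wrap circularly."""
        return self.sequence[(pos - 1) % self.length]

    def fetch(self, start: int, end: int) -> str:
        """Inclusive circular slice. ``start > end`` wraps through position 1."""
        L = self.length
        start = canonicalize(((start - 1) % L) + 1, L)
        end = canonicalize(((end - 1) % L) + 1, L)
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def doubled(self) -> str:
        """Two tandem copies, used to align reads across the origin."""
        return self.sequence + self.sequence

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CircularReference":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected a single-record FASTA, found {len(records)} in {path}"
            )
        rec = records[0]
        return cls(name=rec.id, sequence=str(rec.seq).upper())

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.name, description="")
        with open(path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")
        # SeqIO wraps at 60 by default; width kept for interface symmetry
        _ = width


def canonicalize(pos: int, length: int) -> int:
    """Fold a position on the doubled reference back onto ``[1, length]``."""
    if not 1 <= pos <= 2 * length:
        raise CoordinateError(
            f"position {pos} outside doubled reference [1, {2 * length}]"
        )
    return ((pos - 1) % length) + 1


@dataclass(frozen=True)
class DeletionSpan:
    """A deletion identified by its LS5'/HS5' last-missing-base positions.

    ``wraps`` marks spans whose deleted arc crosses reference position 1;
    those are the only spans allowed to have ``ls5 > hs5``.
    """

    ls5: int
    hs5: int
    wraps: bool = False

    def validate(self, length: int) -> None:
        if not (1 <= self.ls5 <= length and 1 <= self.hs5 <= length):
            raise CoordinateError(
                f"span ({self.ls5}, {self.hs5}) outside [1, {length}]"
            )
        if not self.wraps and self.ls5 > self.hs5:
            raise CoordinateError(
                f"non-wrapping span requires ls5 <= hs5, got ({self.ls5}, {self.hs5})"
            )

    def covers(self, pos: int) -> bool:
        """True if position ``pos`` lies in the deleted arc."""
        if self.wraps:
            return pos >= self.ls5 or pos <= self.hs5
        return self.ls5 <= pos <= self.hs5


def span_length(span: DeletionSpan, ref: CircularReference | int) -> int:
    """Number of deleted bases, inclusive at both termini.

    (8471, 13447) -> 4977 bp, the human common deletion.
    """
    L = ref if isinstance(ref, int) else ref.length
    span.validate(L)
    if span.wraps and span.ls5 > span.hs5:
        n = L - span.ls5 + span.hs5 + 1
    else:
        n = span.hs5 - span.ls5 + 1
    if not 1 <= n <= L - 1:
        raise CoordinateError(f"span length {n} outside [1, {L - 1}]")
    return n


@dataclass(frozen=True)
class Feature:
    name: str
    start: int
    end: int
    category: str


@dataclass
class FeatureMap:
    """Named features on the circle plus the two putative replication origins.

    ``ori_l`` is the light-strand origin and ``seven_s3`` the 3' terminus of
    the 7S DNA (heavy-strand origin region); the arc between them running
    through the bulk of the coding genes is the major arc, the arc through
    the control region (position 1) is the minor arc.
    """

    features: list[Feature] = field(default_factory=list)
    ori_l: int = 5780
    seven_s3: int = 16070

    def by_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"unknown feature: {name!r}")

    def positions(self, name: str, length: int) -> np.ndarray:
        """All 1-based positions of a feature, unwrapped circularly."""
        f = self.get(name)
        if f.start <= f.end:
            return np.arange(f.start, f.end + 1)
        return np.concatenate(
            [np.arange(f.start, length + 1), np.arange(1, f.end + 1)]
        )

    @classmethod
    def from_tsv(cls, path: str | Path, ori_l: int | None = None,
                 seven_s3: int | None = None) -> "FeatureMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        feats = [
            Feature(str(r["name"]), int(r["start"]), int(r["end"]), str(r["category"]))
            for _, r in df.iterrows()
        ]
        fmap = cls(features=feats)
        origins = [f for f in feats if f.category == "origin"]
        for f in origins:
            if f.name.lower() in ("oril", "ori_l"):
                fmap.ori_l = (f.start + f.end) // 2
            if f.name.lower() in ("7s3", "seven_s3", "7s-3", "7s_3prime"):
                fmap.seven_s3 = (f.start + f.end) // 2
        if ori_l is not None:
            fmap.ori_l = ori_l
        if seven_s3 is not None:
            fmap.seven_s3 = seven_s3
        return fmap

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(f.name, f.start, f.end, f.category) for f in self.features],
            columns=["name", "start", "end", "category"],
        )
        df.to_csv(path, sep="\t", index=False)


def arc_class(span: DeletionSpan, fmap: FeatureMap, ref: CircularReference | int) -> str:
    """Classify a deletion by which arc of the circle it removes.

    Returns one of ``minor``, ``major``, ``origin_spanning``,
    ``control_spanning``. Spans covering either replication origin are
    origin_spanning; spans crossing position 1 without touching an origin
    are control_spanning; the rest sit strictly inside one arc.
    """
    L = ref if isinstance(ref, int) else ref.length
    span.validate(L)
    if span.covers(fmap.ori_l) or span.covers(fmap.seven_s3):
        return "origin_spanning"
    if span.wraps or span.covers(1):
        return "control_spanning"
    # major arc runs from ori_l up to seven_s3 (no wrap in default layout)
    lo, hi = sorted((fmap.ori_l, fmap.seven_s3))
    if lo < span.ls5 and span.hs5 < hi:
        return "major"
    return "minor"


# ---------------------------------------------------------------------------
# Bundled synthetic reference
# ---------------------------------------------------------------------------

#: length of the human mtDNA reference build this package targets
DEFAULT_LENGTH = 16571

# 13-bp direct repeat flanking the human mtDNA common deletion
_COMMON_REPEAT = "ACCTCCCTCACCA"
_COMMON_LS5 = 8471
_COMMON_HS5 = 13447


def synthetic_reference(seed: int = 1906) -> CircularReference:
    """Build the bundled synthetic stand-in for the human mtDNA reference.

    The real reference build cannot be redistributed here, so tests and the
    worked examples run against a deterministic synthetic 16,571-bp circle
    that reproduces the sequence properties the analyses depend on:

    * the 13-bp direct repeat flanking the (8471, 13447) common deletion,
      placed so that the left-aligned junction carries 13 bp of terminal
      microhomology;
    * homopolymeric C-runs at positions 303 and 16,184 emulating the
      polymorphic control-region poly-C tracts;
    * an otherwise i.i.d. uniform base composition (no long accidental
      repeats at desk scale).
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=DEFAULT_LENGTH)

    def plant(start_1based: int, s: str) -> None:
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        seq[start_1based - 1 : start_1based - 1 + len(arr)] = arr

    # direct repeat copies: first deleted bases and first retained bases
    plant(_COMMON_LS5, _COMMON_REPEAT)
    plant(_COMMON_HS5 + 1, _COMMON_REPEAT)
    # break the repeat at both ends so TMH is exactly 13 and the
    # representation (8471, 13447) is already left-aligned
    plant(_COMMON_LS5 - 1, "G")
    plant(_COMMON_HS5, "T")
    plant(_COMMON_LS5 + 13, "A")
    plant(_COMMON_HS5 + 14, "C")
    # control-region poly-C tracts
    plant(303, "C" * 7)
    plant(302, "T")
    plant(310, "T")
    plant(16184, "C" * 9)
    plant(16183, "A")
    plant(16193, "A")
    return CircularReference(name="synthetic_mtDNA", sequence=seq.tobytes().decode())


def default_feature_map() -> FeatureMap:
    """Feature annotation for the bundled reference.

    Gene/tRNA/rRNA intervals follow the standard human mtDNA gene order and
    approximate coordinates; the two origin positions default to 5780 (oriL)
    and 16,070 (7S-3'), the terminus-ridge positions used throughout.
    """
    rows = [
        ("control_region", 16024, 576, "control_region"),
        ("7S3", 16070, 16070, "origin"),
        ("oriL", 5780, 5780, "origin"),
        ("PH1", 561, 561, "promoter"),
        ("PL", 407, 407, "promoter"),
        ("TRNF", 577, 647, "tRNA"),
        ("RNR1", 648, 1601, "rRNA"),
        ("TRNV", 1602, 1670, "tRNA"),
        ("RNR2", 1671, 3229, "rRNA"),
        ("TRNL1", 3230, 3304, "tRNA"),
        ("ND1", 3307, 4262, "gene"),
        ("TRNI", 4263, 4331, "tRNA"),
        ("TRNQ", 4329, 4400, "tRNA"),
        ("TRNM", 4402, 4469, "tRNA"),
        ("ND2", 4470, 5511, "gene"),
        ("TRNW", 5512, 5579, "tRNA"),
        ("TRNA", 5587, 5655, "tRNA"),
        ("TRNN", 5657, 5729, "tRNA"),
        ("TRNC", 5761, 5826, "tRNA"),
        ("TRNY", 5826, 5891, "tRNA"),
        ("CO1", 5904, 7445, "gene"),
        ("TRNS1", 7446, 7514, "tRNA"),
        ("TRND", 7518, 7585, "tRNA"),
        ("CO2", 7586, 8269, "gene"),
        ("TRNK", 8295, 8364, "tRNA"),
        ("ATP8", 8366, 8572, "gene"),
        ("ATP6", 8527, 9207, "gene"),
        ("CO3", 9207, 9990, "gene"),
        ("TRNG", 9991, 10058, "tRNA"),
        ("ND3", 10059, 10404, "gene"),
        ("TRNR", 10405, 10469, "tRNA"),
        ("ND4L", 10470, 10766, "gene"),
        ("ND4", 10760, 12137, "gene"),
        ("TRNH", 12138, 12206, "tRNA"),
        ("TRNS2", 12207, 12265, "tRNA"),
        ("TRNL2", 12266, 12336, "tRNA"),
        ("ND5", 12337, 14148, "gene"),
        ("ND6", 14149, 14673, "gene"),
        ("TRNE", 14674, 14742, "tRNA"),
        ("CYTB", 14747, 15887, "gene"),
        ("TRNT", 15888, 15953, "tRNA"),
        ("TRNP", 15956, 16023, "tRNA"),
        ("TERM", 3229, 3256, "terminator"),
        ("major_arc", 5781, 16069, "arc"),
        ("minor_arc", 16071, 5779, "arc"),
    ]
    feats = [Feature(n, s, e, c) for n, s, e, c in rows]
    return FeatureMap(features=feats, ori_l=5780, seven_s3=16070)


def _data_path(fname: str) -> Path:
    return Path(importlib.resources.files("mitodel").joinpath("data", fname))


def default_reference() -> CircularReference:
    """Load the bundled synthetic reference FASTA (writing it on first use)."""
    path = _data_path("synthetic_mtdna.fa")
    if path.exists():
        return CircularReference.from_fasta(path)
    ref = synthetic_reference()
    try:
        ref.to_fasta(path)
    except OSError:
        pass
    return ref


def load_default() -> tuple[CircularReference, FeatureMap]:
    return default_reference(), default_feature_map()
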