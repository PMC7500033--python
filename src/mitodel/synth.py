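"""Synthetic populations of circular genomes and paired-end read emission.

The generator embodies the sampling assumptions behind the frequency
math: a population of molecules (wild type plus deletant species at
specified fractions, optionally linear spike-in molecules with known
junctions), fragments drawn with probability proportional to molecule
abundance times molecule length, fragment start positions uniform on each
(circular) molecule, and paired reads taken from the fragment ends with
per-base substitution errors. Every junction-spanning read is recorded in
a truth table so downstream counts can be checked against ground truth.

Two error profiles exist: the default ``strict`` profile keeps the 5 bp
around a junction error-free inside junction-spanning reads, so pipeline
logic can be tested in isolation from error modeling; the ``realistic``
profile applies errors everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refmap import CircularReference, DeletionSpan, span_length
from .splitread import DeletionCatalog, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PopulationSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeIn:
    """A linear plasmid-like molecule carrying an artificial junction:
    ``flank`` reference bases on each side of the deletion span."""

    span: DeletionSpan
    frequency: float
    flank: int = 2000


@dataclass
class PopulationSpec:
    ref: CircularReference
    species: list[tuple[DeletionSpan | None, float]] = field(default_factory=list)
    spikeins: list[SpikeIn] = field(default_factory=list)
    error_rate: float = 0.001
    read_length: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 60.0
    depth: float = 2000.0
    seed: int = 0
    profile: str = "strict"          # "strict" | "realistic"
    junction_clean_bp: int = 5

    def validate(self) -> None:
        total = sum(f for _s, f in self.species) + sum(s.frequency for s in self.spikeins)
        if any(f < 0 for _s, f in self.species):
            raise PopulationSpecError("negative species frequency")
        if total > 1.0 + 1e-12:
            raise PopulationSpecError(f"frequencies sum to {total} > 1")
        if self.read_length < 40:
            raise PopulationSpecError("read length must allow two anchors")


@dataclass
class Molecule:
    name: str
    sequence: str
    weight: float
    circular: bool
    span: DeletionSpan | None = None
    junction_offset: int | None = None  # 0-based: junction sits before this index

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_population(spec: PopulationSpec) -> list[Molecule]:
    """Expand a spec into concrete molecules with abundance weights.

    The wild type takes the leftover frequency mass. A deletant molecule
    is the reference minus its span, written starting at the first
    retained base after the deletion so the junction falls at the
    (circular) string boundary.
    """
    spec.validate()
    ref = spec.ref
    L = ref.length
    mols: list[Molecule] = []
    used = 0.0
    for j, (span, freq) in enumerate(spec.species):
        used += freq
        if span is None:
            continue
        span.validate(L)
        seq = ref.fetch(span.hs5 + 1, span.ls5 - 1)
        assert len(seq) == L - span_length(span, ref)
        mols.append(Molecule(
            name=f"del_{span.ls5}_{span.hs5}", sequence=seq, weight=freq,
            circular=True, span=span, junction_offset=0))
    for s in spec.spikeins:
        used += s.frequency
        s.span.validate(L)
        left = ref.fetch(s.span.ls5 - s.flank, s.span.ls5 - 1)
        right = ref.fetch(s.span.hs5 + 1, s.span.hs5 + s.flank)
        mols.append(Molecule(
            name=f"spike_{s.span.ls5}_{s.span.hs5}", sequence=left + right,
            weight=s.frequency, circular=False, span=s.span,
            junction_offset=len(left)))
    wt_weight = 1.0 - used
    none_weight = sum(f for sp, f in spec.species if sp is None)
    mols.insert(0, Molecule(name="wildtype", sequence=ref.sequence,
                            weight=wt_weight + none_weight, circular=True))
    total = sum(m.weight for m in mols)
    if not np.isclose(total, 1.0):
        raise PopulationSpecError(f"weights sum to {total}")
    return mols


def _apply_errors(seq_arr: np.ndarray, rng: np.random.Generator,
                  error_rate: float, protect: tuple[int, int] | None) -> int:
    """Substitute bases in place at ``error_rate``; positions inside the
    ``protect`` interval (half-open) are left untouched. Returns the number
    of substitutions."""
    if error_rate <= 0:
        return 0
    hit = np.flatnonzero(rng.random(len(seq_arr)) < error_rate)
    if protect is not None and len(hit):
        hit = hit[(hit < protect[0]) | (hit >= protect[1])]
    for i in hit:
        choices = _BASES[_BASES != seq_arr[i]]
        seq_arr[i] = rng.choice(choices)
    return len(hit)


def generate_reads(spec: PopulationSpec, fq1_path: str | Path,
                   fq2_path: str | Path) -> pd.DataFrame:
    """Emit paired FASTQ files and return the junction truth table.

    Truth rows record, for every emitted read that crosses a deletion
    junction: read id, mate, the species span, and the flank lengths the
    read has on each side of the junction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mols = build_population(spec)
    L = spec.ref.length
    rl = spec.read_length
    n_pairs = int(round(spec.depth * L / (2 * rl)))

    w = np.array([m.weight * m.length for m in mols], dtype=float)
    w /= w.sum()
    which = rng.choice(len(mols), size=n_pairs, p=w)

    qual = "I" * rl
    truth_rows: list[tuple] = []
    resampled = 0

    with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
        for i in range(n_pairs):
            m = mols[which[i]]
            M = m.length
            flen = int(round(rng.normal(spec.fragment_mean, spec.fragment_sd)))
            flen = max(rl, flen)
            if flen > M:
                resampled += 1
                flen = M
            if m.circular:
                s = int(rng.integers(0, M))
                frag = (m.sequence + m.sequence)[s : s + flen]
                # junction of a deletant sits at the molecule string origin
                joff = (M - s) if (m.junction_offset is not None and s + flen > M) else None
                if m.junction_offset is not None and s == 0:
                    joff = None  # junction at fragment start: nothing crosses it
            else:
                s = int(rng.integers(0, M - flen + 1))
                frag = m.sequence[s : s + flen]
                j = m.junction_offset
                joff = (j - s) if (j is not None and s < j < s + flen) else None

            r1 = np.frombuffer(frag[:rl].encode(), dtype=np.uint8).copy()
            r2 = np.frombuffer(revcomp(frag[-rl:]).encode(), dtype=np.uint8).copy()

            # junction offsets within each mate (None when the mate does
            # not cross it)
            j1 = joff if (joff is not None and 0 < joff < rl) else None
            j2 = None
            if joff is not None:
                off2 = joff - (flen - rl)   # offset within the fragment tail
                if 0 < off2 < rl:
                    j2 = rl - off2          # position after revcomp

            clean = spec.junction_clean_bp if spec.profile == "strict" else 0
            _apply_errors(r1, rng, spec.error_rate,
                          (max(0, j1 - clean), min(rl, j1 + clean)) if j1 is not None and clean else None)
            _apply_errors(r2, rng, spec.error_rate,
                          (max(0, j2 - clean), min(rl, j2 + clean)) if j2 is not None and clean else None)

            rid = f"frag{i}"
            f1.write(f"@{rid}/1\n{r1.tobytes().decode()}\n+\n{qual}\n")
            f2.write(f"@{rid}/2\n{r2.tobytes().decode()}\n+\n{qual}\n")

            if m.span is not None:
                if j1 is not None:
                    truth_rows.append((rid, 1, m.span.ls5, m.span.hs5, j1, rl - j1))
                if j2 is not None:
                    truth_rows.append((rid, 2, m.span.ls5, m.span.hs5, rl - j2, j2))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "mate", "ls5", "hs5", "left_flank", "right_flank"])
    truth.attrs["n_pairs"] = n_pairs
    truth.attrs["resampled_fragments"] = resampled
    return truth


def make_control(ref: CircularReference, seed: int = 0,
                 n_background: int = 25, depth: float = 500.0,
                 read_length: float = 150.0, min_anchor: int = 20,
                 max_span: int = 99, max_frequency: float = 1e-5
                 ) -> tuple[DeletionCatalog, np.ndarray]:
    """An idealized control sample: uniform depth plus a sparse background
    of small, low-frequency deletions (emulating the short-indel artifact
    load of a clean cultured-cell control).

    Returns the catalog and its depth profile. Junction read counts are
    the expected counts under the depth model, so subtracting a control
    from itself floors to zero exactly.
    """
    rng = np.random.default_rng(seed)
    L = ref.length
    depth_profile = np.full(L, depth)
    r_t = int(round(depth * L / read_length))
    usable = (read_length - 2 * min_anchor + 1) / read_length

    rows = []
    for _ in range(n_background):
        length = int(rng.integers(1, max_span + 1))
        ls5 = int(rng.integers(1, L - length))
        span = DeletionSpan(ls5, ls5 + length - 1)
        freq = float(10 ** rng.uniform(-6, np.log10(max_frequency)))
        # idealized control: fractional expected junction-read count
        x = freq * depth * usable
        rows.append((span.ls5, span.hs5, length, x, False, False))
    if rows:
        calls = pd.DataFrame(
            rows, columns=["ls5", "hs5", "length", "x_i", "wraps",
                           "possible_insertion"]
        ).groupby(["ls5", "hs5", "length", "wraps", "possible_insertion"],
                  as_index=False).sum()[
            ["ls5", "hs5", "length", "x_i", "wraps", "possible_insertion"]]
    else:
        calls = pd.DataFrame(columns=["ls5", "hs5", "length", "x_i", "wraps",
                                      "possible_insertion"])
    catalog = DeletionCatalog(
        calls=calls, depth=depth_profile.astype(np.int64), r_t=r_t,
        L_r=read_length, sample_id=f"control_seed{seed}",
        min_anchor=min_anchor, stats={"synthetic_control": True})
    return catalog, depth_profile
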