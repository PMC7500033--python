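"""From raw junction counts to species frequencies and ablation levels.

The central conversion assumes sequencing depth is proportional to
population fraction and that each molecule carries at most one deletion.
With ``x_i`` junction-supporting reads, mappability factor ``delta_i``,
deletant molecule length ``L_i = L_u - deleted bases``, mean read length
``L_r`` and ``r_t`` total mapped reads, the population fraction of
deletant species ``i`` is

    f_i = L_u * delta_i * x_i /
          (L_r * r_t - sum_j L_j * delta_j * x_j + sum_j L_u * delta_j * x_j)

with the cheap upper bound  f_i <= L_u * delta_i * x_i / (L_r * r_t).

The raw split-read count systematically undercounts junction-crossing
reads, because a read needs at least ``min_anchor`` aligned bases on both
sides of the junction to be callable: only ``L_r - 2*min_anchor + 1`` of
the ``L_r`` start positions overlapping the junction are usable. The
conversion therefore rescales counts by ``L_r / (L_r - 2*min_anchor + 1)``
before treating them as junction depth (``anchor_correction``).

Ablation is the deleted fraction of the total mtDNA sequence pool:
``a_biopsy = sum_i f_i * (L_u - L_i) / L_u``, the area above the
remaining-fraction curve; ablation at symptom onset is projected linearly
through zero at birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refmap import CircularReference, DeletionSpan, FeatureMap
from .splitread import DeletionCatalog

DELTA_CAP = 10.0


class InfeasibleFrequencyError(ValueError):
    """Eq-denominator nonpositive: inputs violate the depth model."""


@dataclass
class FrequencyTable:
    """Per-deletion frequencies plus the sample-level scalars.

    ``rows`` columns: ls5, hs5, wraps, length, x_i, delta_i, L_i, f_i,
    f_i_bg, bound, low_mappability. ``f_u`` is the undeleted fraction;
    ``f_u + sum(f_i) == 1``.
    """

    rows: pd.DataFrame
    L_u: int
    L_r: float
    r_t: int
    f_u: float
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def copy(self) -> "FrequencyTable":
        return FrequencyTable(self.rows.copy(), self.L_u, self.L_r, self.r_t,
                              self.f_u, self.sample_id, dict(self.meta))

    def write(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def mappability_factor(control_depth: np.ndarray, span: DeletionSpan,
                       cap: float = DELTA_CAP) -> tuple[float, bool]:
    """delta_i = median control depth / mean depth at the two junction
    positions. Returns (delta, low_mappability_flag); zero depth at both
    positions yields the capped value rather than infinity."""
    med = float(np.median(control_depth))
    if med <= 0:
        raise ValueError("control depth profile has nonpositive median")
    pair = (float(control_depth[span.ls5 - 1]) + float(control_depth[span.hs5 - 1])) / 2.0
    if pair <= 0:
        return cap, True
    delta = med / pair
    if delta > cap:
        return cap, True
    return delta, False


def _effective_counts(x: np.ndarray, L_r: float, min_anchor: int,
                      anchor_correction: bool,
                      tmh: np.ndarray | None = None) -> np.ndarray:
    """Rescale raw junction counts to junction-crossing depth.

    Of the ``L_r`` read start positions overlapping a junction, only those
    leaving ``min_anchor`` bases on both sides are callable; junction
    microhomology widens the window by ``tmh`` positions because the split
    point may be placed anywhere inside the homology run.
    """
    if not anchor_correction:
        return x.astype(float)
    usable = L_r - 2 * min_anchor + 1 + (tmh if tmh is not None else 0)
    if np.any(usable <= 0) if isinstance(usable, np.ndarray) else usable <= 0:
        raise ValueError("read length too short for the anchor requirement")
    return x * (L_r / usable)


def frequencies(catalog: DeletionCatalog,
                control_depth: np.ndarray | None = None,
                L_u: int | None = None,
                anchor_correction: bool = True,
                ref: "CircularReference | None" = None,
                delta_cap: float = DELTA_CAP) -> FrequencyTable:
    """Convert a deletion catalog into per-species population fractions.

    Without a control depth profile every junction gets ``delta_i = 1``
    (recorded in ``meta``). Passing ``ref`` lets the anchor correction
    account for junction microhomology per row.
    """
    if catalog.r_t <= 0 or catalog.L_r <= 0:
        raise InfeasibleFrequencyError("catalog has no mapped reads")
    if L_u is None:
        L_u = len(catalog.depth)
    calls = catalog.calls
    if len(calls) == 0:
        rows = pd.DataFrame(columns=[
            "ls5", "hs5", "wraps", "length", "x_i", "delta_i", "L_i",
            "f_i", "f_i_bg", "bound", "low_mappability"])
        return FrequencyTable(rows, L_u, catalog.L_r, catalog.r_t, 1.0,
                              catalog.sample_id,
                              {"delta_source": "none" if control_depth is None else "control"})

    deltas = np.ones(len(calls))
    low = np.zeros(len(calls), dtype=bool)
    if control_depth is not None:
        for j, r in enumerate(calls.itertuples(index=False)):
            deltas[j], low[j] = mappability_factor(
                control_depth, DeletionSpan(int(r.ls5), int(r.hs5), bool(r.wraps)),
                cap=delta_cap)

    x = calls["x_i"].to_numpy(float)
    tmh = None
    if ref is not None and anchor_correction:
        from .context import tmh_length  # local import: avoid module cycle

        tmh = np.array([
            tmh_length(DeletionSpan(int(r.ls5), int(r.hs5), bool(r.wraps)), ref)
            for r in calls.itertuples(index=False)], dtype=float)
    x_eff = _effective_counts(x, catalog.L_r, catalog.min_anchor,
                              anchor_correction, tmh)
    length = calls["length"].to_numpy(int)
    L_i = L_u - length
    dx = deltas * x_eff
    denom = catalog.L_r * catalog.r_t - float(np.sum(L_i * dx)) + float(np.sum(L_u * dx))
    if denom <= 0:
        raise InfeasibleFrequencyError(f"frequency denominator {denom} <= 0")
    f_i = L_u * dx / denom
    bound = L_u * dx / (catalog.L_r * catalog.r_t)
    f_u = 1.0 - float(np.sum(f_i))

    rows = pd.DataFrame({
        "ls5": calls["ls5"].to_numpy(int),
        "hs5": calls["hs5"].to_numpy(int),
        "wraps": calls["wraps"].to_numpy(bool),
        "length": length,
        "x_i": calls["x_i"].to_numpy(),
        "delta_i": deltas,
        "L_i": L_i,
        "f_i": f_i,
        "f_i_bg": f_i,
        "bound": bound,
        "low_mappability": low,
    })
    return FrequencyTable(rows, L_u, catalog.L_r, catalog.r_t, f_u,
                          catalog.sample_id,
                          {"delta_source": "none" if control_depth is None else "control",
                           "anchor_correction": anchor_correction})


def subtract_background(freqs: FrequencyTable,
                        controls: FrequencyTable | list[FrequencyTable] | None
                        ) -> FrequencyTable:
    """Subtract the mean control frequency per exact junction, floored at 0.

    Junctions are matched by their left-aligned (ls5, hs5) key; junctions
    absent from every control subtract nothing.
    """
    out = freqs.copy()
    if controls is None:
        return out
    if isinstance(controls, FrequencyTable):
        controls = [controls]
    if not controls:
        return out
    acc: dict[tuple[int, int], float] = {}
    for c in controls:
        for r in c.rows.itertuples(index=False):
            key = (int(r.ls5), int(r.hs5))
            acc[key] = acc.get(key, 0.0) + float(r.f_i)
    n = len(controls)
    bg = np.array([
        acc.get((int(l), int(h)), 0.0) / n
        for l, h in zip(out.rows["ls5"], out.rows["hs5"])
    ]) if len(out.rows) else np.array([])
    if len(out.rows):
        out.rows["f_i_bg"] = np.maximum(0.0, out.rows["f_i"].to_numpy(float) - bg)
    out.meta["background_subtracted"] = True
    return out


def ablation_at_biopsy(freqs: FrequencyTable) -> float:
    """Deleted fraction of the mtDNA sequence pool (area above the
    remaining-fraction curve)."""
    if len(freqs.rows) == 0:
        return 0.0
    f = freqs.rows["f_i_bg"].to_numpy(float)
    frac = (freqs.L_u - freqs.rows["L_i"].to_numpy(float)) / freqs.L_u
    return float(np.sum(f * frac))


def ablation_at_onset(a_biopsy: float, y_onset: float, y_biopsy: float) -> float:
    """Linear projection of ablation back to the age of symptom onset."""
    if y_biopsy <= 0:
        raise ValueError("biopsy age must be positive")
    if not 0 <= y_onset <= y_biopsy:
        raise ValueError("onset age must lie in [0, biopsy age]")
    return a_biopsy * y_onset / y_biopsy


def remaining_fraction_profile(freqs: FrequencyTable) -> np.ndarray:
    """Per-position retained fraction: 1 minus the summed frequency of
    deletions whose deleted arc covers the position."""
    L = freqs.L_u
    lost = np.zeros(L)
    for r in freqs.rows.itertuples(index=False):
        f = float(r.f_i_bg)
        if f == 0:
            continue
        ls5, hs5 = int(r.ls5), int(r.hs5)
        if bool(r.wraps) and ls5 > hs5:
            lost[ls5 - 1 :] += f
            lost[:hs5] += f
        else:
            lost[ls5 - 1 : hs5] += f
    return 1.0 - lost


def feature_ablation(freqs: FrequencyTable, fmap: FeatureMap,
                     feature_sets: dict[str, list[str]],
                     combine: bool = False) -> dict:
    """Ablation per named feature set, optionally multiplicatively combined.

    A deletion contributes its full background-subtracted frequency to a
    set when its deleted arc covers any base of any feature in the set.
    The combined deficiency treats sets as independent failure modes:
    ``1 - prod_s (1 - a_s)``.
    """
    L = freqs.L_u
    masks: dict[str, np.ndarray] = {}
    for set_name, feat_names in feature_sets.items():
        mask = np.zeros(L, dtype=bool)
        for fname in feat_names:
            mask[fmap.positions(fname, L) - 1] = True
        masks[set_name] = mask

    per_set = {name: 0.0 for name in feature_sets}
    for r in freqs.rows.itertuples(index=False):
        f = float(r.f_i_bg)
        if f == 0:
            continue
        ls5, hs5 = int(r.ls5), int(r.hs5)
        if bool(r.wraps) and ls5 > hs5:
            idx = np.r_[ls5 - 1 : L, 0:hs5]
        else:
            idx = np.arange(ls5 - 1, hs5)
        for name, mask in masks.items():
            if mask[idx].any():
                per_set[name] += f
    out: dict = {"per_set": per_set}
    if combine:
        combined = 1.0
        for a in per_set.values():
            combined *= 1.0 - a
        out["combined_deficiency"] = 1.0 - combined
    return out


def multi_fiber_boundaries(mass_mg: float, density_mg_per_ul: float,
                           fiber_area_um2: float,
                           nuclei_total: float | None = None,
                           mtdna_total: float | None = None) -> dict:
    """Geometry chain for the multi-fiber frequency boundary.

    A biopsy of given mass and density is idealized as a cube; the number
    of truncated fibers crossing one face is the face area divided by the
    mean fiber cross-section, and its reciprocal is the population
    frequency above which a deletion species must occupy several fibers.
    """
    if min(mass_mg, density_mg_per_ul, fiber_area_um2) <= 0:
        raise ValueError("all geometric inputs must be positive")
    volume_ul = mass_mg / density_mg_per_ul          # 1 uL == 1 mm^3
    side_mm = volume_ul ** (1.0 / 3.0)
    face_area_mm2 = side_mm ** 2
    fibers = face_area_mm2 * 1e6 / fiber_area_um2    # mm^2 -> um^2
    out = {
        "volume_ul": volume_ul,
        "cube_side_mm": side_mm,
        "face_area_mm2": face_area_mm2,
        "fibers": fibers,
        "multi_fiber_boundary": 1.0 / fibers,
    }
    if nuclei_total is not None:
        out["nuclei_per_fiber"] = nuclei_total / fibers
    if mtdna_total is not None:
        out["mtdna_per_fiber"] = mtdna_total / fibers
        out["single_copy_frequency"] = 1.0 / mtdna_total
    return out
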