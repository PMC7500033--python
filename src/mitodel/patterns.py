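"""Deletion-pattern summaries: binned breakpoint matrices, hierarchical
clustering, PCA, length spectra, and terminus histograms.

The pattern representation for comparing samples is an 80 x 80 matrix of
breakpoint fractions: the genome is divided into 80 equal bins and each
surviving deletion increments the (ls5-bin, hs5-bin) cell, after two
filters that remove likely short-read artifacts -- deletions whose termini
sit within 40 bp of each other, and deletions falling in a T-shaped
coordinate region associated with DNA-extraction damage. Matrices are
normalized to unit mass and compared by Euclidean distance
(complete-linkage clustering) or mean-centered PCA.

Terminus histograms sum deletion frequencies of the LS5' and HS5' termini
separately into 250-bp bins, excluding extensive-microhomology junctions
(TMH >= 10); on a log scale these show the characteristic "double bowtie"
around the two replication origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from sklearn.decomposition import PCA

from .quant import FrequencyTable

N_BINS = 80
MIN_SPAN_BP = 40

#: (ls5 interval, hs5 interval) pairs excluded as extraction artifacts
T_REGION = (
    ((1, 5700), (15949, 16156)),
    ((3107, 3314), (12000, 16156)),
)


@dataclass
class PatternMatrix:
    bins: np.ndarray               # (80, 80), fractions summing to 1 (or 0)
    sample_id: str = ""
    excluded_mass: float = 0.0
    meta: dict = field(default_factory=dict)

    def flat(self) -> np.ndarray:
        return self.bins.ravel()


@dataclass
class TerminusHistogram:
    ls5_freq: np.ndarray
    hs5_freq: np.ndarray
    bin_size: int = 250
    edges: np.ndarray | None = None


def genome_bin(pos: np.ndarray | int, L: int, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-width bin index; the last bin absorbs the remainder of
    ``L / n_bins``."""
    width = L // n_bins
    return np.minimum((np.asarray(pos) - 1) // width, n_bins - 1)


def _in_t_region(ls5: np.ndarray, hs5: np.ndarray) -> np.ndarray:
    out = np.zeros(len(ls5), dtype=bool)
    for (la, lb), (ha, hb) in T_REGION:
        out |= (ls5 >= la) & (ls5 <= lb) & (hs5 >= ha) & (hs5 <= hb)
    return out


def bin_breakpoints(table: pd.DataFrame, L: int, sample_id: str = "",
                    use: str = "counts", n_bins: int = N_BINS,
                    min_span: int = MIN_SPAN_BP,
                    t_region: tuple = T_REGION) -> PatternMatrix:
    """Filter and bin a sample's breakpoints into a normalized matrix.

    ``table`` needs ls5, hs5, length and x_i (and f_i_bg when
    ``use='frequencies'``) columns. ``use='counts'`` weights each junction
    by its supporting-read count; ``'unique'`` weights every junction
    equally; ``'frequencies'`` uses background-subtracted frequencies.
    """
    bins = np.zeros((n_bins, n_bins))
    if len(table) == 0:
        return PatternMatrix(bins, sample_id, 0.0, {"empty": True})
    ls5 = table["ls5"].to_numpy(int)
    hs5 = table["hs5"].to_numpy(int)
    length = table["length"].to_numpy(int)
    if use == "counts":
        w = table["x_i"].to_numpy(float)
    elif use == "unique":
        w = np.ones(len(table))
    elif use == "frequencies":
        w = table["f_i_bg"].to_numpy(float)
    else:
        raise ValueError(f"unknown weighting {use!r}")

    keep = length >= min_span
    tr = np.zeros(len(table), dtype=bool)
    for (la, lb), (ha, hb) in t_region:
        tr |= (ls5 >= la) & (ls5 <= lb) & (hs5 >= ha) & (hs5 <= hb)
    keep &= ~tr

    total = float(w.sum())
    kept_w = w[keep]
    if kept_w.sum() <= 0:
        return PatternMatrix(bins, sample_id, 1.0 if total > 0 else 0.0,
                             {"warning": "no breakpoints survive filtering"})
    li = genome_bin(ls5[keep], L, n_bins)
    hi = genome_bin(hs5[keep], L, n_bins)
    np.add.at(bins, (li, hi), kept_w)
    bins /= bins.sum()
    excluded = 1.0 - float(kept_w.sum()) / total if total > 0 else 0.0
    return PatternMatrix(bins, sample_id, excluded)


def cluster_samples(matrices: list[PatternMatrix]) -> dict:
    """Complete-linkage agglomerative clustering on Euclidean distances
    between flattened pattern vectors (samples sorted by id first, so the
    result is independent of input order)."""
    if len(matrices) < 2:
        raise ValueError("clustering needs at least 2 samples")
    ms = sorted(matrices, key=lambda m: m.sample_id)
    X = np.stack([m.flat() for m in ms])
    labels = [m.sample_id for m in ms]
    Z = linkage(X, method="complete", metric="euclidean")
    dg = dendrogram(Z, no_plot=True, labels=labels)
    return {
        "linkage": Z,
        "labels": labels,
        "leaf_order": dg["ivl"],
        "newick": _to_newick(Z, labels),
    }


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes: dict[int, tuple[str, float]] = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, h, _cnt) in enumerate(Z):
        sa, ha = nodes[int(a)]
        sb, hb = nodes[int(b)]
        rep = f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})"
        nodes[n + i] = (rep, float(h))
    return nodes[n + len(Z) - 1][0] + ";"


def cut_clusters(cluster: dict, n_clades: int) -> dict[str, int]:
    """Assign samples to ``n_clades`` flat clusters from the dendrogram."""
    from scipy.cluster.hierarchy import fcluster

    assign = fcluster(cluster["linkage"], t=n_clades, criterion="maxclust")
    return dict(zip(cluster["labels"], (int(a) for a in assign)))


def pca_patterns(matrices: list[PatternMatrix], n_components: int = 3) -> dict:
    """Mean-centered (unscaled) PCA of flattened pattern vectors.

    Returns unit-norm component weight maps reshaped to the bin grid,
    per-sample scores, and explained-variance ratios.
    """
    if len(matrices) < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    ms = sorted(matrices, key=lambda m: m.sample_id)
    X = np.stack([m.flat() for m in ms])
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero variance across samples; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    side = int(np.sqrt(X.shape[1]))
    return {
        "components": pca.components_.reshape(n_components, side, side),
        "scores": pd.DataFrame(
            scores, index=[m.sample_id for m in ms],
            columns=[f"PC{i + 1}" for i in range(n_components)]),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "mean": pca.mean_.reshape(side, side),
    }


def length_spectrum(freqs: FrequencyTable, bin_bp: int = 400) -> pd.DataFrame:
    """Background-subtracted frequency mass per span-length bin; mass
    beyond 15 kbp is flagged as possible insertions."""
    rows = freqs.rows
    edges = np.arange(0, freqs.L_u + bin_bp, bin_bp)
    mass = np.zeros(len(edges) - 1)
    if len(rows):
        idx = np.clip(rows["length"].to_numpy(int) // bin_bp, 0, len(mass) - 1)
        np.add.at(mass, idx, rows["f_i_bg"].to_numpy(float))
    df = pd.DataFrame({
        "length_lo": edges[:-1] + 1,
        "length_hi": edges[1:],
        "frequency": mass,
    })
    df["possible_insertion"] = df["length_lo"] > 15000
    return df


def terminus_histogram(annotated: pd.DataFrame, L: int, bin_bp: int = 250,
                       tmh_max: int = 9,
                       weight: str = "f_i_bg") -> TerminusHistogram:
    """Per-bin summed frequencies of LS5' and HS5' termini, excluding
    junctions with TMH above ``tmh_max`` (those belong to the slippage
    class and would mask the origin-anchored pattern)."""
    n_bins = int(np.ceil(L / bin_bp))
    ls = np.zeros(n_bins)
    hs = np.zeros(n_bins)
    if len(annotated):
        sel = annotated[annotated["tmh"] <= tmh_max] if "tmh" in annotated else annotated
        if len(sel):
            w = sel[weight].to_numpy(float)
            li = np.clip((sel["ls5"].to_numpy(int) - 1) // bin_bp, 0, n_bins - 1)
            hi = np.clip((sel["hs5"].to_numpy(int) - 1) // bin_bp, 0, n_bins - 1)
            np.add.at(ls, li, w)
            np.add.at(hs, hi, w)
    edges = np.minimum(np.arange(n_bins + 1) * bin_bp + 1, L + 1)
    return TerminusHistogram(ls, hs, bin_bp, edges)
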