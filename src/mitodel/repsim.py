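"""Monte Carlo models of deletion formation and their regression against
observed terminus histograms.

Six generation schemata are simulated on the circular genome; each draws a
deletion start from one distribution and an end (or length) from another,
then applies survival filters. All models share a linear scaling parameter
and a selection coefficient ``sel`` in [0, 1]: a candidate whose deleted
arc covers a selected-against origin survives with probability ``sel``
(a uniform draw exceeding the coefficient removes it). Candidates shorter
than 1 bp or longer than the reference, and candidates from an anchored
model that impinge on their own origin of origin, are removed outright.
Clockwise and counterclockwise streams share parameters, so no model has
more than five adjustable parameters (scale, sel, mu, sigma, shape).

Model distributions (start/length; ``7S3`` is the 7S-DNA 3' terminus,
``oriL`` the light-strand origin):

1. replication-independent, length-independent: both termini uniform;
   selection against 7S3.
2. replication-independent, length-dependent: start uniform, length ~
   Normal(mu, sigma); selection against 7S3.
3. unidirectional from 7S3 (continuous heavy-strand synthesis): terminus
   offset from 7S3 ~ Exponential(shape), length ~ Normal(mu, sigma);
   single stream; own-origin removal plus selection against oriL.
4. as model 3 but with no oriL selection.
5. bidirectional from 7S3 (strand-coupled): both streams anchored at 7S3;
   own-origin removal plus selection against oriL.
6. asynchronous strand displacement: one stream anchored at 7S3 extending
   toward oriL, the other anchored at oriL extending toward 7S3; each
   stream removes own-origin candidates and selects against the other
   origin.

Fitting minimizes the log-domain least-squares difference between
simulated and observed terminus densities (250-bp bins, LS5' and HS5'
concatenated) with common random numbers per evaluation, and reports a
log-domain R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .patterns import TerminusHistogram
from .refmap import DEFAULT_LENGTH, DeletionSpan

DEFAULT_N_PER_DIRECTION = 240_000

#: per-stream layout: (direction label, anchor attribute or None, drift)
MODEL_STREAMS: dict[int, list[tuple[str, str | None, int]]] = {
    1: [("cw", None, +1), ("ccw", None, -1)],
    2: [("cw", None, +1), ("ccw", None, -1)],
    3: [("cw", "seven_s3", -1)],
    4: [("cw", "seven_s3", -1)],
    5: [("cw", "seven_s3", -1), ("ccw", "seven_s3", +1)],
    6: [("cw", "seven_s3", -1), ("ccw", "ori_l", +1)],
}

#: origins subject to the soft selection coefficient, per model/stream
def _sel_origins(model_id: int, anchor: str | None) -> list[str]:
    if model_id in (1, 2):
        return ["seven_s3"]
    if model_id in (3, 5):
        return ["ori_l"]
    if model_id == 4:
        return []
    # model 6: select against the other origin
    return ["ori_l"] if anchor == "seven_s3" else ["seven_s3"]


FREE_PARAMS: dict[int, list[str]] = {
    1: ["sel"],
    2: ["sel", "mu", "sigma"],
    3: ["sel", "mu", "sigma", "shape"],
    4: ["mu", "sigma", "shape"],
    5: ["sel", "mu", "sigma"],
    6: ["sel", "mu", "sigma", "shape"],
}

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "sel": (0.0, 1.0),
    "mu": (200.0, 14000.0),
    "sigma": (50.0, 6000.0),
    "shape": (10.0, 4000.0),
}

DEFAULT_INIT: dict[str, float] = {"sel": 0.5, "mu": 5000.0, "sigma": 2000.0,
                                  "shape": 500.0}


@dataclass(frozen=True)
class SimModelConfig:
    model_id: int
    n_per_direction: int = DEFAULT_N_PER_DIRECTION
    params: dict = field(default_factory=dict)
    seed: int = 0
    L: int = DEFAULT_LENGTH
    ori_l: int = 5780
    seven_s3: int = 16070

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_STREAMS:
            raise ValueError(f"unknown model id {self.model_id}")
        merged = {"scale": 1.0, "sel": 1.0, "mu": 4000.0, "sigma": 1500.0,
                  "shape": 500.0}
        merged.update(self.params)
        if not 0.0 <= merged["sel"] <= 1.0:
            raise ValueError("sel must lie in [0, 1]")
        object.__setattr__(self, "params", merged)

    def anchor_pos(self, name: str | None) -> int | None:
        if name is None:
            return None
        return getattr(self, name)


@dataclass
class SimResult:
    spans: pd.DataFrame          # ls5, hs5, length, direction
    rejections: dict[str, int]
    attempts: int
    config: SimModelConfig

    @property
    def accepted(self) -> int:
        return len(self.spans)


def _covers(ls5: np.ndarray, length: np.ndarray, pos: int, L: int) -> np.ndarray:
    return ((pos - ls5) % L) < length


def _draw_batch(config: SimModelConfig, anchor: str | None, drift: int,
                rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized candidate draw: (ls5, length) arrays (1-based, length may
    be invalid; filters decide)."""
    L = config.L
    p = config.params
    mid = config.model_id
    if mid == 1:
        start = rng.integers(1, L + 1, size=size)
        end = rng.integers(1, L + 1, size=size)
        if drift > 0:
            ls5 = start
            length = (end - start) % L + 1
        else:
            ls5 = end
            length = (start - end) % L + 1
        return ls5, length
    length = np.rint(rng.normal(p["mu"], p["sigma"], size=size)).astype(np.int64)
    if mid == 2:
        start = rng.integers(1, L + 1, size=size)
    else:
        offset = np.maximum(1, np.ceil(rng.exponential(p["shape"], size=size))
                            ).astype(np.int64)
        a = config.anchor_pos(anchor)
        start = (a + drift * offset - 1) % L + 1
    if drift > 0:
        ls5 = start
    else:
        # start is the HS5' terminus; deletion extends to lower coordinates
        ls5 = (start - length) % L + 1
    return ls5, length


def _filter_batch(config: SimModelConfig, anchor: str | None,
                  ls5: np.ndarray, length: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, dict[str, int]]:
    """Apply the hard and selective filters; returns a keep-mask plus
    per-rule rejection counts (first failing rule wins)."""
    L = config.L
    p = config.params
    alive = np.ones(len(ls5), dtype=bool)
    rej = {"length_lt_1": 0, "exceeds_reference": 0,
           "impinges_own_origin": 0, "origin_selection": 0}

    bad = alive & (length < 1)
    rej["length_lt_1"] = int(bad.sum())
    alive &= ~bad
    bad = alive & (length > L - 1)
    rej["exceeds_reference"] = int(bad.sum())
    alive &= ~bad

    if anchor is not None and config.model_id >= 3:
        pos = config.anchor_pos(anchor)
        bad = alive & _covers(ls5, length, pos, L)
        rej["impinges_own_origin"] = int(bad.sum())
        alive &= ~bad

    sel = p["sel"]
    for origin in _sel_origins(config.model_id, anchor):
        pos = config.anchor_pos(origin)
        hit = alive & _covers(ls5, length, pos, L)
        u = rng.random(len(ls5))
        bad = hit & (u > sel)
        rej["origin_selection"] += int(bad.sum())
        alive &= ~bad
    return alive, rej


def draw_deletion(config: SimModelConfig, direction: str,
                  rng: np.random.Generator) -> DeletionSpan:
    """One candidate span for the given direction (no filtering)."""
    for dname, anchor, drift in MODEL_STREAMS[config.model_id]:
        if dname == direction:
            ls5, length = _draw_batch(config, anchor, drift, rng, 1)
            length = max(1, min(int(length[0]), config.L - 1))
            ls = int(ls5[0])
            hs = (ls + length - 2) % config.L + 1
            return DeletionSpan(ls, hs, wraps=ls > hs)
    raise ValueError(f"model {config.model_id} has no direction {direction!r}")


def filter_candidate(span: DeletionSpan, config: SimModelConfig,
                     rng: np.random.Generator,
                     direction: str | None = None) -> tuple[bool, str | None]:
    """Accept/reject one candidate; returns (accepted, rejection_reason)."""
    streams = MODEL_STREAMS[config.model_id]
    anchor = streams[0][1]
    if direction is not None:
        for dname, a, _ in streams:
            if dname == direction:
                anchor = a
    length = (span.hs5 - span.ls5) % config.L + 1
    alive, rej = _filter_batch(config, anchor, np.array([span.ls5]),
                               np.array([length]), rng)
    if alive[0]:
        return True, None
    reason = next(k for k, v in rej.items() if v > 0)
    return False, reason


def simulate(config: SimModelConfig, min_acceptance: float = 1e-4) -> SimResult:
    """Run the model until ``n_per_direction`` deletions are accepted in
    each applicable direction. Reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    L = config.L
    frames = []
    total_rej = {"length_lt_1": 0, "exceeds_reference": 0,
                 "impinges_own_origin": 0, "origin_selection": 0}
    attempts = 0
    for dname, anchor, drift in MODEL_STREAMS[config.model_id]:
        need = config.n_per_direction
        got_ls, got_len = [], []
        first = True
        while need > 0:
            size = max(int(need * 2.5), 8192)
            ls5, length = _draw_batch(config, anchor, drift, rng, size)
            alive, rej = _filter_batch(config, anchor, ls5, length, rng)
            attempts += size
            for k in total_rej:
                total_rej[k] += rej[k]
            rate = alive.mean()
            if first and rate < min_acceptance:
                raise RuntimeError(
                    f"model {config.model_id} acceptance rate {rate:.2e} "
                    f"below {min_acceptance}; pathological parameters")
            first = False
            take = min(need, int(alive.sum()))
            idx = np.flatnonzero(alive)[:take]
            got_ls.append(ls5[idx])
            got_len.append(length[idx])
            # uncounted rejections for untaken alive candidates are fine:
            # conservation is over *processed* attempts
            attempts -= int(alive.sum()) - take
            need -= take
        ls5 = np.concatenate(got_ls)
        length = np.concatenate(got_len)
        hs5 = (ls5 + length - 2) % L + 1
        frames.append(pd.DataFrame({
            "ls5": ls5, "hs5": hs5, "length": length,
            "direction": dname}))
    spans = pd.concat(frames, ignore_index=True)
    return SimResult(spans=spans, rejections=total_rej, attempts=attempts,
                     config=config)


def result_histogram(result: SimResult, bin_bp: int = 250) -> TerminusHistogram:
    """Bin accepted termini the same way as the observed histograms; the
    linear scaling parameter multiplies the counts."""
    L = result.config.L
    n_bins = int(np.ceil(L / bin_bp))
    ls = np.zeros(n_bins)
    hs = np.zeros(n_bins)
    scale = result.config.params["scale"]
    li = np.clip((result.spans["ls5"].to_numpy(int) - 1) // bin_bp, 0, n_bins - 1)
    hi = np.clip((result.spans["hs5"].to_numpy(int) - 1) // bin_bp, 0, n_bins - 1)
    np.add.at(ls, li, scale)
    np.add.at(hs, hi, scale)
    edges = np.minimum(np.arange(n_bins + 1) * bin_bp + 1, L + 1)
    return TerminusHistogram(ls, hs, bin_bp, edges)


def _log_r2(obs: np.ndarray, model: np.ndarray, eps: float) -> float:
    y = np.log(obs + eps)
    yhat = np.log(model + eps)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_model(observed: TerminusHistogram, model_id: int, seed: int = 0,
              sim_n: int = 24_000, init: dict | None = None,
              bounds: dict | None = None, restarts: int = 3,
              maxfev: int = 250, L: int = DEFAULT_LENGTH,
              ori_l: int = 5780, seven_s3: int = 16070) -> dict:
    """Regress a model's free parameters against an observed terminus
    histogram by log-domain least squares.

    Derivative-free (Nelder-Mead) search with common random numbers: every
    objective evaluation simulates with the same seed, so the surface is
    deterministic. The linear scale parameter is profiled out by total-mass
    matching; the pseudo-count is half the smallest nonzero observed bin.
    """
    obs = np.concatenate([observed.ls5_freq, observed.hs5_freq])
    if obs.sum() <= 0:
        raise ValueError("observed histogram is empty")
    nz = obs[obs > 0]
    eps = 0.5 * float(nz.min())
    names = FREE_PARAMS[model_id]
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    init_p = {**DEFAULT_INIT, **(init or {})}
    bin_bp = observed.bin_size

    n_eval = 0

    def make_objective(n_sim: int):
        def objective(theta: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            params = {n: float(np.clip(t, *bnds[n]))
                      for n, t in zip(names, theta)}
            cfg = SimModelConfig(model_id, n_per_direction=n_sim,
                                 params=params, seed=seed, L=L,
                                 ori_l=ori_l, seven_s3=seven_s3)
            try:
                res = simulate(cfg)
            except RuntimeError:
                return 1e12
            h = result_histogram(res, bin_bp)
            sim = np.concatenate([h.ls5_freq, h.hs5_freq])
            if sim.sum() <= 0:
                return 1e12
            scale = obs.sum() / sim.sum()
            return float(np.sum((np.log(sim * scale + eps)
                                 - np.log(obs + eps)) ** 2))
        return objective

    rng = np.random.default_rng(seed + 7919)
    dim = len(names)
    x0 = np.array([init_p[n] for n in names], dtype=float)
    lo = np.array([bnds[n][0] for n in names])
    hi = np.array([bnds[n][1] for n in names])
    nm_bounds = [bnds[n] for n in names]
    nm_opts = {"maxfev": maxfev, "xatol": 1e-2, "fatol": 1e-3}

    # Stage 1 at reduced simulation size: a dense seeded scan followed by
    # simplex runs from the best scan points, to escape the curved ridges
    # of the loss surface cheaply.
    coarse_n = max(sim_n // 5, 4000)
    coarse = make_objective(coarse_n)
    n_scan = max(32, 40 * dim)
    scan = lo + rng.random((n_scan, dim)) * (hi - lo)
    scan[0] = x0
    scan_loss = np.array([coarse(p) for p in scan])
    order = np.argsort(scan_loss)
    stage1 = []
    for r in range(max(restarts, 4)):
        res = minimize(coarse, scan[order[r]], method="Nelder-Mead",
                       bounds=nm_bounds, options=nm_opts)
        stage1.append(res)
    stage1.sort(key=lambda r: r.fun)

    # Stage 2 at full size: refine the two best coarse optima; between
    # fresh-simplex restarts, run a cyclic per-parameter grid polish to
    # slide along the curved parameter ridges Nelder-Mead stalls on.
    full = make_objective(sim_n)

    def cyclic_polish(x: np.ndarray, fx: float, rounds: int = 2,
                      frac: float = 0.12) -> tuple[np.ndarray, float]:
        x = x.copy()
        for _round in range(rounds):
            for j in range(dim):
                width = frac * (hi[j] - lo[j])
                grid = np.clip(x[j] + np.linspace(-width, width, 7), lo[j], hi[j])
                for g in grid:
                    trial = x.copy()
                    trial[j] = g
                    f = full(trial)
                    if f < fx:
                        x, fx = trial, f
            frac /= 2
        return x, fx

    best = None
    for res0 in stage1[:3]:
        res = minimize(full, np.clip(res0.x, lo, hi), method="Nelder-Mead",
                       bounds=nm_bounds, options=nm_opts)
        if best is None or res.fun < best.fun:
            best = res
    bx, bf = np.clip(best.x, lo, hi), best.fun

    # The selection coefficient couples softly to the other parameters and
    # the loss surface can carry a second local basin along it; profile sel
    # across its range and refine from any better basin found.
    if "sel" in names:
        j = names.index("sel")
        profile = []
        for s in np.linspace(0.05, 0.95, 10):
            trial = bx.copy()
            trial[j] = s
            profile.append((full(trial), trial))
        profile.sort(key=lambda t: t[0])
        for _f, trial in profile[:2]:
            if abs(trial[j] - bx[j]) < 0.05:
                continue
            res = minimize(full, trial, method="Nelder-Mead",
                           bounds=nm_bounds, options=nm_opts)
            if res.fun < bf:
                bx, bf = np.clip(res.x, lo, hi), res.fun
    for _ in range(3):
        bx, bf = cyclic_polish(bx, bf)
        res = minimize(full, bx, method="Nelder-Mead",
                       bounds=nm_bounds, options=nm_opts)
        if res.fun < bf - 1e-3:
            bx, bf = np.clip(res.x, lo, hi), res.fun
        else:
            if res.fun < bf:
                bx, bf = np.clip(res.x, lo, hi), res.fun
            break

    class _Best:
        x = bx
        fun = bf
        success = True

    best = _Best()

    params = {n: float(np.clip(t, *bnds[n])) for n, t in zip(names, best.x)}
    cfg = SimModelConfig(model_id, n_per_direction=sim_n, params=params,
                         seed=seed, L=L, ori_l=ori_l, seven_s3=seven_s3)
    sim_res = simulate(cfg)
    h = result_histogram(sim_res, bin_bp)
    sim = np.concatenate([h.ls5_freq, h.hs5_freq])
    scale = obs.sum() / sim.sum()
    r2 = _log_r2(obs, sim * scale, eps)
    return {
        "model_id": model_id,
        "params": {**params, "scale": float(scale)},
        "loss": float(best.fun),
        "r2": r2,
        "n_eval": n_eval,
        "converged": bool(best.success),
        "rejections": sim_res.rejections,
    }


def compare_models(observed: TerminusHistogram,
                   model_ids: list[int] | None = None, seed: int = 0,
                   sim_n: int = 24_000, **kwargs) -> pd.DataFrame:
    """Fit each model and rank by log-domain R^2 (best first)."""
    if model_ids is None:
        model_ids = list(MODEL_STREAMS)
    if not model_ids:
        raise ValueError("need at least one model id")
    fits = [fit_model(observed, m, seed=seed, sim_n=sim_n, **kwargs)
            for m in model_ids]
    df = pd.DataFrame([
        {"model_id": f["model_id"], "r2": f["r2"], "loss": f["loss"],
         **{f"param_{k}": v for k, v in f["params"].items()}}
        for f in fits
    ]).sort_values("r2", ascending=False).reset_index(drop=True)
    return df
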