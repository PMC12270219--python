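"""Probabilistic information-flow (traversal-distance) ranking.

Starting from a pool of seed cells, the traversal proceeds in synchronous
steps: every not-yet-added cell is accepted into the pool independently with
probability

    P = min(fraction_of_inputs_from_pool / cap, 1),      cap = 0.3

where the input fraction is synapse-weighted by default (pooled incoming
synapses over total incoming synapses).  The step at which a cell first joins
is its traversal distance for that repetition; distances are averaged over
repetitions and the cell's rank is 1 + mean distance, so seeds rank exactly
1.  Ranks are percentile-normalized against a reference population so that a
normalized rank of 20% means 80% of the population ranks farther from the
seed.

``exact_rank_oracle`` computes the same expectation without sampling by
absorbing-Markov-chain analysis over pool states, for small graphs; it is the
independent oracle the Monte-Carlo path is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import StateSpaceError

__all__ = [
    "TraversalParams",
    "traversal_once",
    "traversal_ranks",
    "exact_rank_oracle",
    "normalize_ranks",
    "subtype_normalized_ranks",
    "multisensory_screen",
]


@dataclass
class TraversalParams:
    cap: float = 0.3
    n_reps: int = 1000
    rng_seed: int | None = None
    fraction_basis: str = "synapse"  # or "partner"
    max_steps: int = 100000
    unreached: str = "exclude"  # or "penalty" (max step reached + 1)

    def __post_init__(self) -> None:
        if not (0 < self.cap <= 1):
            raise ValueError(f"cap must be in (0, 1], got {self.cap!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.fraction_basis not in {"synapse", "partner"}:
            raise ValueError("fraction_basis must be 'synapse' or 'partner'")
        if self.unreached not in {"exclude", "penalty"}:
            raise ValueError("unreached must be 'exclude' or 'penalty'")


class _Compiled:
    """Edge table compiled to CSR-by-source with per-cell input totals."""

    def __init__(self, edges: pd.DataFrame, fraction_basis: str):
        ids = np.unique(
            np.concatenate([edges["pre_id"].to_numpy(), edges["post_id"].to_numpy()])
        )
        self.ids = ids
        self.index = {c: i for i, c in enumerate(ids)}
        n = len(ids)
        pre = edges["pre_id"].map(self.index).to_numpy()
        post = edges["post_id"].map(self.index).to_numpy()
        w = (
            edges["syn_count"].to_numpy(dtype=float)
            if fraction_basis == "synapse"
            else np.ones(len(edges))
        )
        order = np.argsort(pre, kind="stable")
        self.src_sorted = pre[order]
        self.dst = post[order]
        self.w = w[order]
        self.indptr = np.searchsorted(self.src_sorted, np.arange(n + 1))
        self.total_in = np.zeros(n)
        np.add.at(self.total_in, post, w)
        self.n = n

    def push(self, members: np.ndarray, pooled_in: np.ndarray) -> None:
        for m in members:
            lo, hi = self.indptr[m], self.indptr[m + 1]
            np.add.at(pooled_in, self.dst[lo:hi], self.w[lo:hi])


def _seed_indices(compiled: _Compiled, seeds: Iterable) -> np.ndarray:
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seeds must be nonempty")
    missing = [s for s in seeds if s not in compiled.index]
    if missing:
        raise KeyError(f"seed cells absent from the edge table: {missing[:10]}")
    return np.array(sorted({compiled.index[s] for s in seeds}), dtype=np.int64)


def _run_once(
    compiled: _Compiled,
    seed_idx: np.ndarray,
    cap: float,
    rng: np.random.Generator,
    max_steps: int,
) -> np.ndarray:
    """One traversal repetition; returns per-cell step of addition (-1 unreached)."""
    n = compiled.n
    step_added = np.full(n, -1, dtype=np.int64)
    in_pool = np.zeros(n, dtype=bool)
    pooled_in = np.zeros(n)
    in_pool[seed_idx] = True
    step_added[seed_idx] = 0
    compiled.push(seed_idx, pooled_in)

    for step in range(1, max_steps + 1):
        active = np.flatnonzero(~in_pool & (pooled_in > 0))
        if len(active) == 0:
            break
        p = np.minimum(pooled_in[active] / compiled.total_in[active] / cap, 1.0)
        accepted = active[rng.random(len(active)) < p]
        if len(accepted) == 0:
            continue
        in_pool[accepted] = True
        step_added[accepted] = step
        compiled.push(accepted, pooled_in)
    return step_added


def traversal_once(
    edges: pd.DataFrame,
    seeds: Iterable,
    params: TraversalParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Single traversal repetition: per-cell step of addition (NaN unreached)."""
    params = params or TraversalParams()
    compiled = _Compiled(edges, params.fraction_basis)
    seed_idx = _seed_indices(compiled, seeds)
    rng = np.random.default_rng(params.rng_seed if rng is None else rng)
    steps = _run_once(compiled, seed_idx, params.cap, rng, params.max_steps)
    out = pd.Series(steps.astype(float), index=compiled.ids, name="step")
    out[out < 0] = np.nan
    return out


def traversal_ranks(
    edges: pd.DataFrame,
    seeds: Iterable,
    params: TraversalParams | None = None,
) -> pd.DataFrame:
    """Mean traversal distance and rank (1 + mean) over repetitions.

    A cell unreached in a repetition is, by default, excluded from that
    repetition's mean (the count of repetitions in which it was reached is
    reported); with ``params.unreached='penalty'`` it instead contributes the
    repetition's last step + 1.
    """
    params = params or TraversalParams()
    compiled = _Compiled(edges, params.fraction_basis)
    seed_idx = _seed_indices(compiled, seeds)
    rng = np.random.default_rng(params.rng_seed)
    sum_steps = np.zeros(compiled.n)
    sum_sq = np.zeros(compiled.n)
    n_reached = np.zeros(compiled.n, dtype=np.int64)
    for _ in range(params.n_reps):
        steps = _run_once(compiled, seed_idx, params.cap, rng, params.max_steps)
        reached = steps >= 0
        if params.unreached == "penalty":
            contrib = np.where(reached, steps, steps.max() + 1).astype(float)
            sum_steps += contrib
            sum_sq += contrib**2
        else:
            sum_steps[reached] += steps[reached]
            sum_sq[reached] += steps[reached].astype(float) ** 2
        n_reached += reached
    denom = (
        np.full(compiled.n, params.n_reps, dtype=float)
        if params.unreached == "penalty"
        else n_reached.astype(float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(denom > 0, sum_steps / np.maximum(denom, 1), np.nan)
        var = np.where(denom > 0, sum_sq / np.maximum(denom, 1) - mean**2, np.nan)
        sd = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {
            "cell_id": compiled.ids,
            "mean_distance": mean,
            "rank": 1.0 + mean,
            "sd_distance": sd,
            "n_reps_reached": n_reached,
            "n_reps": params.n_reps,
        }
    )


def exact_rank_oracle(
    edges: pd.DataFrame,
    seeds: Iterable,
    params: TraversalParams | None = None,
    max_nonseed: int = 12,
) -> pd.Series:
    """Exact expected ranks by enumeration over pool states.

    The pool process is a Markov chain on subsets of cells; transitions out
    of a state strictly enlarge the pool except for the no-addition self
    loop, which is absorbed analytically, so expectations follow from a
    backward pass over states in decreasing pool size.  Unreachable cells get
    rank NaN.  Raises :class:`StateSpaceError` when more than
    ``max_nonseed`` non-seed cells are reachable.
    """
    params = params or TraversalParams()
    compiled = _Compiled(edges, params.fraction_basis)
    seed_idx = set(_seed_indices(compiled, seeds).tolist())

    # reachable = cells with a positive-weight path from the seeds
    reach = set(seed_idx)
    frontier = list(seed_idx)
    while frontier:
        nxt = []
        for m in frontier:
            lo, hi = compiled.indptr[m], compiled.indptr[m + 1]
            for t in compiled.dst[lo:hi]:
                if t not in reach:
                    reach.add(int(t))
                    nxt.append(int(t))
        frontier = nxt
    nonseed = sorted(reach - seed_idx)
    m = len(nonseed)
    if m > max_nonseed:
        raise StateSpaceError(
            f"{m} reachable non-seed cells exceed the enumeration limit {max_nonseed}"
        )
    pos = {c: i for i, c in enumerate(nonseed)}

    # per reachable cell: input weight from seeds, and from each non-seed cell
    seed_w = np.zeros(m)
    contrib = [dict() for _ in range(m)]
    for s in range(compiled.n):
        lo, hi = compiled.indptr[s], compiled.indptr[s + 1]
        for t, w in zip(compiled.dst[lo:hi], compiled.w[lo:hi]):
            if t in pos:
                if s in seed_idx:
                    seed_w[pos[t]] += w
                elif s in pos:
                    contrib[pos[t]][pos[s]] = contrib[pos[t]].get(pos[s], 0.0) + w
    total_in = np.array([compiled.total_in[c] for c in nonseed])

    cap = params.cap
    inf = float("inf")

    def accept_probs(mask: int) -> list[tuple[int, float]]:
        out = []
        for i in range(m):
            if mask >> i & 1:
                continue
            pooled = seed_w[i] + sum(
                w for j, w in contrib[i].items() if mask >> j & 1
            )
            if pooled > 0:
                out.append((i, min(pooled / total_in[i] / cap, 1.0)))
        return out

    full = (1 << m) - 1
    # E[c][mask]: expected remaining steps until c joins, from pool state mask
    memo: dict[int, np.ndarray] = {full: np.zeros(m)}
    states = sorted(range(full + 1), key=lambda s: -bin(s).count("1"))
    for mask in states:
        if mask in memo:
            continue
        cand = accept_probs(mask)
        e = np.full(m, inf)
        for i in range(m):
            if mask >> i & 1:
                e[i] = 0.0
        if not cand:
            memo[mask] = e
            continue
        idxs = [i for i, _ in cand]
        probs = np.array([p for _, p in cand])
        k = len(cand)
        acc = np.zeros(m)
        q0 = 0.0
        for sub in range(1 << k):
            pr = 1.0
            add_mask = 0
            for b in range(k):
                if sub >> b & 1:
                    pr *= probs[b]
                    add_mask |= 1 << idxs[b]
                else:
                    pr *= 1.0 - probs[b]
            if pr == 0.0:
                continue
            if sub == 0:
                q0 = pr
                continue
            nxt = memo[mask | add_mask]
            acc = acc + pr * np.where(np.isinf(nxt), inf, nxt)
        denom = 1.0 - q0
        vals = (1.0 + acc) / denom
        for i in range(m):
            if mask >> i & 1:
                vals[i] = 0.0
        memo[mask] = vals

    e0 = memo[0] if m else np.zeros(0)
    rank = pd.Series(np.nan, index=compiled.ids, name="rank", dtype=float)
    for s in seed_idx:
        rank[compiled.ids[s]] = 1.0
    for c, i in pos.items():
        rank[compiled.ids[c]] = 1.0 + e0[i] if np.isfinite(e0[i]) else np.nan
    return rank


def normalize_ranks(
    ranks: pd.DataFrame, population: Iterable | None = None
) -> pd.DataFrame:
    """Percentile-normalize ranks against a reference population.

    normalized_rank(c) is the fraction of the population whose rank is <=
    rank(c), with ties averaged; for cells in the population this reproduces
    the average fractional rank (1/n ... 1 for strictly ordered ranks).
    Cells outside the population get the midpoint convention against the
    population's rank distribution.  The population defaults to every cell
    with a finite rank.
    """
    out = ranks.copy()
    finite = out.loc[np.isfinite(out["rank"])]
    if population is None:
        pop_ids = set(finite["cell_id"])
    else:
        pop_ids = set(population)
        missing = pop_ids - set(out["cell_id"])
        if missing:
            raise KeyError(f"population cells missing from rank table: "
                           f"{sorted(missing)[:10]}")
    pop_ranks = np.sort(
        finite.loc[finite["cell_id"].isin(pop_ids), "rank"].to_numpy()
    )
    n_pop = len(pop_ranks)
    r = out["rank"].to_numpy()
    les = np.searchsorted(pop_ranks, r, side="left")
    leq = np.searchsorted(pop_ranks, r, side="right")
    in_pop = out["cell_id"].isin(pop_ids).to_numpy()
    norm = np.where(in_pop, (les + leq + 1) / 2.0, (les + leq) / 2.0) / max(n_pop, 1)
    norm[~np.isfinite(r)] = np.nan
    out["normalized_rank"] = norm
    return out


def subtype_normalized_ranks(
    ranks: pd.DataFrame, subtype_map: Mapping
) -> pd.Series:
    """Mean normalized rank over the member cells of each subtype."""
    sub = ranks["cell_id"].map(subtype_map)
    df = ranks.loc[sub.notna() & np.isfinite(ranks["normalized_rank"])]
    return (
        df.groupby(sub.loc[df.index], observed=True)["normalized_rank"]
        .mean()
        .sort_index()
    )


def multisensory_screen(
    subtype_ranks: Mapping[str, pd.Series], cutoff: float = 0.10
) -> pd.DataFrame:
    """Subtypes proximal (normalized rank < cutoff) to two or more seed
    modalities, reported per modality pair; a subtype may appear in several
    pairs."""
    modalities = sorted(subtype_ranks)
    if len(modalities) < 2:
        raise ValueError("need at least 2 modalities")
    rows = []
    for i, a in enumerate(modalities):
        for b in modalities[i + 1 :]:
            ra, rb = subtype_ranks[a], subtype_ranks[b]
            shared = ra.index.intersection(rb.index)
            for st in shared:
                if ra[st] < cutoff and rb[st] < cutoff:
                    rows.append(
                        {
                            "modality_a": a,
                            "modality_b": b,
                            "subtype": st,
                            "rank_a": float(ra[st]),
                            "rank_b": float(rb[st]),
                        }
                    )
    return pd.DataFrame(rows, columns=["modality_a", "modality_b", "subtype",
                                       "rank_a", "rank_b"])
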