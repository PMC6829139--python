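"""Marker ordering within a linkage group and error-prone-locus detection.

Ordering maximises a two-point composite likelihood: the sum of adjacent-
pair LOD scores along the marker chain (an open-path TSP with LOD as the
"gain" of placing two markers next to each other).  Each run starts a
greedy nearest-neighbour chain from a random marker and polishes it with
best-improvement local search (2-opt segment reversals plus single-marker
relocation); the best of ``n_runs`` runs (default 10) is kept.

Error-prone loci are detected after ordering as loci whose phase-aligned
allele disagrees with BOTH flanking neighbours in too many gametes —
singleton double recombinants, the fingerprint of genotyping error rather
than genuine crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OrderedGroup:
    """The selected marker order for one linkage group."""
    lg_id: str
    markers: list                     # ordered marker IDs
    objective: float                  # best sum of adjacent-pair LOD
    run_objectives: list = field(default_factory=list)
    run_seeds: list = field(default_factory=list)


def path_objective(order: np.ndarray, W: np.ndarray) -> float:
    """Sum of adjacent-pair weights along an open path."""
    order = np.asarray(order)
    if len(order) < 2:
        return 0.0
    return float(W[order[:-1], order[1:]].sum())


def _greedy_chain(W: np.ndarray, start: int) -> np.ndarray:
    """Grow a chain from ``start``, appending the unused marker with the
    highest LOD to either chain end (appended at that end)."""
    m = W.shape[0]
    used = np.zeros(m, dtype=bool)
    used[start] = True
    chain = [start]
    Wm = W.copy()
    np.fill_diagonal(Wm, -np.inf)
    for _ in range(m - 1):
        head, tail = chain[0], chain[-1]
        wh = np.where(used, -np.inf, Wm[head])
        wt = np.where(used, -np.inf, Wm[tail])
        ih, it = int(np.argmax(wh)), int(np.argmax(wt))
        if wh[ih] > wt[it]:
            chain.insert(0, ih)
            used[ih] = True
        else:
            chain.append(it)
            used[it] = True
    return np.array(chain, dtype=np.intp)


def _pad_weights(order: np.ndarray, W: np.ndarray):
    """Adjacent weights with virtual zero-weight path endpoints."""
    m = len(order)
    left = np.zeros(m + 1)
    left[1:m] = W[order[:-1], order[1:]]  # left[i] = w(p[i-1], p[i]); ends 0
    return left


def _best_two_opt(order: np.ndarray, W: np.ndarray):
    """Best 2-opt reversal (i..j) and its objective gain, vectorised.

    Reversing order[i..j] replaces edges (p[i-1],p[i]) and (p[j],p[j+1])
    with (p[i-1],p[j]) and (p[i],p[j+1]); internal edges are unchanged
    because W is symmetric.  Path ends act as zero-weight virtual nodes.
    """
    m = len(order)
    if m < 3:
        return 0.0, None
    w_edge = np.zeros(m + 1)
    w_edge[1:m] = W[order[:-1], order[1:]]
    # new left edge for reversal (i, j): W[p[i-1], p[j]] (0 if i == 0)
    left_new = np.zeros((m, m))
    left_new[1:, :] = W[order[:-1]][:, order]
    # new right edge: W[p[i], p[j+1]] (0 if j == m-1)
    right_new = np.zeros((m, m))
    right_new[:, :-1] = W[order][:, order[1:]]
    delta = (left_new + right_new
             - w_edge[:m, None]            # old left edge w(p[i-1], p[i])
             - w_edge[1:m + 1][None, :])   # old right edge w(p[j], p[j+1])
    iu = np.triu_indices(m, k=1)
    gains = delta[iu]
    best = int(np.argmax(gains))
    return float(gains[best]), (int(iu[0][best]), int(iu[1][best]))


def _best_relocation(order: np.ndarray, W: np.ndarray):
    """Best single-marker relocation and its gain, vectorised over (i, slot).

    Removing p[i] joins its former neighbours; inserting it into slot t
    (between p[t-1] and p[t], slots 0..m-1 excluding i's own edges) splits
    that edge.
    """
    m = len(order)
    if m < 3:
        return 0.0, None
    w_edge = np.zeros(m + 1)
    w_edge[1:m] = W[order[:-1], order[1:]]
    remove_gain = np.empty(m)
    for i in range(m):
        bridged = W[order[i - 1], order[i + 1]] if 0 < i < m - 1 else 0.0
        remove_gain[i] = bridged - w_edge[i] - w_edge[i + 1]
    # insert cost of marker i into slot t of the *reduced* path approximated
    # on the original path: slots adjacent to i are no-ops and masked.
    Wio = W[order][:, order]
    ins = np.zeros((m, m + 1))
    ins[:, 1:m] = Wio[:, :-1] + Wio[:, 1:] - w_edge[1:m][None, :]
    ins[:, 0] = Wio[:, 0]
    ins[:, m] = Wio[:, -1]
    delta = remove_gain[:, None] + ins
    for i in range(m):
        delta[i, i] = -np.inf       # re-insert at own place
        delta[i, i + 1] = -np.inf
    flat = int(np.argmax(delta))
    i, t = divmod(flat, m + 1)
    return float(delta[i, t]), (i, t)


def _apply_relocation(order: np.ndarray, i: int, t: int) -> np.ndarray:
    marker = order[i]
    rest = np.delete(order, i)
    t_adj = t if t < i else t - 1  # slot index shifts after removal
    return np.insert(rest, t_adj, marker)


def local_search(order: np.ndarray, W: np.ndarray,
                 tol: float = 1e-9) -> np.ndarray:
    """Best-improvement 2-opt + relocation until no move gains > tol."""
    order = np.asarray(order, dtype=np.intp).copy()
    while True:
        g2, mv2 = _best_two_opt(order, W)
        g1, mv1 = _best_relocation(order, W)
        if max(g2, g1) <= tol:
            return order
        if g2 >= g1:
            i, j = mv2
            order[i:j + 1] = order[i:j + 1][::-1]
        else:
            order = _apply_relocation(order, *mv1)


def order_markers(marker_ids, lod_frame: pd.DataFrame, n_runs: int = 10,
                  seed: int = 0, lg_id: str = "LG01") -> OrderedGroup:
    """Best-of-``n_runs`` stochastic ordering of one linkage group.

    Parameters
    ----------
    marker_ids : markers of the group (bin representatives)
    lod_frame : symmetric DataFrame of pairwise LOD over at least these IDs

    Orientation is normalised so the first marker ID sorts before the last.
    """
    marker_ids = sorted(str(m) for m in marker_ids)
    m = len(marker_ids)
    if m < 2:
        return OrderedGroup(lg_id=lg_id, markers=list(marker_ids),
                            objective=0.0)
    W = lod_frame.loc[marker_ids, marker_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    run_seeds = [int(s) for s in
                 rng.integers(0, 2 ** 31 - 1, size=n_runs)]
    best_order, best_obj, objectives = None, -np.inf, []
    for rs in run_seeds:
        run_rng = np.random.default_rng(rs)
        start = int(run_rng.integers(0, m))
        order = local_search(_greedy_chain(W, start), W)
        obj = path_objective(order, W)
        objectives.append(obj)
        if obj > best_obj + 1e-12:
            best_obj, best_order = obj, order
    ordered = [marker_ids[i] for i in best_order]
    if ordered[0] > ordered[-1]:
        ordered = ordered[::-1]
    return OrderedGroup(lg_id=lg_id, markers=ordered, objective=best_obj,
                        run_objectives=objectives, run_seeds=run_seeds)


def phase_signs(order_idx: np.ndarray, phase_flipped: np.ndarray) -> np.ndarray:
    """Propagate phase orientation along the chain from adjacent-pair
    phase flips: sign[0] = 0, sign[k+1] = sign[k] XOR flip(k, k+1)."""
    m = len(order_idx)
    signs = np.zeros(m, dtype=np.int8)
    for t in range(m - 1):
        flip = phase_flipped[order_idx[t], order_idx[t + 1]]
        signs[t + 1] = signs[t] ^ int(flip)
    return signs


def detect_error_prone(ordered_markers, X: np.ndarray, ids,
                       phase_flipped: np.ndarray,
                       rate_threshold: float = 0.3,
                       min_informative: int = 5) -> pd.Series:
    """Singleton-double-recombinant rate per ordered locus.

    For each locus, over gametes non-missing at the locus and both flanking
    neighbours (terminal markers use their two nearest neighbours), count
    gametes whose phase-aligned allele disagrees with BOTH flanks.  Returns
    the per-locus rate; loci with rate > ``rate_threshold`` are error-prone.
    Groups with fewer than 3 markers yield an empty result.
    """
    ids = pd.Index(ids)
    pos = {str(mk): i for i, mk in enumerate(ids)}
    order_idx = np.array([pos[str(mk)] for mk in ordered_markers],
                         dtype=np.intp)
    m = len(order_idx)
    if m < 3:
        return pd.Series(dtype=float, name="error_rate")
    signs = phase_signs(order_idx, phase_flipped)
    Xo = X[order_idx].astype(np.int16)
    valid = Xo >= 0
    aligned = np.where(valid, Xo ^ signs[:, None], -1)
    rates = np.full(m, np.nan)
    for t in range(m):
        if t == 0:
            l, r = 1, 2
        elif t == m - 1:
            l, r = m - 3, m - 2
        else:
            l, r = t - 1, t + 1
        ok = valid[t] & valid[l] & valid[r]
        n_ok = int(ok.sum())
        if n_ok < min_informative:
            rates[t] = 0.0
            continue
        mismatch = ((aligned[t] != aligned[l]) &
                    (aligned[t] != aligned[r]) & ok)
        rates[t] = mismatch.sum() / n_ok
    return pd.Series(rates, index=[str(mk) for mk in ordered_markers],
                     name="error_rate")
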