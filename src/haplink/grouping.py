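"""Co-segregation binning, LOD-threshold grouping, and singleton joining.

At n = 139 gametes, tightly linked ddRAD markers frequently show zero
recombinants and are indistinguishable ("duplicates"); they are collapsed
into co-segregation bins and one representative per bin carries the bin
through grouping and ordering.  Linkage groups are the connected components
of the marker graph whose edges are pairs with LOD at or above the
threshold (single-linkage at LOD 5 by default); remaining singletons may
then be attached to the group holding their uniquely best LOD.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .twopoint import PairwiseLODMatrix


@dataclass
class CosegregationBins:
    """Marker -> bin assignment plus one representative per bin."""
    assignment: pd.Series          # marker_id -> bin_id
    representatives: pd.Series     # bin_id -> marker_id

    @property
    def n_bins(self) -> int:
        return len(self.representatives)

    def members(self, bin_id) -> list:
        return self.assignment.index[self.assignment == bin_id].tolist()


def collapse_cosegregating(X: np.ndarray, ids, n_min: int = 20
                           ) -> CosegregationBins:
    """Bin markers with identical (phase-equivalent) segregation patterns.

    Two markers co-segregate iff their mismatch count over shared
    non-missing gametes is 0 or n (a pure phase flip), with at least
    ``n_min`` shared gametes; bins are the transitive closure.  The
    representative is the member with fewest missing calls (ties broken by
    lexicographic marker ID).
    """
    X = np.asarray(X, dtype=np.int8)
    ids = pd.Index(ids)
    M = (X >= 0).astype(np.float64)
    A = (X == 1).astype(np.float64)
    B = M - A
    n = M @ M.T
    d = A @ B.T + B @ A.T
    linked = ((d < 0.5) | (d > n - 0.5)) & (n >= max(n_min, 1))
    np.fill_diagonal(linked, False)

    g = nx.from_numpy_array(linked)
    missing_counts = (X < 0).sum(axis=1)
    assignment = {}
    reps = []
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: str(ids[c[0]]))
    for comp in comps:
        rep_pos = min(comp, key=lambda i: (missing_counts[i], str(ids[i])))
        reps.append(ids[rep_pos])
        for i in comp:
            assignment[ids[i]] = len(reps) - 1
    bin_ids = [f"bin{j + 1:05d}" for j in range(len(reps))]
    assign = pd.Series({mk: bin_ids[b] for mk, b in assignment.items()},
                       name="bin_id").reindex(ids)
    representatives = pd.Series(reps, index=pd.Index(bin_ids, name="bin_id"),
                                name="marker_id")
    return CosegregationBins(assignment=assign, representatives=representatives)


@dataclass
class Grouping:
    """LOD-threshold grouping result over bin representatives."""
    groups: dict                # lg_id -> list of marker ids
    singletons: list
    lod_threshold: float

    @property
    def assignment(self) -> pd.Series:
        pairs = {mk: lg for lg, members in self.groups.items()
                 for mk in members}
        return pd.Series(pairs, name="lg")


def group_markers(lod: PairwiseLODMatrix, lod_threshold: float = 5.0
                  ) -> Grouping:
    """Single-linkage grouping: connected components at LOD >= threshold.

    Components of size 1 are singletons.  Groups are numbered LG01, LG02,
    ... by descending member count (ties by smallest member ID).
    """
    ids = lod.ids
    adj = lod.lod >= lod_threshold
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj)
    comps = [sorted(str(ids[i]) for i in c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    groups, singles = {}, []
    for comp in comps:
        if len(comp) == 1:
            singles.append(comp[0])
        else:
            groups[f"LG{len(groups) + 1:02d}"] = comp
    singles.sort()
    return Grouping(groups=groups, singletons=singles,
                    lod_threshold=lod_threshold)


def join_singles(grouping: Grouping, lod: PairwiseLODMatrix,
                 lod_min: float = 5.0, lod_margin: float = 0.0) -> Grouping:
    """Attach singletons to the group holding their uniquely best LOD.

    A singleton joins iff its best group-wise LOD (max over members) is at
    least ``lod_min`` and exceeds the second-best group by more than
    ``lod_margin`` (default: any positive margin, so exact ties stay
    single).  Iterates to a fixpoint so newly joined markers can recruit
    further singletons.
    """
    lod_df = lod.lod_frame()
    groups = {lg: list(members) for lg, members in grouping.groups.items()}
    singles = list(grouping.singletons)
    changed = True
    while changed and singles:
        changed = False
        remaining = []
        for mk in singles:
            best = {lg: float(lod_df.loc[mk, members].max())
                    for lg, members in groups.items()}
            if not best:
                remaining.append(mk)
                continue
            ranked = sorted(best.items(), key=lambda kv: -kv[1])
            top_lg, top = ranked[0]
            second = ranked[1][1] if len(ranked) > 1 else -np.inf
            if top >= lod_min and top - second > lod_margin:
                groups[top_lg].append(mk)
                groups[top_lg].sort()
                changed = True
            else:
                remaining.append(mk)
        singles = remaining
    # re-number by size after joining
    ordered = sorted(groups.values(), key=lambda c: (-len(c), c[0]))
    renumbered = {f"LG{i + 1:02d}": members
                  for i, members in enumerate(ordered)}
    return Grouping(groups=renumbered, singletons=singles,
                    lod_threshold=grouping.lod_threshold)
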