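"""Assembling ordered groups into a linkage map with Kosambi positions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grouping import CosegregationBins
from .ordering import OrderedGroup
from .twopoint import MapFunctionParams, PairwiseLODMatrix, map_distance


@dataclass
class LinkageMap:
    """An assembled genetic map.

    ``entries`` has one row per mapped marker: marker_id, lg, position_cM,
    bin_id, is_representative, error_prone.  Positions are within-LG,
    0-anchored, non-decreasing; co-segregating bin members sit at their
    representative's position.
    """
    entries: pd.DataFrame

    def __post_init__(self):
        cols = {"marker_id", "lg", "position_cM"}
        if not cols.issubset(self.entries.columns):
            raise ValueError(f"map entries need columns {sorted(cols)}")
        for lg, grp in self.entries.groupby("lg", sort=False):
            if np.any(np.diff(grp["position_cM"].to_numpy()) < -1e-9):
                raise ValueError(f"positions decrease within {lg}")

    @property
    def lg_ids(self) -> list:
        return sorted(self.entries["lg"].unique())

    @property
    def lg_lengths(self) -> pd.Series:
        return self.entries.groupby("lg")["position_cM"].max()

    @property
    def total_length(self) -> float:
        return float(self.lg_lengths.sum())

    @property
    def n_markers(self) -> int:
        return len(self.entries)

    def marker_counts(self) -> pd.Series:
        return self.entries.groupby("lg").size()

    def positions(self, lg) -> np.ndarray:
        sel = self.entries.loc[self.entries["lg"] == lg, "position_cM"]
        return sel.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()


def assemble_map(ordered_groups: list[OrderedGroup],
                 pairwise: PairwiseLODMatrix,
                 bins: CosegregationBins | None = None,
                 params: MapFunctionParams = MapFunctionParams(),
                 error_prone: dict | None = None) -> LinkageMap:
    """Cumulative map positions from adjacent recombination fractions.

    For each ordered group the position of marker t is the cumulative sum of
    map-function distances of adjacent r_hat; uninformative pairs contribute
    ``params.default_r``.  Bin members are placed at their representative's
    position with zero-length intervals.
    """
    idx = {str(m): i for i, m in enumerate(pairwise.ids)}
    error_prone = error_prone or {}
    rows = []
    for og in ordered_groups:
        mks = [str(m) for m in og.markers]
        if len(mks) == 1:
            positions = np.array([0.0])
        else:
            ii = [idx[m] for m in mks]
            r_adj = np.array([pairwise.r[a, b]
                              for a, b in zip(ii[:-1], ii[1:])])
            r_adj = np.minimum(r_adj, params.r_cap)
            d_adj = np.atleast_1d(map_distance(r_adj, params))
            positions = np.concatenate([[0.0], np.cumsum(d_adj)])
        flagged = set(error_prone.get(og.lg_id, ()))
        for mk, pos in zip(mks, positions):
            if bins is not None and mk in bins.assignment.index:
                bin_id = bins.assignment[mk]
                for member in bins.members(bin_id):
                    rows.append((str(member), og.lg_id, float(pos), bin_id,
                                 str(member) == mk, str(member) in flagged))
            else:
                rows.append((mk, og.lg_id, float(pos), None, True,
                             mk in flagged))
    entries = pd.DataFrame(rows, columns=["marker_id", "lg", "position_cM",
                                          "bin_id", "is_representative",
                                          "error_prone"])
    entries = entries.sort_values(["lg", "position_cM", "marker_id"],
                                  kind="stable").reset_index(drop=True)
    return LinkageMap(entries=entries)
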