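"""Map statistics: framework extraction, intervals, Poisson blocks, synteny.

A high-density map built at n = 139 gametes carries many co-segregating
markers; the *framework map* keeps one randomly chosen marker per
co-segregation bin and is re-ordered from scratch.  The remaining
statistics characterise marker spacing (adjacent intervals, max gaps),
test whether markers are Poisson-distributed over 10 cM blocks, and
measure order concordance (synteny) between two maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import CosegregationBins
from .mapbuild import LinkageMap


# ---------------------------------------------------------------------------
# framework selection
# ---------------------------------------------------------------------------

def select_framework_markers(bins: CosegregationBins, seed: int = 0) -> list:
    """One marker per co-segregation bin, chosen uniformly at random.

    The selected set defines the framework map; the caller re-orders and
    re-assembles it from scratch (see ``LinkageMapResults.framework``).
    """
    rng = np.random.default_rng(seed)
    chosen = []
    for bin_id in bins.representatives.index:
        members = sorted(str(m) for m in bins.members(bin_id))
        chosen.append(members[int(rng.integers(0, len(members)))])
    return sorted(chosen)


# ---------------------------------------------------------------------------
# interval statistics
# ---------------------------------------------------------------------------

@dataclass
class IntervalStats:
    """Adjacent-interval statistics of a map."""
    per_lg: pd.DataFrame       # lg, n_markers, length_cM, max_gap_cM,
                               # mean_interval_cM
    n_intervals: int
    n_below: int               # intervals < below_cutoff
    n_above: int               # intervals > above_cutoff
    below_cutoff: float
    above_cutoff: float

    @property
    def pct_below(self) -> float:
        return 100.0 * self.n_below / self.n_intervals if self.n_intervals else 0.0

    @property
    def pct_above(self) -> float:
        return 100.0 * self.n_above / self.n_intervals if self.n_intervals else 0.0


def mean_interval(length_cM: float, n_markers: int) -> float:
    """Mean adjacent interval of an LG: length / (marker count - 1)."""
    if n_markers < 2:
        return float("nan")
    return length_cM / (n_markers - 1)


def interval_stats(lmap: LinkageMap, below_cutoff: float = 0.2,
                   above_cutoff: float = 1.0) -> IntervalStats:
    """Adjacent intervals within each LG over all mapped markers.

    Co-segregating bin members contribute zero-length intervals.  The
    global interval count is sum(markers - 1) over LGs.
    """
    rows, all_intervals = [], []
    for lg in lmap.lg_ids:
        pos = np.sort(lmap.positions(lg))
        gaps = np.diff(pos)
        all_intervals.append(gaps)
        rows.append((lg, len(pos), float(pos[-1]) if len(pos) else 0.0,
                     float(gaps.max()) if len(gaps) else 0.0,
                     mean_interval(float(pos[-1]), len(pos))))
    per_lg = pd.DataFrame(rows, columns=["lg", "n_markers", "length_cM",
                                         "max_gap_cM", "mean_interval_cM"])
    gaps = np.concatenate(all_intervals) if all_intervals else np.empty(0)
    return IntervalStats(per_lg=per_lg, n_intervals=len(gaps),
                         n_below=int((gaps < below_cutoff).sum()),
                         n_above=int((gaps > above_cutoff).sum()),
                         below_cutoff=below_cutoff, above_cutoff=above_cutoff)


# ---------------------------------------------------------------------------
# Poisson block distribution
# ---------------------------------------------------------------------------

@dataclass
class BlockDistribution:
    """Markers-per-block frequency distribution vs the Poisson expectation.

    Blocks are half-open [k*B, (k+1)*B) windows anchored at 0 within each
    LG; the final partial block is included.  mu is the pooled mean marker
    count per block; expected class frequencies are n_blocks * pmf(x; mu).
    """
    block_cM: float
    n_blocks: int
    mu: float
    per_block: pd.DataFrame    # lg, block_index, start_cM, end_cM, n_markers
    classes: pd.DataFrame      # count_class, observed, expected (tail pooled)
    gof_chi2: float
    gof_df: int
    gof_p: float


def _pool_tail(observed: np.ndarray, expected: np.ndarray,
               min_expected: float = 5.0):
    """Pool high-count classes from the top until each expected >= min.

    Keeps at least two classes; the last kept class absorbs the full upper
    tail (observed and expected).
    """
    obs = observed.astype(float).copy()
    exp = expected.astype(float).copy()
    while len(exp) > 2 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        obs, exp = obs[:-1], exp[:-1]
    return obs, exp


def block_distribution(lmap: LinkageMap, block_cM: float = 10.0,
                       min_expected: float = 5.0) -> BlockDistribution:
    """Marker counts per block pooled over LGs, with a Poisson GOF test.

    The goodness-of-fit chi-square pools upper-tail count classes so every
    expected frequency is at least ``min_expected``; df = classes - 2 (one
    df lost to the total, one to estimating mu).
    """
    block_rows = []
    for lg in lmap.lg_ids:
        pos = np.sort(lmap.positions(lg))
        length = float(pos[-1]) if len(pos) else 0.0
        n_blocks = max(1, int(np.ceil(length / block_cM)))
        if length > 0 and length % block_cM == 0:
            n_blocks = int(length // block_cM)
        idx = np.minimum((pos // block_cM).astype(int), n_blocks - 1)
        counts = np.bincount(idx, minlength=n_blocks)
        for b in range(n_blocks):
            block_rows.append((lg, b, b * block_cM,
                               min((b + 1) * block_cM, length),
                               int(counts[b])))
    per_block = pd.DataFrame(block_rows, columns=["lg", "block_index",
                                                  "start_cM", "end_cM",
                                                  "n_markers"])
    counts = per_block["n_markers"].to_numpy()
    n_blocks = len(counts)
    mu = counts.mean() if n_blocks else 0.0

    max_count = int(counts.max()) if n_blocks else 0
    xs = np.arange(max_count + 1)
    observed = np.bincount(counts, minlength=max_count + 1).astype(float)
    pmf = stats.poisson.pmf(xs, mu)
    pmf[-1] = stats.poisson.sf(max_count - 1, mu) if max_count else 1.0
    expected = n_blocks * pmf

    obs_p, exp_p = _pool_tail(observed, expected, min_expected)
    df = max(len(obs_p) - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((obs_p - exp_p) ** 2 / exp_p))
    p = float(stats.chi2.sf(chi2, df))
    classes = pd.DataFrame({"count_class": np.arange(len(obs_p)),
                            "observed": obs_p, "expected": exp_p})
    return BlockDistribution(block_cM=block_cM, n_blocks=n_blocks,
                             mu=float(mu), per_block=per_block,
                             classes=classes, gof_chi2=chi2, gof_df=df,
                             gof_p=p)


def poisson_pmf(x, mu: float):
    """P(x) = e^-mu mu^x / x! — expected marker-count frequencies."""
    return stats.poisson.pmf(x, mu)


# ---------------------------------------------------------------------------
# map comparison (synteny)
# ---------------------------------------------------------------------------

@dataclass
class MapComparison:
    """Order concordance between two maps on their shared markers."""
    n_shared: int
    lg_pairs: pd.DataFrame     # lg_a, lg_b, n_shared, spearman, reversed
    links: pd.DataFrame        # marker_id, lg_a, pos_a, lg_b, pos_b

    @property
    def mean_spearman(self) -> float:
        vals = self.lg_pairs["spearman"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")


def compare_maps(map_a: LinkageMap, map_b: LinkageMap,
                 method: str = "spearman") -> MapComparison:
    """Match LGs by shared-marker majority and score order concordance.

    Each matched LG of ``map_b`` is oriented (possibly reversed) to
    maximise the rank correlation with ``map_a``; the reported correlation
    is therefore non-negative for any monotone relationship.
    """
    if method not in ("spearman", "kendall"):
        raise ValueError("method must be 'spearman' or 'kendall'")
    a = map_a.entries.set_index("marker_id")
    b = map_b.entries.set_index("marker_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        warnings.warn("no shared markers between maps", stacklevel=2)
        empty = pd.DataFrame(columns=["lg_a", "lg_b", "n_shared",
                                      "spearman", "reversed"])
        links = pd.DataFrame(columns=["marker_id", "lg_a", "pos_a",
                                      "lg_b", "pos_b"])
        return MapComparison(n_shared=0, lg_pairs=empty, links=links)

    links = pd.DataFrame({
        "marker_id": shared,
        "lg_a": a.loc[shared, "lg"].to_numpy(),
        "pos_a": a.loc[shared, "position_cM"].to_numpy(),
        "lg_b": b.loc[shared, "lg"].to_numpy(),
        "pos_b": b.loc[shared, "position_cM"].to_numpy(),
    })
    corr_fn = stats.spearmanr if method == "spearman" else stats.kendalltau
    rows = []
    for lg_a, grp in links.groupby("lg_a"):
        lg_b = grp["lg_b"].mode().iloc[0]  # majority partner
        sub = grp[grp["lg_b"] == lg_b]
        if len(sub) < 2 or sub["pos_a"].nunique() < 2 \
                or sub["pos_b"].nunique() < 2:
            rho, rev = np.nan, False
        else:
            rho = float(corr_fn(sub["pos_a"], sub["pos_b"]).statistic)
            rev = rho < 0
            rho = abs(rho)  # orientation chosen to maximise correlation
        rows.append((lg_a, lg_b, len(sub), rho, rev))
    lg_pairs = pd.DataFrame(rows, columns=["lg_a", "lg_b", "n_shared",
                                           "spearman", "reversed"])
    return MapComparison(n_shared=len(shared), lg_pairs=lg_pairs, links=links)


# ---------------------------------------------------------------------------
# summary table (full + framework map, per-LG and totals)
# ---------------------------------------------------------------------------

def map_inflation_percent(full_length: float, framework_length: float) -> float:
    """Percent map-length inflation of the full map over the framework."""
    return 100.0 * (full_length - framework_length) / framework_length


def map_summary(full_map: LinkageMap,
                framework_map: LinkageMap | None = None) -> pd.DataFrame:
    """Per-LG summary table with a totals row.

    Columns mirror the customary linkage-map summary: full-map length,
    marker number and max gap per LG; framework marker number, length and
    mean adjacent interval.  The totals row sums lengths and counts; its
    mean-interval entry uses (total markers - n LGs) intervals.
    """
    full_stats = interval_stats(full_map).per_lg.set_index("lg")
    rows = []
    fw_stats = None
    if framework_map is not None:
        fw_stats = interval_stats(framework_map).per_lg.set_index("lg")
    for lg in full_stats.index:
        row = {
            "lg": lg,
            "length_cM": full_stats.loc[lg, "length_cM"],
            "n_markers": int(full_stats.loc[lg, "n_markers"]),
            "max_gap_cM": full_stats.loc[lg, "max_gap_cM"],
        }
        if fw_stats is not None and lg in fw_stats.index:
            row.update({
                "fw_n_markers": int(fw_stats.loc[lg, "n_markers"]),
                "fw_length_cM": fw_stats.loc[lg, "length_cM"],
                "fw_mean_interval_cM": fw_stats.loc[lg, "mean_interval_cM"],
            })
        rows.append(row)
    table = pd.DataFrame(rows)
    totals = {"lg": "Total",
              "length_cM": table["length_cM"].sum(),
              "n_markers": int(table["n_markers"].sum()),
              "max_gap_cM": np.nan}
    if fw_stats is not None:
        n_fw = int(table["fw_n_markers"].sum())
        len_fw = float(table["fw_length_cM"].sum())
        n_lgs = len(table)
        totals.update({
            "fw_n_markers": n_fw,
            "fw_length_cM": len_fw,
            "fw_mean_interval_cM":
                len_fw / (n_fw - n_lgs) if n_fw > n_lgs else np.nan,
        })
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)
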