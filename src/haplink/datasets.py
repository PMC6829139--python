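"""Published reference figures used as worked-example inputs.

The high-density ddRAD linkage map of *Platycladus orientalis* (11
chromosomes, single mother tree, 139 megagametophytes) is the reference
design this package emulates.  Its published per-LG summary is embedded
here as *input data* for worked examples and consistency checks — the
package recomputes every derived figure (totals, means, inflation,
interval percentages) from these per-LG rows rather than trusting the
printed derived values.
"""

from __future__ import annotations

import pandas as pd

# Per-LG summary of the published P. orientalis map: full-set map
# (length, marker count, max gap) and framework map (marker count, length,
# mean adjacent interval).
_PORIENTALIS_ROWS = [
    # lg, full_length_cM, full_n, full_max_gap_cM, fw_n, fw_length_cM, fw_mean
    ("LG01", 176.34, 2902, 7.2, 953, 173.19, 0.18),
    ("LG02", 137.47, 2466, 5.9, 843, 135.37, 0.16),
    ("LG03", 142.05, 2394, 7.9, 862, 143.26, 0.17),
    ("LG04", 148.15, 2218, 7.0, 637, 136.29, 0.21),
    ("LG05", 137.29, 2178, 8.2, 805, 132.47, 0.16),
    ("LG06", 124.62, 2121, 9.3, 416, 114.61, 0.28),
    ("LG07", 151.43, 2033, 4.9, 650, 126.75, 0.20),
    ("LG08", 108.35, 1951, 6.3, 641, 102.29, 0.16),
    ("LG09", 129.97, 1933, 9.3, 610, 136.41, 0.22),
    ("LG10", 129.78, 1883, 16.5, 466, 126.01, 0.27),
    ("LG11", 121.31, 1847, 6.6, 676, 116.13, 0.17),
]

#: Published locus-funnel counts for the same study population.
PORIENTALIS_FUNNEL = {
    "total_loci": 397_226,
    "polymorphic": 108_683,
    "monomorphic": 288_226,
    "repetitive": 317,
    "mother_concordant": 45_959,
    "mapped": 23_926,
}

#: Published adjacent-interval tallies on the full-set map.
PORIENTALIS_INTERVALS = {
    "n_intervals": 23_915,        # 23,926 markers - 11 LGs
    "n_below_0.2cM": 23_012,
    "n_above_1cM": 406,
}


def porientalis_map_summary() -> pd.DataFrame:
    """Per-LG summary rows of the published P. orientalis linkage map."""
    return pd.DataFrame(_PORIENTALIS_ROWS,
                        columns=["lg", "full_length_cM", "full_n_markers",
                                 "full_max_gap_cM", "fw_n_markers",
                                 "fw_length_cM", "fw_mean_interval_cM"])


def porientalis_lg_lengths(which: str = "framework") -> tuple:
    """LG lengths (cM) of the published map; the framework lengths are the
    default genome shape for simulation."""
    col = {"framework": "fw_length_cM", "full": "full_length_cM"}[which]
    return tuple(porientalis_map_summary()[col])
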