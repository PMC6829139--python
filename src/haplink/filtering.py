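"""Locus classification and the pre-mapping filter funnel.

Haploid gametes at a true single-copy locus can only show the mother's two
alleles, so the observed allele count classifies each locus directly:
1 allele = monomorphic, 2 = polymorphic, >2 = repetitive (collapsed
paralogues).  Polymorphic loci are then screened for concordance with the
mother's heterozygous genotype, missing rate, and 1:1 segregation
(chi-square at alpha = 0.05, 1 df, no continuity correction, no
multiple-testing adjustment).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import HaploidGenotypeMatrix, MotherGenotype

logger = logging.getLogger(__name__)

MONOMORPHIC = "monomorphic"
POLYMORPHIC = "polymorphic"
REPETITIVE = "repetitive"


@dataclass
class FilterConfig:
    """Thresholds for the locus filter funnel."""
    missing_threshold: float = 0.20
    missing_comparator: str = "le"   # "le": keep <= threshold; "lt": keep <
    segregation_alpha: float = 0.05
    exact_binomial: bool = False     # exact test instead of chi-square

    def __post_init__(self):
        if not 0.0 < self.missing_threshold <= 1.0:
            raise ValueError("missing threshold must lie in (0, 1]")
        if self.missing_comparator not in ("le", "lt"):
            raise ValueError("missing comparator must be 'le' or 'lt'")


@dataclass
class FilterReport:
    """Locus counts at each stage of the funnel."""
    total: int = 0
    monomorphic: int = 0
    polymorphic: int = 0
    repetitive: int = 0
    all_missing: int = 0
    mother_concordant: int = 0
    pass_missing: int = 0
    pass_segregation: int = 0

    def as_dict(self) -> dict:
        return asdict(self)

    def log_lines(self) -> list[str]:
        """The funnel in narrative order for side-by-side comparison."""
        return [
            f"total loci: {self.total}",
            f"  polymorphic: {self.polymorphic}  "
            f"monomorphic: {self.monomorphic}  repetitive: {self.repetitive}"
            + (f"  all-missing: {self.all_missing}" if self.all_missing else ""),
            f"  concordant with mother genotype: {self.mother_concordant}",
            f"  passing missing-rate filter: {self.pass_missing}",
            f"  passing 1:1 segregation test: {self.pass_segregation}",
        ]


def classify_loci(matrix: HaploidGenotypeMatrix) -> pd.Series:
    """Classify each locus by its distinct non-missing allele count.

    Loci with zero non-missing calls are excluded from the result with a
    warning (they carry no information at all).
    """
    counts = matrix.n_alleles()
    empty = counts.index[counts == 0]
    if len(empty):
        warnings.warn(f"{len(empty)} loci have no non-missing calls; "
                      "excluded from classification", stacklevel=2)
    counts = counts.drop(empty)
    labels = pd.Series(
        np.select([counts == 1, counts == 2], [MONOMORPHIC, POLYMORPHIC],
                  default=REPETITIVE),
        index=counts.index, name="locus_class")
    return labels


def mother_concordance_filter(matrix: HaploidGenotypeMatrix,
                              loci, mother: MotherGenotype) -> pd.Index:
    """Keep polymorphic loci whose two gamete alleles equal the mother's
    heterozygous pair as a set.  Loci with unknown mother genotype are
    dropped; so are loci where the mother is homozygous (two observed gamete
    alleles there indicate genotyping error or collapsed paralogy).
    """
    observed = matrix.subset(loci=loci).observed_alleles()
    kept = [loc for loc, alleles in observed.items()
            if mother.pair(loc) is not None and mother.pair(loc) == alleles]
    return pd.Index(kept)


def missing_rate_filter(matrix: HaploidGenotypeMatrix, loci,
                        threshold: float = 0.20,
                        comparator: str = "le") -> pd.Index:
    """Keep loci whose missing fraction passes the threshold (<= or <)."""
    rates = matrix.subset(loci=loci).missing_rate()
    keep = rates <= threshold if comparator == "le" else rates < threshold
    return rates.index[keep]


def segregation_test_table(matrix: HaploidGenotypeMatrix, loci,
                           alpha: float = 0.05,
                           exact: bool = False) -> pd.DataFrame:
    """Per-locus 1:1 segregation test on non-missing calls.

    chi2 = (n1 - n2)^2 / (n1 + n2) with 1 df; the exact alternative is a
    two-sided binomial test at p = 1/2.  decision is "discard" iff
    p <= alpha.  Loci with zero informative calls are dropped with a warning.
    """
    sub = matrix.subset(loci=loci)
    rows = []
    for loc in sub.loci:
        vals = sub.calls.loc[loc].dropna()
        counts = vals.value_counts()
        if len(counts) == 0:
            warnings.warn(f"locus {loc!r} has no calls at segregation stage; "
                          "dropped", stacklevel=2)
            continue
        if len(counts) > 2:
            raise ValueError(f"locus {loc!r} is not biallelic at "
                             "segregation stage")
        n1 = int(counts.iloc[0])
        n2 = int(counts.iloc[1]) if len(counts) == 2 else 0
        chi2 = (n1 - n2) ** 2 / (n1 + n2)
        if exact:
            p = stats.binomtest(n1, n1 + n2, 0.5).pvalue
        else:
            p = float(stats.chi2.sf(chi2, df=1))
        rows.append((loc, n1, n2, chi2, p,
                     "discard" if p <= alpha else "keep"))
    return pd.DataFrame(rows, columns=["marker_id", "n1", "n2", "chi2", "p",
                                       "decision"]).set_index("marker_id")


def segregation_filter(matrix: HaploidGenotypeMatrix, loci,
                       alpha: float = 0.05,
                       exact: bool = False) -> tuple[pd.Index, pd.DataFrame]:
    """Discard loci with significant segregation distortion (p <= alpha)."""
    table = segregation_test_table(matrix, loci, alpha=alpha, exact=exact)
    kept = table.index[table["decision"] == "keep"]
    return kept, table


def run_filter_funnel(matrix: HaploidGenotypeMatrix, mother: MotherGenotype,
                      config: FilterConfig = FilterConfig()
                      ) -> tuple[HaploidGenotypeMatrix, FilterReport,
                                 pd.DataFrame]:
    """classify -> mother concordance -> missing rate -> 1:1 segregation.

    The per-locus filters are independent, so the final set does not depend
    on their order; the narrative order above is fixed for reporting.
    Returns the filtered matrix, the funnel report, and the segregation
    test table.
    """
    report = FilterReport(total=matrix.n_loci)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = classify_loci(matrix)
    report.all_missing = matrix.n_loci - len(labels)
    report.monomorphic = int((labels == MONOMORPHIC).sum())
    report.polymorphic = int((labels == POLYMORPHIC).sum())
    report.repetitive = int((labels == REPETITIVE).sum())

    poly = labels.index[labels == POLYMORPHIC]
    concordant = mother_concordance_filter(matrix, poly, mother)
    report.mother_concordant = len(concordant)

    low_missing = missing_rate_filter(matrix, concordant,
                                      threshold=config.missing_threshold,
                                      comparator=config.missing_comparator)
    report.pass_missing = len(low_missing)

    kept, seg_table = segregation_filter(matrix, low_missing,
                                         alpha=config.segregation_alpha,
                                         exact=config.exact_binomial)
    report.pass_segregation = len(kept)
    for line in report.log_lines():
        logger.info(line)
    return matrix.subset(loci=kept), report, seg_table
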