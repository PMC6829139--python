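"""Core in-memory containers for haploid genotype data.

A megagametophyte panel is a loci x gametes table of single-allele calls:
each gamete is one meiotic product of the mother tree, so at a heterozygous
maternal locus it carries exactly one of the mother's two alleles.  Allele
codes are opaque string labels; missing calls are ``None``/NaN in memory and
``"."`` on disk.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "."


class HaploidGenotypeMatrix:
    """Loci x gametes matrix of haploid allele calls with a missing mask.

    Parameters
    ----------
    calls : pandas.DataFrame
        Rows indexed by unique marker IDs, columns by unique gamete IDs.
        Values are allele labels (strings); missing calls are NaN/None.
    """

    def __init__(self, calls: pd.DataFrame):
        if calls.index.has_duplicates:
            dups = calls.index[calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate marker IDs: {dups[:5]}")
        if calls.columns.has_duplicates:
            dups = calls.columns[calls.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gamete IDs: {dups[:5]}")
        self.calls = calls.astype(object).where(calls.notna(), other=np.nan)

    # -- basic geometry -------------------------------------------------
    @property
    def loci(self) -> pd.Index:
        return self.calls.index

    @property
    def gametes(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_loci(self) -> int:
        return self.calls.shape[0]

    @property
    def n_gametes(self) -> int:
        return self.calls.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<HaploidGenotypeMatrix {self.n_loci} loci x "
                f"{self.n_gametes} gametes>")

    # -- derived per-locus statistics -----------------------------------
    def missing_mask(self) -> pd.DataFrame:
        return self.calls.isna()

    def missing_rate(self) -> pd.Series:
        """Per-locus fraction of missing calls over all gametes."""
        return self.calls.isna().mean(axis=1)

    def observed_alleles(self) -> pd.Series:
        """Per-locus frozenset of distinct non-missing alleles."""
        return self.calls.apply(
            lambda row: frozenset(row.dropna().tolist()), axis=1)

    def n_alleles(self) -> pd.Series:
        return self.calls.apply(lambda row: row.dropna().nunique(), axis=1)

    def subset(self, loci: Sequence | None = None,
               gametes: Sequence | None = None) -> "HaploidGenotypeMatrix":
        calls = self.calls
        if loci is not None:
            calls = calls.loc[list(loci)]
        if gametes is not None:
            calls = calls[list(gametes)]
        return HaploidGenotypeMatrix(calls)

    # -- numeric encoding for linkage computations ----------------------
    def encode_biallelic(self, loci: Iterable | None = None
                         ) -> tuple[np.ndarray, pd.DataFrame]:
        """Encode biallelic loci as an int8 array (0/1 alleles, -1 missing).

        The 0/1 coding per locus is arbitrary (alleles sorted lexically);
        two-point estimation is phase-minimised so the coding never matters.

        Returns
        -------
        X : (n_loci, n_gametes) int8 array
        allele_map : DataFrame indexed by locus with columns allele0, allele1
        """
        sub = self.calls if loci is None else self.calls.loc[list(loci)]
        n, g = sub.shape
        X = np.full((n, g), -1, dtype=np.int8)
        a0, a1 = [], []
        values = sub.to_numpy(dtype=object)
        for i in range(n):
            row = values[i]
            present = [v for v in row if isinstance(v, str)]
            alleles = sorted(set(present))
            if len(alleles) != 2:
                raise ValueError(
                    f"locus {sub.index[i]!r} is not biallelic "
                    f"({len(alleles)} alleles observed)")
            lookup = {alleles[0]: 0, alleles[1]: 1}
            X[i] = [lookup[v] if isinstance(v, str) else -1 for v in row]
            a0.append(alleles[0])
            a1.append(alleles[1])
        allele_map = pd.DataFrame({"allele0": a0, "allele1": a1},
                                  index=sub.index)
        return X, allele_map


class MotherGenotype:
    """Diploid mother-tree genotype: an unordered allele pair per locus.

    Loci absent from the table, or with a missing allele, are UNKNOWN.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"allele1", "allele2"}
        if not required.issubset(table.columns):
            raise ValueError("mother table needs columns allele1, allele2")
        if table.index.has_duplicates:
            raise ValueError("duplicate marker IDs in mother table")
        self.table = table[["allele1", "allele2"]].astype(object)

    def pair(self, locus) -> frozenset | None:
        """The allele pair as a set, or None if unknown."""
        if locus not in self.table.index:
            return None
        a1, a2 = self.table.loc[locus, "allele1"], self.table.loc[locus, "allele2"]
        if not isinstance(a1, str) or not isinstance(a2, str):
            return None
        return frozenset((a1, a2))

    def is_heterozygous(self, locus) -> bool:
        p = self.pair(locus)
        return p is not None and len(p) == 2

    @property
    def loci(self) -> pd.Index:
        return self.table.index
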