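"""The LinkageMapper model and its fitted results.

``LinkageMapper`` holds the observed data (haploid genotype matrix +
mother genotype) and the pipeline configuration; ``fit()`` runs the full
estimation — filter funnel, co-segregation binning, pairwise two-point
estimation, LOD grouping, singleton joining, stochastic ordering with
best-of-n selection, error-prone-locus removal, and Kosambi map assembly —
and returns a ``LinkageMapResults`` carrying the map, diagnostics and
summary tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .filtering import FilterConfig, FilterReport, run_filter_funnel
from .grouping import (CosegregationBins, Grouping, collapse_cosegregating,
                       group_markers, join_singles)
from .mapbuild import LinkageMap, assemble_map
from .matrix import HaploidGenotypeMatrix, MotherGenotype
from .ordering import OrderedGroup, detect_error_prone, order_markers
from .twopoint import MapFunctionParams, pairwise_two_point


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the mapping pipeline.

    Defaults are the reference single-tree megagametophyte protocol:
    missing rate <= 0.20, 1:1 segregation at alpha = 0.05, grouping and
    singleton joining at LOD 5, 10 ordering runs, error-rate flag at 0.3,
    default r = 0.4 for uninformative pairs, Kosambi conversion, 10 cM
    blocks for the marker-distribution test.
    """
    missing_threshold: float = 0.20
    missing_comparator: str = "le"
    segregation_alpha: float = 0.05
    exact_binomial: bool = False
    grouping_lod: float = 5.0
    join_singles_lod: float = 5.0
    join_singles_margin: float = 0.0
    ordering_runs: int = 10
    error_rate_threshold: float = 0.3
    map_function: str = "kosambi"
    default_r: float = 0.4
    r_cap: float = 0.4999
    n_min_overlap: int = 20
    bin_n_min: int = 20
    block_cM: float = 10.0
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(missing_threshold=self.missing_threshold,
                            missing_comparator=self.missing_comparator,
                            segregation_alpha=self.segregation_alpha,
                            exact_binomial=self.exact_binomial)

    def map_params(self) -> MapFunctionParams:
        return MapFunctionParams(function=self.map_function,
                                 r_cap=self.r_cap, default_r=self.default_r)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class LinkageMapper:
    """Single-family haploid linkage-mapping model.

    Parameters
    ----------
    matrix : HaploidGenotypeMatrix
        Loci x gametes single-allele calls (one meiotic product per gamete).
    mother : MotherGenotype
        Diploid mother genotype used to validate polymorphic loci.
    config : PipelineConfig, optional

    Examples
    --------
    >>> model = LinkageMapper(matrix, mother)
    >>> res = model.fit(seed=1)
    >>> res.map_.total_length
    >>> print(res.summary())
    """

    def __init__(self, matrix: HaploidGenotypeMatrix,
                 mother: MotherGenotype,
                 config: PipelineConfig | None = None):
        self.matrix = matrix
        self.mother = mother
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, calls: pd.DataFrame, mother: pd.DataFrame,
                       config: PipelineConfig | None = None
                       ) -> "LinkageMapper":
        return cls(HaploidGenotypeMatrix(calls), MotherGenotype(mother),
                   config=config)

    @classmethod
    def from_tsv(cls, genotype_path, mother_path,
                 config: PipelineConfig | None = None) -> "LinkageMapper":
        from .io import read_genotypes, read_mother
        return cls(read_genotypes(genotype_path),
                   read_mother(mother_path), config=config)

    # -- estimation -----------------------------------------------------
    def fit(self, seed: int | None = None,
            skip_filters: bool = False) -> "LinkageMapResults":
        """Run the full pipeline and return the fitted results.

        ``skip_filters`` maps a matrix that is already filtered/biallelic
        (used when re-fitting framework marker subsets).
        """
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        if skip_filters:
            filtered, report, seg_table = self.matrix, None, None
        else:
            filtered, report, seg_table = run_filter_funnel(
                self.matrix, self.mother, cfg.filter_config())
        if filtered.n_loci < 2:
            raise ValueError("fewer than two loci survive filtering")

        X, allele_map = filtered.encode_biallelic()
        ids = filtered.loci
        bins = collapse_cosegregating(X, ids, n_min=cfg.bin_n_min)
        rep_ids = [str(m) for m in bins.representatives]
        rep_pos = {str(m): i for i, m in enumerate(ids)}
        X_rep = X[[rep_pos[m] for m in rep_ids]]

        pairwise = pairwise_two_point(X_rep, ids=rep_ids,
                                      default_r=cfg.default_r,
                                      n_min=cfg.n_min_overlap)
        grouping = group_markers(pairwise, lod_threshold=cfg.grouping_lod)
        if grouping.singletons:
            grouping = join_singles(grouping, pairwise,
                                    lod_min=cfg.join_singles_lod,
                                    lod_margin=cfg.join_singles_margin)

        lod_frame = pairwise.lod_frame()
        rng = np.random.default_rng(seed)
        ordered, error_flags = [], {}
        for lg_id in sorted(grouping.groups):
            members = grouping.groups[lg_id]
            lg_seed = int(rng.integers(0, 2 ** 31 - 1))
            og = order_markers(members, lod_frame,
                               n_runs=cfg.ordering_runs, seed=lg_seed,
                               lg_id=lg_id)
            flagged = self._error_prone(og, X_rep, rep_ids, pairwise)
            if flagged:
                keep = [m for m in og.markers if m not in flagged]
                if len(keep) >= 2:
                    og = order_markers(keep, lod_frame,
                                       n_runs=cfg.ordering_runs,
                                       seed=lg_seed, lg_id=lg_id)
                error_flags[lg_id] = flagged
            ordered.append(og)

        lmap = assemble_map(ordered, pairwise, bins=bins,
                            params=cfg.map_params())
        removed = sorted(m for fl in error_flags.values() for m in fl)
        lmap.entries = lmap.entries[~lmap.entries["marker_id"].isin(removed)]
        return LinkageMapResults(
            model=self, map_=lmap, filter_report=report,
            segregation_table=seg_table, bins=bins, pairwise=pairwise,
            grouping=grouping, ordered_groups=ordered,
            error_prone=error_flags, allele_map=allele_map,
            filtered_matrix=filtered, seed=seed)

    def _error_prone(self, og: OrderedGroup, X_rep, rep_ids, pairwise):
        if len(og.markers) < 3:
            return []
        rates = detect_error_prone(og.markers, X_rep, rep_ids,
                                   pairwise.phase_flipped,
                                   rate_threshold=self.config.error_rate_threshold)
        return sorted(rates.index[rates > self.config.error_rate_threshold])


@dataclass
class LinkageMapResults:
    """Fitted linkage map plus every diagnostic the fit produced."""
    model: LinkageMapper
    map_: LinkageMap
    filter_report: FilterReport | None
    segregation_table: pd.DataFrame | None
    bins: CosegregationBins
    pairwise: object
    grouping: Grouping
    ordered_groups: list
    error_prone: dict
    allele_map: pd.DataFrame
    filtered_matrix: HaploidGenotypeMatrix
    seed: int
    _framework_cache: dict = field(default_factory=dict, repr=False)

    # -- headline quantities --------------------------------------------
    @property
    def n_linkage_groups(self) -> int:
        return len(self.map_.lg_ids)

    @property
    def total_length(self) -> float:
        return self.map_.total_length

    def summary(self, framework: "LinkageMapResults | None" = None
                ) -> pd.DataFrame:
        """Per-LG summary table (with framework columns if provided)."""
        fw_map = framework.map_ if framework is not None else None
        return analysis.map_summary(self.map_, fw_map)

    def summary_text(self) -> str:
        lines = ["Haploid linkage map fit",
                 "=" * 47,
                 f"linkage groups : {self.n_linkage_groups}",
                 f"mapped markers : {self.map_.n_markers}",
                 f"total length   : {self.total_length:.2f} cM",
                 f"co-seg bins    : {self.bins.n_bins}"]
        if self.filter_report is not None:
            lines.append("filter funnel  :")
            lines += ["  " + l for l in self.filter_report.log_lines()]
        if self.error_prone:
            n = sum(len(v) for v in self.error_prone.values())
            lines.append(f"error-prone loci removed: {n}")
        return "\n".join(lines)

    # -- downstream analyses --------------------------------------------
    def interval_stats(self, below_cutoff: float = 0.2,
                       above_cutoff: float = 1.0) -> analysis.IntervalStats:
        return analysis.interval_stats(self.map_, below_cutoff, above_cutoff)

    def block_distribution(self, block_cM: float | None = None
                           ) -> analysis.BlockDistribution:
        if block_cM is None:
            block_cM = self.model.config.block_cM
        return analysis.block_distribution(self.map_, block_cM=block_cM)

    def framework(self, seed: int = 0) -> "LinkageMapResults":
        """Framework map: one random marker per co-segregation bin,
        re-ordered and re-assembled from scratch."""
        if seed in self._framework_cache:
            return self._framework_cache[seed]
        chosen = analysis.select_framework_markers(self.bins, seed=seed)
        sub = self.filtered_matrix.subset(loci=chosen)
        fw_model = LinkageMapper(sub, self.model.mother,
                                 config=self.model.config)
        res = fw_model.fit(seed=self.seed, skip_filters=True)
        self._framework_cache[seed] = res
        return res

    def compare(self, other: "LinkageMapResults",
                method: str = "spearman") -> analysis.MapComparison:
        return analysis.compare_maps(self.map_, other.map_, method=method)
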