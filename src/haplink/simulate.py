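"""Synthetic mapping populations: ground-truth maps, gametes, and noise.

The generator emulates a single-tree conifer megagametophyte design: one
heterozygous mother, n haploid gametes, 11 chromosomes totalling roughly
1,500 cM.  Each gamete starts every linkage group in a random parental
phase; each adjacent marker interval of length d cM recombines
independently with probability r = kosambi_inverse(d), so adjacent-interval
distances are exactly recoverable under the Kosambi conversion (no
higher-order interference model).

``degrade`` then injects the imperfections real ddRAD data carry —
monomorphic loci, repetitive (>2 allele) loci, mother-discordant loci,
allele-flip genotyping errors, missing calls, and optional segregation
distortion — recording every injection so downstream filters can be tested
against exact truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import HaploidGenotypeMatrix, MotherGenotype
from .twopoint import kosambi_inverse

#: Published per-LG framework map lengths (cM) for P. orientalis, used as
#: the default simulated genome shape (11 chromosomes, ~1,443 cM).
DEFAULT_LG_LENGTHS_CM = (173.19, 135.37, 143.26, 136.29, 132.47, 114.61,
                         126.75, 102.29, 136.41, 126.01, 116.13)
DEFAULT_N_GAMETES = 139


@dataclass(frozen=True)
class TrueMap:
    """Ground-truth marker map: LG lengths plus marker positions."""
    linkage_groups: tuple  # of (lg_id, length_cM)
    markers: pd.DataFrame  # marker_id, lg_id, position_cM (sorted within LG)

    def __post_init__(self):
        if len(self.linkage_groups) < 1:
            raise ValueError("need at least one linkage group")
        lengths = dict(self.linkage_groups)
        for lg, grp in self.markers.groupby("lg_id", sort=False):
            pos = grp["position_cM"].to_numpy()
            if np.any(pos < 0) or np.any(pos > lengths[lg] + 1e-9):
                raise ValueError(f"marker positions outside [0, L] on {lg}")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"marker positions not sorted on {lg}")

    @property
    def total_length(self) -> float:
        return float(sum(L for _, L in self.linkage_groups))

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class SimulationConfig:
    """Noise/degradation settings for a simulated dataset.

    Pool fractions are proportions of the locus pool converted to the named
    class; injection is by rounded count, not a per-locus coin flip, so the
    realised composition is exact.
    """
    n_gametes: int = DEFAULT_N_GAMETES
    frac_monomorphic: float = 0.0
    frac_repetitive: float = 0.0
    frac_mother_discordant: float = 0.0
    missing_rate: float = 0.0
    error_rate: float = 0.0
    distortion: tuple | None = None  # (locus_ids, viability_weight in (0,1])
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_monomorphic, self.frac_repetitive,
                 self.frac_mother_discordant)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("pool fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("pool fractions sum to more than 1")
        for name in ("missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_gametes < 2:
            raise ValueError("need at least two gametes")
        if self.distortion is not None:
            _, w = self.distortion
            if not 0.0 < w <= 1.0:
                raise ValueError("viability weight must lie in (0, 1]")


@dataclass
class SimulatedDataset:
    """A degraded matrix plus everything needed to check it against truth."""
    matrix: HaploidGenotypeMatrix
    mother: MotherGenotype
    truth: TrueMap
    truth_labels: pd.Series          # locus -> class label
    error_positions: set = field(default_factory=set)  # of (locus, gamete)
    config: SimulationConfig | None = None


def simulate_true_map(n_lgs: int, lg_lengths, n_markers: int,
                      placement: str = "uniform", seed: int = 0,
                      clustered_excess: float = 3.0) -> TrueMap:
    """Draw a ground-truth map with markers spread over the LGs.

    Markers are assigned to LGs proportionally to length (largest remainder
    rounding).  ``placement="clustered"`` concentrates extra markers in the
    central 20% of each LG, emulating the centromeric marker clustering seen
    in Cupressaceae maps: the centre is oversampled ``clustered_excess``-fold
    relative to a uniform draw.
    """
    lg_lengths = [float(x) for x in lg_lengths]
    if n_lgs != len(lg_lengths):
        raise ValueError("n_lgs must equal len(lg_lengths)")
    if any(L <= 0 for L in lg_lengths):
        raise ValueError("zero-length linkage group")
    if n_markers < n_lgs:
        raise ValueError("need at least one marker per linkage group")
    if placement not in ("uniform", "clustered"):
        raise ValueError(f"unknown placement {placement!r}")

    rng = np.random.default_rng(seed)
    total = sum(lg_lengths)
    quotas = [n_markers * L / total for L in lg_lengths]
    counts = [max(1, int(np.floor(q))) for q in quotas]
    remainders = np.array([q - np.floor(q) for q in quotas])
    while sum(counts) < n_markers:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    while sum(counts) > n_markers:  # floor clamping overshoot
        i = int(np.argmax(counts))
        counts[i] -= 1

    rows = []
    width = len(str(n_lgs))
    for idx, (L, c) in enumerate(zip(lg_lengths, counts)):
        lg_id = f"LG{idx + 1:0{width}d}" if width > 1 else f"LG{idx + 1:02d}"
        if placement == "uniform":
            pos = rng.uniform(0.0, L, size=c)
        else:
            centre = rng.random(c) < (clustered_excess /
                                      (clustered_excess + 4.0))
            pos = np.where(centre,
                           rng.uniform(0.4 * L, 0.6 * L, size=c),
                           rng.uniform(0.0, L, size=c))
        pos.sort()
        for j, p in enumerate(pos):
            rows.append((f"{lg_id}_M{j + 1:05d}", lg_id, float(p)))
    markers = pd.DataFrame(rows, columns=["marker_id", "lg_id", "position_cM"])
    lgs = tuple((f"LG{i + 1:02d}", lg_lengths[i]) for i in range(n_lgs))
    return TrueMap(linkage_groups=lgs, markers=markers)


def _draw_lg_gamete(rng, r_adj: np.ndarray, n_markers: int) -> np.ndarray:
    """One haploid product for one LG: phase start + interval crossovers."""
    phase = rng.integers(0, 2)
    flips = rng.random(n_markers - 1) < r_adj if n_markers > 1 else np.empty(0)
    alleles = np.empty(n_markers, dtype=np.int8)
    alleles[0] = phase
    for i, f in enumerate(flips):
        alleles[i + 1] = alleles[i] ^ int(f)
    return alleles


def simulate_gametes(true_map: TrueMap, n: int, seed: int = 0,
                     distortion: tuple | None = None) -> HaploidGenotypeMatrix:
    """Simulate n haploid gametes from a ground-truth map.

    Alleles are coded "A"/"B" per locus, identifying the parental strand.
    LGs segregate independently.  ``distortion=(locus_ids, w)`` applies
    viability selection by rejection: a gamete whose allele at a distorted
    locus is the disfavoured one ("B") is kept with probability w, else the
    whole LG is re-drawn — neighbouring-marker linkage is thereby preserved.
    """
    if n < 1:
        raise ValueError("need at least one gamete")
    rng = np.random.default_rng(seed)
    distorted = set(distortion[0]) if distortion else set()
    weight = distortion[1] if distortion else 1.0

    blocks = []
    locus_ids = []
    for lg, grp in true_map.markers.groupby("lg_id", sort=False):
        pos = grp["position_cM"].to_numpy()
        m = len(pos)
        r_adj = kosambi_inverse(np.diff(pos)) if m > 1 else np.empty(0)
        dist_idx = [i for i, mk in enumerate(grp["marker_id"]) if mk in distorted]
        cols = np.empty((m, n), dtype=np.int8)
        for g in range(n):
            while True:
                alleles = _draw_lg_gamete(rng, r_adj, m)
                if not dist_idx:
                    break
                if all(alleles[i] == 0 or rng.random() < weight
                       for i in dist_idx):
                    break
            cols[:, g] = alleles
        blocks.append(cols)
        locus_ids.extend(grp["marker_id"].tolist())
    X = np.vstack(blocks) if blocks else np.empty((0, n), dtype=np.int8)
    letters = np.array(["A", "B"], dtype=object)
    calls = pd.DataFrame(letters[X],
                         index=pd.Index(locus_ids, name="marker_id"),
                         columns=[f"G{j + 1:03d}" for j in range(n)])
    return HaploidGenotypeMatrix(calls)


def _default_mother(matrix: HaploidGenotypeMatrix) -> pd.DataFrame:
    """Heterozygous A/B mother at every simulated locus."""
    return pd.DataFrame({"allele1": "A", "allele2": "B"},
                        index=matrix.loci.copy())


def degrade(matrix: HaploidGenotypeMatrix, config: SimulationConfig,
            true_map: TrueMap | None = None) -> SimulatedDataset:
    """Inject noise classes, genotyping errors and missingness.

    A rounded count of loci per class is converted in place (the pool size
    is unchanged): monomorphic loci become single-allele columns, repetitive
    loci are re-drawn from three equiprobable alleles, mother-discordant
    loci keep their segregation pattern but the recorded mother genotype is
    homozygous for one of the two alleles (so the gametes carry an allele
    absent from the mother's pair).  Allele-flip errors are applied to
    biallelic loci only; every flip and every injected class is recorded.
    """
    rng = np.random.default_rng(config.seed)
    calls = matrix.calls.copy()
    loci = list(calls.index)
    m = len(loci)
    n_mono = int(round(config.frac_monomorphic * m))
    n_rep = int(round(config.frac_repetitive * m))
    n_disc = int(round(config.frac_mother_discordant * m))
    if n_mono + n_rep + n_disc > m:
        raise ValueError("pool fractions convert more loci than exist")

    order = rng.permutation(m)
    mono_idx = order[:n_mono]
    rep_idx = order[n_mono:n_mono + n_rep]
    disc_idx = order[n_mono + n_rep:n_mono + n_rep + n_disc]

    labels = pd.Series("polymorphic", index=calls.index, name="truth_class")
    mother = _default_mother(matrix)
    g = calls.shape[1]

    for i in mono_idx:
        allele = rng.choice(["A", "B"])
        calls.iloc[i, :] = allele
        mother.iloc[i] = [allele, allele]
        labels.iloc[i] = "monomorphic"
    rep_alleles = np.array(["A", "B", "C"], dtype=object)
    for i in rep_idx:
        draw = rng.integers(0, 3, size=g)
        draw[:3] = (0, 1, 2)  # guarantee >2 observed alleles
        calls.iloc[i, :] = rep_alleles[draw]
        mother.iloc[i] = ["A", "B"]
        labels.iloc[i] = "repetitive"
    for i in disc_idx:
        a = rng.choice(["A", "B"])
        mother.iloc[i] = [a, a]  # gametes still segregate A/B
        labels.iloc[i] = "mother_discordant"

    # allele-flip errors on biallelic loci only (keeps truth labels exact)
    error_positions: set = set()
    if config.error_rate > 0:
        flippable = labels.isin(["polymorphic", "mother_discordant"]).to_numpy()
        flips = (rng.random(calls.shape) < config.error_rate) & flippable[:, None]
        flip_map = {"A": "B", "B": "A"}
        rows, cols = np.nonzero(flips)
        vals = calls.to_numpy(dtype=object)
        for ri, ci in zip(rows, cols):
            vals[ri, ci] = flip_map[vals[ri, ci]]
            error_positions.add((calls.index[ri], calls.columns[ci]))
        calls = pd.DataFrame(vals, index=calls.index, columns=calls.columns)

    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = calls.mask(miss)

    if true_map is None:
        lgs = (("LG01", 1.0),)
        mk = pd.DataFrame({"marker_id": loci, "lg_id": "LG01",
                           "position_cM": 0.0})
        true_map = TrueMap(linkage_groups=lgs, markers=mk)

    return SimulatedDataset(matrix=HaploidGenotypeMatrix(calls),
                            mother=MotherGenotype(mother),
                            truth=true_map, truth_labels=labels,
                            error_positions=error_positions, config=config)


def simulate_dataset(n_lgs: int = 11, lg_lengths=DEFAULT_LG_LENGTHS_CM,
                     n_markers: int = 550,
                     config: SimulationConfig = SimulationConfig(),
                     placement: str = "uniform") -> SimulatedDataset:
    """One-call convenience: true map -> gametes -> degraded dataset."""
    tm = simulate_true_map(n_lgs, lg_lengths, n_markers, placement=placement,
                           seed=config.seed)
    matrix = simulate_gametes(tm, config.n_gametes, seed=config.seed + 1,
                              distortion=config.distortion)
    return degrade(matrix, config, true_map=tm)
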