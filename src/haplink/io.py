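"""File formats: genotype TSV, haploid VCF, mother table, map and report
output, and Lep-MAP-compatible genotype export.

The canonical interchange format is TSV: a header row of gamete IDs, then
one row per locus with the marker ID followed by one allele code (or ``.``
for missing) per gamete.  VCF input is a read-only convenience for
haploid GT calls.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd

from .filtering import FilterReport
from .mapbuild import LinkageMap
from .matrix import MISSING_TOKEN, HaploidGenotypeMatrix, MotherGenotype


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = "tsv") -> HaploidGenotypeMatrix:
    """Read a haploid genotype matrix from TSV or VCF."""
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotypes_tsv(path) -> HaploidGenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header needs marker_id + gamete IDs")
        gametes = header[1:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}")
            ids.append(parts[0])
            rows.append([np.nan if v == MISSING_TOKEN or v == "" else v
                         for v in parts[1:]])
    calls = pd.DataFrame(rows, index=pd.Index(ids, name="marker_id"),
                         columns=gametes, dtype=object)
    return HaploidGenotypeMatrix(calls)


def read_genotypes_vcf(path) -> HaploidGenotypeMatrix:
    """Read haploid GT calls from a VCF (uncompressed or bgzipped).

    Each sample's GT must be a single haploid allele index ("0", "1", ...,
    or "." for missing); diploid GT fields are a hard error.  Multi-allelic
    sites are allowed (they become repetitive candidates downstream).
    """
    import pysam

    ids, rows, samples = [], [], None
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            marker = rec.id or f"{rec.chrom}_{rec.pos}"
            alleles = rec.alleles  # (ref, alt1, ...)
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    row.append(np.nan)
                    continue
                if len(gt) != 1:
                    raise ValueError(
                        f"{path}: diploid GT at {marker} sample {s}; "
                        "expected haploid calls")
                row.append(alleles[gt[0]])
            ids.append(marker)
            rows.append(row)
    calls = pd.DataFrame(rows, index=pd.Index(ids, name="marker_id"),
                         columns=samples, dtype=object)
    return HaploidGenotypeMatrix(calls)


def write_genotypes(matrix: HaploidGenotypeMatrix, path) -> None:
    out = matrix.calls.fillna(MISSING_TOKEN)
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# mother genotypes / truth tables
# ---------------------------------------------------------------------------

def read_mother(path) -> MotherGenotype:
    """Mother TSV: marker_id, allele1, allele2 (``.`` = unknown)."""
    table = pd.read_csv(path, sep="\t", dtype=str).set_index("marker_id")
    table = table.replace(MISSING_TOKEN, np.nan)
    return MotherGenotype(table)


def write_mother(mother: MotherGenotype, path) -> None:
    out = mother.table.fillna(MISSING_TOKEN)
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t")


def write_truth(dataset, path) -> None:
    """Truth TSV for a simulated dataset: marker, LG, position, class."""
    truth = dataset.truth.markers.set_index("marker_id")
    labels = dataset.truth_labels
    rows = []
    for mk in dataset.matrix.loci:
        if mk in truth.index:
            lg = truth.loc[mk, "lg_id"]
            pos = f"{truth.loc[mk, 'position_cM']:.2f}"
        else:
            lg, pos = MISSING_TOKEN, MISSING_TOKEN
        rows.append((mk, lg, pos, labels.get(mk, MISSING_TOKEN)))
    pd.DataFrame(rows, columns=["marker_id", "lg", "position_cM",
                                "class"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# maps and reports
# ---------------------------------------------------------------------------

def write_map(lmap: LinkageMap, path) -> None:
    """Map TSV: marker_id, lg, position_cM (2 dp), bin_id, representative
    and error-prone flags.  Byte-stable for identical inputs."""
    out = lmap.entries.copy()
    out["position_cM"] = out["position_cM"].map(lambda v: f"{v:.2f}")
    if "bin_id" not in out.columns:
        out["bin_id"] = MISSING_TOKEN
    out["bin_id"] = out["bin_id"].fillna(MISSING_TOKEN)
    for col, default in (("is_representative", True),
                         ("error_prone", False)):
        if col not in out.columns:
            out[col] = default
        out[col] = out[col].map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)


def read_map(path) -> LinkageMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "lg": str})
    df["position_cM"] = df["position_cM"].astype(float)
    if "bin_id" in df.columns:
        df["bin_id"] = df["bin_id"].where(df["bin_id"] != MISSING_TOKEN)
    return LinkageMap(entries=df)


def write_report(report: FilterReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict() if is_dataclass(report) else report, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")


def write_lod_matrix(pairwise, path) -> None:
    """Pairwise LOD matrix TSV for heat-map rendering."""
    frame = pairwise.lod_frame().round(4)
    frame.index.name = "marker_id"
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Lep-MAP-compatible export
# ---------------------------------------------------------------------------

def write_lepmap_export(matrix: HaploidGenotypeMatrix,
                        mother: MotherGenotype, path) -> None:
    """Export genotypes in the Lep-MAP pseudo-diploid coding.

    The maternal genotype is written 1/2, the (unknown) paternal genotype
    1/1, missing calls 0/0, and each haploid gamete call is converted to a
    homozygous diploid: allele1 of the mother -> "1 1", allele2 -> "2 2".
    Loci whose mother genotype is unknown or homozygous are skipped.
    """
    with open(path, "w") as fh:
        header = ["marker_id", "mother", "father"] + list(matrix.gametes)
        fh.write("\t".join(str(h) for h in header) + "\n")
        for mk in matrix.loci:
            pair = mother.pair(mk)
            if pair is None or len(pair) != 2:
                continue
            a1, a2 = sorted(pair)
            coding = {a1: "1 1", a2: "2 2"}
            row = [str(mk), "1 2", "1 1"]
            for val in matrix.calls.loc[mk]:
                row.append(coding.get(val, "0 0") if isinstance(val, str)
                           else "0 0")
            fh.write("\t".join(row) + "\n")
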