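"""In silico double-digest (ddRAD) restriction fragment prediction.

A genome is cut at every occurrence of two enzymes' recognition sites;
ddRAD retains only fragments flanked by one cut of *each* enzyme whose
length falls in the size-selection window.  Recognition sites are
non-degenerate DNA words with a cut offset (e.g. EcoRV GAT^ATC cuts 3 bases
into its site).  Palindromic sites are scanned on the forward strand only
(the reverse-complement scan is identical); non-palindromic sites are
scanned on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

_DNA = set("ACGT")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as recognition site + cut offset (5'->3')."""
    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        site = self.site.upper()
        if not site or not set(site) <= _DNA:
            raise ValueError(f"site must be non-degenerate DNA: {self.site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut offset outside recognition site")
        object.__setattr__(self, "site", site)

    @property
    def is_palindromic(self) -> bool:
        return self.site == str(Seq(self.site).reverse_complement())


ECORV = Enzyme("EcoRV", "GATATC", 3)  # blunt cutter, GAT^ATC
SCAI = Enzyme("ScaI", "AGTACT", 3)    # blunt cutter, AGT^ACT


@dataclass
class FragmentSet:
    """Retained ddRAD fragments: 0-based half-open genome intervals."""
    fragments: pd.DataFrame  # sequence_id, start, end, left_enzyme,
                             # right_enzyme, length_bp

    def __len__(self) -> int:
        return len(self.fragments)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.fragments.itertuples(index=False):
                name = f"{row.left_enzyme}-{row.right_enzyme}"
                fh.write(f"{row.sequence_id}\t{row.start}\t{row.end}\t{name}\n")

    def to_tsv(self, path) -> None:
        self.fragments.to_csv(path, sep="\t", index=False)


def _cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """All cut coordinates of one enzyme in one sequence (0-based)."""
    positions = []
    for site, offset in _scan_words(enzyme):
        start = seq.find(site)
        while start != -1:
            positions.append(start + offset)
            start = seq.find(site, start + 1)
    return positions


def _scan_words(enzyme: Enzyme):
    """Forward-strand words to scan: adds the reverse complement for
    non-palindromic sites (a bottom-strand site read on the top strand)."""
    words = [(enzyme.site, enzyme.cut_offset)]
    if not enzyme.is_palindromic:
        rc = str(Seq(enzyme.site).reverse_complement())
        words.append((rc, len(enzyme.site) - enzyme.cut_offset))
    return words


def in_silico_ddrad(genome, enzyme_a: Enzyme, enzyme_b: Enzyme,
                    size_range: tuple[int, int]) -> FragmentSet:
    """Predict size-selected dual-enzyme fragments for a genome.

    Parameters
    ----------
    genome : mapping of sequence_id -> sequence string, or iterable of
        Bio.SeqRecord
    size_range : (min_bp, max_bp) inclusive size-selection window

    Returns fragments flanked by one cut of each enzyme, within the window,
    in ascending coordinate order per sequence.  Terminal fragments (ending
    at a sequence boundary rather than a cut) are never retained.
    """
    lo, hi = size_range
    if lo > hi:
        raise ValueError("size_range min exceeds max")
    if hasattr(genome, "items"):
        records = genome.items()
    else:
        records = ((rec.id, str(rec.seq)) for rec in genome)

    rows = []
    for seq_id, seq in records:
        seq = str(seq).upper()
        cuts = ([(p, enzyme_a.name) for p in _cut_positions(seq, enzyme_a)] +
                [(p, enzyme_b.name) for p in _cut_positions(seq, enzyme_b)])
        cuts.sort()
        for (p1, e1), (p2, e2) in zip(cuts, cuts[1:]):
            length = p2 - p1
            if e1 != e2 and lo <= length <= hi:
                rows.append((seq_id, p1, p2, e1, e2, length))
    frame = pd.DataFrame(rows, columns=["sequence_id", "start", "end",
                                        "left_enzyme", "right_enzyme",
                                        "length_bp"])
    return FragmentSet(fragments=frame)
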