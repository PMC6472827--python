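"""Nucleotide alignments, tip dates, and site-pattern compression.

States are stored as 4-bit masks over {A,C,G,T} so that IUPAC ambiguity
codes and gaps (treated as fully missing) share one representation.  A site
pattern is *invariant-capable* when at least one nucleotide is compatible
with every taxon's (possibly ambiguous) state in that column -- the set of
columns that can contribute to the proportion-of-invariable-sites term of
the phylogenetic likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .trees import Taxon

__all__ = [
    "AMBIGUITY_MASKS",
    "Alignment",
    "SitePatterns",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "compress_patterns",
]

# bit per nucleotide: A=1, C=2, G=4, T=8
AMBIGUITY_MASKS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15, "X": 15,
}

_MASK_TO_CHAR = {v: k for k, v in AMBIGUITY_MASKS.items() if k not in "U-?X"}
_MASK_TO_CHAR[15] = "N"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Equal-length nucleotide sequences, one per taxon."""

    taxa: list[Taxon]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise AlignmentError("empty alignment")
        labels = [t.label for t in self.taxa]
        if len(set(labels)) != len(labels):
            raise AlignmentError("duplicate taxon labels in alignment")
        lengths = {lab: len(self.sequences[lab]) for lab in labels}
        distinct = set(lengths.values())
        if len(distinct) != 1:
            bad = max(lengths, key=lambda l: abs(lengths[l] - np.median(list(lengths.values()))))
            raise AlignmentError(
                f"ragged alignment: sequence for {bad!r} has length "
                f"{lengths[bad]}, others {sorted(distinct - {lengths[bad]})}"
            )
        self.sequences = {lab: self.sequences[lab].upper() for lab in labels}
        for lab in labels:
            bad_chars = set(self.sequences[lab]) - set(AMBIGUITY_MASKS)
            if bad_chars:
                raise AlignmentError(
                    f"sequence for {lab!r} contains invalid symbols {sorted(bad_chars)}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.taxa]

    def masks(self) -> np.ndarray:
        """(n_taxa, length) uint8 array of 4-bit state masks."""
        table = np.zeros(128, dtype=np.uint8)
        for ch, m in AMBIGUITY_MASKS.items():
            table[ord(ch)] = m
        rows = [
            table[np.frombuffer(self.sequences[lab].encode(), dtype=np.uint8)]
            for lab in self.labels
        ]
        return np.vstack(rows)


@dataclass
class SitePatterns:
    """Unique alignment columns with multiplicities.

    ``masks`` is (n_patterns, n_taxa); ``invariant_masks[p]`` is the bitwise
    AND over taxa -- nonzero iff pattern ``p`` is invariant-capable, and its
    set bits are the compatible nucleotides.
    """

    labels: list[str]
    masks: np.ndarray
    weights: np.ndarray
    invariant_masks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        inv = np.full(self.masks.shape[0], 255, dtype=np.uint8)
        for j in range(self.masks.shape[1]):
            inv &= self.masks[:, j]
        self.invariant_masks = inv & 15

    @property
    def n_patterns(self) -> int:
        return self.masks.shape[0]

    @property
    def is_invariant_capable(self) -> np.ndarray:
        return self.invariant_masks != 0

    def tip_partials(self, label: str) -> np.ndarray:
        """(n_patterns, 4) indicator vectors for a taxon's states."""
        col = self.masks[:, self.labels.index(label)]
        return np.stack([(col >> k) & 1 for k in range(4)], axis=1).astype(float)


def compress_patterns(aln: Alignment) -> SitePatterns:
    """Collapse identical columns; weights sum to the alignment length."""
    masks = aln.masks().T  # (length, n_taxa)
    uniq, counts = np.unique(masks, axis=0, return_counts=True)
    return SitePatterns(aln.labels, uniq, counts.astype(int))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_dates(
    labels: list[str],
    date_format: str | None,
    date_table: str | None,
) -> dict[str, float]:
    """Tip dates to heights.

    ``date_format="suffix"`` parses a trailing ``|<decimal value>`` from
    each label (forward-time values, e.g. decimal years); ``date_table`` is
    a 2-column TSV of label and forward-time value.  Values are converted
    to heights by subtracting each from the maximum.
    """
    if date_format is None and date_table is None:
        return {lab: 0.0 for lab in labels}
    raw: dict[str, float] = {}
    if date_table is not None:
        with open(date_table) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                lab, val = line.split("\t")[:2]
                raw[lab] = float(val)
        missing = set(labels) - set(raw)
        if missing:
            raise AlignmentError(f"date table missing taxa: {sorted(missing)}")
    else:
        for lab in labels:
            if "|" not in lab:
                raise AlignmentError(f"label {lab!r} has no '|<date>' suffix")
            raw[lab] = float(lab.rsplit("|", 1)[1])
    latest = max(raw[lab] for lab in labels)
    return {lab: latest - raw[lab] for lab in labels}


def read_alignment(
    path: str,
    format: str = "fasta",
    date_format: str | None = None,
    date_table: str | None = None,
) -> Alignment:
    """Read a FASTA or NEXUS nucleotide alignment.

    Sequences are upper-cased; ambiguity codes are preserved.  Tip dates
    come from a ``|<decimal>`` label suffix (``date_format="suffix"``) or a
    2-column TSV date table; absent both, all tips are contemporaneous at
    height 0.
    """
    records: list[tuple[str, str]] = []
    if format == "fasta":
        for rec in SeqIO.parse(path, "fasta"):
            records.append((rec.id, str(rec.seq)))
    elif format == "nexus":
        import dendropy

        mat = dendropy.DnaCharacterMatrix.get(path=path, schema="nexus")
        for tax in mat.taxon_namespace:
            records.append((tax.label.replace(" ", "_"), str(mat[tax])))
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    labels = [lab for lab, _ in records]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise AlignmentError(f"duplicate labels: {dup}")
    heights = _parse_dates(labels, date_format, date_table)
    taxa = [Taxon(lab, heights[lab]) for lab in labels]
    return Alignment(taxa, dict(records))


def write_alignment(aln: Alignment, path: str, format: str = "fasta") -> None:
    with open(path, "w") as fh:
        if format == "fasta":
            for lab in aln.labels:
                fh.write(f">{lab}\n{aln.sequences[lab]}\n")
        elif format == "nexus":
            fh.write("#NEXUS\nBegin data;\n")
            fh.write(
                f"    Dimensions ntax={len(aln.taxa)} nchar={aln.length};\n"
            )
            fh.write('    Format datatype=dna missing=? gap=-;\n    Matrix\n')
            for lab in aln.labels:
                fh.write(f"        {lab}  {aln.sequences[lab]}\n")
            fh.write("        ;\nEnd;\n")
        else:
            raise ValueError(f"unknown alignment format {format!r}")
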