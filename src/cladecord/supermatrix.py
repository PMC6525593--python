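"""Codon-alignment bookkeeping: masking, concatenation, translation,
codon-position subsets and Ser/Ile/Arg ambiguity recoding.

All coordinates are 0-based half-open internally; mask files and NEXUS
output use the 1-based inclusive convention humans write. The genetic code
defaults to the bacterial/plastid table (NCBI translation table 11).

The ambiguity recoding replaces every codon of the three amino acids with
split synonymous families — serine (TCN + AGY), isoleucine (ATH) and
arginine (CGN + AGR) — by the minimal IUPAC pattern covering the whole
family, removing codon-usage signal at those sites while keeping the
amino-acid identity recoverable. The pattern table lives in a single
mapping (:data:`DEGEN_PATTERNS`) so an alternative convention can be
swapped in at one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable, IUPACData

from .taxa import TaxonSet

__all__ = [
    "CodonAlignment",
    "ProteinAlignment",
    "MaskSpec",
    "Supermatrix",
    "DEGEN_PATTERNS",
    "apply_mask",
    "concatenate",
    "translate",
    "position_subset",
    "ambiguity_recode",
    "read_fasta_alignment",
    "read_mask_file",
    "propose_mask",
]

GAP = "-"

#: Minimal IUPAC cover of each split synonymous family, keyed by residue.
DEGEN_PATTERNS: dict[str, str] = {"S": "WSN", "I": "ATH", "R": "MGN"}

#: Degen patterns decode back to their residue (the patterns cover codons
#: outside the source family, so generic ambiguity expansion cannot).
_DEGEN_DECODE: dict[str, str] = {v: k for k, v in DEGEN_PATTERNS.items()}

_AMBIG = {k.upper(): v.upper() for k, v in IUPACData.ambiguous_dna_values.items()}


@dataclass
class CodonAlignment:
    """An in-frame aligned nucleotide matrix for one gene."""

    sequences: dict[str, str]
    gene_id: str
    frame_offset: int = 0
    code_id: int = 11

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: sequences differ in length {lengths}")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def n_codons(self) -> int:
        usable = self.length - self.frame_offset
        if usable % 3:
            raise ValueError(
                f"{self.gene_id}: {usable} in-frame columns not divisible by 3"
            )
        return usable // 3

    def codon(self, taxon: str, i: int) -> str:
        start = self.frame_offset + 3 * i
        return self.sequences[taxon][start : start + 3]

    def column_positions(self) -> np.ndarray:
        """Codon position (1/2/3) per column; 0 for leading out-of-frame."""
        pos = np.zeros(self.length, dtype=int)
        for col in range(self.frame_offset, self.length):
            pos[col] = (col - self.frame_offset) % 3 + 1
        return pos


@dataclass
class ProteinAlignment:
    """An aligned amino-acid matrix for one gene."""

    sequences: dict[str, str]
    gene_id: str

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: sequences differ in length {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.sequences)


@dataclass(frozen=True)
class MaskSpec:
    """Columns to exclude from one gene's alignment (0-based indices)."""

    gene_id: str
    excluded_columns: frozenset[int]

    @classmethod
    def from_ranges(cls, gene_id: str, ranges: Iterable[tuple[int, int]]) -> "MaskSpec":
        """Build from 1-based inclusive (start, end) ranges."""
        cols: set[int] = set()
        for start, end in ranges:
            if start < 1 or end < start:
                raise ValueError(f"bad 1-based range {start}-{end}")
            cols.update(range(start - 1, end))
        return cls(gene_id, frozenset(cols))


def apply_mask(
    aln: CodonAlignment, mask: MaskSpec, snap_codons: bool = True
) -> CodonAlignment:
    """Remove masked columns from an alignment.

    With ``snap_codons`` (the default) any codon losing at least one column
    is dropped entirely, which keeps the matrix in frame for codon-position
    partitioning. Without snapping, a mask that splits codons raises.
    """
    if not mask.excluded_columns:
        return replace(aln, sequences=dict(aln.sequences))
    bad = [c for c in mask.excluded_columns if not 0 <= c < aln.length]
    if bad:
        raise ValueError(f"{aln.gene_id}: mask columns out of range: {sorted(bad)}")
    excluded = set(mask.excluded_columns)
    if snap_codons:
        for c in list(excluded):
            if c >= aln.frame_offset:
                codon_start = aln.frame_offset + 3 * ((c - aln.frame_offset) // 3)
                excluded.update(range(codon_start, min(codon_start + 3, aln.length)))
    keep = [c for c in range(aln.length) if c not in excluded]
    new_offset = sum(1 for c in keep if c < aln.frame_offset)
    new_len = len(keep)
    if (new_len - new_offset) % 3:
        raise ValueError(
            f"{aln.gene_id}: mask splits codons ({new_len - new_offset} in-frame "
            "columns remain); enable codon snapping or fix the mask"
        )
    seqs = {t: "".join(s[c] for c in keep) for t, s in aln.sequences.items()}
    return CodonAlignment(seqs, aln.gene_id, new_offset, aln.code_id)


@dataclass
class Supermatrix:
    """A concatenated multi-gene matrix with per-column provenance.

    ``column_gene`` and ``column_position`` record, for every column, the
    source gene and the codon position (1/2/3; 0 for amino-acid matrices),
    from which partition CHARSETs are derived.
    """

    sequences: dict[str, str]
    column_gene: list[str]
    column_position: np.ndarray
    alphabet: str = "nucleotide"  # or "amino-acid"

    def __post_init__(self):
        self.column_position = np.asarray(self.column_position, dtype=int)
        for t, s in self.sequences.items():
            if len(s) != len(self.column_gene):
                raise ValueError(f"row {t} length does not match column count")
        if len(self.column_gene) != len(self.column_position):
            raise ValueError("column metadata lengths differ")

    @property
    def n_columns(self) -> int:
        return len(self.column_gene)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.column_gene:
            seen.setdefault(g)
        return list(seen)

    def gene_range(self, gene_id: str) -> tuple[int, int]:
        idx = [i for i, g in enumerate(self.column_gene) if g == gene_id]
        if not idx:
            raise KeyError(f"gene {gene_id!r} not in supermatrix")
        return idx[0], idx[-1] + 1

    def partitions(self) -> list[tuple[str, int, int, int]]:
        """(gene, start, end, codon_position) runs tiling [0, n_columns)."""
        out: list[tuple[str, int, int, int]] = []
        i = 0
        while i < self.n_columns:
            g, p = self.column_gene[i], int(self.column_position[i])
            j = i
            while (
                j < self.n_columns
                and self.column_gene[j] == g
                and int(self.column_position[j]) == p
            ):
                j += 1
            out.append((g, i, j, p))
            i = j
        return out

    def charset_lines(self) -> list[str]:
        """NEXUS CHARSET lines, one per gene x codon position (1-based)."""
        lines = []
        for gene in self.genes:
            start, end = self.gene_range(gene)
            if self.alphabet == "amino-acid":
                lines.append(f"charset {gene} = {start + 1}-{end};")
                continue
            for pos in (1, 2, 3):
                cols = [
                    i
                    for i in range(start, end)
                    if int(self.column_position[i]) == pos
                ]
                if not cols:
                    continue
                if all(b - a == 3 for a, b in zip(cols, cols[1:])):
                    lines.append(
                        f"charset {gene}_pos{pos} = {cols[0] + 1}-{cols[-1] + 1}\\3;"
                    )
                else:
                    spans = " ".join(str(c + 1) for c in cols)
                    lines.append(f"charset {gene}_pos{pos} = {spans};")
        return lines

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in self.sequences.items():
                fh.write(f">{taxon}\n{seq}\n")

    def write_nexus(self, path: str | Path) -> None:
        datatype = "protein" if self.alphabet == "amino-acid" else "dna"
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(
                f"  dimensions ntax={self.n_taxa} nchar={self.n_columns};\n"
                f"  format datatype={datatype} gap=- missing=?;\n  matrix\n"
            )
            for taxon, seq in self.sequences.items():
                name = f"'{taxon}'" if " " in taxon else taxon
                fh.write(f"    {name}  {seq}\n")
            fh.write("  ;\nend;\nbegin sets;\n")
            for line in self.charset_lines():
                fh.write(f"  {line}\n")
            fh.write("end;\n")

    def write_raxml_partitions(self, path: str | Path) -> None:
        model = "LG" if self.alphabet == "amino-acid" else "DNA"
        with open(path, "w") as fh:
            for line in self.charset_lines():
                body = line.removeprefix("charset ").removesuffix(";")
                fh.write(f"{model}, {body}\n")


def concatenate(
    alignments: Sequence[CodonAlignment | ProteinAlignment],
    universe: TaxonSet,
) -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix over ``universe``.

    Genes keep the given order; taxa absent from a gene are gap-filled over
    that gene's range. Codon positions are recorded per column for
    nucleotide input.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    gene_ids = [a.gene_id for a in alignments]
    if len(set(gene_ids)) != len(gene_ids):
        dup = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")
    is_protein = isinstance(alignments[0], ProteinAlignment)
    for a in alignments:
        if isinstance(a, ProteinAlignment) != is_protein:
            raise ValueError("cannot mix nucleotide and amino-acid alignments")
        stray = [t for t in a.taxa if t not in universe]
        if stray:
            raise ValueError(f"{a.gene_id}: taxa not in universe: {stray}")
    covered = {t for a in alignments for t in a.taxa}
    orphans = [t for t in universe if t not in covered]
    if orphans:
        raise ValueError(f"taxa present in no gene: {orphans}")

    rows = {t: [] for t in universe}
    column_gene: list[str] = []
    column_position: list[int] = []
    for a in alignments:
        for t in universe:
            rows[t].append(a.sequences.get(t, GAP * a.length))
        column_gene.extend([a.gene_id] * a.length)
        if is_protein:
            column_position.extend([0] * a.length)
        else:
            column_position.extend(int(p) for p in a.column_positions())
    return Supermatrix(
        sequences={t: "".join(parts) for t, parts in rows.items()},
        column_gene=column_gene,
        column_position=np.array(column_position),
        alphabet="amino-acid" if is_protein else "nucleotide",
    )


def _expand(codon: str) -> list[str]:
    opts = [_AMBIG.get(b, b) for b in codon]
    out = [""]
    for o in opts:
        out = [p + b for p in out for b in o]
    return out


def translate_codon(codon: str, code_id: int = 11) -> str:
    """Translate one (possibly ambiguous or gapped) codon.

    Gap-containing codons give a gap; the three recoding patterns decode to
    their residue; other ambiguity codons give their residue when every
    expansion agrees, else X; stop codons give ``*``.
    """
    codon = codon.upper()
    if GAP in codon or "?" in codon:
        return GAP
    if codon in _DEGEN_DECODE:
        return _DEGEN_DECODE[codon]
    table = CodonTable.unambiguous_dna_by_id[code_id]
    residues = set()
    for c in _expand(codon):
        if c in table.stop_codons:
            residues.add("*")
        else:
            residues.add(table.forward_table.get(c, "X"))
        if len(residues) > 1:
            return "X"
    return residues.pop() if residues else "X"


def translate(aln: CodonAlignment) -> ProteinAlignment:
    """Translate an in-frame codon alignment; one residue per codon.

    Internal stop codons are translated as ``*`` with a warning giving the
    taxon and codon index (plastid annotations occasionally contain such
    artifacts)."""
    n = aln.n_codons  # validates frame
    out: dict[str, str] = {}
    for taxon in aln.taxa:
        residues = []
        for i in range(n):
            r = translate_codon(aln.codon(taxon, i), aln.code_id)
            if r == "*" and i < n - 1:
                warnings.warn(
                    f"{aln.gene_id}: internal stop codon in {taxon} at codon {i}",
                    stacklevel=2,
                )
            residues.append(r)
        out[taxon] = "".join(residues)
    return ProteinAlignment(out, aln.gene_id)


def position_subset(sm: Supermatrix, positions: Iterable[int]) -> Supermatrix:
    """Retain exactly the columns whose codon position is in ``positions``."""
    if sm.alphabet != "nucleotide":
        raise ValueError("codon-position subsets require a nucleotide matrix")
    wanted = set(int(p) for p in positions)
    if not wanted <= {1, 2, 3}:
        raise ValueError(f"positions must be within {{1,2,3}}, got {sorted(wanted)}")
    keep = [i for i in range(sm.n_columns) if int(sm.column_position[i]) in wanted]
    if not keep:
        raise ValueError("position subset selects no columns")
    return Supermatrix(
        sequences={t: "".join(s[i] for i in keep) for t, s in sm.sequences.items()},
        column_gene=[sm.column_gene[i] for i in keep],
        column_position=sm.column_position[keep],
        alphabet="nucleotide",
    )


def ambiguity_recode(aln: CodonAlignment) -> CodonAlignment:
    """Replace every Ser/Ile/Arg codon by its family-wide IUPAC pattern.

    Idempotent: the patterns themselves decode to the same residues and are
    re-replaced by themselves. Codons of other amino acids, gapped codons
    and non-decodable ambiguity codons are untouched."""
    n = aln.n_codons
    out: dict[str, str] = {}
    for taxon in aln.taxa:
        seq = aln.sequences[taxon]
        parts = [seq[: aln.frame_offset]]
        for i in range(n):
            codon = aln.codon(taxon, i)
            residue = translate_codon(codon, aln.code_id)
            parts.append(DEGEN_PATTERNS.get(residue, codon))
        out[taxon] = "".join(parts)
    return CodonAlignment(out, aln.gene_id, aln.frame_offset, aln.code_id)


# ---------------------------------------------------------------------------
# file IO helpers


def read_fasta_alignment(
    path: str | Path, gene_id: str | None = None, frame_offset: int = 0
) -> CodonAlignment:
    """Read one gene's aligned FASTA into a :class:`CodonAlignment`."""
    from Bio import SeqIO

    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate taxon {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    return CodonAlignment(seqs, gene_id or path.stem, frame_offset)


def read_mask_file(path: str | Path) -> dict[str, MaskSpec]:
    """Read a mask file: one line per gene, ``gene start-end[,start-end...]``
    with 1-based inclusive ranges. Returns a mapping gene -> MaskSpec."""
    out: dict[str, MaskSpec] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            gene, spans = line.split(maxsplit=1)
            ranges = []
            for span in spans.replace(",", " ").split():
                a, b = span.split("-")
                ranges.append((int(a), int(b)))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed mask line {raw!r}") from exc
        out[gene] = MaskSpec.from_ranges(gene, ranges)
    return out


def propose_mask(aln: CodonAlignment, gap_threshold: float = 0.5) -> MaskSpec:
    """Convenience gap-fraction mask: exclude columns with more than
    ``gap_threshold`` gapped rows. This is a helper heuristic, not a
    homology assessment — curated masks should be preferred."""
    n = len(aln.sequences)
    cols = set()
    for c in range(aln.length):
        gaps = sum(1 for t in aln.taxa if aln.sequences[t][c] in (GAP, "?"))
        if gaps / n > gap_threshold:
            cols.add(c)
    return MaskSpec(aln.gene_id, frozenset(cols))
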