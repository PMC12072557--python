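"""Sequence and table I/O plus strand-aware CDS extraction.

All genomic coordinates are 1-based inclusive (VCF convention). CDS
coordinates are 1-based with position 1 = the A of the initiator ATG, so
HGVS-style c.-notation maps directly onto string indices minus one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGT")
ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Malformed FASTA record (empty sequence or bad alphabet)."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A,C,G,T,N}."""


class CoordinateError(ValueError):
    """Genomic coordinates outside the supplied sequence."""


class FrameError(ValueError):
    """CDS length not divisible by three."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated nucleotide sequence, optionally in reading frame.

    When ``is_cds`` is true the sequence is a coding sequence: length > 0
    and divisible by 3, with position 1 the A of the initiator ATG.
    Non-ACGT bases are restricted to N (masked/low-quality sites).
    """

    id: str
    seq: str
    is_cds: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        bad = set(self.seq) - ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id}: invalid characters {sorted(bad)}; "
                "only A,C,G,T,N allowed (uppercase)"
            )
        if self.is_cds:
            if len(self.seq) == 0:
                raise FrameError(f"{self.id}: empty CDS")
            if len(self.seq) % 3 != 0:
                raise FrameError(
                    f"{self.id}: CDS length {len(self.seq)} not divisible by 3"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ExonModel:
    """Exon coordinates of a transcript on a genomic contig.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted ascending
    and non-overlapping. For minus-strand models the coding order of exons
    is the reverse of the genomic order.
    """

    chrom: str
    exons: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("exon model needs at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise CoordinateError(f"bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise CoordinateError("exons must be sorted and non-overlapping")
            prev_end = end

    @property
    def exonic_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


@dataclass(frozen=True)
class VariantCall:
    """One single-nucleotide variant call with a simple genotype class."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # hom_ref | het | hom_alt | missing

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CoordinateError(f"position {self.pos} < 1")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise AlphabetError(
                f"{self.chrom}:{self.pos} ref/alt must be single bases in ACGT"
            )
        if self.genotype not in ("hom_ref", "het", "hom_alt", "missing"):
            raise ValueError(f"unknown genotype class {self.genotype!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N is self-complementary."""
    bad = set(seq) - ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a multi-record FASTA; sequences uppercased, U mapped to T."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} has invalid characters {sorted(bad)}"
            )
        records.append(CodingSequence(id=rec.id, seq=seq, source=str(path)))
    return records


def write_fasta(records: Iterable[CodingSequence], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def extract_cds(genomic_seq: str, model: ExonModel, seq_id: str = "cds") -> CodingSequence:
    """Concatenate exonic sequence; minus-strand models are reverse-complemented
    so the output is the 5'->3' coding strand."""
    bad = set(genomic_seq) - ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)}")
    parts = []
    for start, end in model.exons:
        if end > len(genomic_seq):
            raise CoordinateError(
                f"exon ({start}, {end}) outside sequence of length {len(genomic_seq)}"
            )
        parts.append(genomic_seq[start - 1 : end])
    cds = "".join(parts)
    if model.strand == "-":
        cds = reverse_complement(cds)
    if len(cds) % 3 != 0:
        raise FrameError(f"exonic length {len(cds)} not divisible by 3")
    return CodingSequence(id=seq_id, seq=cds, is_cds=True, source=f"{model.chrom}:{model.strand}")


# --- substitution tables -------------------------------------------------

TSV_COLUMNS = ["substitution", "transition_type", "potential_cause", "consequence"]


def write_tsv_substitutions(records: Sequence[dict], path: str | Path) -> None:
    """Write substitution rows as TSV with the fixed four-column layout."""
    for rec in records:
        unknown = set(rec) - set(TSV_COLUMNS)
        if unknown:
            raise ValueError(f"unknown columns {sorted(unknown)}")
    df = pd.DataFrame(list(records), columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_tsv_substitutions(path: str | Path) -> list[dict]:
    """Read a substitution TSV written by :func:`write_tsv_substitutions`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(TSV_COLUMNS)
    if unknown:
        raise ValueError(f"{path}: unknown columns {sorted(unknown)}")
    df = df.reindex(columns=TSV_COLUMNS, fill_value="")
    return df.to_dict(orient="records")


# --- VCF -----------------------------------------------------------------

_GT_MAP = {
    (0, 0): "hom_ref",
    (0, 1): "het",
    (1, 0): "het",
    (1, 1): "hom_alt",
}


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read single-sample SNV calls from a VCF (v4.x, plain text).

    Multi-allelic records use the first ALT with a warning; non-SNV records
    are skipped with a warning.
    """
    import warnings

    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1:
                warnings.warn(
                    f"{rec.chrom}:{rec.pos}: multi-allelic record, using first ALT"
                )
            if not alts:
                continue
            alt = alts[0]
            if len(rec.ref) != 1 or len(alt) != 1:
                warnings.warn(f"{rec.chrom}:{rec.pos}: not a SNV, skipped")
                continue
            if rec.samples:
                gt = rec.samples[0]["GT"]
                if gt is None or None in gt:
                    genotype = "missing"
                else:
                    genotype = _GT_MAP.get(tuple(sorted(gt)), "hom_alt")
            else:
                genotype = "hom_alt"
            calls.append(
                VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt, genotype=genotype
                )
            )
    return calls


_VCF_GT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contig_lengths: dict[str, int],
    sample: str = "sample",
) -> None:
    """Write SNV calls as a minimal single-sample VCF v4.2."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
        lines.append(
            f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\tPASS\t.\tGT\t"
            + _VCF_GT[call.genotype]
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --- exon model TSV ------------------------------------------------------

def read_exon_model(path: str | Path) -> ExonModel:
    """Read an exon model TSV: columns chrom, start, end, strand (one row per exon)."""
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    strands = df["strand"].unique()
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError(f"{path}: exon model must have a single chrom and strand")
    exons = tuple(sorted((int(s), int(e)) for s, e in zip(df["start"], df["end"])))
    return ExonModel(chrom=str(chroms[0]), exons=exons, strand=str(strands[0]))


def write_exon_model(model: ExonModel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [model.chrom] * len(model.exons),
            "start": [s for s, _ in model.exons],
            "end": [e for _, e in model.exons],
            "strand": [model.strand] * len(model.exons),
        }
    )
    df.to_csv(path, sep="\t", index=False)
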