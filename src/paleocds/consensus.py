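"""Build per-individual coding sequences by applying variant calls to a
reference CDS — the consensus step of an ancient-genome workflow, restricted
to SNVs on a known exon model.

Heterozygous sites in a diploid archaic genome are ambiguous in a haploid
consensus; the ``het_policy`` argument makes the choice explicit:

``ref``
    do not apply heterozygous calls (default; cannot create false derived
    alleles),
``alt``
    apply the alternate allele,
``mask``
    write N at the site.

Missing genotypes are treated as homozygous reference with a warning.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

from .seqio import (
    CodingSequence,
    CoordinateError,
    ExonModel,
    VariantCall,
    reverse_complement,
)

HET_POLICIES = ("ref", "alt", "mask")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the reference CDS base."""


def genomic_to_cds_pos(model: ExonModel, gpos: int) -> Optional[int]:
    """Map a genomic position to a 1-based CDS coordinate.

    Returns None for intronic or out-of-model positions. On the minus
    strand CDS position 1 is the last base of the genomically last exon.
    """
    offset = 0
    for start, end in model.exons:
        if start <= gpos <= end:
            plus_pos = offset + (gpos - start) + 1
            if model.strand == "+":
                return plus_pos
            return model.exonic_length - plus_pos + 1
        offset += end - start + 1
    return None


def cds_to_genomic_pos(model: ExonModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds_pos` for valid CDS coordinates."""
    if not 1 <= cds_pos <= model.exonic_length:
        raise CoordinateError(f"CDS position {cds_pos} outside 1..{model.exonic_length}")
    plus_pos = cds_pos if model.strand == "+" else model.exonic_length - cds_pos + 1
    offset = 0
    for start, end in model.exons:
        width = end - start + 1
        if plus_pos <= offset + width:
            return start + (plus_pos - offset) - 1
        offset += width
    raise AssertionError("unreachable")  # pragma: no cover


def apply_variants(
    ref_cds: CodingSequence,
    model: ExonModel,
    calls: Iterable[VariantCall],
    het_policy: str = "ref",
) -> CodingSequence:
    """Apply SNV calls to a reference CDS, returning the sample's CDS.

    Calls are in genomic coordinates; on minus-strand models alleles are
    complemented before application to the coding strand. Calls outside
    the exon model are ignored with a warning; a REF allele that does not
    match the reference base raises :class:`ReferenceMismatchError`.
    """
    if het_policy not in HET_POLICIES:
        raise ValueError(f"het_policy must be one of {HET_POLICIES}")
    if len(ref_cds) != model.exonic_length:
        raise CoordinateError(
            f"reference CDS length {len(ref_cds)} != exonic length {model.exonic_length}"
        )
    seq = list(ref_cds.seq)
    for call in calls:
        cds_pos = genomic_to_cds_pos(model, call.pos)
        if cds_pos is None:
            warnings.warn(
                f"{call.chrom}:{call.pos}: call outside exons, ignored"
            )
            continue
        ref, alt = call.ref, call.alt
        if model.strand == "-":
            ref, alt = _COMP[ref], _COMP[alt]
        current = seq[cds_pos - 1]
        if current == "N":
            continue  # masked reference site stays masked
        if current != ref:
            raise ReferenceMismatchError(
                f"{call.chrom}:{call.pos} (c.{cds_pos}): VCF REF {call.ref} maps to "
                f"{ref} but reference CDS has {current}"
            )
        genotype = call.genotype
        if genotype == "missing":
            warnings.warn(f"{call.chrom}:{call.pos}: missing genotype treated as hom_ref")
            genotype = "hom_ref"
        if genotype == "hom_alt":
            seq[cds_pos - 1] = alt
        elif genotype == "het":
            if het_policy == "alt":
                seq[cds_pos - 1] = alt
            elif het_policy == "mask":
                seq[cds_pos - 1] = "N"
            # "ref": leave as is
    return CodingSequence(
        id=ref_cds.id,
        seq="".join(seq),
        is_cds=ref_cds.is_cds,
        source=f"consensus({ref_cds.id})",
    )
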