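"""Enumerate and classify coding substitutions between a sample CDS and a
baseline (typically ancestral) CDS.

Ancient DNA accumulates post-mortem deamination damage that reads out as
transitions. Two directional classes are distinguished:

TS1 (A->G and T->C)
    deamination of adenine to hypoxanthine, read as G (and its
    complementary-strand mirror image),
TS2 (C->T and G->A)
    deamination of cytosine or 5-methylcytosine to uracil/thymine (and its
    mirror image).

All eight transversions fall outside both classes and cannot be produced
by deamination, so they are the candidate true mutations. Any TS-typed
substitution is attributed to degradation — a deliberately strict rule;
records keep a ``both_possible`` reading (a TS-typed change could still be
a genuine transition mutation), so strictness is a presentation choice.

Protein consequences use HGVS-style numbering on the full-length precursor:
residue_index = floor((cds_pos - 1) / 3) + 1 with the initiator Met as
residue 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .seqio import CodingSequence, NUCLEOTIDES

TS1 = "TS1"
TS2 = "TS2"
NONE = "NONE"

_TS1_PAIRS = {("A", "G"), ("T", "C")}
_TS2_PAIRS = {("C", "T"), ("G", "A")}

_C_NOTATION_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


class LengthMismatchError(ValueError):
    """Sequences of unequal length; no implicit alignment is performed."""


class ConsistencyError(ValueError):
    """Record's reference base disagrees with the CDS."""


def classify_transition(ref_base: str, alt_base: str) -> str:
    """Type a substitution as TS1, TS2 or NONE (transversion)."""
    if ref_base not in NUCLEOTIDES or alt_base not in NUCLEOTIDES:
        raise ValueError(f"bases must be in ACGT, got {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError(f"identical bases {ref_base!r}: not a substitution")
    pair = (ref_base, alt_base)
    if pair in _TS1_PAIRS:
        return TS1
    if pair in _TS2_PAIRS:
        return TS2
    return NONE


@dataclass(frozen=True)
class ProteinConsequence:
    """Effect of a coding substitution on the translated protein."""

    residue_index: int
    ref_aa: str
    alt_aa: str
    synonymous: bool
    undetermined: bool = False

    @property
    def p_notation(self) -> str:
        if self.undetermined:
            return "undetermined"
        if self.synonymous:
            return "synonymous"
        return f"{self.ref_aa}{self.residue_index}{self.alt_aa}"


@dataclass(frozen=True)
class SubstitutionRecord:
    """One single-nucleotide coding substitution in c.-notation."""

    cds_pos: int
    ref_base: str
    alt_base: str
    transition_type: str = NONE
    consequence: Optional[ProteinConsequence] = None

    def __post_init__(self) -> None:
        expected = classify_transition(self.ref_base, self.alt_base)
        if self.transition_type != expected:
            raise ValueError(
                f"{self.c_notation}: transition_type {self.transition_type} "
                f"inconsistent with bases (expected {expected})"
            )

    @property
    def c_notation(self) -> str:
        return f"c.{self.cds_pos}{self.ref_base}>{self.alt_base}"

    @property
    def residue_index(self) -> int:
        return (self.cds_pos - 1) // 3 + 1

    @property
    def both_possible(self) -> bool:
        """TS-typed changes could be damage or a genuine transition mutation."""
        return self.transition_type in (TS1, TS2)


def make_record(cds_pos: int, ref_base: str, alt_base: str) -> SubstitutionRecord:
    """Build a record with its transition type filled in."""
    return SubstitutionRecord(
        cds_pos=cds_pos,
        ref_base=ref_base,
        alt_base=alt_base,
        transition_type=classify_transition(ref_base, alt_base),
    )


def parse_c_notation(notation: str) -> SubstitutionRecord:
    """Parse a string like ``c.909A>C`` into a classified record."""
    m = _C_NOTATION_RE.match(notation.strip())
    if not m:
        raise ValueError(f"cannot parse c.-notation {notation!r}")
    return make_record(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True)
class SubstitutionScan:
    """Result of comparing two equal-length CDSs.

    Iterable over its records; ``masked_sites`` counts positions skipped
    because either sequence carried N.
    """

    records: tuple[SubstitutionRecord, ...]
    masked_sites: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def enumerate_substitutions(
    sample: CodingSequence, baseline: CodingSequence
) -> SubstitutionScan:
    """List positions where sample and baseline carry different ACGT bases.

    Positions with N in either sequence are skipped and tallied in
    ``masked_sites``. Records are sorted by CDS position; the record's
    ref is the baseline base and alt the sample base.
    """
    if len(sample) != len(baseline):
        raise LengthMismatchError(
            f"lengths differ ({len(sample)} vs {len(baseline)}); "
            "sequences must be pre-aligned and equal length"
        )
    if not (sample.is_cds and baseline.is_cds):
        raise ValueError("both sequences must be CDSs (is_cds=True)")
    records = []
    masked = 0
    for i, (b, s) in enumerate(zip(baseline.seq, sample.seq), start=1):
        if b == "N" or s == "N":
            masked += 1
            continue
        if b != s:
            records.append(make_record(i, b, s))
    return SubstitutionScan(records=tuple(records), masked_sites=masked)


def protein_consequence(
    sub: SubstitutionRecord, cds: CodingSequence
) -> ProteinConsequence:
    """Translate the codon affected by ``sub`` before and after the change.

    ``cds`` is the baseline sequence carrying the record's reference base.
    Codons containing N translate to an undetermined consequence.
    """
    if sub.cds_pos > len(cds):
        raise ConsistencyError(
            f"{sub.c_notation}: position beyond CDS of length {len(cds)}"
        )
    codon_idx = (sub.cds_pos - 1) // 3
    codon = cds.seq[codon_idx * 3 : codon_idx * 3 + 3]
    offset = (sub.cds_pos - 1) % 3
    if codon[offset] != sub.ref_base and codon[offset] != "N":
        raise ConsistencyError(
            f"{sub.c_notation}: CDS has {codon[offset]} at position {sub.cds_pos}"
        )
    alt_codon = codon[:offset] + sub.alt_base + codon[offset + 1 :]
    if "N" in codon or "N" in alt_codon:
        return ProteinConsequence(
            residue_index=codon_idx + 1,
            ref_aa="X",
            alt_aa="X",
            synonymous=False,
            undetermined=True,
        )
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return ProteinConsequence(
        residue_index=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
    )


def annotate_consequences(
    scan_or_records: Iterable[SubstitutionRecord], cds: CodingSequence
) -> list[SubstitutionRecord]:
    """Return records with their protein consequences filled in."""
    return [
        replace(rec, consequence=protein_consequence(rec, cds))
        for rec in scan_or_records
    ]


@dataclass(frozen=True)
class DamageReport:
    """Deamination-typing tally plus the expected damage count in a target
    gene, scaled from a control gene by CDS length."""

    n_total: int
    n_ts1: int
    n_ts2: int
    n_none: int
    control_length: int
    target_length: int

    @property
    def n_ts(self) -> int:
        return self.n_ts1 + self.n_ts2

    @property
    def expected_damage_in_target(self) -> float:
        return self.n_ts * self.target_length / self.control_length

    def summary(self) -> str:
        return (
            f"{self.n_ts} of {self.n_total} substitutions are deamination-consistent "
            f"(TS1={self.n_ts1}, TS2={self.n_ts2}); expected damage in target of "
            f"length {self.target_length}: {self.expected_damage_in_target:.1f}"
        )


def damage_report(
    subs: Iterable[SubstitutionRecord], control_length: int, target_length: int
) -> DamageReport:
    """Tally TS1/TS2/transversion counts in a control gene and scale the
    TS count to a target gene of possibly different length."""
    if control_length <= 0 or target_length <= 0:
        raise ValueError("lengths must be positive")
    subs = list(subs)
    n_ts1 = sum(1 for s in subs if s.transition_type == TS1)
    n_ts2 = sum(1 for s in subs if s.transition_type == TS2)
    return DamageReport(
        n_total=len(subs),
        n_ts1=n_ts1,
        n_ts2=n_ts2,
        n_none=len(subs) - n_ts1 - n_ts2,
        control_length=control_length,
        target_length=target_length,
    )


def mutation_candidates(
    subs: Iterable[SubstitutionRecord],
    exclude_shared_with_outgroup: Optional[set[str]] = None,
) -> list[SubstitutionRecord]:
    """Substitutions not attributable to deamination (transversions only).

    ``exclude_shared_with_outgroup`` optionally drops sites (by c.-notation)
    that also occur on an outgroup lineage and are therefore better read as
    independent events than as lineage-specific mutations.
    """
    exclude = exclude_shared_with_outgroup or set()
    return [
        s
        for s in subs
        if s.transition_type == NONE and s.c_notation not in exclude
    ]


def comparative_report(
    per_sample_subs: dict[str, Sequence[SubstitutionRecord]],
    site_annotations: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Presence/absence matrix of derived alleles across samples.

    All samples must have been compared to the same baseline. Rows are
    sites (c.-notation, ordered by CDS position); one boolean column per
    sample, plus ``n_samples``, ``shared_by_all`` and a free-text
    ``annotation`` column. Shared-by-subset sites order mutations on the
    tree: a change carried by every sample predates sample-specific ones.
    """
    site_annotations = site_annotations or {}
    samples = list(per_sample_subs)
    by_site: dict[str, SubstitutionRecord] = {}
    ref_at_pos: dict[int, str] = {}
    for recs in per_sample_subs.values():
        for rec in recs:
            known_ref = ref_at_pos.setdefault(rec.cds_pos, rec.ref_base)
            if known_ref != rec.ref_base:
                raise ValueError(
                    f"inconsistent baselines at c.{rec.cds_pos}: "
                    f"ref {known_ref} vs {rec.ref_base}"
                )
            by_site.setdefault(rec.c_notation, rec)
    sites = sorted(by_site.values(), key=lambda r: r.cds_pos)
    rows = []
    for rec in sites:
        presence = {
            s: any(r.c_notation == rec.c_notation for r in per_sample_subs[s])
            for s in samples
        }
        n = sum(presence.values())
        row = {
            "site": rec.c_notation,
            "cds_pos": rec.cds_pos,
            "transition_type": rec.transition_type,
            **presence,
            "n_samples": n,
            "shared_by_all": n == len(samples),
            "annotation": site_annotations.get(rec.c_notation, ""),
        }
        if rec.consequence is not None:
            row["consequence"] = rec.consequence.p_notation
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("site")
    return df


def records_to_table_rows(records: Iterable[SubstitutionRecord]) -> list[dict]:
    """Render records in the four-column substitution-table layout."""
    rows = []
    for rec in records:
        cause = "DNA degradation" if rec.both_possible else "mutation"
        consequence = rec.consequence.p_notation if rec.consequence else ""
        rows.append(
            {
                "substitution": rec.c_notation,
                "transition_type": rec.transition_type.lower()
                if rec.transition_type == NONE
                else rec.transition_type,
                "potential_cause": cause,
                "consequence": consequence,
            }
        )
    return rows
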