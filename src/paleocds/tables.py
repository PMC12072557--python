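"""Published substitution catalogs for the Denisova 3 genome.

These are the printed lists of coding substitutions observed in the
Denisovan (*Denisova 3*) *GLUD1* and *GLUD2* sequences relative to the
reconstructed ancestral sequence, bundled as fixtures for classification
and reporting. *GLUD1* is under strong purifying selection, so its
substitution list serves as a damage control for the equally long *GLUD2*.

Each row: (c.-notation, consequence) where consequence is "synonymous",
a p.-style missense string, or "" when not printed.
"""

from __future__ import annotations

from .substitutions import SubstitutionRecord, parse_c_notation
from .seqio import TSV_COLUMNS

# Denisovan GLUD1 substitutions vs the ancestral sequence (damage control).
GLUD1_DENISOVAN: tuple[tuple[str, str], ...] = (
    ("c.342T>C", ""),
    ("c.376G>A", ""),
    ("c.462T>C", ""),
    ("c.527T>C", ""),
    ("c.771T>C", ""),
    ("c.909A>C", "synonymous"),  # Thr303, the single transversion
    ("c.942A>G", ""),
    ("c.1175A>G", ""),
    ("c.1255G>A", ""),
    ("c.1479G>A", ""),
)

# Denisovan GLUD2 substitutions vs the ancestral sequence.
GLUD2_DENISOVAN: tuple[tuple[str, str], ...] = (
    ("c.94C>A", "synonymous"),  # Arg32
    ("c.103G>A", "G35R"),
    ("c.123G>T", "synonymous"),  # Ser41
    ("c.232G>A", "A78T"),
    ("c.460A>C", "T154P"),
    ("c.582C>T", "synonymous"),
    ("c.986C>T", "A329V"),
    ("c.1072A>C", "I358L"),
    ("c.1184G>A", "R395K"),
    ("c.1241A>G", "D414G"),
    ("c.1371A>G", "synonymous"),
    ("c.1395C>T", "synonymous"),
    ("c.1492T>G", "S498A"),
)

# Sites also observed on other lineages; used to separate lineage-specific
# mutation candidates from likely independent events.
SITE_ANNOTATIONS: dict[str, str] = {
    "c.1072A>C": "also found on the chimpanzee branch (independent occurrence)",
    "c.227G>A": "shared by Altai Neanderthal and Denisovan (R76H)",
    "c.1055G>A": "modern humans and younger Neanderthals (R352K)",
    "c.1402A>C": "all Homo samples (M468L)",
}

# Printed c.-position -> protein-residue pairings used as an arithmetic check.
C_TO_P_PAIRINGS: tuple[tuple[int, int], ...] = (
    (227, 76),
    (460, 154),
    (1055, 352),
    (1072, 358),
    (1402, 468),
    (1492, 498),
)

# Full-length GDH precursor: 558 aa + stop codon.
GDH_CDS_LENGTH = 559 * 3


def catalog_records(catalog: tuple[tuple[str, str], ...]) -> list[SubstitutionRecord]:
    """Parse a catalog into classified substitution records."""
    return [parse_c_notation(notation) for notation, _ in catalog]


def catalog_table_rows(catalog: tuple[tuple[str, str], ...]) -> list[dict]:
    """Catalog rendered in the standard four-column table layout."""
    rows = []
    for notation, consequence in catalog:
        rec = parse_c_notation(notation)
        cause = (
            "DNA degradation"
            if rec.transition_type in ("TS1", "TS2")
            else ("synonymous mutation" if consequence == "synonymous" else "mutation")
        )
        rows.append(
            dict(
                zip(
                    TSV_COLUMNS,
                    [
                        notation,
                        rec.transition_type if rec.both_possible else "none",
                        cause,
                        consequence,
                    ],
                )
            )
        )
    return rows


def make_paper_fixture(out_dir) -> dict[str, str]:
    """Write both catalogs as TSV fixtures; returns name -> path."""
    from pathlib import Path

    from .seqio import write_tsv_substitutions

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, catalog in (
        ("glud1_denisovan", GLUD1_DENISOVAN),
        ("glud2_denisovan", GLUD2_DENISOVAN),
    ):
        path = out / f"{name}_substitutions.tsv"
        write_tsv_substitutions(catalog_table_rows(catalog), path)
        paths[name] = str(path)
    return paths
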