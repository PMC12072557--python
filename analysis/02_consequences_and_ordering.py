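"""Protein consequences of the Denisovan GLUD2 mutation candidates and the
ordering of the two human-specific GDH2 substitutions.

Consequence calling runs on a synthetic GLUD2-like surrogate CDS whose
codons at every cataloged site are pinned to the published states, so the
printed split — two synonymous changes (Arg32, Ser41) and the missense
trio T154P / I358L / S498A — is reproduced by translation, not lookup.

The cross-sample presence/absence matrix then orders the human-lineage
changes: c.1402A>C (M468L) is carried by every human-clade sample, so it
predates c.1055G>A (R352K), which only modern humans and the younger
Neanderthals (Vindija, Chagyrskaya) carry; c.227G>A (R76H) marks the
Altai Neanderthal + Denisovan pair.

Writes results/glud2_consequences.tsv and results/mutation_ordering.tsv.
"""

from pathlib import Path

from paleocds.seqio import write_tsv_substitutions
from paleocds.simulate import make_glud2_like_cds
from paleocds.substitutions import (
    annotate_consequences,
    comparative_report,
    mutation_candidates,
    parse_c_notation,
    records_to_table_rows,
)
from paleocds.tables import GLUD2_DENISOVAN, SITE_ANNOTATIONS, catalog_records

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# Derived-allele sharing pattern of the human-clade samples relative to the
# human/chimpanzee ancestor, per the comparative genome analysis.
SHARED_ALL = ["c.1402A>C"]              # M468L: every Homo sample
SHARED_MODERN_YOUNG = ["c.1055G>A"]     # R352K: modern + younger Neanderthals
SHARED_ALTAI_DENISOVAN = ["c.227G>A"]   # R76H


def main() -> None:
    cds = make_glud2_like_cds(seed=0)
    candidates = mutation_candidates(catalog_records(GLUD2_DENISOVAN))
    annotated = annotate_consequences(candidates, cds)
    write_tsv_substitutions(records_to_table_rows(annotated), OUT / "glud2_consequences.tsv")
    print("Denisovan GLUD2 mutation candidates:")
    for rec in annotated:
        print(f"  {rec.c_notation}: {rec.consequence.p_notation}")

    per_sample = {
        "modern_human": SHARED_ALL + SHARED_MODERN_YOUNG,
        "vindija": SHARED_ALL + SHARED_MODERN_YOUNG,
        "chagyrskaya": SHARED_ALL + SHARED_MODERN_YOUNG,
        "altai": SHARED_ALL + SHARED_ALTAI_DENISOVAN,
        "denisova3": SHARED_ALL
        + SHARED_ALTAI_DENISOVAN
        + [c.c_notation for c in candidates],
    }
    matrix = comparative_report(
        {k: [parse_c_notation(n) for n in v] for k, v in per_sample.items()},
        site_annotations=SITE_ANNOTATIONS,
    )
    matrix.to_csv(OUT / "mutation_ordering.tsv", sep="\t")
    shared = matrix.index[matrix["shared_by_all"]].tolist()
    print(f"\nshared by all human-clade samples (earliest): {shared}")
    print(
        "subset sites:",
        {
            site: int(matrix.loc[site, "n_samples"])
            for site in matrix.index
            if not matrix.loc[site, "shared_by_all"]
        },
    )
    print(f"wrote {OUT}/mutation_ordering.tsv")


if __name__ == "__main__":
    main()
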