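"""Type the published Denisovan substitution catalogs as deamination damage
vs candidate mutations.

GLUD1 is under purifying selection, so its ten Denisovan substitutions act
as a damage control: nine are TS1/TS2 transitions (deamination-consistent)
and the one transversion (c.909A>C) is synonymous. Scaling the control's
TS count by CDS length (the two genes are equally long) predicts ~9
degradation substitutions in GLUD2, matching the 8 TS-typed records among
its 13; the 5 transversions are the mutation candidates.

Writes results/table_glud1_typed.tsv, results/table_glud2_typed.tsv and
results/damage_summary.json.
"""

import json
from pathlib import Path

from paleocds.seqio import write_tsv_substitutions
from paleocds.substitutions import damage_report, mutation_candidates
from paleocds.tables import (
    GDH_CDS_LENGTH,
    GLUD1_DENISOVAN,
    GLUD2_DENISOVAN,
    catalog_records,
    catalog_table_rows,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    summary = {}
    for name, catalog in (("glud1", GLUD1_DENISOVAN), ("glud2", GLUD2_DENISOVAN)):
        records = catalog_records(catalog)
        rep = damage_report(records, GDH_CDS_LENGTH, GDH_CDS_LENGTH)
        candidates = mutation_candidates(records)
        write_tsv_substitutions(catalog_table_rows(catalog), OUT / f"table_{name}_typed.tsv")
        summary[name] = {
            "n_total": rep.n_total,
            "n_ts1": rep.n_ts1,
            "n_ts2": rep.n_ts2,
            "deamination_consistent": f"{rep.n_ts} of {rep.n_total}",
            "mutation_candidates": [c.c_notation for c in candidates],
            "expected_damage_in_equal_length_target": rep.expected_damage_in_target,
        }
        print(f"{name.upper()}: {rep.summary()}")
        print(f"  candidates: {', '.join(c.c_notation for c in candidates)}")
    (OUT / "damage_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"\nwrote {OUT}/damage_summary.json")


if __name__ == "__main__":
    main()
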