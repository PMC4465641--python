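#!/usr/bin/env python
"""Filter the per-experiment peptide tables to the high-confidence set.

Applies each dataset's specificity/score/engine filters, the
missed-cleavage support rule, and the >= 2-experiments requirement, then
grades the result against the generator's truth labels.
"""

import json
from pathlib import Path

from isopept import filtering as fl
from isopept import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    per_ds = {
        p.stem: fl.read_peptide_tsv(p)
        for p in sorted((OUT / "experiments").glob("*.tsv"))
    }
    kept, audits = fl.run_filter_pipeline(per_ds, sd.default_filter_configs())
    fl.write_peptide_tsv(kept, OUT / "filtered_peptides.tsv")
    (OUT / "filter_audit.json").write_text(json.dumps(audits, indent=1))

    truth = json.loads((OUT / "truth.json").read_text())
    origin = truth["peptide_origin"]
    kept_canon = {r.canon_seq for r in kept}
    clean = {c for c, o in origin.items() if o.startswith("clean")}
    artifacts = {c for c, o in origin.items() if o.startswith("artifact")}
    print(f"kept {len(kept_canon)} unique high-confidence peptides "
          f"from {sum(len(v) for v in per_ds.values())} observations")
    print(f"  artifacts surviving: {len(artifacts & kept_canon)} of {len(artifacts)}")
    print(f"  clean peptides lost: {len(clean - kept_canon)} of {len(clean)}")
    for ds, audit in sorted(audits.items()):
        print(f"  {ds}: removed {audit}")


if __name__ == "__main__":
    main()
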