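"""GO enrichment of a target gene set against a background.

Plants one over-represented term into a synthetic annotation and shows it
is the one recovered at a 10% FDR, with observed/expected counts and the
odds ratio.
"""

import numpy as np
import pandas as pd

from sepkit import GOMap, analyze_all_go, analyze_go_term

rng = np.random.default_rng(5)
genes = [f"g{i}" for i in range(400)]
background = set(genes)

rows = []
for t in range(30):  # thirty unremarkable terms
    for g in rng.choice(genes, size=12, replace=False):
        rows.append({"gene_id": g, "go_id": f"GO:{t:07d}", "aspect": "BP",
                     "descr": f"background process {t}"})
target = set(rng.choice(genes, size=40, replace=False))
for g in sorted(target)[:20]:  # planted: half the target shares one term
    rows.append({"gene_id": g, "go_id": "GO:1111111", "aspect": "BP",
                 "descr": "planted process"})
gomap = GOMap(pd.DataFrame(rows))

hits = analyze_all_go(target, background, gomap, fdr=0.10)
print(f"{len(hits)} terms pass a 10% FDR:")
print(hits[["go_id", "description", "odds", "O", "E", "p_value", "q_value"]]
      .to_string(index=False))

row = analyze_go_term(target, background, gomap, "GO:1111111")
print(f"\nsingle-term view: O={row.observed} target genes annotated vs "
      f"E={row.expected:.2f} expected under independence "
      f"(odds {row.odds:.1f}, p={row.p_value:.2e})")
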