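#!/usr/bin/env python
"""Functional co-analysis checks on the packaged GO-slim contingency rows.

Recomputes the one-sided Fisher exact p for every packaged GO-slim
contingency table and verifies it is bounded by the printed Bonferroni-
corrected value (the original correction factor — the number of GO-slim
terms per branch — is not recoverable, so the raw p can only bound the
printed value).  Also demonstrates the modification-interplay proportion
on the published arginine-methylation/phosphorylation overlap counts.
"""

from pathlib import Path

import pandas as pd

from methylsieve.fixtures import load_table4
from methylsieve.functional_stats import ContingencyTable, interplay_proportion
from methylsieve.io import write_tsv

ROOT = Path(__file__).resolve().parents[1]


def main():
    rows = []
    for row in load_table4().itertuples():
        tab = ContingencyTable(int(row.n11), int(row.n12), int(row.n21),
                               int(row.n22))
        raw = tab.fisher_greater()
        rows.append(
            {"branch": row.branch, "term": row.term, "raw_fisher_p": raw,
             "printed_corrected_p": row.corrected_p,
             "raw_bounds_printed": raw <= float(row.corrected_p)}
        )
    df = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    write_tsv(results / "go_enrichment_check.tsv", df)
    n_ok = int(df.raw_bounds_printed.sum())
    print(f"{n_ok}/{len(df)} GO-slim rows: recomputed one-sided Fisher p is "
          "bounded by the printed Bonferroni-corrected value")
    top = df.iloc[df.raw_fisher_p.idxmin()]
    print(f"strongest enrichment: {top.term} (raw p = {top.raw_fisher_p:.2e})")

    # arginine methylation / phosphorylation interplay, published counts
    flags = {f"P{i}": i < 30 for i in range(32)}
    out = interplay_proportion([f"P{i}" for i in range(32)], flags)
    print(f"interplay proportion: {out['flagged']}/{out['total']} = "
          f"{out['percent_rounded']}% of arginine-methylated proteins with "
          "known phosphorylation")


if __name__ == "__main__":
    main()
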