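"""Assemble ranked hit tables and the screen-survival scatter table.

Per-drug top-10 hit lists per cell line, the multi-drug hit ranking, and
the join of multi-drug scores with per-gene survival p-values.
"""

import json
from pathlib import Path

import pandas as pd

from resistscreen import reporting

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)
    gs = pd.read_csv(ROOT / "scores" / "gene_scores.tsv", sep="\t")
    md = pd.read_csv(ROOT / "scores" / "multidrug_scores.tsv", sep="\t")
    cox = pd.read_csv(ROOT / "survival" / "cox_results.tsv", sep="\t")
    truth = json.loads((ROOT / "sim" / "truth.json").read_text())

    per_drug = reporting.rank_hits_per_drug(gs, top_k=10)
    per_drug.to_csv(out / "hits_per_drug.tsv", sep="\t", index=False)
    hits = reporting.rank_hits(md)
    hits.to_csv(out / "hits_multidrug.tsv", sep="\t", index=False)
    joined = reporting.integrate_screen_survival(hits, cox)
    joined.to_csv(out / "screen_survival_join.tsv", sep="\t", index=False)

    planted = set(truth["planted_genes"])
    in_top10 = per_drug[per_drug["gene"].isin(planted)]
    print(f"planted genes occupy {len(in_top10)} of {len(per_drug)} per-drug top-10 slots")
    top = hits[hits["rank"] <= 10]
    print(f"multi-drug top-10 per cell line contains "
          f"{int(top['gene'].isin(planted).sum())} planted-gene entries")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
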