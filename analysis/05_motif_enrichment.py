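#!/usr/bin/env python
"""Scan promoter windows for PWM matches and stratify by breadth pattern.

Generates promoter sequences with motif occurrences planted at a higher rate
in narrow-peak promoters (2x) and half rate in unmarked promoters, scans
both strands with the log-odds threshold at 80 % of each motif's maximum
score, and compares per-pattern match densities against the marked-TSS
background and the marked-vs-all enrichment filter.
"""

from pathlib import Path

import pandas as pd

from tssbreadth import motifs as mo
from tssbreadth import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 11


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = syn.GeneratorConfig(n_tss=1500, seed=SEED)
    truth = syn.simulate_truth(cfg)
    seqs, pwms, planted = syn.generate_motif_data(cfg, truth)
    mo.write_meme(pwms, OUT / "motifs.meme")
    print(f"scanning {len(seqs)} promoters for {len(pwms)} motifs "
          f"({', '.join(p.consensus for p in pwms)})")

    matches = pd.concat([mo.scan(seqs, p) for p in pwms], ignore_index=True)
    matches.to_csv(OUT / "motif_matches.tsv", sep="\t", index=False)
    print(f"{len(matches)} matches found ({len(planted)} planted)")

    calls = pd.DataFrame({"gene_id": truth.table["gene_id"],
                          "label": truth.table["pattern_ctrl"]})
    overall, profile = mo.profile_enrichment(matches, calls)
    overall.to_csv(OUT / "pattern_enrichment.tsv", sep="\t", index=False)
    profile.to_csv(OUT / "positional_profiles.tsv", sep="\t", index=False)
    print("match density per TSS relative to the marked background:")
    for row in overall.itertuples():
        flag = " (enriched >=20%)" if row.enriched else ""
        print(f"  {row.pattern:>20}: ratio {row.enrichment_ratio:.2f}{flag}")

    marked = mo.overall_marked_enrichment(matches, calls)
    marked.to_csv(OUT / "marked_vs_all_enrichment.tsv", sep="\t", index=False)
    n_enr = int(marked["enriched"].sum())
    print(f"{n_enr}/{len(marked)} motifs enriched >=20% at marked TSSs")


if __name__ == "__main__":
    main()
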