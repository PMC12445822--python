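# kacmeta

Cross-species meta-analysis of lysine acetylation (Kac). Published
acetylomes — lists of proteins with their acetylated lysine positions —
differ wildly in proteome size, so raw site counts are not comparable
between species. `kacmeta` implements the analysis stack used to compare
dozens of acetylomes across archaea, bacteria, fungi, protozoa, worms,
plants, insects, fish and mammals:

* **Normalized acetylome metrics** — percentage of acetylated lysines over
  the proteome's total lysines, and of Kac proteins over proteome size:
  `pct_sites = 100 · n_Kac_sites / n_lysines`,
  `pct_proteins = 100 · n_Kac_proteins / n_proteins`.
* **Site-count distributions** — each Kac protein binned by its number of
  distinct acetylated positions into {1}, {2}, {3–5}, {6–10}, {>10}, with
  count-weighted pooling across acetylomes, plus the exactly-5 / 6–10 / >10
  split of highly acetylated proteins used for domain summaries.
* **Fisher-exact GO/KEGG enrichment** — per-term 2×2 contingency tables
  (study-with-term, study-without, background-with, rest) and the one-sided
  hypergeometric tail p = Σ_{x≥a} C(K,x)·C(N−K,n−x)/C(N,n), evaluated in
  exact integer arithmetic (log-space above N = 10⁴), with fold enrichment
  (a/(a+b))/((a+c)/N), optional GO `is_a` propagation and
  Benjamini–Hochberg correction. OBO ontologies and KEGG BRITE htext files
  are parsed natively.
* **Pathway acetylation matrices** — per-enzyme, per-species presence
  (acetylated at ≥1 site), site counts and Kac percentage for the core
  glycolytic and TCA-cycle enzymes, with "not assessed" distinguished from
  "not acetylated".
* **Regulatory-lysine conservation** — affine-gap Needleman–Wunsch
  (BLOSUM62, gap open −10, extend −0.5) to project a regulatory site (e.g.
  an Hsp70 K77 or aldolase K147) onto orthologs, classifying each target
  column as conserved K, conservative R, other, or gap; motif scanning with
  bounded mismatches; percent identity.
* **Structure-region measurements** — funnel lysine counts (FK/FKac) over
  named residue ranges, sphere-grid cavity volume (count grid points inside
  an 8 Å sphere farther than r_atom + r_probe from every atom, × spacing³),
  and minimum residue–residue distances, over single- or multi-model PDB
  frames.
* **Synthetic data with planted truth** — generators for every input format
  (proteome FASTA, acetylome tables, annotation tables, ortholog families,
  toy structures) whose ledgers state exactly what was planted, so every
  stage is testable without downloads.

## Worked example

```python
from kacmeta.synthetic_data import (
    SyntheticSpec, generate_proteome, generate_acetylome)
from kacmeta.site_statistics import summarize, site_count_distribution

spec = SyntheticSpec(seed=1, n_proteins=1000, kac_protein_fraction=1.0)
proteome, _ = generate_proteome(spec)
dataset, _ = generate_acetylome(proteome, spec)

s = summarize(dataset, proteome)
print(f"{s.n_kac_sites} Kac sites = {s.pct_kac_sites:.2f}% of lysines")
print(f"{s.n_kac_proteins} Kac proteins = {s.pct_kac_proteins:.1f}% of proteome")
print(site_count_distribution(dataset).to_frame().to_string(index=False))
```

prints

```
2654 Kac sites = 8.45% of lysines
1000 Kac proteins = 100.0% of proteome
 bin  n_proteins  percent
   1         500     50.0
   2         200     20.0
 3-5         200     20.0
6-10          70      7.0
 >10          30      3.0
```

The acetylome was planted with bin proportions (0.50, 0.20, 0.20, 0.07,
0.03) under deterministic quota assignment, and the distribution recovers
them exactly; the site percentage stays below 10% because each planted
protein carries only a handful of its ~30 lysines acetylated.

A thin CLI mirrors the library (`kacmeta ingest`, `kacmeta stats`,
`kacmeta enrich`, `kacmeta simulate`, `kacmeta volume`).

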