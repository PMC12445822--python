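# Methods

## Normalization and site-count statistics

Acetylome comparisons across species are normalized by the denominators of
each species' predicted proteome: the Kac-site percentage divides the
number of distinct acetylated positions by the proteome's total lysine
count, and the Kac-protein percentage divides the number of proteins with
at least one site by the proteome size. Both are reported on the 0–100
scale. Lysines are counted case-insensitively; ambiguity codes (X/B/Z/U)
are accepted in sequences but never counted as K, so the denominator is
deterministic. Percentages are undefined (an error) when a denominator is
zero rather than silently 0 or NaN.

A protein's site count is its number of *distinct* acetylated positions —
duplicate (protein, position) rows, common in supplementary tables that
list one row per peptide, are collapsed on ingestion. The site-count
distribution uses five disjoint bins {1}, {2}, {3–5}, {6–10}, {>10}; the
"exactly 5" class used for the highly-acetylated selection overlaps {3–5}
and therefore lives only in that selection (classes exactly-5 / 6–10 / >10,
disjoint by construction), not in the distribution. Pooling across
acetylomes sums counts and recomputes percentages from the pooled counts;
a mean of per-acetylome percentages would weight a 100-protein acetylome
as much as a 10,000-protein one.

Site validation defaults to lenient-with-report: a reported position whose
proteome residue is not lysine, or whose protein is missing, is flagged and
tallied (`n_valid + n_mismatch + n_unmapped = n_rows_after_dedup`) but
retained, because published tables were built against proteome releases
that may differ from the one at hand. Strict mode turns both into hard
errors and is what the synthetic tests use. Proteome files are fingerprinted
by SHA-256 checksum rather than by guessed release versions.

## Enrichment engine

For each term the 2×2 table is (a) study genes with the term, (b) study
genes without, (c) background genes with the term outside the study, (d)
the rest. The one-sided enrichment p-value is the hypergeometric upper
tail, evaluated as a sum of exact integer binomial products divided by
C(N, n); above N = 10⁴ the scipy log-space survival function takes over, so
the computation is stable to at least N = 10⁶. This makes p-values exact to
float rounding for every desk-scale background — the test suite checks
agreement with full rational enumeration at 10⁻¹² relative error over all
tables with N ≤ 60.

Fold enrichment is the study frequency over the background frequency.
Results cover every term with a ≥ 1 and are sorted by fold, then p.

Two knobs are deliberately exposed rather than fixed, because the upstream
analysis convention is ambiguous in the literature this mirrors:

* **Background.** Default is the annotated universe (all genes with ≥ 1
  annotation), the least-assuming population; study genes without any
  annotation then fall outside the population and are dropped, as is
  conventional for annotated-universe backgrounds. An explicit background
  set can be passed instead, in which case the study must be a subset of
  it.
* **GO propagation.** `is_a` ancestor propagation is on by default
  (standard practice); turning it off reproduces the behaviour of scripts
  that test only direct annotations. Both paths are tested.

Significance defaults to raw p < 0.01 with no multiplicity correction,
mirroring the plain p-cut convention of the upstream analyses;
Benjamini–Hochberg is available (`correction="bh"`, via scipy's
false-discovery control) and is never more permissive than the raw cut.

OBO parsing is delegated to `obonet` after a light structural pre-scan
that reports malformed stanza lines by number; `is_a` cycles are rejected.
KEGG BRITE htext parsing maps D-level KO entries to their enclosing
C-level pathway; KOs encountered before any pathway header are flagged as
orphans instead of being silently dropped.

## Conservation projection

Pairwise global alignment is an in-repo Gotoh (three-state affine)
implementation: BLOSUM62, gap open −10, gap extend −0.5, with a gap run of
length L scoring open + (L−1)·extend and end gaps penalized. The aligner
is deliberately not an external-tool wrapper, so projection is hermetic;
the test suite validates scores against Biopython's independent
`PairwiseAligner` on random pairs and against exhaustive alignment
enumeration on tiny ones. Traceback ties break deterministically
(substitution > gap-in-target > gap-in-reference).

A reference site is projected by locating its alignment column and reading
the target residue and coordinate there. Classification is exact-match: K
→ conserved, R → conservative (the charge-preserving substitution; other
positives such as histidine count as "other"), gap → gap. Percent identity
divides identical columns by columns where at least one sequence is
non-gap, stated explicitly because "percent identity" is otherwise
ambiguous. Pre-computed alignments, when supplied, take precedence over
the internal aligner.

## Structure-region measurements

Cavity volume uses a sphere-grid scheme: an axis-aligned grid at the given
spacing (default 0.5 Å) centred on the probe centre, keeping points within
the sphere radius (default 8 Å); a point is occluded when within
r_atom + r_probe of any atom. Volume = free points × spacing³. Atomic
radii are a fixed element table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å)
with probe radius defaulting to 0 (free-volume counting). At 0.5 Å spacing
the empty-sphere volume is within 0.5% of 4/3·π·r³ and converges as the
spacing shrinks; seeded multi-atom scenes agree with a 10⁶-point
Monte-Carlo rejection oracle to well under 3%.

Multi-model PDB files are read as trajectories (one frame per MODEL, via
Biopython's parser, ATOM records only); trajectory volume series report
the mean and *population* SD, matching the parenthetical-SD convention of
the measurements this mirrors. Producing frames — the MD engine, force
fields, solvation, pKa prediction, acetyl-group building — is explicitly
out of scope, as is reproducing published MD volume means, which require
hundreds of nanoseconds of simulation; the volume algorithm is instead
validated by the analytic and Monte-Carlo properties above. Funnel lysine
counting is sequence-based: FK counts lysines inside named residue ranges,
FKac those also acetylated; the ranges are configuration inputs because no
per-species funnel coordinates are published.

## Synthetic data and what passing tests show

Generators are pure functions of (spec, seed) — byte-identical output
across runs. Defaults encode the study conditions: lysine frequency 0.07,
protein lengths 250–650, ~15% of proteins acetylated, bin proportions
(0.50, 0.20, 0.20, 0.07, 0.03) echoing the pooled empirical distribution
in which roughly half of Kac proteins carry a single site. Deterministic
quota assignment uses largest-remainder rounding, so the planted bin
proportions are recovered *exactly*, giving the suite a deterministic
acceptance surface; the multinomial mode samples them and is checked
within binomial bounds. Every protein is generated with at least as many
lysines as the largest plantable site count (topping up a small fraction
of short proteins), so quotas are always feasible without biasing the
overall lysine frequency detectably (the 3-SE binomial check passes at
n = 1000 proteins).

The enrichment plant solves per-gene term probabilities (p for study
genes, q for background) from the requested odds ratio and expected term
size, so the planted term's study/background odds equal the plant exactly
in expectation. Power (~97–98% at odds ratio 8, term 30/1000, study 100,
α = 0.01) and null calibration (false-positive rate at or below the
nominal 0.01, reflecting the discreteness-induced conservatism of the
exact test) are measured by simulation at 200 and 500 replicates — sizes
chosen to keep the suite fast while leaving the binomial acceptance
regions tight.

The ortholog-family fixtures (`hsp70_family`, `aldolase_family`,
`soda_family`) are synthetic stand-ins, not database sequences: random
backbones with conserved windows around the key sites, planted
substitutions (K→R in the bacterial/plant Hsp70 targets), N-terminal
extensions that shift the key coordinate (aldolase K147 → K185/K147/K162/
K147/K157 across targets), and planted funnel lysine layouts in which the
human enzyme carries the most acetylated funnel lysines. They exercise the
coordinate arithmetic, alignment robustness and classification rules on
families whose truth is known by construction. What passing tests do *not*
show: behaviour on real mass-spectrometry artifacts (missed cleavages,
FDR-filtered site lists, isoform ambiguity) or on real sequence-divergence
patterns — the generators plant uniform substitution rates, not
position-specific conservation.

## Numerical choices and limitations

* Positions are 1-based everywhere, matching K147-style notation; 0-based
  input tables are shifted on ingestion via the dialect config.
* Fisher p-values: exact integers below N = 10⁴, log-space above; the
  crossover is far above any desk-scale background.
* Ranking ties (equal Kac percentages) break lexicographically and are
  visible in the output rather than arbitrary.
* Grid volume is slightly below the analytic sphere volume at finite
  spacing (boundary points are counted conservatively); the discretization
  error is the dominant term and shrinks with spacing³ sampling density.
* The enzyme catalogs for pathway matrices are curated inputs; no ortholog
  inference (BLAST/OrthoFinder) is attempted, and species absent from a
  catalog yield "not assessed" cells rather than false negatives.
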