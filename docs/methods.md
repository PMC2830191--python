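# Methods

## Mass arithmetic

Peptide masses are monoisotopic [M+H]⁺: the sum of residue masses plus
water plus one proton, with +15.994915 Da per Met/Trp oxidation. The
residue mass table is generated at import time from residue elemental
compositions (C,H,N,O,S counts) and NIST monoisotopic atomic masses, not
hand-typed, so independent composition-summing implementations agree to
< 1 nDa. Methyl increments are exact CH₂ multiples (mono +14.015650,
di +28.031300, tri +42.046950 Da); acetylation is +42.010565 Da, only
0.0364 Da above trimethylation — the reason trimethyl-lysine matches are
discarded outright rather than risked at MALDI-ToF accuracy.

## Digestion

Trypsin cleaves C-terminal to K/R. Suppression of cleavage before proline
is a flag, default on (standard practice; nothing in the protocol this
package models depends on the choice, and the packaged reference windows
avoid KP/RP edge cases). Peptides carry 0 or 1 missed cleavage; every
1-missed-cleavage peptide is the concatenation of two adjacent fully
cleaved peptides, and the fully cleaved peptides tile the mature chain
exactly (property-tested). Coordinates are 1-based inclusive in the parent
protein frame throughout, matching the site notation `mK121`/`dR35`.
Oxidation variants are enumerated from 0 up to min(2, #M+#W) per peptide
(cap configurable). Missed cleavages are counted on the unmodified
sequence; methylation does not change the count.

## Tailor-made tolerance

Because the protein behind each spectrum is known, each spectrum gets its
own error bound: each peak is paired with the nearest theoretical
unmodified mass within a coarse 0.15 Da window and the tolerance is the
median absolute deviation of those pairs. The median (rather than the
mean) is robust to the occasional contaminant pairing. With fewer than 3
pairings the estimate falls back to 0.04 Da, the compendium-wide
average/median error of the data this models; estimates are floored at
0.001 Da so noise-free input remains matchable, and spectra above 0.1 Da
are excluded from site discovery (but not from discovery-rate
computation, which uses its own 1.5 Da window).

## Matching and ambiguity

Every (peak, peptide variant, modification) combination within tolerance
is a match, with exactly one modification instance per peptide
(multi-modified peptides are out of scope). The candidate positions of a
match are all target residues in the peptide, in parent coordinates. A
query mass is unambiguous iff exactly one (peptide span, modification)
identity explains it; oxidation variants of the same peptide+modification
collapse to one identity, and candidate multiplicity within one peptide
does not create ambiguity — localization is the consensus filter's job.

## The five filters

Filters run on the pooled matches of each protein across its replicate
spectra, because the cleaved (0 MC) and read-through (1 MC) forms of a
methylated peptide typically surface in different replicates. Filter 3
groups matches by shared candidate position per modification
identity+degree (sharing a position implies coordinate overlap), requiring
two distinct peptide sequences by default (`require_distinct_peptides`
lowers this to two match instances). Filter 5 is degree-strict: mono- and
di-methyl evidence never merge into one site; a residue supported at both
degrees yields two site records. Audit counts are reported at
peptide-match granularity after every stage and are asserted
non-increasing on every run. A configuration with `max_missed=0` is
rejected: without read-through peptides the overlap filter is unreachable.

## Benchmarking

Artificial benchmark sets sample ~6% of K and R residues per class
(monomethyl-K, dimethyl-K, monomethyl-R, dimethyl-R) and emit all host
peptides (≤ 1 MC, oxidation variants) whose modified mass falls in
500–3000 Da. Each benchmark mass is matched back against its protein at a
fixed tolerance (0.04 Da nominal); one match is one (peptide variant,
modification) pair, scored TP iff the methylation type is correct and the
planted position is among the candidates, FP otherwise, so false
positives arise exactly from mass collisions. tp_rate = 100·TP/(TP+FP) is
a precision over matches; recall (sites with ≥ 1 correct match) is
reported separately since the two answer different questions. Classes
with fewer than 10 test sites are flagged N.D. The rate is non-increasing
in tolerance (property-tested over 0.01–0.10 Da).

## Discovery rates

The identification unit is one replicate spectrum. Proteins with
identical mature sequences are pooled (PMF cannot distinguish them), and
the peptide rate is the fraction of the pooled spectra containing a peak
within 1.5 Da of the peptide's mass. Residue rates sum the rates of
distinct covering peptides, kept separate per methylation degree. The
headline comparison is peptide-level: rates of each site's methylated
peptide forms against rates of all unmodified fully cleaved peptides of
the site proteins (Mann–Whitney); residue-level methylated/unmodified
pairs feed Kendall's τ.

## Motif analysis

Windows are up to ±10 residues around a site, clipped at the termini;
the clipped positions are absent, and the per-offset denominator counts
only windows covering that offset. Named motifs are position-specific
letters anchored on the modified residue (X = any). Enrichment uses the
exact one-sided binomial tail by default rather than the chi-squared
proportion test with continuity correction (also provided, as
`method="prop"`): the observed counts in this setting are small (≤ 8),
where the exact tail is strictly preferable. Bonferroni correction
defaults to 20 letters × 21 offsets = 420 tests. The background is the
residue frequency over the analysed protein set.

## Functional statistics

GO-slim enrichment is a one-sided (greater) Fisher exact test per term,
Bonferroni-corrected by the number of terms tested per ontology branch;
the packaged contingency rows can only be bounded, not reproduced, since
the original branch-level correction factors are unknown. Group
comparisons (abundance in copies/cell, half-life in minutes) are
two-sided Mann–Whitney with missing values dropped. Interplay proportions
report flagged/total with half-up integer rounding. Ubiquitination
prediction is not reimplemented (it is an external trained model); the
module accepts any precomputed binary flag table and reports the overlap
generically.

## Synthetic data generator

The generator emulates the statistical structure of a replicate-rich PMF
compendium; its defaults are the study conditions every seeded test runs
under:

| parameter | default | rationale |
|---|---|---|
| replicates/protein | Poisson(11), min 3 | replicate structure of the modelled compendium |
| mass error σ | 0.02 Da (Gaussian) | the compendium's average mass error |
| site stoichiometry | 0.3 | sub-stoichiometric methylation (literature reports < 33% site occupancy as typical) |
| detection probability | 0.7 | plausible MALDI peptide coverage |
| partial cleavage at methylated K/R | 0.5 | both cleaved and read-through forms occur |
| contaminants | Poisson(2)/spectrum, uniform 500–3000 Da | chemical noise floor |
| K/R site fraction | 0.05 each | ~1–3 compatible sites per 400-aa protein |
| composition | yeast-average frequencies | realistic D/E density (~12%), K+R (~12%) |
| lengths | lognormal(5.9, 0.35), clipped 120–1500 | yeast-like length distribution |

Detection is modelled as abundance-independent Bernoulli sampling: an
unmodified peptide appears with probability d (scaled by 1−s when it
hosts a planted site of stoichiometry s), and each methylated form —
cleaved and read-through — with probability s·d per replicate. The
partial-cleavage probability gates which forms exist (1 → only cleaved,
0 → only read-through, otherwise both); its magnitude does not scale the
emission rate, which keeps the noise-free limit exact: with σ = 0, no
contaminants, s = d = 1, every spectrum contains precisely the theoretical
masses of all in-window peptides and their methylated forms.

Filter-compatible planting accepts only cleavable K/R whose cleaved and
read-through host peptides are D/E-free, fall in the detectable window
after modification, and whose cleaved span carries no second K/R (a
proline-suppressed KP/RP inside the peptide would make the candidate
intersection two residues wide and the emitted localization genuinely
ambiguous — a real limitation of overlap-based localization that the
adversarial mode deliberately exercises instead). With these constraints
the pipeline's noise-free precision is 100% by construction, and planted
site recovery under default noise is a seed-pinned regression quantity.

What the generator does not model: peak intensities, isotope envelopes,
ionisation-efficiency differences between peptides, correlated mass error
within a spectrum, real chemical noise spectra, and multi-modified
peptides. Passing tests on this generator therefore demonstrate the
logic and statistics of the pipeline, not instrument-level performance on
real spectra.

## Problem sizes

Seeded test and acceptance runs use 15–80 synthetic proteins with mean 11
replicates each (a few hundred spectra, ~10⁴ peaks) and benchmark sets of
a few hundred planted sites — large enough for the binomial concentration
bounds asserted in the tests, small enough that the whole suite runs in
well under a minute.

## Known limitations

- Localization resolves only to the candidate-intersection of overlapping
  peptides; sites inside KP/RP-containing peptides can remain ambiguous.
- The default modification screen (methylations, acetyl, oxidation) is
  deliberately minimal; a realistic screen should supply the full
  modification TSV, which will raise the ambiguous-match fraction.
- Discovery rates assume presence/absence matching; no intensity model.
- The exact binomial enrichment assumes independent windows; overlapping
  paralogous sites violate this mildly.
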