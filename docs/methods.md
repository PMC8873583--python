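# Methods

## The problem and the model

A tumor specimen is a mixture: a fraction *f* of clonal tumor cells and
1 − *f* of stromal (normal) cells. At an STR locus where the germline
genotype has copy numbers c_g(a) ∈ {0, 1, 2} and the tumor clone, after a
somatic event, has copy numbers c_t(a) (total C_t), the expected fraction
of signal (reads or peak height) attributable to allele *a* is

    share(a) = [(1 − f)·c_g(a) + f·c_t(a)] / [(1 − f)·2 + f·C_t]

For *f* < 1 every germline allele keeps a strictly positive share, so a
sufficiently low detection threshold always recovers the full germline
genotype. Somatic event kinds and their share consequences:

| kind        | clone change                          | C_t | lost-allele share |
|-------------|---------------------------------------|-----|-------------------|
| `loh`       | one germline allele deleted           | 1   | (1−f)/(2−f)       |
| `aadd`      | one non-germline allele gained        | 3   | —                 |
| `anew_slip` | germline allele → ±1-repeat neighbour | 2   | (1−f)/2           |

Events are clonal (every tumor cell carries them); subclonality is out of
scope because the status categories are defined at clone level.

## Allele calling and status classification

An allele is called iff its signal reaches
`max(absolute_threshold, relative_threshold × locus_total)`; thresholds
are inclusive (ties call), which makes sensitivity exactly monotone in the
thresholds. Default regimes: CE = (20%, 50 RFU) — the ~5-fold-excess
minor-contributor limit of capillary electrophoresis plus the usual
analytic floor; NGS-IT = (4.5%, 10 reads) and NGS-AT = (1.5%, 10 reads),
the widely published UAS-style interpretation and analytical thresholds.
Per-locus overrides are supported because vendor software may apply
locus-specific defaults.

Status rules, evaluated in order on distinct-allele sets G (germline) and
T (tumor), with N = T∖G: no-call → Failed; N ≠ ∅ and G ⊆ T → Aadd; N ≠ ∅
→ Anew; |G| = 2 and |T∩G| = 1 → L; T = G, |G| = 2 and heterozygote balance
(minor/major germline-allele signal) < h_min → pLOH; otherwise S. Putting
the new-allele checks first means a locus that both gains and loses is
Anew, matching how Aadd/Anew conflicts are tabulated in practice. A
single-allele germline call is treated as homozygous; LOH there is
undetectable and classifies S (a documented blind spot). h_min = 0.6 by
default; since the S/pLOH boundary is a local convention, reports merge
S and pLOH into one category, and h_min is configurable.

Concordance counts a locus typed on exactly one platform as discordant
(the choice is not dictated by the category definitions; it is the
conservative reading). Percentages are reported to 2 decimals, half-up.
Germline recovery takes loci whose baseline status is neither S nor
Failed and asks, per query regime, whether every germline allele is among
the called tumor alleles.

## Kinship simulation

Unrelated individuals are two independent draws per locus from the allele
frequency table (Hardy–Weinberg, loci independent). Relatives are
conditioned on the patient's *germline* profile: a PO relative inherits
one uniformly chosen anchor allele plus one population draw; for an FS
relative two parents are reconstructed (each one anchor allele, randomly
assigned when the anchor is heterozygous, plus one population draw) and
the sibling receives one uniform allele from each parent. Meiosis is
mutation-free, so simulated pedigrees are exactly Mendel-consistent.
Frequencies default to a synthetic per-locus table (8 consecutive integer
alleles, Dirichlet(1.5) weights, expected heterozygosity ≈ 0.8 — typical
of forensic autosomal STRs); plug-in estimation from a germline cohort
and external tables are also supported.

## Synthetic cohort defaults (the study conditions)

55 paired cases, each forced to harbour ≥ 1 somatic event; 75 UIs; 1 FS
and 2 PO relatives per case, giving 55 PC, 4125 UI, 55 FS and 110 PO
pairs (the pair counts implied by the granularity of the published
specificity values: 2/55, 1/110, 2/4125). Tumor content f ~ Uniform(0.75,
0.95): pathology floors content at 30%, and the predominance of complete
L (rather than pLOH) under CE implies the stromal fraction usually sits
below CE's 20% detection share, i.e. f > 0.75 for most specimens.
Per-locus event probabilities p_loh = 0.08, p_aadd = 0.038, p_anew =
0.012, chosen analytically from the share model so the cohort-level CE
status distribution lands near the reference proportions (S/pLOH ≈ 88%, L
≈ 6.5%, Aadd ≈ 3.8%, Anew ≈ 1%); a ±5-percentage-point calibration test
asserts this. Locus depth is negative-binomial (mean 1000, dispersion 10)
with multinomial per-allele reads, so threshold effects rather than depth
noise dominate; `depth_noise=False` emits exact expected shares for
oracle-grade tests. CE "peak heights" reuse the same generator scale.

What the generator does **not** emulate: stutter and other PCR artifacts,
amplification bias, subclonal event fractions, locus dropout beyond the
threshold model (an optional elevated-dropout preset exists for the four
empirically unstable loci Penta E, Penta D, D18S51, D6S1043 via panel
exclusion), linkage between loci, and population substructure. Passing
tests therefore demonstrate correctness of the threshold/mixture logic
and the statistical machinery, not performance on real sequencing data.

## Scoring and cutoff analysis

Pairs are scored over the 27 autosomal ForenSeq panel loci
(pairwise-complete: loci untyped in either member are dropped). Tumor
profiles are scored under NGS-AT by default — the regime that restores
germline alleles. A₁/A₂/IBS are oriented high-is-positive; A₀ is
inverted so all four statistics share one ROC code path. Integer cutoffs
1..27 (1..54 for IBS) are tabulated; sensitivity/specificity are
empirical fractions (no smoothing), kept at full precision internally and
rounded half-up to 2 decimals only for display; Youden = sens + spec −
100 is computed before rounding. The optimal cutoff maximizes Youden with
ties broken toward the smallest cutoff (maximizing sensitivity). AUC is
the rank-sum pair-ranking probability with ties counting ½ (equal to the
trapezoidal empirical-ROC area); a brute-force enumeration oracle checks
it exactly in the tests. Group differences use Welch's t-test by default
(pooled-variance Student form switchable); p-values are uncorrected for
multiple comparisons, the usual convention for group-contrast marks.
Degenerate t-test inputs follow the convention (0, 1) for two constant
equal groups.

The interpretive rule (`recommend`) applies two A₂ thresholds, default
13 (unrelated exclusion) and 18 (same source), and always labels its
output heuristic: the thresholds derive from one cohort design and panel.

## Numerical and design notes

- Allele identity is length-based repeat-number nomenclature; sequence
  strings are collapsed to their numeric prefix, since cross-platform
  comparison is only defined at length level. Normalization is idempotent
  and strict (unparsable labels raise with the offending text).
- Genotypes are multisets; a homozygote equals its single-label form
  (`{12}` ≡ `{12,12}`), which makes IBS counting with homozygotes exact.
- All simulation is driven by `numpy.random.Generator` seeded from the
  config; the pipeline derives its relative-simulation stream from the
  master seed, and equal seeds give byte-identical outputs.
- The packaged reference cutoff table ships as printed; its PO columns
  reach sensitivity = specificity = 100 at cutoff 15, so the Youden
  argmax recomputed from the columns is (15, 100) even though the
  accompanying narrative quotes a PO peak of 99.09 at cutoff 14 — the
  reanalysis here follows the printed columns.
- Problem sizes in the test suite (10–55-case cohorts, 10⁴-draw
  distribution checks, 200-list AUC oracle sweeps) are chosen so the full
  suite runs in seconds while keeping every 3σ check well-powered.

## Known limitations

Tri-allelic germline genotypes are rejected rather than modelled; X/Y
STRs and sequence-level isoalleles are out of scope; no likelihood-ratio
kinship indices (the IBS counts are deliberately model-free); no
confidence intervals on AUC. The verdict thresholds are transferable only
to comparable 27-locus panels scored under an analytical threshold.
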