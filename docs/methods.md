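# Methods

This note documents the models behind `amplimeth`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Bisulfite clone quantification

**Readout model.** Bisulfite treatment converts unmethylated cytosine to
uracil (sequenced as T) and leaves 5-methylcytosine intact.  Cloning and
sequencing individual converted amplicons therefore yields one complete
methylation pattern per molecule.  The reference amplicon is kept
*unconverted*; the aligner absorbs conversion into its scoring.

**Alignment.** Global Needleman–Wunsch with linear gaps (match +1,
mismatch −1, gap −2) and a bisulfite-asymmetric substitution rule:
reference C against read T scores as a match (conversion-consistent),
while reference T against read C remains a mismatch.  At a declared C/A
SNP offset, read A (alternate allele), C (methylated reference allele) and
T (converted unmethylated reference allele) all score as matches, so
neither allele is penalised; read G falls through to the ordinary rule.
Both read orientations are aligned and the better kept (forward wins
ties).  Tie-breaking in the traceback is fixed — substitution before gap,
gap-in-read before gap-in-reference — so outputs are bit-reproducible.
The inner recursion is vectorised per DP row; the within-row left-gap
chain `max_k(M_k + g·(j−k))` is computed as `g·j + cummax(M_k − g·k)`,
one numpy pass per row.  Scores are validated against an exhaustive
recursion on short strings in the test suite.

**Per-clone calls and QC.** A CpG cytosine aligned to read C is
methylated, to T unmethylated, to anything else missing.  The SNP-CpG is
called only on clones assigned to the C allele (it does not exist on the A
allele).  Conversion efficiency — the fraction of *non-CpG* reference
cytosines read as T — flags incompletely converted clones; the default
threshold is 0.95 with a minimum of 3 informative clones per reported CpG.
Both defaults are conventional bisulfite-cloning practice, configurable,
and recorded in run provenance; the field has no single standard.

**Profiles.** Per-CpG fraction = methylated / (methylated + unmethylated)
over passing clones; CpGs below the informative minimum are *absent* from
the profile rather than reported as 0.  The overall mean is the unweighted
mean of per-CpG fractions (each site counts once, so a deeply covered site
does not dominate).  The allelic ratio is the C-allele overall mean over
the A-allele overall mean across shared CpGs, excluding the SNP-CpG
itself, undefined (NaN) when the A-allele mean is zero.

## Promoter CpG density

`ratio = n_CpG · L / (n_C · n_G)` over a window, with overlap-counted CG
dinucleotides; the statistic is strand-symmetric, so one strand suffices.
Ns are removed from counts and length, an N breaks a dinucleotide, and a
window over 50% N is reported undefined.  A promoter is a CpG island iff
ratio > 0.6 **strictly**, by the ratio criterion alone — the classical
additional conditions (GC fraction, minimum length) are deliberately not
applied, because the analysis this package supports stratifies by the
ratio only.  Quartile bins use empirical 25/50/75 percentiles with linear
interpolation; ties at a cut point go to the lower quartile.  The
genome-scale promoter window is a required, recorded configuration value
(−500/+500 is a common choice); no window is silently assumed.

The packaged CRP-like fixture is synthetic: a 551-bp sequence built by the
amplicon generator to carry exactly five CpGs (one the −286 C/A SNP-CpG)
at GC fraction 0.3975, giving ratio 5·551/(110·109) ≈ 0.230.  Its
descriptor JSON records the generating call and seed.  Tests against it
are round-trip checks of the scorer, not checks against genomic sequence.

## Reversible methylation dynamics

Mean promoter methylation follows two first-order relaxations:

    m(t) = m_ind + (m0 − m_ind) e^(−k_down t)                  t ≤ t_e
    m(t) = m0 − (m0 − m(t_e)) e^(−k_up (t − t_e))              t > t_e

with baseline `m0`, induced floor `m_ind`, demethylation rate `k_down`,
re-methylation rate `k_up` (per hour) and stimulation end `t_e`.  The
two-phase exponential is a modelling choice: the observed behaviour —
rapid demethylation under stimulation, prompt re-methylation after
withdrawal — is the relaxation of a level towards a state-dependent fixed
point, and a first-order form is the simplest model with that property.
Defaults (`m0=0.8, m_ind=0.2, k_down=0.2, k_up=0.1, t_e=48 h`) are
**illustrative, not fitted** — no measured rates exist for this system —
and mirror a 48 h stimulation / 36 h washout design.  Trajectories are
confined to `[m_ind, m0]` and return within 1% of baseline once
`t − t_e ≥ 5/k_up`.

The time-course inverse-coupling score is the fraction of
consecutive-timepoint intervals in which expression and methylation moved
in opposite directions, among intervals where both changed; zero-change
intervals are counted and reported separately, and the score is NaN when
no interval is usable.

## Clone read simulator

Per clone: allele drawn from the configured fractions (0.5/0.5 by
default); each CpG methylated by an independent Bernoulli draw of that
allele's per-CpG probability; every unmethylated C (CpG or not) reads T
with probability `conversion_efficiency` (default 0.99); methylated CpG
cytosines read C; uniform substitution errors at `error_rate` (default
0.001) applied last.  No indels are simulated — clone Sanger reads are
high quality — but the aligner tolerates them regardless.  Truth labels
(allele, per-CpG states) accompany every read, and round-trip through the
FASTA description field.

## Cohort generator

Promoter ratios come from a two-mode Beta mixture, Beta(4,16) (mean 0.2,
CpG-poor, weight 0.6) and Beta(16,4) (mean 0.8, CGI), straddling the 0.6
threshold.  The CpG-poverty score `s = max(0, 1 − ratio/0.6)` enters the
model twice, mirroring the emulated biology in which CpG-poor promoters
are both *more likely* to respond and respond *more strongly*:

* response flag `B ~ Bernoulli(0.1 + 0.5·s)`;
* responsive genes change expression by `±coupling_beta·s` in log2 units
  (direction up with probability 0.5 — an inflammatory response both
  induces and represses genes) plus `N(0, 0.3)` background;
* promoter methylation moves *opposite* to expression by
  `meth_coupling·s`, so induced genes demethylate and repressed genes gain
  methylation; CpG-poor promoters start at Uniform(0.55, 0.95), CGI
  promoters at Uniform(0, 0.1) and barely change (noise sd 0.01 vs 0.02).

Counts are negative-binomial (dispersion 0.05, a typical bulk-tissue
value) around CPM-scaled means at mean library size 10⁶, three replicates
per condition.  Two earlier design variants were rejected for failing to
reproduce the qualitative quartile trend the generator exists to emulate:
an all-upward response inflates the induced library mass so CPM
normalisation shifts every null gene's measured log2FC by about −0.3,
which makes weakly boosted genes look *smaller* in magnitude than nulls;
and a poverty-independent response probability saturates quartile medians
(each quartile's median lands at the same percentile of the null
distribution once boosts separate from noise), so adjacent quartiles tie.
The bidirectional, poverty-gated form above produces monotone
non-increasing medians Q1→Q4 with Q1-vs-Q4 K-S p < 10⁻³ in every seed
tested at 4000 genes, and a Q1-vs-Q4 rejection rate consistent with the
nominal 5% when both couplings are zero.

## Induction analysis

Counts are normalised to CPM with a pseudocount of 1 added *after*
scaling (all-zero genes sit at exactly 1 everywhere); fold change is the
ratio of condition means of normalised values; bins use the magnitude
`max(fc, 1/fc)` with half-open edges [1,2), [2,5), [5,15), [15,∞), so a
5.0-fold change falls in the 5–15 bin and down-regulation lands in the
same bins as up-regulation.  Signed log2FC is always emitted alongside, so
an up-only analysis remains reproducible.  Promoter methylation per gene is
the coverage-weighted mean over window CpGs with total coverage ≥ 5
(configurable, recorded); genes with no qualifying CpG are missing, not
zero, and are excluded from K-S inputs.  The two-sample K-S test is
scipy's, with the asymptotic p-value by default (cohort arms run to
thousands of genes) and the exact method behind a flag for small samples;
the D statistic is validated against a brute-force ECDF supremum in the
tests.

## Problem sizes and what the experiments show

The benchmark experiments (`amplimeth.experiments`, also driven by
`scripts/acceptance.py`) use 50 clones per condition, ~100 clones per
allele, 100 recovery replicates, and 20/40-seed power/type-I runs on
4000-gene cohorts — sizes chosen to match bisulfite-cloning practice and
to keep a full run in tens of seconds.  Passing them shows that the
pipeline recovers what the generators programmed, under the generators'
assumptions: independent CpGs, uniform conversion and error rates,
indel-free reads, independent genes with a clean two-mode density mixture.
Real data violate most of these — correlated methylation along a molecule,
batch structure, PCR duplicates among clones, compositional shifts larger
than the simulated ones — so recovery here bounds implementation
correctness, not field performance.

## Known limitations

* No genome-scale WGBS read mapping or CGI segmentation; methylation
  enters as per-CpG tables, alignment is amplicon-scale only.
* Clones are treated as independent molecules; no PCR-duplicate
  collapsing.
* The K-S comparison treats genes as independent; no multiple-testing
  structure beyond the single Q1-vs-Q4 contrast per variable.
* Dynamics parameters are illustrative; fitting them to time-course data
  is out of scope.
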