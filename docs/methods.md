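# Methods

`capcensus` implements a quantitative census of autophagic proteome
remodelling from multiplexed (TMT) proteomics of autophagy-proficient (WT)
and autophagy-null (e.g. *ATG7*- or *FIP200*-knockout) cells, untreated or
nutrient-starved. This note records the models, the parameters that matter,
and the design decisions made where the design was genuinely open.

## Consensus-profile CAP calling

Each experiment is a protein × channel relative reporter-intensity matrix.
Channels are scaled so every column total (sum method; median for proximity
labelling) equals the grand mean of column totals — equalizing loading
while preserving the overall scale — then log2-transformed and row-wise
standardized (sample n−1 SD) across the experiment's channels.
Standardization is within one experiment/plex; merged multi-plex z-scoring
would mix batch structure into the profile and is deliberately not done.

Known autophagy fluxers (a caller-supplied panel; the default is TEX264,
CCPG1, CALCOCO1, SQSTM1, MAP1LC3B, GABARAPL2) define the expected profile:
for each fluxer the median z per (genotype, treatment) condition is taken,
and the median across fluxers gives the consensus value per condition. Each
channel inherits its condition's consensus value, and every protein is
scored by

    RMSE = sqrt( Σ_i (predicted_i − observed_i)² / n_channels )

over the experiment's channels. The lowest-RMSE decile of scored proteins is
called as candidate autophagy proteins (CAPs): `k = floor(fraction ×
N_scored)` with fraction 0.10 by default. The floor is computed with exact
decimal arithmetic (`Fraction("0.1") × N`) because binary-float
`0.1 × N` can fall a hair below an exact decile boundary. Boundary ties are
broken by protein-ID lexicographic order so membership is deterministic and
invariant to input order.

Missing-data policy: by default only proteins quantified in every channel
receive an RMSE (the formula divides by the full channel count); incomplete
proteins are flagged `complete=False` and excluded from the decile
denominator. A per-observed-channel variant (`missing_policy="observed"`)
is available for sparser data.

Compartment enrichment of CAPs against the scored background uses a
two-sided Fisher's exact test per flat term, BH-adjusted across terms.
Differential abundance uses an equal-variance two-sided Student's t on log2
data with BH adjustment per contrast.

## TMT-adapted proteome ruler

MS1 precursor area integrates material from every multiplexed sample, so
each peptide's area is apportioned to the untreated-WT reference channels
by its reporter-intensity share, Σ(reference reporter)/Σ(all reporter) ×
MS1 area, summed per protein. Copies per cell then follow the
histone-anchored proteomic ruler:

    copies_i = signal_i × (m_DNA × N_A / M_i) / Σ_histones signal_h

with m_DNA the DNA mass per cell and M_i the molar mass. The default
m_DNA = 6.5 pg corresponds to a diploid human genome; HEK293 is
pseudotriploid, so the constant is exposed (`dna_mass_pg`) rather than
hidden — it rescales all copies by a common factor and does not affect any
relative quantity.

Copies lost on starvation are `copies × max(0, 1 − 2^log2FC)` using the
WT starved/untreated contrast mean across replicates; proteins that
increase lose zero (a signed mode retains negative losses). The compartment
census sums losses per compartment (optionally splitting Golgi membrane
from Golgi-associated proteins) into the CAP-attributable and total loss,
the compartment's share of all CAP loss (sums to 100%), and the
CAP-attributable fraction of the compartment's loss (missing where a
compartment lost nothing). Each protein carries a single primary
compartment from the annotation table.

## Receptor prioritization

Turnover priority rewards starvation-dependent, autophagy-dependent loss:
`min(|WT FC|, KO−WT)` when WT log2FC ≤ 0 and KO−WT ≥ 0, else 0. Proximity
priority rewards LIR-dependent ATG8 proximity: `min(WT FC, |mutant−WT|)`
when WT log2FC ≥ 0 and mutant−WT ≤ 0, else 0. Within each experiment,
priorities are ranked descending (dense 1..N, protein-ID tie-break — the
source method is silent on ties) and scaled by the number of proteins
quantified in that experiment. Zero-priority proteins occupy the tail in ID
order by default; a `drop` mode excludes them before scaling, since it is
ambiguous whether they should enter the denominator. Across experiments of
one evidence class the minimum scaled rank is kept; the two class ranks are
summed and sorted ascending into the final composite rank. A protein must
be quantified in at least one experiment of each class to be ranked.

KO-dependence classification marks a protein stabilized when
KO log2FC − WT log2FC exceeds a threshold (default 0.2, strict inequality,
matching the printed ">" convention), with counts reported per Golgi class
over a caller-supplied reference set.

## Synthetic data: what it emulates and what it does not

The generator plants five protein classes in a WT/KO × untreated/starved
design: autophagy clients (depleted `client_effect` log2 in starved WT,
rescued by `rescue_fraction` in the KO), known fluxers (a labelled client
subset seeding the consensus), translation-suppressed confounders (depleted
`suppression_effect` in both genotypes — the genotype-independent response
the classifier must reject), stable proteins, and histones. Intensities are
baseline copies × 2^(effect + N(0, noise_sd)) per channel; copies are drawn
log-uniform over five orders of magnitude (1e2–1e7).

Defaults (chosen once as the study conditions): 5,000 proteins,
client_effect −1, rescue_fraction 1.0, noise_sd 0.25, 3 replicates.
The confounder magnitude is not quantified by the source data and is a free
parameter (default −0.75, same order as the client effect so the rescue
contrast, not effect size, separates the classes). Clients plus fluxers
total 10% of the proteome: the CAP call is a fixed-size decile set, so the
planted prevalence must match the cut for precision and recall to be
commensurable — mirroring the real analysis, where the CAP prevalence is
10% by construction. Planted receptors (default 2) are Golgi-membrane
clients with twice the client turnover effect, reflecting that validated
receptors sit among the strongest fluxers.

Peptide simulation gives each protein `1 + Poisson(mean−1)` peptides whose
summed MS1 area is proportional to molar mass × summed channel amount,
split by a Dirichlet draw, with reporter intensities following the
protein's channel profile. Histone copies are rescaled so total histone
mass equals the configured DNA mass (ratio 1.0) — the same physical anchor
the ruler assumes — making ruler recovery exact (slope 1) in the noiseless
limit. The proximity generator enriches receptors by `receptor_effect`
(log2, default 2) in starved WT-ATG8 channels, attenuated by `lds_rescue`
in the LDS-mutant channels, with flat bystanders.

Not emulated: peptide sequences and missed cleavages, isotopic-interference
structure, plex-to-plex batch effects, correlated (complex-level)
abundance changes, compositional distortion from large abundance shifts,
and non-autophagic degradation beyond the single translational-suppression
class. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated noise model, not robustness to every
artefact of real reporter-ion data.

## Numerical choices and degenerate inputs

- Zeros before log2 become missing (reporter-ion zero = non-quantification),
  never pseudocounted; missing cells stay missing end to end.
- Constant rows cannot be z-scored and become all-missing with a warning.
- All-zero channels, empty backgrounds, zero known fluxers, zero scored
  proteins, and missing histone signal are hard errors, not silent results.
- Peptides with zero total reporter signal are excluded from apportionment
  (logged): they carry no channel information to apportion by.
- Fisher's odds ratio is the sample (cross-product) estimate; degenerate
  tables (caps = background) yield p = 1 with an undefined odds ratio.

## Problem sizes

The test suite and the acceptance script run the default 5,000-protein,
12-channel design (plus smaller configurations down to a few proteins for
hand-checkable oracles); the full pipeline completes in seconds on one CPU,
so these sizes are comfortable for routine re-runs while matching the scale
of a real single-plex experiment (~8,000 quantified proteins).

## Known limitations

- The RMSE averages error across the whole profile, so a protein deviating
  strongly in a single condition can still be called, and a true client
  with high replicate variance can be missed — inherent to the score.
- The decile cut is a fixed-size rule; it does not adapt to the true client
  prevalence, and calibration of the fraction is left to the user.
- The census assigns each protein one compartment; dual-localized proteins
  contribute their whole loss to their primary compartment.
- The ruler's absolute scale depends linearly on the DNA-mass constant and
  on the histone annotation being correct and complete.
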