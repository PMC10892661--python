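# Methods

This note documents the models behind `sipseek`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions.

## Microcosm kinetics

Headspace methane consumption is modelled as a lagged logistic: the consumed
fraction is `f(t) = f_max / (1 + exp(-r (t - t_mid)))` with the midpoint
placed so that only 5% of the final consumption has occurred by the end of
the lag phase, and `r` set from the configured peak consumption rate
(`max_rate = C0 · f_max · r / 4`). Concentrations start at 25,000 ppmv and
the incubation terminates on the first day below 5,000 ppmv — by
construction 80% consumed at the threshold — or at the configured maximum
duration otherwise. The gas-well preset (lag 13 d, peak 1,200 ppmv/d,
f_max 0.995, cap 44 d) crosses the threshold around day 36; the dry-well
preset (lag 26 d, peak 900 ppmv/d, f_max 0.90, cap 57 d) never crosses it
and terminates at the cap, reproducing the qualitative contrast between the
two soils. The functional form is a modelling choice: only the lag/rate
narrative and the termination rule are constrained, not the equation.

## Buoyant-density gradient

A genotype's DNA mass is spread over the fractions proportionally to a
Gaussian density kernel (sd 0.004 g mL⁻¹). The kernel centre interpolates
linearly between the unlabelled position (1.7235 g mL⁻¹) and the fully
labelled position (1.744 g mL⁻¹) with `activity × 1[treatment = ¹³C]`,
since buoyant density grows approximately linearly with the ¹³C content of
DNA. Multiplicative log-normal noise (sd 0.1 on the natural-log scale)
perturbs each fraction and the mass is then renormalized, so per-genotype
mass is conserved exactly and, for a fixed seed, the abundance-weighted
mean density is non-decreasing in activity (the noise draw does not depend
on the activities).

The default 14-fraction density grid is piecewise linear and anchored on
the two diagnostic windows: fractions 4–6 at 1.748/1.744/1.740 g mL⁻¹
(heavy) and fractions 8–10 at 1.728/1.7235/1.719 g mL⁻¹ (light). No single
linear ramp can place both windows on those fraction numbers
simultaneously, so the grid interpolates between the anchored segments and
extends them outward (1.760 at fraction 1 down to 1.701 at fraction 14).

Labeling is called from the difference in abundance-weighted mean density
between the ¹³C profile and its ¹²C control. The threshold (0.008 g mL⁻¹,
about half the heavy/light centre separation) is a declared convention —
in the field this judgement is made visually — and the statistic depends
only on profile shapes, not on absolute abundance scales. The gradient for
labeling detection is simulated on the *post-incubation* community
(`incubated_profile`): in a background soil the in-situ community is
dominated by inactive atmospheric-methane oxidizers (USC-γ), but weeks of
high-methane incubation let the few active *Methylocystis* grow to
dominance, which is what the gradient actually sees.

## Reference sequences and reads

Reference databases are generated top-down: a random root sequence
(471 nt, the *pmoA* amplicon scale), per-genotype consensus sequences
mutated from the root, and per-genotype references mutated from the
consensus. Substitution rates are solved from the target mean pairwise
p-distances via `d = 2q(1−q) + (2/3)q²` (two lineages mutated independently
at per-site rate `q`, uniform base choice). Defaults: 8 references per
genotype, within-genotype divergence 0.02, between-genotype 0.15 — deep
enough that an alignment-free classifier resolves genotypes, comparable to
the divergence among *pmoA* lineages. Reads copy a uniformly chosen
reference of a multinomially drawn genotype and receive i.i.d.
substitutions (default 1%); indels, chimeras and quality scores are not
modelled, which is consistent with the alignment-free classifier
downstream.

## Classifier

RDP/mothur-style naive Bayes over 8-mers. Word evidence per genotype `g`:
`P(w|g) = (refs of g containing w + 0.5) / (n_g + 1)`; a read's score for
`g` sums `log P(w|g)` over all of its overlapping 8-mers, and the best
score wins (exact ties go to the lexicographically smallest genotype name).
Confidence is the percentage of 100 bootstrap replicates — each resampling
⌈m/8⌉ of the read's m 8-mers with replacement, the RDP convention — that
agree with the call; replicate-level exact ties are broken uniformly at
random so that a perfect two-way tie yields ≈50% confidence. Calls under
80% confidence are reported `unclassified` and excluded from downstream
relative abundances. k = 8, 100 resamples and the 80% cutoff follow common
classifier practice. The implementation stores the full 4⁸ × genotypes
log-evidence table and classifies read batches vectorized; bootstrap
positions are drawn once per processing chunk (each read's replicates
remain i.i.d. uniform draws over its positions).

## Phylogenetics

Distances are p-distances on the fixed-length synthetic alignments.
Neighbor joining follows the Saitou–Nei agglomeration with deterministic
tie-breaking (lowest index pair in the current matrix) and negative branch
lengths clamped to zero; the result is an unrooted tree with a
trifurcating root. Bootstrap supports resample alignment columns with
replacement (default 1,000 replicates), rebuild the NJ tree and report the
percentage of replicates containing each internal bipartition. The NJ
implementation is validated in the tests against an exhaustive
least-squares topology search (≤6 taxa), against generating topologies of
additive matrices (≤8 taxa) and against scikit-bio's NJ.

## Community indices, qPCR, group tests

Relative abundances live on the 0–100 percent scale. The Shannon–Wiener
index is computed as `H = −Σ p_i log₂ p_i` in bits over groups with
`p_i > 0`, with proportions renormalized over the retained groups (the
minus sign makes H positive for proportions; zero-abundance groups are
excluded because `log 0` is undefined and richness counts only groups
present). Evenness is `H / log₂ S`, defined for `S ≥ 2`. The heavy-fraction
summary composition is the unweighted mean of the per-fraction percentages.
On the worked-example table the mean heavy-fraction compositions give
H = 1.61 (gas) and 0.52 (background) bits over the top-10 genotypes; the
published values (1.68 / 0.53) cannot be reconstructed exactly from a
top-10 table — the full community had 32 genotypes — so desk checks accept
±0.1.

qPCR standard curves are least-squares fits of Cq against log₁₀(copies)
(SciPy `linregress`); unknowns are `10^((Cq − intercept)/slope)` and
efficiency is `10^(−1/slope) − 1`. R² < 0.98 or slopes outside
[−3.9, −3.0] warn rather than fail. Two-group comparisons use Student's
t-test (equal variances), more groups one-way ANOVA with Tukey's HSD;
significance at p < 0.05.

## Indicators and biotic index

A genotype is *active* when its unweighted mean relative abundance over the
heavy fractions reaches 5% — the smallest round threshold that reproduces
the worked-example deduction (RPC-2 at 31.3% in the gas soil, 2.4% in the
background). Indicators are the set difference active(gas) −
active(background). The labeling-contrast rule (≥10× the control share and
≥1% absolute) is an operational version of "the control heavy fractions
hold under 1% methanotrophs". BI is the plain sum of indicator abundances
in a site's in-situ profile, hence additive and bounded by [0, 100].

## Survey and map

Survey sites are evenly spaced along a 10 km line with 100 m lateral
jitter; a site's zone comes from containment in the gas polygon. Site BI is
drawn logit-normal with the location parameter calibrated numerically
(Gauss–Hermite quadrature + Brent root-finding) so that the *expectation*
equals the zone mean — 24.9% inside, 2.8% outside (the inside mean divided
by the observed 8.9-fold contrast). The dispersion default (0.65 on the
logit scale) spreads inside-zone sites over roughly 10–60%, matching the
reported range. The BI splits between RPC-2 and *Methylosarcina* in their
in-situ ratio (25.6 : 14.6) and a fixed non-indicator community fills the
remainder.

IDW uses power 2, exact interpolation at site locations, and co-located
sites are collapsed by averaging before weighting (so duplicating a site
cannot double its influence). The default cell size is 1/200 of the survey
extent. Anomaly cells satisfy `surface ≥ background mean + 2 sd` (site BI
of background-labelled sites); zones are 4-connected components; cells
with no site within the search radius stay missing and never enter the
mask. IDW was chosen over kriging for determinism and testability; its
convexity (surface bounded by the site value range) is exploited in the
tests.

## Reproducibility and problem sizes

Every generator is a pure function of (configuration, seed); the forward
model derives per-stage seeds as
`SeedSequence(master_seed, spawn_key=(crc32(stage_name),))`, so stages are
independently reproducible and two runs with the same config produce
byte-identical artifacts. Default forward-model sizes (5,000 reads per
heavy fraction, 1,000 per survey site, 40 sites) keep a full run under a
minute on one core. The recovery studies in `scripts/acceptance.py` use
50,000 reads per heavy-fraction estimate and 200 survey sites × 5,000
reads, with 25 bootstrap resamples per read — at the divergences used,
confidence is saturated and the resample count does not affect the
estimates.

## What the generators do not capture

Synthetic references are generated pre-aligned with uniform substitution
processes: there is no rate heterogeneity, no indels, no conserved-motif
structure, and genotype divergence is homogeneous rather than reflecting
the real *pmoA* phylogeny. Reads carry no quality scores, chimeras or
PCR/primer bias, and cross-feeding of ¹³C into non-methanotrophs — which
depresses real heavy-fraction MOB shares — enters only through the
configured community compositions, not as a process. The survey model
ignores geology: the anomaly boundary is driven solely by BI, whereas a
real interpretation would combine it with fault and gas–water-contact
data. Passing tests therefore demonstrate that the *analysis chain*
recovers what the generators encode at realistic noise levels, not that
the biology of any particular field site is reproduced.
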