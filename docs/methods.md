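# Methods

## Coordinates and motif definitions

Protein positions, window starts and pocket indices are 1-based and
inclusive. A 9mer bound in MHC class I exposes pockets p4–p8 to the TCR
(TCEM I) and buries p1,p2,p3,p9 in the groove (GEM I). A 15mer bound in MHC
class II is modelled with a fixed core 9mer starting at 15mer position 4;
TCEM II is the discontinuous pentamer at core p2,p3,p5,p7,p8 (15mer positions
5,6,8,10,11) and GEM II the core anchors p1,p4,p6,p9 (15mer positions
4,7,9,12). Core sliding is out of scope. The GEM II positions are the set
complement of TCEM II within the core; no authoritative definition beyond
that complement exists, so the choice is flagged here rather than asserted.

Windows covering any non-canonical letter are dropped. The ambiguity
alphabet is deliberately a conservative superset — X, U, B plus Z, J, O and
the stop symbol `*` — of the letters that actually occur in curated
proteomes. Terminal fragments shorter than the window width are never
emitted. Each width is windowed independently; deriving 9mers as prefixes of
15mers instead would drop the last eight 9mers of every protein, a ≤8
windows/protein discrepancy we chose not to inherit.

Duplicate amino-acid changes (same protein, position, alternate residue,
e.g. from different codon substitutions) are de-duplicated before
annotation. A mutation whose recorded reference residue does not match the
supplied isoform raises a verification error and is reported in an exclusion
list with a reason code, never silently dropped. Isoform selection is the
data supplier's job: the package takes one sequence per protein id and
errors on duplicates.

## Pentamer frequency tables

A table covers the complete 20⁵ = 3,200,000 key space (base-20 encoding of
the residue alphabet, dense int64 array, O(1) lookup). Class I tables tally
the p4–p8 pentamer of every clean 9mer window; class II tables the
discontinuous pentamer of every clean 15mer. The invariant `sum(counts) =
clean windows` is enforced at construction. On disk a table is one JSON
metadata line (format version, window count, digest) followed by
lexicographically ordered `pentamer<TAB>count` rows with zeros omitted;
loads verify row count and digest. The microbiome reference is simply a
second table built from a different FASTA; no taxon bookkeeping.

## Distribution fits and standardization

**Zero-inflated Poisson.** Counts are modelled as `P(0) = π + (1−π)e^{−λ}`,
`P(k>0) = (1−π)e^{−λ}λ^k/k!`. The MLE uses a 1-D profile likelihood on λ
(Brent on log λ; π̂ given λ is closed-form from the zero fraction), Wald 95%
intervals from the numerically differentiated observed Fisher information.
When the observed zero fraction does not exceed the plain-Poisson
expectation e^{−mean}, the plain Poisson fit is returned with π = 0. An
all-zero sample is a flagged degenerate fit (π → 1, λ unidentifiable).

**Transform-to-normal Zscale.** Values (log2(1+count) for frequency
displays; Ln(ic50) for binding, within each protein × allele group) are
mapped to a latent normal scale by the Johnson SU member of the
sinh-arcsinh family, `z = skew + tailweight · asinh((x − location)/scale)`,
fitted by maximum likelihood (scipy's `johnsonsu`). The fit is computed on
internally standardized data, which makes the resulting zscores exactly
equivariant under affine rescaling of the input. A final affine correction
pins the sample mean to 0 and variance to 1; the whole map is strictly
monotone (rank-preserving). Groups smaller than 8, constant-free failures
or non-finite MLEs fall back to Blom rank-based inverse-normal scores,
flagged per group. The pure Jones–Pewsey parameterization (a terminal
`sinh`) was evaluated and rejected: its MLE leaves residual skewness ≈ 0.18
on lognormal input, where the Johnson SU form reaches |g1| < 0.02.

**Threshold.** The working binding cut is z ≤ −1σ, configurable. On the
standardized scale −1σ is the ≈16th percentile per allele; across a 6-allele
genotype the cumulative fraction of peptides bound by at least one allele is
a sigmoid in the cut point whose 4PL inflection falls near −1.2σ under
independent alleles (analytically, the mode of d/dz [1−(1−Φ(z))⁶]), which is
why −1σ approximates the genotype-level half-maximal binding point.

**Curve fits.** The 4-parameter logistic is the logistic (Hill) form
`lower + (upper−lower)/(1+exp(−hill·(x−c)))` — the x axis is a Zscale, so a
ratio form `(x/c)^h` would be undefined for negative cuts. The Weibull
growth model is `a(1−exp(−(x/c)^b))` with an optional `a ≤ 1` bound for
cumulative fractions. Both use trust-region least squares from 5
deterministic quantile-based starts (xtol/ftol/gtol 1e-12), tie-broken by
cost then parameter norm; noiseless generate-and-refit recovers parameters
to <1e-6.

## Binding model

Peptides are encoded QSAR-style: each residue maps to the first d (default
3) principal-component scores of a packaged 8-property physicochemical
table (Kyte–Doolittle hydropathy, volume, mass, Grantham polarity, pI,
Chou–Fasman helix and sheet propensities, net charge); columns are z-scored
across the 20 residues, the SVD is deterministic, scores are whitened to
unit variance and sign-fixed (largest-magnitude loading positive). Position
vectors are concatenated (9mer × d=3 → 27 features).

Per allele, `train_ensemble` fits `n_candidates` (default 300) regressors,
each on an n-of-n bootstrap resample of Ln(ic50) targets, ranks them by
out-of-bag RMSE with an R² tie-break, and keeps the best `n_keep` (default
25). The base learner is a single-hidden-layer perceptron (16 units, lbfgs);
ridge and other learners sit behind the same interface, and the whole module
is replaceable by anything exposing `predict_batch(peptides) → (mean, sd)`.
Training refuses fewer than 200 examples per allele. Predictions report the
ensemble mean and population-convention SD of Ln(ic50); `exp(mean)` is on
the nM scale. Everything is deterministic given the seed. The selection
statistics (the unnamed "four measures" of the original platform) and layer
sizes are documented package choices, not reconstructions.

## Genotype logic

Allele slot order is input order (the first A allele listed is A1); no
name-based sorting. A class I bitmap bit is 1 iff that allele's mutant-peptide
zscore ≤ threshold AND the register exposes the mutant; DRB1 alleles get the
2-bit analogue. Lowering the threshold can only turn 1-bits into 0-bits.
Lost/Gained/Retained classifies (wildtype z, mutant z) against the cut and is
antisymmetric under swapping. The 6×5 register matrix takes the minimum over
defined cells only — registers truncated at termini are excluded cells, not
zeros — with ties within 1e-9 all listed and the dominant cell the first in
(A1..C2) × ascending-register order.

The down-selection cascade counts, per case: all mutant-containing records
(9mers + 15mers), 9mers, 9mers bound by ≥1 class I allele, bound 9mers whose
register exposes the mutant, and bound+exposed 9mers whose *mutation* also
has a DRB1-bound, mutant-exposing 15mer. That mutation-level dual-class
linkage is the default; a stricter "the 15mer must contain the 9mer window"
rule is available (`dual_class_rule="containing"`) because the row definition
is genuinely ambiguous. Exposure fractions are emitted under both
denominators — (register, allele) binding events, and bound peptides — for
the same reason. Under register-uniform binding the expected event-level
exposure fraction is 5/9 ≈ 0.556.

## Synthetic data

The generators are pure functions of (spec, seed) and define the study
conditions:

* **Proteome**: 700 proteins, uniform lengths 150–450, i.i.d. residues from
  a human-like composition in which W, C, M, H are naturally the rarest —
  so mutations *toward* those residues create rare pentamers by
  construction, the central mechanism. That yields ≈2×10⁵ 15mer windows.
* **Microbiome**: the same spec scaled ~10× in protein count, with
  composition mixed 70/30 between the proteome's composition and a
  deterministic permutation of it — an overlapping but distinct pentamer
  population (its tables are ~10× denser and less zero-inflated).
* **Mutations**: 1,500 interior missense substitutions (≥14 residues from
  both termini so all 9 + 15 registers exist), one per protein while
  proteins last, reference residue verified, alternate residue ≠ reference
  and drawn with a 6× weight on W/C/H/M (`rare_bias`).
* **Genotypes**: 30 cases, 6 class I + 2 DRB1 slots from a 4-allele pool per
  locus, 10% per-locus homozygosity.
* **Binding truth**: additive per-pocket energies with pocket preferences
  drawn from the span of the packaged descriptor components (binding tracks
  residue chemistry, and recovery by a descriptor-encoded regressor is
  well-posed); anchor pockets (p2/p9 for 9mers; core p1,p4,p6,p9 for 15mers)
  carry 5× the weight scale. `Ln(ic50) = 8.5 + energy` (≈5 µM mid-scale);
  training ic50s add Gaussian noise (sd 0.3) on the log scale.

What the generator does *not* emulate, hence what passing tests do not show
about real data: at 2×10⁵ windows ~94% of pentamers are absent from the
reference (the real human proteome covers ~75% of the key space), so absolute
absent-motif fractions are far higher here than in real cohorts; wildtype
motifs always have count ≥ 1 because the mutated proteins are part of the
reference; the additive truth has no mutation-direction-specific binding
gains at anchors, so the cohort exposure fraction sits near the 5/9 null
rather than the ~0.3 seen in patients; and there is no expression,
processing, or linkage structure between mutations. The qualitative
signatures — mutant TCEMs rarer than wildtype, anchor mutations perturbing
predicted binding far more than TCEM mutations, depression of the
mutant-aligned frequency profile only at mutant-containing offsets — are
scale-independent and are what the tests assert.

## Pipeline

`annotate_mutations` produces one record per (mutation × width × register):
wildtype and mutant TCEM/GEM, reference counts from both tables, per-slot
wildtype and mutant zscores (standardized within protein × allele over all
clean windows of that protein), bitmaps, pockets and offsets. Mutant and
wildtype sequences are standardized separately; scores are cached per
(protein, allele, variant). `compare_mut_wt` fits ZIPs to the exposed-TCEM
count distributions and adds a 2-df likelihood-ratio test of a shared
(λ, π) — an extension beyond the original fits, reported as such, with
Benjamini–Hochberg available via statsmodels when applied across many
comparisons. `mutant_alignment_profile` standardizes pooled
log2(1+count) values once so wildtype and mutant profiles share a scale;
offsets whose TCEM excludes the mutant are identical by construction, and
empty offset bins are reported missing, not zero. `run_case` resolves all
config inputs before any compute, writes annotation/down-selection TSVs and
a summary JSON, and is byte-identical across reruns for a fixed config and
seed.

Problem sizes in the analysis drivers (700-protein proteome, 150-protein
calibration subset, 60-candidate/15-member ensembles, 1,500 mutations) are
the package's desk-scale choices; all scale parameters are ordinary function
arguments.

## Known limitations

No expression or transcript evidence, no proteasomal/cathepsin processing,
no DP/DQ pairing (four possible heterodimers per patient), no non-classical
MHC, no TCR-side avidity or clone-size modelling, no indels or splice
variants. HLA allele names are carried as verbatim input text. The binding
model is a reference implementation for synthetic truths and plug-in
replacement, not a trained clinical predictor.
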