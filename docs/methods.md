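# Methods

## Dose–response model

Viability is modelled with the 5-parameter logistic
y(x) = B + (T−B)/(1 + 10^{b(x−xmid)})^s on log10 molar dose x. The sign
convention makes positive slope b mean viability falling with dose (y → T
as x → −∞, y → B as x → +∞); s > 0 skews the transition. Lower-order
variants fix parameters: 2P (B=0, T=1, s=1), 3P (+T free), 4P (+B free),
5P (all). Parameters are estimated by bounded least squares
(`scipy.optimize.least_squares`, trf) on θ = (B, T−B, xmid, b, s), which
builds the T ≥ B constraint into the parameterization. Initialization is
deterministic: five starts on a grid over xmid (quartiles of the dose
range) and slope sign/steepness; no random restarts, so fits are exactly
reproducible and invariant to replicate order.

*Weighting.* The literature the assay analysis follows uses "weighted"
n-parameter logistic regression without stating the weights; here an
unweighted first pass provides residuals r_i and the final fit minimizes
Σ w_i (y_i − ŷ_i)² with w_i = 1/max(|r_i|, ε)^p, p = 2 by default
(configurable), ε a small floor that keeps noiseless data from producing
infinite weights. Model order is selected by weighted R²; ties within 1e−9
go to the fewer-parameter model, so noiseless low-order data is reported at
its true order. Non-convergence is flagged on the returned fit rather than
raised.

*AUC.* Predicted viability is clipped to [0, 1] and integrated with
composite Simpson's rule (default 201 grid points; the integrand is smooth,
so doubling the grid moves the integral by < 1e−9) over the observed dose
range; dividing by the range width gives a dimensionless AUC in [0, 1].
Range-normalization was chosen over per-drug max-normalization because it
needs no cross-drug reference and keeps single-agent and combination AUCs
on one scale; clipping (rather than keeping >1 viability) keeps the score
interpretable as "fraction of viability retained". Both choices are
arguments (`clip`, `x_range`).

## Natural-breaks classification

`jenks_breaks` is the exact Fisher–Jenks dynamic program, O(k·n²) with
prefix sums — exactness matters at cohort sizes of a few dozen values and
allows brute-force verification by enumerating all C(n−1, k−1) partitions.
Cost ties resolve toward the smallest leftmost break. A reported break is
the smallest value of its upper class and belongs to the upper class:
classification at a break value lands on the resistant side, consistent
with the rule that a regimen is resistant only when every component AUC is
*at least* the threshold.

GVF(k) = 1 − SS_within/SS_total (defined as 1 when SS_total = 0). The class
count is chosen as the smallest k with GVF(k) ≥ 0.9 or marginal gain
GVF(k+1) − GVF(k) < 0.05; both constants are arguments. A structural note:
for four equal-size, equally spaced tight clusters the optimal 3-class
partition explains *exactly* 90% of the variance (within₃/total → gmin²·
n_pair/ SS_total = 0.1 in the tight-cluster limit), i.e. such data sits
precisely on the default GVF target and k=3 vs k=4 is a coin flip. The
planted-recovery simulation therefore uses cluster sizes (4, 8, 8, 4),
where merging the heavier middle clusters is genuinely expensive and k=4 is
recovered in ≈96% of seeds.

The segregation break maximizes the number of correctly separated in vivo
labels (responders strictly below, non-responders at/above); ties take the
lower boundary — the conservative choice, extending "sensitive" calls only
to clearly lower AUCs. All boundaries are reported alongside the selected
one, since which ordinal break carries the biology cannot be decided from
boundary values alone.

## In vivo metrics

Volume V = L·W²/2 with a swap-normalize convention (width ≤ length).
T/C at day d is mean(V_d/V_0 treated)/mean(V_d/V_0 control), with linear
interpolation in volume between caliper days. mRECIST-style calls use the
arm-mean percent-change trajectory: best response = min over days ≥ t_min
(default 10, to avoid immediate post-dose noise) and best average response
= min running mean over the same days; the default threshold table is
CR: best < −95 and avg < −40; PR: best < −50 and avg < −20; SD: best < 35
and avg < 30; else PD — strict inequalities, so boundary values never earn
the better class. The exact published table for this study design is in
unavailable supplementary material, so the table is configuration and is
serialized into every `ResponseCall`.

## Glycomics

Composition strings H{h}N{n}F{f}S{s} (zero counts omitted) round-trip
through a strict regex parser; a valid N-glycan needs N ≥ 2 (chitobiose
core). Permethylated monoisotopic masses are assembled from residue
formulas after full methylation — Hex C9H16O5 (204.0998), HexNAc C11H19NO5
(245.1263), dHex C8H14O4 (174.0892), NeuAc C16H27NO8 (361.1737) — plus the
chain-terminal C2H6O and the adduct (sodiated, electron-corrected, by
default). Deriving the table from atomic formulas rather than hard-coding
literature increments makes the mass table auditable element by element
(H5N2 [M+Na]+ = 1579.783).

Peak annotation enumerates compositions with N ∈ [2, 10], H ≤ 12, F ≤ 5,
S ≤ 6 whose mass falls in the recorded 500–6000 m/z window, and assigns
each peak the minimum-|ppm| candidate within 20 ppm (default); exact ties
go to fewer total residues. Unassigned peaks are reported, not dropped
silently.

Subtype assignment from composition alone is necessarily heuristic — the
hybrid/complex distinction is structural. The rule table: high-mannose
(N=2, 5–9 H, no F/S), pauci-mannose (N=2 with H ≤ 3, or H=4 with core
fucose), hybrid (N=3, H ≥ 5), complex otherwise; N=3 calls are flagged
ambiguous. Derived traits are the S and F counts. The cross-sample census
takes any nonzero annotated intensity as "present" (configurable floor),
computes the union, the core (present in all samples), and categorizes each
glycan as paired (both members of ≥1 matched pair), discordant (both
sources, never in a matched pair), or source-only.

## EV biomarkers

Quantile normalization maps each column onto the mean sorted profile after
log2(x+1); tied values receive the average of the quantile values they span
(average-rank convention), so zeros stay at the minimum rank. The
enrichment filter is deliberately the plain fold/prevalence rule —
detected (≥ floor, default the smallest nonzero intensity, i.e. any
nonzero counts) in ≥ `prevalence` tumor lines and mean tumor ≥ `fold` ×
mean reference on the linear scale (reference zeros replaced by the floor);
a per-line variant is provided. Moderated-statistics alternatives are out
of scope by design. PCA is SVD of the centered (and unit-scaled)
sample-by-protein matrix; scores are U·Σ.

Blot normalization divides each marker row by the CD9 loading-control row
per patient, then divides by the per-marker cohort median and multiplies by
100; implemented in that order so the per-marker median is bit-exact 100
for odd cohort sizes (m/m ≡ 1 in IEEE arithmetic; even cohorts agree to
~1e−15 because the median is the mean of two rescaled values).

The two-sample KS test computes D from ECDFs; exact p-values count the
monotone lattice paths from (0,0) to (n,m) staying strictly inside
|i/n − j/m| < D (O(nm) DP, auto-selected for n·m ≤ 1e4; float path counts
stay < C(200,100) ≈ 9e58, inside double range). The exact routine assumes
continuous data and falls back to the asymptotic Kolmogorov p with a
warning when cross-sample ties occur. At equal small cohort sizes the
attainable p-lattice is discrete and the test is conservative (true
type-I rate ≈ 0.026 at 6 vs 6); the null-calibration test therefore uses
coprime sizes 29 vs 37, which densify the lattice (measured rejection rate
≈ 0.04–0.05 at α = 0.05).

## Synthetic data

The generators emulate the study conditions, not raw instrument output:

* **Viability plates** — 9 doses spanning 10 nM–100 µM (log10 −8…−4),
  3 replicates, additive Gaussian noise sd 0.05 on the viability fraction,
  truncated to [0, 1.5] (assays do report >100% viability); planted
  logistic parameters per drug, untreated mean 1.0.
* **Caliper series** — V0 = 225 mm³ (enrollment at 200–250 mm³), control
  growth ×4 over the 28-day study (r = ln4/28 per day), thrice-weekly
  reads, treated rate = control rate × planted effect, multiplicative
  (1+ε) noise with sd 0.10; length = width = (2V)^{1/3} so the volume
  formula inverts exactly.
* **Glycan profiles** — 5 matched PDX/PXO pairs; a 57-composition core
  (5 high-mannose, 3 pauci-mannose, 7 hybrid, 42 complex) present in every
  sample at higher abundance; 227 variable glycans each present per sample
  with p = 0.37 (≈140 glycans/sample, ≈280 in the union); lognormal
  intensities with a shared per-pair effect. A variable glycan drawn
  present in all samples has one occurrence removed so the planted core
  stays exact — the generator defines the core, it does not merely make it
  likely.
* **EV tables** — 300 proteins × (6 tumor lines + 2 exocrine references),
  lognormal base abundances with 15% multiplicative noise; planted markers
  (CD44, GPC4, VGLUT2, CD14, ANXA11) elevated 4-fold in all tumor lines.
  Blot table: 6 + 6 patients, positive CD9 row, 4-fold planted cohort
  shift for a subset of markers.
* **AUC cohorts** — 24 values in 4 Gaussian clusters (means 0.15, 0.38,
  0.61, 0.84, sd 0.04) with the planted sensitivity threshold 0.52 inside
  the central gap; responder labels follow the cluster truth.

All draws flow through one `numpy.random.default_rng(seed)` per generator
call; a fixed config reproduces byte-identical tables. What the simulations
do **not** model: pharmacokinetics, inter-drug correlation within a line,
raw MALDI spectra (peak lists only), isotope patterns, batch effects, or
missingness structure in proteomics beyond simple zeros — so passing
recovery tests demonstrates correctness of the estimators under the stated
noise models, not robustness to every artifact of real data.

## Problem sizes and numerical choices

The logistic recovery study uses 200 seeds at 6 doses × 3 replicates; the
T/C recovery 100 seeds; the segregation-break study 100 seeded cohorts of
24 AUCs; the KS calibration 500 draws. Optimizer tolerances are 1e−14
(xtol/ftol/gtol) with ≤2000 function evaluations per start; Jenks DP
tie tolerance 1e−12; annotation ppm tie tolerance 1e−12; Simpson grids are
odd, ≥ 11 points. Degenerate inputs (flat viability, zero total intensity,
constant matrices, identical labels) either return defined values
documented above or raise with a specific message.

## Known limitations

* Subtype calls from composition cannot resolve hybrid vs complex or
  fucose linkage (Lewis-X vs core); ambiguous N=3 calls are flagged.
* The mRECIST table and the class-count constants stand in for
  unavailable supplementary definitions; both are configuration, and
  conclusions that depend on them should be checked for sensitivity.
* The enrichment filter is a screen, not an inference procedure: it
  controls no error rate.
* Exact KS p-values assume no cross-sample ties; heavily tied data falls
  back to the asymptotic approximation.
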