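# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, what the synthetic data do and do not emulate, and the choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and footprint geometry

All transcript coordinates are 0-based half-open internally; SAM input
(1-based) is converted at the boundary. Footprints live in transcript space
(alignments against a transcript FASTA); genome-space spliced alignment is
out of scope. The sample sheet is the single source of condition and
replicate labels, keeping alignment records label-free. Every filter logs a
funnel (input, kept, reason-coded drops) at INFO level.

The analysis keeps reads of 29–31 nt whose A-site window — read positions
15–17, 1-based, for every accepted length; no per-length offset
calibration — is codon-aligned with the ORF: `(five_prime + 14 − cds_start)
mod 3 == 0`. A read whose 5′ end sits "in frame" in this sense has its
A-site codon exactly on the ORF grid; reads shifted ±1 nt fail the test.
Reads decoding the first 15 nt of the ORF (A-site codon index < 6, 1-based)
are excluded, because initiation biases act at the decoded codon. Reads
whose +4 window would touch the stop codon are dropped whole rather than
per-site, so all five site tallies cover the identical read set; this
preserves the exact equivalence between count-based and within-site
frequency-based occupancy.

## Occupancy statistic

For each codon c, occupancy at the A-site is
`n_A(c) / mean(n_{+1}(c), n_{+2}(c), n_{+3}(c))` — a codon-usage
correction using the *same* codon's downstream counts, not the occupancy of
whatever codons happen to sit downstream of each read. Under a uniform
dwell model the statistic is 1 for every codon. The +1-site control repeats
the computation one codon downstream (normalised by +2/+3/+4); codons there
have not been decoded, so genuine decoding-speed effects must vanish.
Stop codons are excluded throughout (A-site stop decoding is termination,
not elongation). No pseudocounts: a zero denominator propagates as missing
and is flagged, never silently smoothed.

Condition summary: the KO/WT ratio of condition means of per-replicate
occupancies, with dispersion the standard deviation over all pairwise
(KO replicate / WT replicate) ratios — a symmetric, documented choice; the
estimator behind published per-codon mean ± sd plots is typically unstated.
Codon-frequency quartiles rank the 61 sense codons by their frequency over
all ORF sense codons, ties broken alphabetically; the rarest quartile takes
the extra codon (16/15/15/15).

### What the generator emulates, and a bias worth knowing

The footprint generator realises the stationary interpretation of the
occupancy statistic directly: it picks an ORF sense codon (beyond the first
five) with probability proportional to its condition-specific dwell weight
and places the read so that codon occupies positions 15–17, then draws the
length (28–32 nt) and applies an off-frame ±1 shift with small probability.
It does not simulate elongation trajectories, initiation/termination peaks,
sequence-dependent digestion bias, or sequencing error; passing tests
therefore demonstrate correctness of the statistic under its own model, not
robustness to those artefacts of real libraries.

One consequence the synthetic study makes explicit: with a fixed read total,
slowing a codon set S by a factor m renormalises every codon's share, so
unaffected codons sit at `Σu/(Σ w·u)` (≈ 61/62 ≈ 0.984 for m = 1.5 on two
codons under uniform usage), not exactly at 1, and the planted codons
recover m times that factor (≈ 1.48). At the standard depth
(2×10⁵ reads × 3 replicates per condition) the per-codon ratio noise is
≈ 2% sd, so the extreme over ~60 codons regularly exceeds 5% deviation;
claims about unaffected codons and the +1 control are therefore assessed on
their central tendency (median) and on the strict separation between
planted and unaffected codons, which is the scientifically meaningful
statement. Problem sizes used throughout (50 transcripts, ~100-codon ORFs,
2×10⁵ reads per sample) are the package's standard desk-scale study.

## Peptide mass arithmetic and stoichiometry

Monoisotopic residue masses (six decimals), water 18.010565 Da, proton
1.007276 Da, methyl increment CH₂ = 14.015650 Da. Only the
monoisotopic-mass + proton-mass combination reproduces the monitored
selective-ion settings at two decimals; printed-value comparison rounds
half away from zero. The methylation site (α- vs ε-amine) does not change
the mass and is annotation only. SILAC shifts come from isotope mass
differences: K8 = 6·(¹³C−¹²C) + 2·(¹⁵N−¹⁴N) ≈ 8.0142 Da, R10 ≈ 10.0083 Da.

XICs sum intensity over a symmetric ppm window per retention time.
Stoichiometry integrates each Me-state trace by the trapezoid rule after
subtracting a constant baseline (median intensity of the first and last 5%
of time points, floored at 0 — simple and testable; vendor integration
behaviour is proprietary) and reports relative areas. The chromatogram
generator emits one Gaussian elution peak per methyl state (default
separated by 0.5 min; co-elution is configurable since extraction is
m/z-based), monoisotopic traces only — no isotope envelopes, charge-reduced
species, or retention-time drift.

## Processivity kinetics

Species S0..S3 and complexes E·S0..E·S2 under mass action: binding k_on
(µM⁻¹s⁻¹), dissociation k_off, catalysis k_cat (s⁻¹), shared across steps
by default (no step-resolved kinetics are available to fit; per-step
overrides exist). AdoMet is assumed saturating and is not a state variable.
Distributive catalysis releases (E·Sᵢ → E + Sᵢ₊₁); processive catalysis
hands off (E·Sᵢ → E·Sᵢ₊₁), releasing only the trimethylated product.
Deterministic stiff-safe integration (LSODA, rtol 1e-8, atol 1e-10);
substrate and enzyme conservation are checked to 1e-6 relative. µM-scale
copy numbers justify ODEs over stochastic simulation.

Defaults k_on = 1 µM⁻¹s⁻¹, k_off = 0.01 s⁻¹, k_cat = 1 s⁻¹, S = 1 µM,
t = 3600 s (a typical end-point incubation): the per-encounter release
probability k_off/(k_off+k_cat) ≈ 1% keeps a processive enzyme's
intermediates scarce, while every distributive encounter releases. The
classifier scores a titration by the maximum Me1+Me2 over partially
converted points (Me0 < 0.95 and Me3 < 0.95; at completely unconverted or
fully converted points the mechanisms are indistinguishable) with decision
threshold 0.2, chosen midway between the analytic extremes of the two
mechanisms at matched conversion. The two models coincide exactly as
k_off/k_cat → ∞ (hand-off never beats release), so mechanism recovery is
only claimed on rate grids satisfying k_cat ≥ 20·k_off; inside that region
the seeded two-decade grid is recovered perfectly by the tests.

## Motif analysis

Arrays arrive as quantified grids (image quantification and blank-spot
subtraction are upstream concerns): intensity per (position 1–9, residue)
over the 18 proteinogenic residues minus Cys and Trp, normalised by the
wild-type spot. Logo columns treat relative activity as letter frequency;
information content uses alphabet size 20 (conventional logo scaling, even
though arrays omit two residues — hence a uniform 18-residue column carries
log₂20 − log₂18 ≈ 0.152 bits), no small-sample correction. The consensus
rule includes residue a at position p iff activity ≥ θ·max(p), prepends the
fixed initiator-methionine class, and drops trailing positions with no
selectivity (class = all 18). θ defaults to 0.25 — a tool parameter
calibrated on the planted synthetic array, not a claim about any
laboratory's (unstated) inclusion rule. Proteome scanning is exact anchored
class matching, deterministic and auditable, rather than a BLAST
heuristic; published candidate counts additionally depend on proteome
version and redundancy curation, so no specific count is claimed beyond
planted-truth recovery.

## Differential statistics

The moderated statistic is d = (mean₁ − mean₂)/(sₑ + s₀) with sₑ the
pooled-variance two-sample standard error; s₀ = 0 reduces exactly to
Student's t. Default s₀ = 0.1, overridable (reported conventions vary
between 0.01 and 0.1 even within one study; both are accepted via the
parameter). The FDR curve evaluates, at each observed |d| as candidate
cutoff c, `FDR̂(c) = mean over label permutations of #{|d_perm| ≥ c} /
#{|d_obs| ≥ c}`; the threshold is the smallest c with FDR̂ ≤ target, ties
called significant (deterministic). Label assignments are enumerated
exactly when few (3-vs-3 has C(6,3) = 20) and sampled without replacement
otherwise; designs with fewer than 20 distinct assignments are rejected.
The observed assignment and its mirror are excluded from the null — with
them included FDR̂ can never fall below 1/n_perm, and small balanced
designs could never reach stringent targets.

Left-censored missing values are imputed per sample from
Normal(mean − 1.8·sd, (0.3·sd)²) — the widely used down-shift convention
for label-free proteomics, documented as a default rather than a claim
about any specific study's parameters. Imputation never alters observed
cells. By construction ~30% of imputed draws can exceed the observed 5th
percentile (the draw centre is 1.8 sd down with 0.3 sd spread, versus
1.645 sd for p5), so tests assert concentration in the lower tail rather
than strict domination.

Significance B orders features by intensity into bins of 300 (remainder
merged into the last bin), computes per-bin robust z-scores (median centre;
half the 15.87–84.13 percentile spread as scale — the Gaussian-consistent
robust sd), and reports two-sided standard-normal p-values; two-sided is
the documented default where the original convention is unstated. Bin
membership depends only on intensity ranks, so the p-values are invariant
to monotone intensity rescaling. BH adjustment delegates to statsmodels
and is oracle-checked against the hand-computed step-up.

The intensity-table generator uses per-feature baselines N(25, 2²) log2
units and within-group replicate noise of 0.15 log2 units, representative
of well-controlled isotope-label quantification; with only 18 informative
3-vs-3 permutations, substantially noisier replicates would make stringent
permutation FDR targets unreachable at n = 3 regardless of implementation.
Left-censoring applies a missingness probability rising linearly below a
threshold quantile of the pooled intensities.

## Known limitations

- The occupancy model is stationary; no initiation/termination peaks,
  per-length offset calibration, or RNA-seq normalisation.
- XIC mathematics is monoisotopic-only; no envelope fitting or cross-run
  retention alignment.
- Kinetic rate constants are illustrative defaults, not fits to any
  measured titration; mechanism classification is undefined where
  hand-off and release compete evenly.
- The permutation FDR needs ≥ 20 distinct label assignments; 2-vs-3
  designs are rejected rather than silently under-powered.
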