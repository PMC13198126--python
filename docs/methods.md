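# Methods

This note documents the models, conventions and design choices behind
`lipidtiers`, in the order data flows through the package.

## Lipid shorthand grammar

The parser accepts the dialects targeted-lipidomics reports actually
print:

* *sum composition* — `TG 52:3`, `SM 33:1;O2`: class code plus total
  carbons:double-bonds, optionally `;On` extra oxygens. No acyl
  attribution is possible at this level.
* *molecular species with header* — `DG 36:3(18:2_18:1)`,
  `PE O-38:6(O-18:2_20:4)`: the chain list must sum to the header totals,
  asserted during parsing. Ether (`O-`) and vinyl-ether (`P-`) chains
  contribute their carbons and double bonds to the header exactly as
  printed (verified against the 38:6 = 18:2 + 20:4 ether example); an
  optional normalization rewriting `P-` as `O-` with one extra double bond
  exists but is off by default so output matches input dialect.
* *bare chain list* — `Cer d18:1/17:0`, `PE 17:0/17:0`: the standards
  dialect without a totals header. Sphingoid bases (`d`/`t` prefix) are a
  distinct chain kind and are never matched by acyl queries.
* *single chain* — `FA 16:0`, `LPC 17:0`; an optional ω-suffix
  (`FA 18:3 n-3`) records chromatographically resolved double-bond-series
  isomers. The package never infers ω-position from composition.

Both `_` (sn-unresolved) and `/` (sn-resolved) separators are accepted and
preserved; canonical output uses a single space after the class code and
no space before the chain list. Names printed with a space before the
parenthesis parse to the same species; the canonical form drops the space
(a purely typographic normalization).

A bare composition on a sphingolipid class (`SM 33:1;O2`) stays
sum-composition because the totals fold the base and N-acyl together; on a
single-slot glycerolipid class it is a molecular species.

### Saponifiability accounting

The class registry (`data/lipid_classes.csv`, editable CSV) records per
class the number of acyl slots and how many are released by alkaline
hydrolysis. Sphingolipid N-acyls (amide bond) and ether/vinyl-ether
chains are not; the free-acid class FA has nothing to hydrolyse. The
`acyl_multiplicity` counter matches on (carbons, double bonds, linkage,
oxygenation) — an `O-18:2` chain never matches an ester 18:2 query — and
under saponifiable-only counting (the default, used everywhere in tier
accounting) returns 0 for every non-ester chain.

## Panel and internal standards

Chain-length subclasses follow the common literature bins, extended to be
contiguous: SCFA ≤ C6, MCFA C7–C14, LCFA C15–C21, VLCFA ≥ C22. The
quantification recipe, however, routes C7–C12 acids to the octanoate
standard, so internal-standard assignment uses its own boundary scheme
(C2–C6 → butyrate-d2, C7–C12 → octanoate-1-¹³C, ≥ C13 saturated →
d31-palmitate, ≥ C13 unsaturated → d8-arachidonate; polar acids map to
their matched deuterated standard). Labelling and routing serve different
purposes and genuinely disagree for C13–C14; both schemes are
`BoundaryScheme` dataclasses and configurable. Flags are structural:
OCFA = odd carbon count, PUFA ≥ 2 double bonds (diunsaturated = exactly
2), VLC-PUFA = both VLCFA and PUFA.

Spiked internal-standard amounts derive from the cocktail concentrations
(e.g. d31-palmitate at 5 µg/mL, 50 µL spike) and the labelled molecular
weights; they are overridable per run.

The packaged branch-C panel (`data/panel_branchC_synthetic.csv`) is a
synthetic reconstruction, as its name says: a chemically plausible
analyte list with the canonical subclass census (7 SCFA, 6 MCFA, 38 LCFA,
50 VLCFA, 15 polar = 116), including ω-isomer pairs and two branched
short-chain isomers that share a shorthand but are distinct analytes.
Replace it with a laboratory's own registry for real use.

## Quantification and validation metrics

`amount_pmol = area/area_IS × spiked_pmol`; tissue normalization divides
by tissue mass (pmol/mg ≡ nmol/g). Negative or zero analyte areas are
treated as missing, never clamped into amounts; a missing IS area
withholds the sample's dependent analytes with a flag; a zero IS area is
an error.

Calibration is unweighted OLS of peak area on concentration in mmol/L
(mg/L divided by the analyte's molecular weight; FA weights are computed
from CnH(2n−2d)O2, polar acids carry explicit weights). σ is the residual
standard error with the n−2 regression denominator — the conventional
reading of "standard error of response". LOD = 3.3σ/S and LOQ = 10σ/S, so
LOQ/LOD = 10/3.3 identically. Expressing limits in pmol on column
requires an injection volume; it is a config parameter (default 2 µL) and
is the dominant uncertainty when comparing pmol-scale limits between
laboratories. The linear range is the longest contiguous run of ≥ 3
distinct levels whose own fit reaches R² ≥ 0.98 (cutoff configurable).
1/x-weighted fitting is available behind `weighting="1/x"`. Replicate
injections enter one pooled regression by default.

Recovery `[(S3−S0)/(S1−S0)]/3 × 100 %` is undefined (flagged, not
computed) when the 1× spike does not rise above background. Precision
uses the n−1 standard deviation: intra-day CV is the mean of per-day CVs,
inter-day CV the CV of the pooled multi-day set.

## Tier integration

The ledger computes esterified = total − free element-wise on matching
(sample, FA) pairs. Measurement noise can push free above total for FAs
with small esterified pools; negative differences are clamped to zero
**with an explicit flag**, preserving non-negativity without hiding the
QC signal. FAs present in one tier only are flagged `unmatched` and
excluded from partitioning. On noiseless synthetic data the clamp rate is
zero by construction.

Partition fractions weight each resolved species by its saponifiable
multiplicity of the query FA. Two denominators are implemented because
the definitional choice is genuinely open: *tier-derived* (the esterified
amount from subtraction — the workflow's definition; the default) and
*lipidome-sum* (fractions then sum to 1 over fully resolved species).
`coverage` = lipidome-sum / tier-derived esterified diagnoses how much of
the subtraction-derived pool the measured lipidome explains; it is 1 on
noiseless synthetic data. Sum-composition species cannot be attributed
to a specific FA and accumulate in `unresolved_amount` (only classes with
saponifiable slots count — an unresolved SM cannot hide esterified FAs);
they still participate in class-level analyses such as TG carbon bins.

TG carbon-number bins default to (≤ 50, > 50) with the boundary inclusive
on the lower bin. Published descriptions of the short-to-medium bin vary
between C45–C50 and C46–C50; the boundary is a parameter
(`tg_carbon_bins(boundary)`) and the discrepancy is surfaced here rather
than resolved.

## Statistics

Two-group comparison is the two-sided **pooled-variance** Student t test
(Welch behind a flag), significance at p < 0.05 with no multiple-testing
correction by default — matching the single-tissue screening design this
mirrors — with Benjamini–Hochberg available for larger reuse. Fold change
is the ratio of group means (not the mean of ratios); log2 is applied only
in display tables. The fully degenerate case (both groups constant and
equal) returns t = 0, p = 1, flagged. Set overlaps use the exclusive
(UpSet) convention, so counts partition the union. Heatmap preparation
standardizes each analyte row to mean 0, sd 1 (n−1); z-scoring is a
choice, labelled as such, since display normalizations vary between
publications.

## Synthetic data

The generator's defaults are the study conditions: two groups of n = 4
(young/old), ≈ 30 mg tissue, an 8-FA panel subset with free amounts of a
few to tens of nmol/g, a 17-species lipidome with resolved acyls across
TG/DG/PC/PE/PI/PS plus sphingolipids, multiplicative group effects
(2–2.5× TG enrichment, strongest for the odd-chain 17:1-bearing TG; 1.3×
free 18:1; 1.5× SM), and log-normal multiplicative area noise with
sd 0.05 — the standard error model for MS responses; an additive baseline
is available and defaults to 0. Response factors are shared across tiers
per analyte (tiers differ only in which pool is rendered); per-tier
scales exist to stress-test denominator modes. Calibration simulation
uses the 0.0005–0.25 mg/L nine-level grid with Gaussian residuals, so the
analytic detection limit 3.3σ₀/S₀ of the generating process is known.

What the generator does **not** emulate: chromatographic peak shapes and
integration error, retention drift, carryover, isotope patterns, batch
effects, biological covariance between analytes, or heteroscedastic
(intensity-dependent) noise. Passing tests therefore demonstrate the
correctness of the accounting and inference layer under the stated error
model, not robustness to those acquisition artifacts.

A seed fully determines every table; re-rendering is byte-identical.

## Problem sizes and numerics

The test suite and acceptance script use the generator's default sizes
(8 + 8 samples, 8 FAs, 17 species), 200 replicate studies for power, and
1,000 null contrasts for the type-I rate — sizes chosen so the Monte-Carlo
error of the checked rates (binomial sd ≈ 0.7 pp at n = 1000) is well
inside the asserted bands. All amounts are carried at full double
precision; display rounding happens only in report tables. Ties in the
linear-range search prefer the longer run, then the earlier (lower
concentration) window. Degenerate inputs (all-equal concentrations,
zero-mean replicate sets, empty panels) raise typed errors rather than
returning NaN silently.

## Known limitations

* Sum-composition TGs are excluded from FA-specific partitioning rather
  than deconvolved; positional (sn-1/sn-2) specificity is not modelled.
* The packaged panel is a synthetic reconstruction (above), not a
  laboratory registry; molecular weights for FAs are average masses from
  the molecular formula.
* Multiple-MRM-pair selection is represented by per-pair linear-range
  tags; automatic cross-validated pair choice is not implemented.
* Branch A may not capture every esterified pool, so tier-derived
  coverage below 1 on real data is expected and reported, not corrected.
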