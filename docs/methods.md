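# Methods

## Scope and data model

The pipeline starts where the chemistry ends: at a GC-MS FAME
composition table giving, per sample, the mass percent of total
extracted lipid recovered as each fatty acid methyl ester. It performs
no chromatogram processing and no renormalization — the percentages and
their column sum (the total FAME recovery, typically 60–90% after
direct transesterification) are taken as reported.

Fatty acids are identified purely by shorthand (`Cx:y n-z`). The parser
accepts the dialect spread seen in published tables — optional leading
`C`, explicit `:0` on saturated acids, omega written `n-3`, `(n-3)`,
`ω3` or `w3`, stray whitespace — and canonicalizes to one form
(saturated: `C16`; unsaturated: `C18:3n-3`). Structural sanity is
enforced at parse time: at most `(carbons − 2)/2` double bonds, omega
class in `[1, carbons − 2]` and present exactly when the acid is
unsaturated. Branched, hydroxy and trans-designated acids are rejected
rather than guessed, because a silently wrong double-bond count
corrupts every downstream number. The omega class is declarative (read
from the name), never derived from positional locants; locants live
only in the systematic methyl-ester names of the catalog. The
double-bond count is therefore always computed from the name — there is
no way to hand-enter an unsaturation into the pipeline.

## Unsaturation and fuel-property correlations

The central statistic is the average degree of unsaturation,
`ADU = Σ Mᵢ·Yᵢ`, with `Mᵢ` the parsed double-bond count and `Yᵢ` the
mass fraction **of total lipid**. The denominator convention matters:
renormalizing a profile with 83.46% recovery to sum to 1 would inflate
its ADU by ~20% and break agreement with the reference property table
the fixtures reproduce; the unnormalized convention is the one under
which that table is internally consistent.

Five properties are linear in ADU (kinematic viscosity, specific
gravity, cetane number, iodine value, higher heating value; see the
README for coefficients and units). The coefficients are a published
regression over algal-oil FAMEs and ship as a replaceable TSV, since
several alternative coefficient sets exist in the literature. Profiles
whose ADU falls outside [0.6, 1.6] — the quality-limit range the
correlations are judged against — get a logged extrapolation warning
but still return values.

## Rounding policy

Two policies are explicit rather than implicit:

- `"none"` (default): full float precision end to end. Use for any
  downstream numerical work.
- `"paper"`: printed-table arithmetic. The ADU is rounded half-up to
  two decimals and **each correlation is applied to the rounded ADU**,
  then rounded to its own printed precision (Vis 2 dp, SG 3 dp, CN 1 dp,
  IV 2 dp, HHV 1 dp).

The two-stage scheme is not cosmetic: at ADU 1.6671 the iodine value is
136.70 at full precision but 136.91 when computed from the rounded
1.67, and only the latter matches the reference table. A regression
test pins this. Rounding is half-up via `decimal` on the float's
shortest repr — banker's rounding would flip ties and is deliberately
not used. The rounding rule itself is an inference from the reproduced
table (all 24 cells match), not a documented convention of the source
data.

## Compliance checking

Criteria are inclusive two-sided or one-sided bounds per property:
Vis, SG, CN from ASTM D6751, IV from EN 14214, and ADU/HHV ranges that
the source table lists without attributing to either standard (tagged
`paper_stated` and user-replaceable). Verdicts are computed on the
values as given — under policy `"paper"` that means printed precision,
so "HHV 41.4 vs limit 41" fails deterministically instead of hinging on
float noise. Each verdict carries a signed margin (slack to the nearest
bound for passes, size of the violation for fails). A criterion naming
a property the input lacks is a configuration error, never a silent
skip.

Note an inconsistency in the source study's prose: it describes the two
*M. conductrix* isolates as weak only in iodine value, yet their printed
HHV (41.4, 41.5) exceeds the stated 38–41 range and G4-3's ADU 1.63
exceeds 0.6–1.6. The module reports what the numbers imply (three
violations each); the prose claim is not encoded.

## Screening metrics

Volumetric lipid yield is `dry_biomass × lipid_content/100` (g L⁻¹,
reported to 3 decimals) — the quantity a feedstock screen ultimately
compares. Rankings are descending on any of lipid yield, FAME recovery,
dry biomass or lipid content, ties broken by sample id; records missing
the key (G4-9's biomass was reported only graphically and is stored as
missing) rank last with a logged notice, so no figure-derived guesses
enter the data. Only means enter computations; reported standard
deviations are stored as metadata. The source study also prints a
lipid yield of "4.52 ± 0.007 g L⁻¹" for isolate P5-4 that cannot be
reconciled with its own biomass (1.30 g L⁻¹) and lipid content
(66.72%), whose product is 0.867 g L⁻¹; the package computes and
reports the product.

## Synthetic profiles

The generator emulates the structure of real screening tables: a panel
of C14–C24 acids (default: the 21 acids of the packaged fixtures), a
sparse subset drawn uniformly without replacement, component weights
drawn as a symmetric composition (independent Gamma(shape =
`concentration`) variates, normalized — the standard Dirichlet
construction), and the column total drawn uniformly from a recovery
range. Defaults: 12 components, concentration 0.7 (real profiles are
dominated by a few acids; sub-unit shape reproduces that spikiness),
recovery 60–90% matching observed direct-transesterification totals.
Each profile stores its ground-truth ADU computed from the unrounded
weights at generation time, giving an exact oracle for the pipeline
(agreement to 1e-9 is asserted over 200 profiles; after serialization
at two decimals the discrepancy is bounded by 0.005·max M·n_components).
One seeded `numpy` generator drives each batch; identical seed and spec
reproduce output byte-identically.

What the generator does **not** emulate: GC-MS measurement error,
co-elution, detector response, or any biology linking culture
conditions to composition. Passing tests on synthetic data therefore
demonstrate arithmetic and contract correctness of the pipeline, not
robustness to instrument noise.

## Numerical and design choices

- All printed-precision values go through one shared half-up rounding
  helper; there is exactly one rounding implementation.
- Profile sum tolerance defaults to 0.5 percentage points over 100,
  configurable; printed tables carry rounding error.
- Empty cells mean "not detected" and produce no component; explicit
  zeros are dropped with a logged notice; the distinction is preserved
  on write (absent acids serialize as empty cells).
- An empty profile has ADU 0 and property values equal to the
  correlation intercepts — degenerate but well-defined.
- Validation findings are data (an ordered list of strings), not
  exceptions, so a QC step can collect them across many profiles;
  hard errors are reserved for unreadable or structurally broken input.

## Problem sizes

The reference computation is four profiles of 8–18 components — the
whole quantitative surface reproduces in well under a second. Property
and oracle tests use 200 synthetic profiles, which keeps the full suite
around a second while exercising every acid in the panel many times.

## Known limitations

- Property models are linear in ADU only; no per-acid blending rules,
  cold-flow or oxidative-stability models.
- Compliance covers the six tabulated parameters, not the full ASTM/EN
  test suites (flash point, sulfur, glycerides, ...).
- The shorthand grammar excludes branched/hydroxy/trans acids by
  design; tables containing them must be curated before loading.
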