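# Methods

This note documents the statistical model, the defaults and the design
choices behind `lofburden`, and what the synthetic-data validation does
and does not establish.

## Model

Each gene is summarised as a 2×2 allele table. On the case side, `a` is
the number of qualifying LoF alleles observed among `AN_case = 2·n`
alleles in `n` discovery cases; the allele number is fixed at `2·n` with
no per-sample missingness adjustment, matching how a fully genotyped
panel cohort is usually counted. On the reference side, `c` is the sum
of qualifying per-variant allele counts and `AN_ref` the reference
allele number. The two-sided Fisher's exact p-value ranks genes; the
test is exact but, at these sample sizes, a ranking device rather than a
per-gene significance claim.

Two conventions matter and are fixed deliberately:

- **Odds ratio.** The reported OR is the sample cross-product estimate
  `ad/bc`, not the conditional maximum-likelihood estimate that
  `fisher.test`-style outputs print. Published gene-level ORs in this
  setting reproduce only under the cross-product definition (verified in
  the test suite for ten genes to printed precision). `bc = 0` with
  `ad > 0` reports +inf; the empty table `a = c = 0` reports an
  undefined OR with p = 1.
- **Two-sidedness.** p is the sum of hypergeometric table probabilities
  not exceeding that of the observed table (the convention of R and of
  `scipy.stats.fisher_exact`). A tail-doubling rule is available via
  `gene_fisher(..., two_sided_rule="double")` for sensitivity analysis.

The 95% CI is the exact conditional interval
(`scipy.stats.contingency.odds_ratio`, `kind="conditional"`). It brackets
the cross-product OR in all tested configurations but is a different
estimator's interval; it is reported for orientation, not tested against
published intervals, which follow no reconstructible rule.

### Combined carrier frequency and risk ratio

Reference per-variant frequencies are combined as
`1 − ∏(1 − AF_i)` — the probability of carrying at least one qualifying
allele under independent segregation (no linkage). The risk ratio is
the case carrier frequency (`a / AN_case`) divided by this combined
reference frequency; it drives the fold-enrichment rule, while the
Fisher test uses raw allele counts. Both are emitted because the two
case-side conventions (allele frequency vs carrier frequency) coincide
only when no sample carries two variants in the same gene.

### Reference allele number

Two modes (`DiscoveryConfig.an_mode`):

- `global` (default): `AN_ref = 118,190` (2 × 59,095 reference
  individuals) for every gene. Published proposed-gene ORs reproduce
  exactly under this mode.
- `per_gene`: the maximum AN over the gene's qualifying variants, which
  tracks per-gene coverage in the reference call set. Published
  candidate tables are internally consistent with reduced ANs for a few
  genes, so both modes exist and the mode is recorded in the manifest.

Pathway-level reference ANs follow the same mode (sum of per-gene ANs,
or gene count × global AN). Published pathway ORs are not exactly
reproducible under the global mode because the underlying per-gene ANs
are unpublished; pathway outputs are therefore structurally tested
(accounting identities, union-row deduplication) rather than
golden-value tested.

## Filter cascade

Stage order is fixed: impact → total MAF → canonical transcript →
quality → protein-coding biotype → popmax MAF. All thresholds are
inclusive on the keep side (MAF ≤ 0.005 is kept, quality exactly 500 is
not flagged). A variant absent from the reference is treated as AF 0:
unseen implies rare. The four sequencing-quality metrics (quality score
< 500, depth < 60, alt fraction < 0.35, not bidirectional) *flag* a
variant for review, mirroring a manual bam-inspection queue; setting
`drop_flagged` turns them into hard filters for unattended runs. A
caller-level filter failure (non-PASS) always drops the variant at the
quality stage. Each dropped variant records exactly the first stage it
failed, and the summary counts unique variants and genes surviving each
stage, so any alternative stage ordering can be audited from the
decision log.

## Phase-aware collapsing

Within one sample and gene, variants sharing a phase-group label are
known to lie in cis and collapse to a single allele; the most severe
consequence (frameshift > stop-gain > splice > start-loss) is the one
reported. Phase-unknown co-occurring variants contribute all their
alleles. Carriers count once per gene regardless of variant
multiplicity. Homozygous genotypes contribute two alleles; the
machinery supports them although they are vanishingly rare at these
frequencies.

## Prioritisation

Candidates must have ≥ 3 case carriers, p at or below the
Benjamini–Hochberg threshold (largest sorted `p_(k) ≤ (k/m)·FDR` with
FDR 0.3 over the m tested genes — genes with at least one retained case
variant), and ≥ 3-fold enrichment. The fold rule has two scopes
(`fold_check_mode`): `primary` compares against the primary reference
population only; `all_outbred` (default) additionally requires that no
major outbred sub-population's combined frequency exceeds one third of
the case frequency, using the popmax annotations of the qualifying
variants. Ties in the ranking are broken by descending OR, then gene
symbol, making the output order deterministic.

## Synthetic cohort generator

The generator emulates the discovery setting so the whole pipeline can
run with no access-controlled data. Defaults, chosen once as the study
conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_cases` | 500 | discovery cohort scale |
| `global_ref_an` | 118,190 | 2 × 59,095 reference individuals |
| `variants_per_gene_mean` | Poisson mean 3 | rare LoF sites per gene |
| `af_range` | log-uniform [1e-6, 5e-3] | per-site reference AF |
| `known_gene_carrier_rate` | 0.01 | solved-case carriers to inject |
| `planted_min_combined_af` | 1e-3 | floor for plantable signal |
| `family_history_rate` | 0.5 | two-level family-history split |

Case alleles are independent Bernoulli draws per chromosome: allele
count ~ Binomial(2, fold × AF), fold 1 for background genes. This is
exactly the independence model under which the combined carrier
frequency is the carrier probability — the generator and the statistic
share their assumption by construction. Reference allele counts are
`round(AF × AN)`, so realized reference AFs differ slightly from the
generative ones (down to zero at very rare sites); the truth table keeps
both. Corruption rates write configurable fractions of variants with
failing QC metrics, non-canonical transcripts, MODERATE impact or a
common popmax, exercising every cascade branch.

What the generator does **not** model: linkage between sites, population
structure and ancestry mismatch between cases and reference,
relatedness, per-sample coverage variation, annotation errors, and
recurrent artefact sites. Passing the synthetic validation therefore
shows that the statistical machinery is correct under its own
assumptions — not that those assumptions hold in a given real cohort,
where ancestry matching and sequencing-artefact review carry much of the
burden of proof.

## Validation strategy and problem sizes

The exact test is validated against a brute-force hypergeometric
enumeration (exhaustive for tables with margins ≤ 10, and 5,000 seeded
random tables with margins ≤ 50); the BH threshold against an
independent brute-force scan on 1,000 random p-vectors; the combined
carrier frequency against Monte-Carlo at 10⁶ draws. Null calibration
uses 2,000 simulated genes at 500 cases (the exact test is conservative,
so at most 5% + 3σ of tested genes may reach p < 0.05); planted-gene
recovery uses 5 genes at ten-fold over 20 seeded replicates of 200
genes, requiring ≥ 4/5 recovered in ≥ 90% of replicates. These sizes
keep the full suite under a minute of compute while leaving each check
statistically sharp.

## Known limitations

- No covariate adjustment or ancestry correction; the popmax filter is
  the only guard against population mismatch.
- No variance-component or dispersion-robust burden test; genes with
  many ultra-rare singletons and genes with one recurrent variant are
  treated identically at equal counts.
- The risk-ratio convention on the case side (carrier frequency) is one
  of two defensible choices; the allele-count Fisher test is unaffected.
- Confidence intervals are decoupled from the point estimate (exact
  conditional interval around a cross-product OR).
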