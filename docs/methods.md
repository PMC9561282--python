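# Methods

## Scope and design

`driploop` packages two bespoke computations around damage-induced
DNA:RNA hybrids: (i) the break-centric DRIP-seq analysis — fragment
coverage, per-site windowed quantification, knockdown-deviation
classification, metagene, group contrasts and the pre-existing-hybrid
correlation analysis — and (ii) a cross-study proteomic hit-frequency
meta-analysis, plus the percent-input and resection qPCR quantifications.
Raw sequencing data for such experiments are rarely redistributable, so
the package is built around a synthetic-data generator whose planted
ground truth makes every pipeline stage falsifiable at desk scale. The
repository is organised as an analysis project: the numbered scripts
under `analysis/` are thin narrative drivers; all computation lives in
`src/driploop/` where the tests and the acceptance script import it.

## Coverage model

Paired-end alignments are consumed as BEDPE rows and collapsed to
mate-spanning fragments `(contig, min(starts), max(ends))`; fragments,
not read mates, are the unit of coverage. Depth is a sweep-line over
fragment endpoints stored as run-length blocks, so whole-genome tracks
cost O(fragments), not O(genome). Normalisation is fragments-per-million
(`10^6 / L`); any other constant would cancel in the fold changes, so the
choice only fixes the units of the pseudocount. All coordinates are
0-based half-open. Conservation (Σ depth = Σ fragment lengths) and
equality with naive per-base counting are enforced by tests on random
instances.

## Site quantification and classification

Per site and condition, the signal is the mean normalised depth over
`[cut − W, cut + W)`, clipped at contig edges with the clipped width in
the denominator. Defaults: `W` = 2,000 bp; metagene span ±5,000 bp in
100-bp bins. These window choices are conventional for restriction-induced
break maps, where damage-induced hybrid signal concentrates within a few
kilobases of the cut; all are configurable.

Per siRNA arm, `log2FC = mean over replicates of
log2((m_+OHT + ε)/(m_−OHT + ε))` with `ε = 0.1` normalised units.
Replicates are combined as the mean of per-replicate log fold changes
rather than the fold change of pooled coverage: it weights replicates
equally under depth imbalance. Classification uses the deviation
`Δ = log2FC_kd − log2FC_ctrl` with threshold τ = 0.5: dependent below
−τ, increased above +τ, independent otherwise. Ties at exactly ±τ stay
independent (conservative). Classification is scale-invariant: scaling
all four condition signals of a site by k > 0 (with ε scaled likewise)
leaves Δ unchanged — property-tested.

Group contrasts use a directional unpaired Wilcoxon test; the high/low
transcription split is at the median transcription level. No
multiple-testing correction is applied across contrasts: each contrast is
reported with its own p-value, matching how such per-figure tests are
usually presented. The correlation analysis is Pearson's r of the
pre-existing hybrid level (measured control −OHT signal) against the
per-arm log2FC, with the t-based two-sided p.

## Statistical tests

`driploop.stats` implements the three tests directly so their
small-sample behaviour is exact and auditable:

* **Rank-sum** — Mann–Whitney U with midranks. When the pooled sample has
  ≤ 12 observations and no ties, the p-value is computed by full
  enumeration of all rank assignments; otherwise a normal approximation
  with tie correction and continuity correction is used. The
  approximation is within 0.02 of the enumerated null for tie-free
  per-group sizes ≥ 3; below that the normal approximation is known to be
  poor (e.g. 2 vs 2, U = 0: exact 1/6 vs approximate 0.123), which is why
  the exact path owns that regime.
* **Pearson** — `t = r sqrt((n−2)/(1−r²))` with n−2 df, two-sided.
* **Paired t** — `t = d̄/(s_d/√n)`, df n−1, two-sided by default because
  assay figure legends rarely state sidedness; a one-sided flag exists.
  All-zero differences return t = 0, p = 1; constant non-zero differences
  are degenerate (raised as an error in the library; the qPCR driver maps
  them to a diverging t, as produced by noise-free simulated plates).

Type-I error of the Pearson and paired-t tests is verified at α = 0.05
within [0.04, 0.06] over 10,000 null simulations in the acceptance suite.

## Synthetic data generator

The generator emulates the statistical structure the break analysis
assumes, not sequencing reads. Per experiment: 99 cut sites placed ≥ 2W
apart on a 4 × 500 Mb genome; per-site pre-existing hybrid level
lognormal with ln-mean ln(400) CPM (fragments per million over the 4-kb
window) and ln-sd 0.8; induction magnitude proportional to the
pre-existing level (ratio 4, lognormal jitter 0.35); dependence classes
split 40/51/8 (dependent/independent/increased). Under knockdown the
induction is multiplied by 0 (dependent), 1 (independent) or 2
(increased). Dependent sites have their pre-existing ln-mean shifted down
by 1.0 (`coupling_shift`), which couples knockdown dependence to
hybrid-poor loci.

Window counts are negative binomial (variance μ + αμ², α = 0.005,
reflecting the low replicate-to-replicate variability of a clonal cell
system; the Poisson limit is α → 0). Fragment midpoints are uniform in
the window; lengths are truncated normal (mean 300, sd 100, floor 50 bp —
a generic sonication smear). The remainder of each library is uniform
genome-wide background so that the total equals `library_size` (400,000
fragments per condition and replicate) exactly; two replicates per
condition. Induction proportional to the pre-existing level makes the
control-arm fold change independent of the pre-existing level by
construction, so the correlation switch seen downstream (control arm
null, knockdown arm positive) is produced solely by the class coupling —
with `coupling_shift = 0` both arms are null.

Default parameters were chosen once, by a power analysis of the
classification margin: with ~160 fragments in a −OHT window and two
replicates, the deviation score has sd ≈ 0.17–0.25, giving ≥ 95% planted
label recovery at τ = 0.5, the package's central parameter-recovery
property; recovery degrades monotonically as α grows (≈ 0.99 / 0.84 /
0.42 at α = 0.005 / 0.08 / 0.5). The genome is kept large relative to the
library so the per-window background (~1 fragment) cannot compress fold
changes at hybrid-poor sites, which would otherwise leak a spurious
positive correlation into the control arm.

RNase-H pre-treatment multiplies hybrid-derived signal by a residual
factor (default 0) without touching the random stream, so residual = 1
reproduces the untreated library byte-for-byte. With the default of no
site-local extra background, residual = 0 site windows contain only the
same uniform background as anywhere else and are exchangeable with random
genomic windows — the RNase-H control property holds by construction and
is verified by rank-sum.

What the generator does **not** emulate: mappability and GC structure,
copy-number variation, broader R-loop domains outside break windows,
fragment-level duplicates, or cut-efficiency heterogeneity between sites.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure under the stated noise model — not
robustness to every artefact of real sequencing data.

## qPCR quantifications

Percent input adjusts the input-well Ct for its dilution factor D
(`Ct' = Ct_input − log_eff(1/D)`, amplification efficiency fixed at 2 and
configurable) and reports `100 · eff^(Ct' − Ct_IP)`; it is invariant to a
common Ct shift of all wells. D has no default in the drivers' API
surface beyond the simulated plates' 0.1 — it is a property of the
bench protocol and must be supplied. Damaged/undamaged fold changes are
per-replicate ratios aggregated as arithmetic mean ± SEM with a paired t
on the per-replicate percent-input values; RNase-H wells form a separate
control channel expected near 1. The resection assay uses
`ssDNA% = 100/(2^(ΔCt−1) + 0.5)` on digested-minus-undigested Ct, the
standard quantification for restriction-protection resection assays at
sequence-defined breaks; ΔCt < −0.5 is flagged assay-inconsistent but
still reported. Simulated plates invert these formulas exactly, so
noise-free recovery is exact by construction and is tested as such.

## Proteomic meta-analysis

Protein identifiers are opaque strings uppercased on ingest; no
cross-database mapping is attempted, since harmonisation rules are
dataset-specific — that is the caller's responsibility and the main
practical caveat of the module. Frequency counts distinct studies, not
occurrences. Candidate ordering is deterministic (count descending, then
identifier), Venn regions are exact set algebra (conservation against the
union is asserted), and the nominated-candidate query returns the
top-ranked protein carrying one flag (hybrid interactor) and not another
(known repair factor). The SQ scanner counts S→Q (optionally T→Q)
dipeptides over the 20-letter alphabet and is generic rather than bound
to any particular peptide; the generator plants one candidate
phospho-peptide carrying exactly two SQ motifs, identical across the
three phospho studies.

## Numerical and interface choices

* bedGraph output merges equal-value runs, writes zero runs so that
  write → read is an exact identity, and formats floats as their shortest
  round-trip decimal.
* Depth blocks and window sums use int64 breakpoints with cached
  cumulative sums; window means divide by the clipped width actually
  used.
* Exact rank-sum enumeration is capped at pooled n = 12 (C(12,6) = 924
  assignments) as a fidelity/runtime balance.
* Seeds: every generator derives independent streams from a single
  integer seed via `SeedSequence`; the RNase-H scale deliberately does
  not enter the stream derivation (see above).
* Problem sizes in the test and acceptance batteries (99 sites, 400k
  fragments, 50 Monte-Carlo seeds, 10,000 null simulations) are the
  package's desk-scale study conditions; they keep a full run in the
  minutes range on one core.

## Known limitations

* The window W, metagene span/bin and pseudocount are field-conventional
  defaults, not values with an external ground truth; conclusions that
  hinge on them should be checked across a range (classification is
  robust to ε over the tested range — property-tested).
* The rank-sum normal approximation is only guaranteed to 0.02 against
  the exact null for per-group sizes ≥ 3 without ties.
* Percent-input assumes perfect doubling per cycle unless an efficiency
  is supplied; no standard-curve estimation is provided.
* The transcription-activity covariate is treated as supplied metadata;
  the package does not derive it from expression data.
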