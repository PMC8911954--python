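# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic data does and does not emulate, and the judgement calls
made where the design was genuinely open. Nothing here states an empirical
result that the tests or `scripts/acceptance.py` do not themselves compute.

## The synthetic instrument

Runs are emitted as time-ordered centroid scans on a 63-minute grid at
2.5 spectra/s (9450 scans), mass range 30–400 Th — the acquisition geometry
of a GC-QTOF volatile-profiling method. Each planted compound contributes
one chromatographic peak per fragment ion, co-apexed at the compound's
retention time; fragment areas split the compound area in proportion to
relative intensity.

Peak model: Gaussian with `peak_sigma` = 2.5 s, switching to an
exponentially-modified Gaussian when `tailing_tau` > 0 (default 0). Noise
model defaults, chosen so a well-behaved instrument's validation envelope
(area %RSD < 20, RT %RSD < 0.5, MF %RSD < 2, r > 0.99, < 5 ppm) is
achievable end to end:

| parameter | default | unit | meaning |
|---|---|---|---|
| `area_cv` | 0.08 | fraction | per-compound, per-run multiplicative area scatter |
| `rt_jitter_sd` | 1.5 | s | per-compound, per-run retention shift |
| `mass_error_sd` | 1.5 | ppm | per-centroid-point m/z perturbation |
| `baseline_level` / `baseline_sd` | 100 / 20 | counts | positive additive baseline |
| `peak_window_s` | 25 | s | extent of emitted centroid points around each apex |
| `saturation_counts` | off | counts | optional intensity clipping (ion saturation) |

Baseline points are emitted only inside the peak window: real centroiding
discards near-zero points, so scans far from any signal are empty. Same-scan
points closer than 10 ppm are merged into one centroid, mirroring the
instrument's inability to resolve them (and the pipeline's ±10 ppm
extraction window).

**Fragment spectra are invented.** Each compound draws 4–8 sub-formula
masses of its molecular formula (the doubled formula for very small
molecules, giving cluster-ion-like masses); intensities are uniform draws
with one base peak at 100. Spectra are deterministic in the seed. They are
plausible in mass arithmetic but not in fragmentation physics; passing tests
therefore validate the *processing chain* — trace building, peak metrics,
scoring, alignment, statistics — not EI chemistry, and say nothing about
real-library match quality.

**Retention design.** The canonical alkane ladder maps C8→320 s and
C40→3680 s linearly; planted compounds are placed by inverting the linear
RI formula on this ladder, so RI recovery is exact in the noiseless limit.
Two generator rules keep the *study-design* scenarios orthogonal to
resolution questions: catalog retention indices are spaced at least 7.5 RI
units (~8 s) apart, and entries eluting within 30 s of each other never
share a fragment mass to within 20 ppm. Distinct compounds that co-elute
*and* are isobaric to ppm accuracy are a resolution stress case, exercised
by dedicated collision/drift tests instead. p-Cymene, which is both a
validation standard and a wine volatile, carries one spectrum everywhere,
and spiked-pool (PWS) areas add the spike to the pool for shared compounds.

**Study design.** 2 vineyards × 2 vintages × 3 replicates; a pooled-wine QC
(every compound present anywhere, at its mean across present groups) in
triplicate; PWS = pool + the four standards at level-4 concentration;
standards at 1.56–25 ng/L (pinenes) and 0.31–5 ng/L (p-cymene,
2-undecanone) on 1:1 dilution steps: five levels in triplicate on day 1,
levels 1/3/5 in triplicate on day 2, and four further L1 injections on day
3 so that ten L1 injections span three days. Response slope: 1.65×10⁵ area
counts per ng/L — no instrument-specific response factor is available, so
one arbitrary-but-fixed slope keeps the LOD/LOQ arithmetic verifiable; it
is configuration, not a measurement.

## Deconvolution

Scan-to-scan greedy chaining links each centroid to the nearest open trace
within ±10 ppm of its intensity-weighted centre; a second in-window point in
the same scan merges rather than opening a duplicate trace; traces idle for
more than 25 scans (10 s) close, which keeps the noise estimate of a
recurring fragment m/z local to its chromatographic neighbourhood.

Per trace, baseline and noise are the median and 1.4826×MAD of the whole
trace — robust while peaks occupy under half the points, unbiased on pure
baseline. Peak candidates need prominence ≥ `snr_min`×noise (suppressing
sub-peaks carved out of a flank by baseline noise) and height ≥
`snr_min`×noise above baseline. Integration bounds run to the first
crossing of baseline+noise or, failing that, the minimum towards the
neighbouring apex; areas are trapezoidal on the baseline-subtracted trace.
The apex is the intensity-weighted centroid of the upper half of the peak —
stable to a fraction of a scan, where the raw argmax wanders ±2 scans on a
flat Gaussian top under baseline noise.

Grouping seeds on the tallest unassigned peak and admits peaks within the
co-elution window whose shape score (100×max(0, Pearson r) against the
seed's shape on the seed's time grid) clears the threshold. Two vendor
parameters have no public definition and are mapped to explicit
configuration: the "RT window factor 300" becomes `coelute_window_s` = 1.2 s
(3 scans at 2.5 Hz), and the "25% component shape threshold" becomes
`shape_min` = 25 on the 0–100 scale (the alternative reading, max 25% shape
deviation ⇒ r ≥ 0.75, is a matter of passing `shape_min=75`). Components
keep 4–10 ions; spectra use ion *areas* (areas are what validation %RSD is
computed on), and no area/height floor is applied beyond the SNR gate so
minor compounds survive.

## Retention index

Linear (van den Dool & Kratz) indexing, appropriate for a
temperature-programmed oven; Kovats logarithmic indexing is out of scope.
Outside the ladder the terminal segment extrapolates linearly and the value
is flagged rather than raised — reference RIs live well inside C8–C40, but
synthetic edge cases should not crash. Calibrating on a deconvolved alkane
run assigns carbon numbers to the 33 components in elution order.

## Identification

Match factor: peaks aligned greedily one-to-one by m/z within 10 ppm;
weights `w = √intensity × m/z`; MF = 100 × (Σ matched w·w)² / (Σw²·Σw²).
The vendor's formula is unpublished; this NIST-style weighted cosine
reproduces the expected behaviour (self-match 100, disjoint 0, >80 on clean
rediscovery). The accurate-mass gate takes the maximum |ppm| over aligned
fragments at ≥ 30 m/z — aligned within a 40 ppm window so that a 20–40 ppm
discrepancy is measured and rejected rather than treated as two different
fragments — and fails when nothing aligns.

The RT penalty is trapezoidal with half-widths 12 s (penalty-free) and 18 s
(full exclusion): "greater than 12 s" triggers the penalty, consistent with
a |ΔRT| ≤ 12 s free band. It multiplies the MF (keeping the 0–100 scale and
the MF ≥ 70 floor meaningful); a subtractive variant is available via
`penalty_mode`. The ΔRI < 30 gate applies only when both sides carry an RI.
Ties break by penalized MF, then ΔRI, ΔRT, name.

Identification levels: 1 only for components matching a spiked authentic
standard with retention evidence; otherwise the library entry's level
(named entries 2, class-level or RI-less entries 3); Unknowns are level 4,
named `Unknown <RT>` with RT in minutes to 4 decimals, and carry the
base-peak exact mass plus formula candidates from an exhaustive search over
C≤30 H≤60 N≤3 O≤6 S≤1 Cl≤2 F≤3 with RDBE ≥ 0, ranked by |ppm|.

## Recursive pipeline

The internal library keeps an entry only when its compound appears in
*every* QC injection (hits keyed by name; unknowns matched across
injections by spectrum ≥ 70 MF and a 12 s RT window), with the observed
mean RT/RI. Fiber/column artifacts are removed by a configurable name
blacklist (siloxanes etc.). Sample components then pass: (1) internal
library with the RT trapezoid; (2) external libraries, RT-free — hits and
new Unknowns are appended with their observed RT/RI. An external re-hit
whose name already exists in the library (i.e., the trapezoid rejected the
internal entry) becomes its own entity with an `@RT` suffix — a drifted or
second elution is real information, not a silent merge. A final back-fill
pass re-aligns every run against the augmented library, making the outcome
order-independent and the procedure idempotent.

The 3-replicate rule operates per wine group: present iff detected in all
three replicate injections, abundance = arithmetic mean (chosen over the
median for n = 3 stability); QC entries require presence in all QC
injections of the batch. Relative abundance is 100 × abundance / column
maximum.

## Validation and QC statistics

%RSD = 100 × sample SD / mean (n ≥ 2, non-zero mean). Repeatability:
per-standard, per-level %RSD of the day-1 triplicates. Reproducibility:
day-1 and day-2 injections pooled at the levels repeated on day 2 — the
two-day design does not fix the pooling; matching-level pooling is this
package's reading. Linearity: Pearson r of concentration vs mean day-1 area
(reported as |r| with a direction check). LOD/LOQ: 3.3σ/m and 10σ/m with σ
the SD of the ten L1 areas and m the day-1 response slope — the σ/slope
convention is the standard reading where the source workflow delegates to
vendor software. Carryover passes when blank signal < 20% of LOQ, boundary
excluded. Mass accuracy is checked on the five most abundant fragments of
each standard per injection.

The QC diagnostic runs the covariance PCA on the transformed table of all
runs and compares the RMS distance of QC injections about their centroid to
the RMS distance of all runs about the overall centroid, in the PC1–PC2
plane; a ratio below 0.5 grants the *high quality* flag. The ratio is
`None` (degenerate) when all runs coincide.

## Differential analysis

Presence/Venn logic always uses raw ND flags. The numeric matrix is log2
abundance with ND imputed as half the entity's smallest detected value
(minimum substitution), median-centred per entity across all samples — the
reading adopted for the vendor phrase "transformed with the median of the
baseline of all samples"; imputed values never feed presence logic. PCA is
an SVD of the centred samples×entities matrix (covariance method — no
variable scaling; correlation scaling available). Fold change is
max(a,b)/min(a,b) ≥ 1 with a direction against the baseline wine
(LaChanga2017; LaChanga2018 for entities ND there); entities ND in either
group report "-".

The moderated t-test fits the scaled-inverse-χ² variance prior (d₀, s₀²) by
matching moments of log s²_g — digamma/trigamma inversion via Newton — and
shrinks per-entity variances to s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g), with
t on d₀+d_g df; d₀→0 recovers the ordinary t-test, d₀→∞ pools one variance.
Significance requires BH-adjusted p < 0.05 *and* FC > 1.1. With fewer than
two entities, moderation is impossible and the ordinary t-test is used with
a warning. The two-way ANOVA is the classical balanced 2×2×r sums-of-squares
decomposition (unbalanced designs are rejected — the study design is
balanced by construction). Stars: * p<0.05, ** p<0.01, *** p<0.001,
two-sided.

## Scenario problem sizes

The canned scenarios are sized for a single CPU: the validation scenario
simulates 28 standards injections plus one alkane ladder (~5 s); the study
replay simulates 16 runs with the full 101-compound design (~20 s); the QC
drift scenario is generated directly in entity space (the raw-signal chain
is already exercised by the other two). Null-calibration checks of the
moderated t-test use 1000 repetitions × 200 entities.

## Known limitations

- Spectra, response slope and noise magnitudes are synthetic; conclusions
  transfer to the code paths, not to instrument performance.
- The alkane ladder is simulated like any other run; systematic RT offsets
  between liquid-injection calibration and headspace sample runs are not
  modelled.
- mzML input is read through pyteomics when installed, but no mzML writer
  is available here, so that path lacks a round-trip test; the columnar
  text dialect is the tested interchange format.
- The generator's minimum RI spacing means the scenarios never present two
  co-eluting isobaric compounds; the pipeline's behaviour there is covered
  only by the targeted collision/drift tests, and real chimeric spectra
  will degrade identification in ways these scenarios do not measure.
- Ion saturation is off by default; enabling `saturation_counts` clips
  intensities but no de-saturation logic exists (saturated peaks in real
  data are flagged by unidentifiable components, as in any MF-gated
  workflow).
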