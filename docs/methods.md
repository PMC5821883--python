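# Methods

## The measurement model

A chip run is 2,500 independent 20 nL PCR partitions. Loading a solution with
ΣN template molecules places each molecule in a uniformly random well, so the
per-well copy number m is multinomial with Poisson(λ = ΣN/2500) marginals.
A well with m ≥ 1 molecules amplifies; anchored at the single-copy
quantification cycle Cq₁ and per-cycle amplification efficiency E (fraction of
templates copied per cycle, 1.0 = perfect doubling), it crosses the detection
threshold at

    Cq(m) = Cq₁ − ln(m)/ln(1+E) + ε,    ε ~ Normal(0, σ_Cq).

This is the unique per-well model consistent with both the copy-conversion
relation copies = (1+E)^(Cq₁−Cq) and the per-cell relation A = 2^(Cq₁−Cq)
(which assumes E = 1). Wells with m = 0 stay negative; a configurable fraction
of wells fail (unfilled or bubbled — excluded from both k and n′); and
template-free chips develop a Poisson number of primer-dimer false positives
with a late, high-variance Cq signature.

Bulk (non-partitioned) reactions follow the same threshold model with one
physical correction: a 20 µL reaction must accumulate 1,000× the amplicons of
a 20 nL well to reach the same fluorophore concentration, so its threshold is
offset by ln(1000)/ln(1+E) ≈ 10.8 cycles. Without this, the model would
predict negative Cq at high template; with it, a simulated bulk dilution
series spans Cq ≈ 6–37 over nine decades, as a real instrument does.

## Estimators

- **Digital quantification**: λ̂ = −ln(1 − k/n′) and
  ΣN̂ = log(1 − k/n′)/log(1 − 1/n′), with n′ = n − fail − expected dimers.
  The expected dimer count comes from no-template controls (NTC); it always
  reduces n′, and subtraction from k is an explicit option (off by default —
  it is not identifiable per chip, and published per-level values match the
  unsubtracted form). k may be a replicate mean, so it is treated as real.
  The 95 % interval uses the delta-method variance var(λ̂) ≈ (e^λ − 1)/n′,
  standard digital-PCR practice.
- **One-copy certification**: chip-wide P(X ≤ 1) = e^(−λ)(1+λ) with
  λ = k/(n − fail). This cumulative convention reproduces the published
  per-level percentages (98.5 % at k = 454.5; 76.5 % at k = 2301); the
  singleton-given-positive convention λe^(−λ)/(1−e^(−λ)) is also provided
  because it answers the sharper question "is a positive well a true
  singleton". Both are reported.
- **Standard curve**: OLS of per-level mean Cq on log₁₀(concentration);
  E = 10^(−1/slope) − 1, stored as a fraction and reported as percent.
  The digital plateau is the maximal low-concentration suffix whose
  consecutive mean-Cq differences stay below a tolerance (default 0.5
  cycles) despite ≥ 2-fold concentration steps; a lone flat level is not
  evidence, so a strictly linear series yields an empty plateau.
- **Single-copy anchor**: pooled positive-well Cq over runs whose chip-wide
  one-copy probability is ≥ 0.95. Per-well pooling (default) weights levels
  by their well counts; per-level weighting (mean of level means) is provided
  because the two differ when digital levels have very unequal occupancy, and
  published per-level means do not disambiguate which was used upstream.
  Note the per-well anchor carries a small downward multiplet bias at the
  upper edge of the digital regime (doublets fire one ln2/ln(1+E) step
  early); at the 0.95 certification threshold the bias is ≲ 0.08 cycles.
- **Inhibition**: percent-of-control from Cq shift (bulk) or from the ratio
  of Poisson copy estimates (chips). The inhibitory efficiency decrement is
  E′ = (1+E)((N_apparent/N_true)^(1/Cq′) − 1), obtained by equating the
  inhibited and uninhibited threshold expressions. IC50 comes from nonlinear
  least squares of a 4-parameter log-logistic with top and bottom fixed at
  100 % and 0 % (percent-of-control is defined on that range; both can be
  freed). Zero-concentration points define the control and are excluded from
  the log abscissa. The paper's functional form is unstated; the log-logistic
  is the field's default for dose–response summaries.
- **Occupancy**: the chip size is fixed at n = 2,500, so the Poisson
  occupancy curves P₀, P₁, P₂₊ have no free parameter; the "fit" reports
  per-category R² of observed proportions against the theory at the nominal
  loads (unweighted, as the upstream analysis is unstated) plus the Poisson
  inversion estimate of each true load. `recommend_loading` returns the
  largest load meeting a target single-cell fraction — the fraction is
  monotone decreasing, so the boundary load is the throughput-optimal choice.
- **Expression**: per-well copies A = 2^(Cq₁−Cq) under the one-cell-per-well
  assumption; groups are summarised by geometric means (arithmetic mean in Cq
  space — an exact identity, tested) and log₁₀ histograms with
  Freedman–Diaconis bins. Distribution shape is screened with one-sample KS
  tests against normal/lognormal families with moments estimated from the
  data; this inflates type-I error (the Lilliefors effect), which is
  documented and mitigated by an optional parametric-bootstrap p-value.
  Differential expression uses the two-sample KS statistic on log copies
  (transform-invariant) with asymptotic p-values, Holm-corrected across the
  full family of pairwise comparisons in a report so the experiment-wide
  error rate is controlled; raw p-values are kept alongside.

## The synthetic-data generator

Defaults are the study conditions: 2,500 wells × 20 nL, Cq₁ = 26.20,
E = 0.8981 (slope −3.593 cycles/decade), NTC primer-dimer mean 1.67 wells per
chip at Cq 28.80 ± 5.08, heparin concentrations
{0.001, 0.01, 0.025, 0.05, 0.25} IU/mL final (stock/20), cell loads
500–16,000 over 2,500 wells, and EMT panels (E-cadherin, N-cadherin,
vimentin, GAPDH) across control/d1/d2/d4. Choices the source conditions do
not pin down, made once:

- **Per-well Cq noise σ_Cq = 0.4 cycles**, inside the 0.19–0.72 range of the
  published per-level SDs.
- **Effective template volume 1 µL per chip** (copies/chip = concentration ×
  1 µL), matching the two fully digital calibration levels; the published
  per-level copy yields are internally inconsistent (ratio to nominal 1.0–1.9
  across levels), so one value was fixed rather than per-level factors.
- **Primer dimers form only on template-free chips by default**
  (`dimer_template_max = 0`): published sample-level positive counts show no
  dimer excess over nominal while NTCs average 1.67, consistent with template
  amplification outcompeting dimer formation. The rate is configurable for
  chips where dimers and template coexist.
- **Heparin acts through two channels**: complete per-well inhibition with
  log-logistic probability in concentration (midpoint `ic50_complete` = 0.02
  IU/mL, Hill 1) and an efficiency decrement E′(c) = −0.05·log₁₀(1 + c/0.001)
  on surviving wells. Observed instrument behaviour shows both channels
  (wells disappearing, and surviving wells shifting late) without quantifying
  the split, so the split is a generator parameter. Partitioning tolerance
  emerges rather than being imposed: counting survives the efficiency channel
  entirely, while the bulk Cq shift compounds it exponentially.
- **EMT programs** are per-cell lognormal in log₁₀ copies (SD 0.45):
  N-cadherin location rises 0.8→1.2→1.6→2.0 through the time course,
  vimentin rises then falls (1.2→1.8→2.1→1.6), E-cadherin is flat at 1.5
  (the null gene), GAPDH flat at 2.5 (SD 0.35). Multi-cell wells sum
  independent per-cell draws and are flagged in the generator's truth record.

All randomness flows from a single numpy Generator passed explicitly; a fixed
seed reproduces a run byte-for-byte. Simulated runs carry a `truth` attribute
(per-well molecule counts, dimer/fail indices) that tests consult and the
analysis path never reads.

**What the generator does not emulate**, hence what passing tests do not
show about real data: per-cycle fluorescence curves and Cq-calling from them;
reverse-transcription and capture efficiency; cell-size or settling bias and
doublet dissociation; spatial structure on the chip (wells are exchangeable);
inhibitor chemistry beyond the two-channel heparin abstraction; and
between-day instrument drift.

## Numerical and design notes

- SDs are sample (n−1) throughout; CV = 100·sd/mean over positive-well Cq.
- Fail status takes precedence over any recorded Cq; a well with Cq above
  the 40-cycle protocol limit is negative. Endpoint fluorescence is carried
  in the data model but not used for calling (no threshold is defined for it).
- Saturated chips (k = n′) raise an explicit saturation error rather than
  returning infinity; the full-dynamic-range estimator switches from Poisson
  counting to Cq-anchored estimation above 95 % positive occupancy.
- `log1p`/`expm1` forms are used near λ → 0; total-copies equals
  λ/(−ln(1−1/n′)) exactly and tends to k as the chip empties.
- The IC50 fit optimises log₁₀(IC50) with bounds three decades beyond the
  data and seeds the search at the 50 % log-interpolation crossing; a points
  set spanning less than a 10-point percent-of-control range is rejected as
  having no transition.
- Grid indexing is 0-based over 50 × 50 with well ids "R{row}C{col}" when
  absent; CSV round-trips are exact (`float_precision="round_trip"`).

## Known limitations

- The cumulative one-copy convention and the per-well vs per-level anchor
  weighting are both exposed because upstream practice is ambiguous; results
  that depend on the choice should report which was used.
- The delta-method CI on total copies understates uncertainty when replicate
  means (non-integer k) hide between-replicate variance.
- The one-sample KS screen is anti-conservative with estimated moments unless
  the bootstrap p-value is requested.
- Simulation sizes in the test suite (e.g. 200 chips per recovery level, 100
  replicates for the partitioned-vs-bulk comparisons, 30 seeds for the EMT
  time course) were chosen to make sampling error comfortably smaller than
  the tested margins while keeping the suite quick to run.
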