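# Methods

This note records the statistical model behind `embryosync`, the estimator
choices that were genuinely open, the defaults and why they hold, and what
the synthetic-data validation does and does not establish.

## The measurement model

An embryo silhouette in a binarized plate image is reduced to the
moment-equivalent ellipse of its pixel set: with pixel centers at integer
coordinates and $C$ the population covariance matrix of those coordinates,
the axis lengths are $4\sqrt{\lambda_{1,2}}$ for the eigenvalues of $C$ and
the orientation is the principal eigenvector angle. For a solid ellipse of
semi-axes $a \ge b$ the coordinate variances are $a^2/4$ and $b^2/4$, so
the convention recovers the full major axis $2a$ exactly in the continuum
limit; it is also the definition behind the standard "fit ellipse"
measurement in common image-analysis software, which keeps lengths
comparable with interactively measured data. Embryo length is the major
axis times the mm-per-pixel calibration.

Numerical behaviour: measurements are rotation- and translation-invariant
to within rasterization error (< 2% for objects ≥ 50 px long, the regime
the default 0.02 mm/px calibration puts 1–5 mm embryos in); lengths scale
exactly linearly and areas exactly quadratically in the calibration; a
single pixel degenerates to zero-length axes by construction rather than
raising. Components are 8-connected (the common particle-analysis
default), components under `min_pixels` (default 16) are dropped as
rasterization debris, and touching embryos are *not* split — the synthetic
renderer places embryos without contact by default, and watershed-style
splitting is out of scope. Areas are pixel counts times the calibration
squared; no sub-pixel contouring.

## The synchronization statistics

Lengths are binned into half-open intervals $[k\delta, (k+1)\delta)$ from a
configurable origin (default 0 mm, matching the conventional 0–1, 1–2, …
mm intervals; the origin is configurable because coarse-bin widths are
origin-sensitive). The normalized distribution function
$\varphi(\bar q)$ is the counts divided by the maximum count, evaluated at
bin centers, interpolated linearly between centers, and taken as zero one
$\delta$ beyond each end. The width at fraction $f$ is the distance
between the *outermost* crossings of the level $f$ — outermost being the
conservative reading of "full width" should a curve be multimodal. Any
positive rescaling of the counts cancels from these widths, so the choice
of normalization constant is consequence-free (a property the test suite
asserts).

**Peak estimation.** The level crossed is $f \cdot \hat p$, where
$\hat p$ is an estimate of the curve maximum in units of the largest bin.
For coarse histograms (fewer than three bins within 90% of the maximum —
the usual case at $\delta$ of 0.5–1 mm) $\hat p = 1$, i.e. the raw
maximum. For finely binned data the raw maximum of many noisy bins is
biased upward, which narrows *every* fractional width systematically
(measured at $n = 10^5$, $\delta = 0.05\sigma$: −1.5% on the FWHM, −4.2%
at 75% of maximum); there $\hat p$ is the vertex of a least-squares
parabola through the near-peak bins, clipped to at most 1 so it can only
remove the upward bias. With this estimator the noise-free discretization
error is ≤ 0.06% and the stochastic bias ≤ 0.8% at all three reported
fractions, so the Gaussian closed form
$w_f = 2\sigma\sqrt{2\ln(1/f)}$ (FWHM $= 2.3548\,\sigma$) is recovered
within 2% in expectation at $n = 10^5$. A single draw at that $n$ still
carries ~2% crossing noise per width, which is why the convergence test
averages over independent samples.

The coefficient of variation uses the $n-1$ sample SD throughout. Its
confidence interval is McKay's $\chi^2$ approximation: with observed CV
$K$, $\nu = n - 1$, $u_1 = \chi^2_{1-\alpha/2,\nu}$ and
$u_2 = \chi^2_{\alpha/2,\nu}$, the limits are
$K / \sqrt{(u_i/\nu)(1 + K^2) - K^2}$ (lower limit from $u_1$). The
approximation is accurate for $K \lesssim 0.3$; a non-positive radicand
(huge $K$, tiny $n$) raises with the condition named. Default level 90%,
the level conventionally reported for these CVs.

Group comparison is Student's pooled-variance two-sample $t$ (the
classical default when only "independent two-sample t test" is specified);
Welch is available behind a flag. Exactly constant groups are handled
explicitly: equal means give $t = 0, p = 1$, unequal means are an error —
"constant" meaning variance below $10^{-12}\max(1, |\bar x|)$, since
identical floats can acquire round-off variance through the mean
subtraction. Yield per gram fresh weight extrapolates the harvested count
through the sampled area fraction: $\text{yield} = h / f_s / w_0$.
Germination outcomes are reported as integer percentages of embryos
collected. A Shapiro–Wilk normality check is attached to every fit as a
diagnostic warning only, never a gate.

## The synthetic-data model

The generator emulates the statistical structure such experiments report,
not their optics:

- **Lengths** are normal within replicate, truncated to $(0, \infty)$ by
  rejection (lengths are physically positive; at the reported means of
  2–3 mm and SDs of 0.4–1.3 mm the truncation is almost inactive — the
  closed-form truncated-normal moments from `scipy.stats.truncnorm` serve
  as the test oracle). Between-replicate variation is a normal mean shift
  per replicate, default SD 0 so single-population tests are exact.
- **Plate images** are binary silhouettes: filled ellipses with the major
  axis equal to the embryo length, aspect ratio drawn from a clipped
  normal (default 0.35 ± 0.05, the elongated shape of cotyledonary spruce
  embryos), uniform random orientation and position, placed without
  contact by rejection sampling (a candidate dilated by one pixel must not
  intersect placed tissue). No lighting, suspensors, or color — the
  morphometry consumes binary masks, so silhouettes are the sufficient
  fixture. Default calibration 0.02 mm/px puts a 1 mm embryo at 50 px,
  comfortably above rasterization-error territory.
- **Aggregate areas** are log-normal — a modeling choice; the source
  reports only a binned, right-skewed distribution — with the location
  parameter solved from one calibration quantile,
  $\mu = \ln t - \sigma\,\Phi^{-1}(p)$, e.g. 80% of aggregate areas at or
  below 0.2 mm². $\sigma$ stays a free shape parameter (default 1.0, a
  visibly right-skewed but not extreme spread). Default count 651 per
  sample, the reported per-sample average.
- **Germination** is a binomial chain,
  started $\sim B(\text{collected}, p_s)$ and
  rooted $\sim B(\text{started}, p_r)$, which enforces
  rooted ≤ started ≤ collected by construction.

One integer seed drives a whole study; `numpy.random.SeedSequence.spawn`
splits it per group and per stage (lengths / imaging / germination), so
toggling the image route does not perturb the sampled lengths.

Because every replicate draws exactly `n_embryos` lengths, per-replicate
*counts* (hence extrapolated yields) are constant within a synthetic
group; the pipeline records the resulting degenerate yield $t$-test as
absent with a note instead of failing. Count dispersion across bioreactors
is real in wet-lab data but is not part of this generator.

## Validation scale and what it shows

The default validation sizes mirror the study design the package targets:
~1000 pooled lengths per bioreactor treatment group (6 replicates), 200
rendered embryos of 1–5 mm for ground-truth recovery, $10^5$ draws for
distributional limits, and 200 seeded repetitions for ordering checks
(e.g. a 2.06 ± 0.42 mm group shows smaller widths and CV than a
2.47 ± 0.67 mm group in every one of 200 runs at that $n$). At
solid-medium scale (~390 vs ~230 lengths) the same ordering holds for the
CV and FWHM but the 66%/75% widths overlap in roughly one run in ten —
the fractional-maximum widths lose discriminating power on small, coarsely
binned samples, a genuine limitation to keep in mind when tabulating
them for plate-scale experiments.

Passing these tests shows the estimators are correct and well-calibrated
on data satisfying the generator's assumptions (normal lengths, clean
binary silhouettes, non-touching objects). It does not certify behaviour
on raw photographs — background tissue, touching embryos, uneven
illumination and manual trimming are all outside the model — nor the
biological claim that dispersion improves synchronization, which is a
property of cultures, not of this software.

## Interfaces

Length tables are CSV (`replicate,treatment,length_mm`), measurements CSV
(`id,area_mm2,major_mm,minor_mm,cx_px,cy_px,theta_rad`), ground truth CSV
(`id,cx_px,cy_px,theta_rad,major_mm,area_mm2`); images 8-bit PNG/TIFF,
background 0 / foreground 255; studies one YAML document. A run writes
`table1_lengths_cv.csv` (lengths and CVs), `table2_widths.csv`
(per-replicate width summaries), `table3_germination.csv`, a sorted-key
`summary.json` (byte-identical across reruns of the same seeded config; a
provenance block carries the config hash, seed and version), and `run.log`
with stage timings. Report rounding follows the field's display
conventions: two decimals for lengths and CVs, integer percent for
germination. The `embryosync` CLI exposes the generator (`synth`), the
morphometry (`measure`), single-sample analysis (`analyze`), full studies
(`run`) and report printing (`report`) as thin wrappers over the library.
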