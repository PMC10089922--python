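# Methods

`fretkit` implements burst-wise analysis of diffusion-based single-molecule
FRET measurements with alternating excitation, together with a synthetic
photon-stream generator that provides ground truth for every estimator in
the package.  This note records the models, the parameters that matter, the
numerical choices, and the known limitations.

## Photon streams and excitation alternation

Photons carry integer macrotimes (default 12.5 ns clock ticks), a detector
id mapped to a spectral band (and optionally polarization), and — for
pulsed excitation — a TCSPC microtime.  Alternation is config-driven:
microsecond windows on the macrotime axis (µs-ALEX) or windows on the
microtime axis (PIE/ns-ALEX).  Photons outside all windows are flagged and
excluded from the three intensity channels I_Dem|Dex, I_Aem|Dex, I_Aem|Aex;
donor-band photons during acceptor excitation are retained but unused by
the intensity formulas.

## The simulator

The generator emulates freely diffusing labeled molecules: bursts with
lognormal durations (default 1.7 ± 0.9 ms) and lognormal molecular
brightness (default 60 ± 20 kHz detected), constant intensity within a
burst, exponential gaps between events (default 150 ms, i.e. ~6 events/s —
dilute conditions under which two-molecule coincidence is negligible), a
70/20/10 mixture of double-labeled, donor-only and acceptor-only species,
and Poisson background per channel (default 1.0/0.8 kHz donor/acceptor).
Burst envelopes rather than diffusion trajectories are simulated because
every estimator in the package consumes burst statistics; an explicit
diffusion model would add parameters without changing any tested quantity.

Photon colors follow the full photophysics: per donor-excitation event the
molecule transfers with probability E, the acceptor photon is detected with
efficiency g_A φ_A, the donor photon with g_D φ_D, a detected donor photon
is routed to the acceptor channel with probability p_ct (dichroic leakage),
and the acceptor is directly excited at a rate d·Λ relative to the donor.
The implied correction factors are therefore exact:

- α = p_ct/(1 − p_ct)
- γ = g_A φ_A / (g_D φ_D (1 − p_ct)) — the (1 − p_ct) appears because
  crosstalk removes photons from the donor channel
- β = excitation-flux ratio × duty-cycle ratio
- δ = d/β

Defaults reproduce the benchmark calibration values α = 0.05, β = 1.6,
γ = 0.40, δ = 0.12 (φ_D = 0.72, φ_A = 0.32, g_A/g_D = 6/7, excitation
ratio 1.6).  Multi-state molecules follow a continuous-time Markov chain
with stationary initialization; donor microtimes are exponential with
τ = τ_D(0)(1 − E) convolved with a Gaussian IRF (2.0 ± 0.25 ns); acceptor
microtimes are single-exponential (1.5 ns).  The excitation model is a
hybrid: alternation acts on macrotimes while every photon also carries a
microtime, so intensity- and lifetime-based analyses run on one stream.

Two kinds of Gaussian distance broadening are distinguished, because they
have different observable consequences:

- `sigma_linker` — *fast* dye-linker fluctuations, redrawn per excitation.
  They make burst-averaged efficiencies species averages and donor decays
  multi-exponential; this is what curves the static FRET line.
- `sigma_static` — *slow* conformational heterogeneity, redrawn per burst.
  It broadens windowed E histograms (the PDA broadening) and moves
  molecules along the static line.

What the generator does not emulate: diffusion-path brightness profiles,
detector dead time and afterpulsing, spectral fluctuations of the dyes, and
acceptor photoisomerization.  Passing recovery tests therefore demonstrate
estimator correctness under the stated statistical model, not robustness
to every instrumental artifact of real data.

## Background, burst search, selection

Background rates per channel come from the exponential tail of the
inter-photon delay distribution (delays above an iteratively chosen
threshold are background-dominated; truncated-exponential MLE).  Burst
search is the all-photon sliding-window criterion (m = 10 photons, rate
threshold F = 6 × total background, minimum 30 photons).  Two estimator
artifacts required care:

- *Edge padding*: marked windows extend up to m photons past the dense
  region, and the background photons swept in arrived, by selection,
  faster than the average rate; the per-burst duration × rate subtraction
  under-corrects them.  Burst edges are therefore trimmed while the
  outermost inter-photon delay exceeds half the dense-window mean delay.
- *Species selection*: donor-only (S > 0.8), acceptor-only (S < 0.2) and
  FRET-pair (0.25 ≤ S ≤ 0.75, ≥ 10 Aex photons) gates operate on the
  background-corrected stoichiometry.

## Correction factors and accurate E/S

α and δ come from the donor-only and acceptor-only population centers,
β and γ from the linear regression of 1/S against the α/δ-corrected
proximity ratio across two or more FRET populations (intercept
Ω = 1 + βγ, slope Σ = β(1 − γ)).  Population centers are *subensemble*
(pooled-count) ratios over sigma-clipped burst sets rather than Gaussian
means of per-burst ratios: per-burst ratio estimators carry a
shot-noise (Jensen) bias of order 1/N that exceeds the package's recovery
tolerances at realistic burst sizes, while the pooled ratio is unbiased
and the sigma-clipping supplies the same outlier resistance a Gaussian fit
would.  Gaussian fits (unbinned ML mixtures) remain the reporting
convention for histogram means.  The lifetime route for γ (forcing a
static population onto the static FRET line) is implemented and exact in
the population center, but is advisory: it requires a static sample.

The γ-driven efficiency uncertainty is ΔE = E(1 − E)Δγ/γ with the
study-level default Δγ/γ = 0.23.

## Dynamics

**BVA** splits each burst's Dex photons into consecutive non-overlapping
5-photon windows; the burst statistic is the window-SD of the acceptor
fraction.  The population center is a sigma-clipped 2D mean computed in
the *variance* domain (per-burst SDs are biased low at few windows; the
variance is not), and ds_BVA is its excess over the shot-noise semicircle
sqrt(E(1−E)/n).

**E–τ**: per-burst donor lifetimes are single-exponential MLEs with a flat
background term on a tail window (start 2.75 ns ≈ IRF mean + 3σ).  The
static FRET line with linker broadening is computed by Gauss–Legendre
quadrature over a Gaussian distance distribution (σ = 6 Å): intensity
E is the species average, the lifetime axis is the donor-photon-weighted
⟨τ⟩_F = ⟨τ²⟩/⟨τ⟩; a least-squares cubic provides fast evaluation, the
quadrature curve is the source of truth.  ds_Eτ is the vertical offset of
the sigma-clipped population center from the line (a convention chosen for
dimensional consistency with ds_BVA).  The fluctuation amplitude δR
inverts the equal-occupancy two-state model (distances R ± δR) by
bisection; the forward map is strictly monotone.

**Dynamic PDA** uses the exact two-state occupancy-time distribution over
a window (atoms for transition-free windows plus the renewal-series
bridge, truncated at 1e−10 after the term peak near the mean transition
count), Gauss–Hermite quadrature for the quasi-static distance broadening,
binomial photon statistics on the empirical total-count distribution, and
Poisson background convolution.  Windows are chopped from searched bursts
with a fill criterion (count ≥ 0.85 × burst rate × window): edge windows
mix background-only stretches into the histogram and masquerade as
dynamics; selection on the total count alone is unbiased because the count
distribution enters the model empirically.  The global fit (0.5/1/1.5/2 ms
windows, shared rates and states, Pearson residuals) reports the
relaxation time 1/(k₁₂ + k₂₁).  With 10 ms exchange probed by ≤ 2 ms
windows the likelihood is intrinsically shallow — the benchmark therefore
reports the median over a few independently simulated measurements.
(State parameters may also be held at structurally known values via
``fixed_params``, as a global analysis with external information would.)

**Filtered FCS** builds reference patterns over (channel × microtime bin)
from subensembles selected at the lower and upper edges of the burst E
histogram, solves the statistical filters from the weighted unbiasedness
condition, and computes species auto-/cross-correlations by direct
weighted photon-pair counting on a quasi-logarithmic lag grid (numba).
For kinetics the fitted model is

    G_s(τ) = a_c·E(τ) + [Σ_i A_ci exp(−τ/t_i)]·(1 + E(τ)/κ),

where E(τ) is the *measured total* autocorrelation serving as a
data-driven transit envelope and κ its background dilution
(signal/(signal+background))², measured, not fitted.  This form follows
from the exact factorization of presence × state correlations when the
total detected brightness is state-independent; the more familiar
"divide by the total curve" shortcut distorts recovered times because the
kinetic factor multiplies (1 + G_P), not G_P.  Imperfect (mixed) reference
patterns change only the amplitudes, never the shared relaxation times.

**MEM** inverts tail-region donor decays into distance distributions on an
R grid via maximize entropy relative to a prior subject to χ²_red = 1
(discrepancy principle, bisection over the entropy weight with annealed
warm starts; softmax parameterization with analytic gradients and an
analytically profiled amplitude).  When the target is unreachable (e.g.
photon counts beyond the grid's representational accuracy) the closest
solution is returned flagged.

## Dye clouds and distances

Accessible volumes are computed on a deterministic grid (default 0.9 Å,
tests use 0.5 Å): a position is allowed when the dye sphere clears all
heavy atoms (vdW + dye radius) and the shortest obstacle-avoiding path
from the attachment atom is within the linker length.  Geodesics use
label-correcting relaxation over the radius-2 primitive-vector
neighbourhood (98 directions, midpoint checks against tunneling), keeping
the lattice-metric overestimate below ~2%; the practical consequence is a
~2% rim trim of the cloud.  AV3 unions three single-radius volumes with
equal weights.  The ACV reweights the ≤3 Å surface shell to a contact
fraction, which by default maps from residual anisotropy as
f = r_∞/r₀ (r₀ = 0.38) — the simplest monotone relation consistent with
using anisotropy to gauge sticking.  Pair sums for ⟨E⟩ are exact to
4×10⁶ pairs and weight-proportionally subsampled beyond, with reported
standard error.

## Anisotropy and the κ² filter

Anisotropy decays r(t) = (I∥ − G·I⊥)/(I∥ + 2G·I⊥) are fitted with
nonnegative amplitudes and plateau.  The κ²-related distance uncertainty
uses a calibrated two-population surrogate: fractions f_i = r_∞,i/r₀ of
each dye are orientationally frozen and the doubly-frozen pair fraction
(r_c,∞/r₀)² carries a frozen-pair κ²_t ≈ 1.855 chosen so that
ΔR_app = 10% corresponds exactly to r_c,∞ = 0.25; a wobbling-in-a-cone
variant is calibrated to the same point.  The two surrogates agree within
a factor of two over the operating range of the filter (r_c,∞ ≈ 0.15–0.3)
and both vanish for free dyes; their leading orders at small r_∞ differ
(quadratic vs linear), which is inherent to the two pictures.  The
dye-artifact filter flags r_c,∞ ≥ 0.25 or ΔR_app ≥ 10% (boundaries
inclusive).

## Benchmark scenarios and problem sizes

- Correction recovery: two static populations (E = 0.3, 0.7) of 10⁴
  bursts each with the consensus dye physics; tolerances α ± 0.005,
  δ ± 0.01, γ ± 0.02, β ± 0.08, E ± 0.01.
- Filtered FCS: a three-state chain whose rate sums are solved so the
  eigen-relaxation times are exactly 9 µs and 300 µs (E = 0.55/0.90
  fast pair, 0.85 compact; 35% compact occupancy); long transits
  (5 ± 2 ms, large observation volume), ns alternation, ≥ 60 s per
  measurement; the benchmark reports the median over five simulated
  measurements.
- Dynamic PDA: detached ensemble (R = 60 Å, σ_static = 8 Å) exchanging
  with a compact state (R = 45 Å, σ_static = 6 Å) at relaxation 10 ms and
  25% compact occupancy; 2×10⁴ bursts per measurement, ideal dye physics,
  very dilute arrivals; median over three simulated measurements.

## Known limitations

- The burst search assumes Poisson background; correlated background
  (room light flicker, afterpulsing) would bias the delay-tail estimate.
- Per-burst lifetime fitting needs ≥ 20 donor photons, which preferentially
  drops high-E bursts; population centers in the E–τ plane are computed
  over the surviving subset, and for dynamic samples the center travels
  along the dynamic line accordingly.
- The dynamic-PDA relaxation time is weakly identified when the exchange
  is five times slower than the longest window; single-measurement
  estimates scatter by tens of percent, which matches the precision the
  windowed-histogram method can offer at these conditions.
- MEM distance distributions are limited by the R-grid resolution at very
  high photon counts (the χ² = 1 target becomes unreachable and is
  flagged).
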