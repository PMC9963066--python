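# Methods

This note documents the models implemented in fretscape, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Burst analysis

Bursts are found with an all-photon interphoton-gap criterion: a gap larger
than `max_gap` (default 100 µs) splits clusters, and a cluster is kept when
it contains at least `threshold` donor-excitation photons (default 50).
This is standard confocal practice; both knobs are exposed because real
instruments vary.  All correction constants default to neutral values
(γ = 1, zero background/crosstalk/direct excitation) so that uncorrected
counts pass through unchanged; instrument values are supplied through
`FretSetup`.

The corrected efficiency is E = n_A′/(n_A′ + γ n_D′) with

    n_D′ = n_D − b_D·Δt,
    n_A′ = n_A − b_A·Δt − α·n_D′ − δ·n_AA,

(b background rates, α crosstalk, δ direct excitation, Δt burst duration).
Reported E is clipped to [−0.1, 1.1]: background over-subtraction can push
single-burst estimates slightly outside [0, 1], and the margins keep those
bursts in the histogram rather than silently discarding them.  Histograms
default to 50 bins over that range.  Stoichiometry filtering retains
S ∈ [0.3, 0.7], which removes donor-only (S ≈ 1) and acceptor-only
(S ≈ 0) molecules under pulsed interleaved excitation.

Burst variance analysis slices each burst's donor-excitation photons into
windows of 5 photons (configurable), and compares the standard deviation of
window efficiencies with the binomial expectation √(Ē(1−Ē)/window).  The
per-burst envelope uses a χ² quantile on the window variance; static
populations should fall inside it at the nominal rate, and conformational
exchange on the burst timescale inflates the spread beyond it.

## Histogram decomposition

Population fractions come from a K-component Gaussian-peak fit to the
binned efficiencies, maximised via Pearson residuals (Poisson bin counts).
Each peak's width is √(σ_shot² + σ_excess²) where σ_shot = √(E(1−E)/n̄) at
the mean burst size n̄ (default 80): a static state cannot be narrower than
shot noise, so the floor is enforced by construction and only the excess
width is free.  Fractions are amplitude ratios with the first amplitude
pinned (the overall scale is not a degree of freedom); their standard
errors come from the amplitude covariance by the delta method.  Components
are reported sorted by ascending mean E, which makes output ordering
deterministic.  Fits with vanishing fractions or component means closer
than one peak width are flagged as degenerate rather than rejected.
Condition-linked fits (shared peak positions across, e.g., denaturant
conditions, free fractions per condition) are available through
`fit_mixture_shared`; the drifting mean efficiency of unfolded populations
with denaturant is handled there, not in the thermodynamic model.

## Distance models

The Förster relation E = 1/(1+(r/R₀)⁶) uses R₀ = 5.4 nm by default, the
value appropriate for the Alexa 488/594 pair; it is a `FretSetup` field.
Internally all lengths are nm; PDB coordinates are converted from Å at the
boundary.  Distances are label-site distances: no accessible-volume dye
cloud is modelled, and the only linker correction available is a fixed
scalar offset added to r (default 0).

The worm-like chain uses the Thirumalai–Ha closed-form radial density

    P(r) ∝ r² (1−(r/l_c)²)^(−9/2) · exp(−3l_c / (4l_p(1−(r/l_c)²))),

with finite support at the contour length and the Gaussian-chain limit at
l_c ≫ l_p.  Measured accuracy at the stiffness of interest
(l_p/l_c ≈ 0.2–0.4): the density reproduces the exact WLC mean-square
end-to-end distance 2·l_p·l_c·[1−(l_p/l_c)(1−e^(−l_c/l_p))] to better than
1% (tests assert 2%), and its quadrature ⟨E⟩ agrees with an exact discrete-
chain Monte Carlo to within 0.01.  A known consequence: for
(l_p, l_c) = (2.5, 7.7) nm and R₀ = 5.4 nm the bare quadrature gives
⟨E⟩ = 0.57 (exact chain: 0.58), noticeably below measured values near 0.61
reported for populations fitted with these parameters in lifetime-plane
analyses that include dye-linker modelling.  Reproducing such values
requires the full instrument-level fit, which is out of scope here; the
package reports the bare distribution average and documents the gap rather
than adjusting the density.

Mean efficiencies and Var(E) use adaptive quadrature (absolute tolerance
10⁻¹², error estimates above 10⁻⁶ raise with a tolerance report); dense
Riemann sums serve as the cross-check in the test suite (10⁻⁴).  The
contour length of a disordered segment is 0.38 nm per residue, the common
polypeptide convention.

Lifetime-plane geometry: rigid distances satisfy τ̄/τ₀ = 1−E; any
distribution lies above the line by Var(E)/(1−⟨E⟩) (Cauchy–Schwarz), which
is the rigid-vs-dynamic diagnostic.  The computation degenerates as
⟨E⟩ → 1 and raises there.

Distance fits solve one parameter per observable: rigid and Gaussian-chain
families in closed form or by 1-D root bracketing; a WLC with one of
(l_p, l_c) fixed likewise; both WLC parameters free requires the lifetime
observable as a second constraint and is solved by least squares — a
one-observable two-parameter request raises instead of silently picking a
solution.

## Titration thermodynamics

The sign convention is ΔG⁰_s = G_s − G_U at zero denaturant, so stable
folded states are negative and destabilising m-values are positive;
midpoints are −ΔG⁰/m.  The reference state is chosen canonically as the
state most populated at the highest measured concentration (the
unfolded-like state), which makes fits invariant under renaming or
reordering of states; it can be overridden.

The default objective is weighted least squares on the observed fractions
of the *non-reference* states.  Because per-condition fractions are
normalized to one, the reference state's residual row is a linear
combination of the others; including it double-counts information and
demonstrably shrinks the covariance (coverage of 95% intervals drops to
~75% in simulation; excluding it restores 93–95%).  A multinomial-deviance
objective with a configurable effective count is available as an option.
Parameter covariance is (JᵀJ)⁻¹·s² at the optimum; bootstrap percentile
intervals (default 1000 resamples, seeded) resample per-point Gaussian
noise around the fitted curves.  Diagnostics flag (a) intermediates whose
fitted occupancy never exceeds 10% (weakly identified) and (b) strong lag-1
autocorrelation of per-state residual profiles along the concentration axis,
the signature of fitting too few states.

The free-energy difference between two populations observed at one
condition is the log-ratio ΔG = −ln(p_b/p_a); for a 60/40 split this is
0.41 RT.  Values near 1 RT quoted for such splits in the literature
typically derive from a fitted zero-denaturant extrapolation rather than
the raw log-ratio; the package exposes the log-ratio and the titration-fit
route separately and does not reconcile them.

## Photon simulation from Markov models

The state path advances by one transition-matrix step every
τ_lag × rescale of experiment time; the default rescale of 225 maps 10-ns
lag kinetics onto the microsecond–millisecond burst window and is exposed
as configuration.  Bursts have fixed duration (default 1 ms) at constant
photon rate (default 100 kHz) — a diffusion transit-time distribution is a
possible extension, but fixed-duration bursts already reproduce the two
features the comparison needs, shot noise and kinetic averaging.  Each
donor-excitation photon is an acceptor photon with the current state's E;
crosstalk, direct excitation and Poisson background are applied at
detection.  The γ imbalance is analysis-side only and not simulated.
Acceptor-excitation photons are interleaved at parity with donor-excitation
ones so double-labelled molecules sit at S ≈ 0.5.

Seeding: one master seed; each burst draws from an independent substream
derived via `SeedSequence(seed, spawn_key=(burst,))`, so enlarging a
dataset never reshuffles earlier bursts.

The MSM estimator counts transitions at a lag, symmetrises (C + Cᵀ)/2 and
row-normalises — detailed balance holds by construction with respect to the
resulting stationary vector (computed by power iteration).  Never-visited
states are dropped with a warning; a disconnected transition graph warns of
non-unique stationary distributions.  Histogram comparison is the per-bin
L1 distance of normalized histograms (0 = identical, 2 = disjoint),
requiring identical binning.

## Contact analytics

Residue centres of mass are computed over heavy atoms (hydrogens excluded)
with standard element masses.  Two residues are in contact when their COMs
are strictly closer than 3 Å and |j−i| ≥ 6 in residue numbering — the
boundary case of exactly six residues apart counts, and both choices
(heavy-atom COM; inclusive separation) are deliberate readings of the usual
definition, exposed as `ContactDefinition`.  The KD-tree search is asserted
identical to the O(n²) scan.  Persistent contacts use weighted frame
occurrence; frame weights default to uniform and should be the Markov
model's stationary populations when frames derive from one.
Subpopulation boxes must be non-overlapping at construction; assignment
labels every frame (or "unassigned") so label weights always partition the
total.  Correlation maps are weighted 2-D histograms normalized to unit
mass, whose marginals equal the 1-D histograms exactly.

## Synthetic data: what it does and does not emulate

The generators emulate multi-population burst ensembles with shot noise,
donor-only contamination and stoichiometry structure; denaturant-dependent
fractions with truncated-Gaussian noise (truncation at [0, 1] plus
renormalization biases fractions near the simplex boundary slightly inward
— documented, not corrected); exponential-dwell Markov kinetics; and
residue-level coordinate ensembles with planted contacts and planted
distance-pair geometry.  Burst sizes are log-normal with median 80
donor-excitation photons and shape 0.4, a realistic spread for diffusing
molecules.

They do **not** emulate: dye photophysics (blinking, quenching),
accessible-volume dye clouds, diffusion transit-time profiles, instrument
response functions for lifetime deconvolution, or lipid-bound/FCS
observables.  Passing tests therefore demonstrate the correctness of the
analysis chain under idealised photon statistics, not robustness to
photophysical artefacts in real data.

## Problem sizes used in the test and acceptance suites

Simulated datasets are sized to give clear statistical power while staying
small: 5000 bursts per condition for the shot-noise law, 600–1000 bursts
for kinetic-averaging limits, 100 replicates × 16 concentrations for
titration parameter recovery, 200 random frames for contact-oracle
equivalence, 25 replicate datasets for mixture CI calibration.  These are
the package's chosen study sizes; the generators scale to larger runs
directly.

## Known limitations

- The bare WLC quadrature ⟨E⟩ understates measured mean efficiencies when
  the quoted chain parameters come from instrument-level fits with linker
  modelling (see Distance models above).
- The mixture model is a Gaussian-peak approximation, not a full
  photon-distribution-analysis likelihood; lifetime handling is
  moment-based (no IRF deconvolution).
- Fraction standard errors from the delta method ignore mean-width
  covariance; bootstrap the scenario generator when that matters.
- The simulator's fixed-duration bursts make burst-size and duration
  distributions unrealistic; quantities conditioned on burst size are
  unaffected, absolute burst-rate observables are.
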