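# Methods

## The model

A nitroxide spin label is a two-spin system: electron S = 1/2 coupled to
the ring nitrogen (I = 1 for ¹⁴N, I = 1/2 for ¹⁵N).  Its CW ESR
lineshape is governed by two anisotropic interactions — the electron
Zeeman coupling (tensor **g**) and the nitrogen hyperfine coupling
(tensor **A**) — modulated in time as the label's principal axes system
(PAS: x along the N–O bond, z normal to the ring plane) reorients
relative to the laboratory field.  With both tensors split into an
isotropic part and a traceless PAS anisotropy, the laboratory-frame
Hamiltonian in angular-frequency units is

    H(t) = (μB/ħ) S·g_iso·B0
         + (μB/ħ) S·(R(t) g_aniso^PAS R(t)⁻¹)·B0
         + A_iso S·I + S·(R(t) A_aniso^PAS R(t)⁻¹)·I ,

with B0 along laboratory z.  Nuclear Zeeman and ¹⁴N quadrupole terms are
omitted from the model on purpose: at X band they shift no observable
electron transition beyond the linewidth, and leaving them out keeps the
two lineshape engines strictly comparable.  R(t) is whatever
orientational trajectory the user supplies — extracted from atomic
coordinates, or produced by the synthetic generators.

The package predicts the detected spectrum by two independent routes:

1. **Direct propagation** (exact): per-frame propagators
   U_k = exp(i H(t_k) δ) are accumulated along the trajectory, the
   density matrix σ(0) = Sx is conjugated through them, and the
   transverse magnetization FID(τ) = Tr{S₊σ(τ)} is averaged over
   evolution windows sliding along the trajectory — the ensemble average
   over spin packets.  Detection emulates field modulation with
   phase-sensitive detection:
   s(ω) = −Im ∫ FID(τ) J₁(Hm τ/2) e^(−iωτ) dτ, with the peak-to-peak
   modulation amplitude Hm converted from mT to rad/s.
2. **Redfield theory** (second-order): the rank-2 fluctuations of the
   Zeeman and hyperfine anisotropies are reduced to scalar channel
   coefficients whose auto- and cross-correlation functions g(τ),
   estimated from the same trajectory (or supplied analytically), are
   transformed to one-sided spectral densities J(ω) and assembled into a
   Liouville-space relaxation supermatrix by the double-commutator rule.
   The spectrum is a sum of complex Lorentzians from the eigenmodes of
   the Liouvillian.  Cross terms between the two interactions — the
   interference that makes one component of a ¹⁵N doublet sharp and tall
   and the other broad and short, in exact analogy to TROSY in NMR — can
   be switched off, which renders the doublet symmetric.

Redfield theory is valid when τ_c ≪ T₂e; `validity_report` grades
τ_c/T₂e as valid (< 0.05), marginal (< 0.2) or invalid.  A
solvent-exposed label (τ_c ~ 1 ns, T₂e ~ 100 ns) sits comfortably in the
valid tier; a buried label whose motion is mostly the ~3 ns protein
tumbling (T₂e ~ 15–20 ns) pushes the condition to its limits.

## Frames, conventions, units

* Rotations are unit quaternions, scalar-first, composed right-to-left
  (q_total = q_global ∘ q_internal); R(q) maps PAS → lab.  Sequences are
  sign-aligned on load (q_k·q_{k+1} ≥ 0) so the double cover never
  introduces spurious jumps; long re-accumulations use a vectorized
  prefix scan.
* Internal units: rad/s for couplings, Tesla for fields, seconds for
  time.  Files use ps (time), mT (field axes), μT (widths), MHz or
  field units (hyperfine input, explicit unit tag).
* Propagation runs in the laboratory frame with the full Hamiltonian;
  the detected FID is demodulated at ω_ref = g_iso μB B0/ħ.  Because
  each per-frame propagator is an exact matrix exponential, carrier
  phase accumulation costs no accuracy, and the non-secular terms —
  whose J(ω₀) contributions the Redfield engine also keeps — stay in the
  dynamics.  A rotating-frame formulation with a static Hamiltonian
  would have to drop them, making the two engines inconsistent at the
  few-percent level in linewidth.
* Sign conventions: propagators use exp(+iHδ) with σ(τ) = Γ⁻¹σ(0)Γ;
  field offsets map as ΔB = −ħΔω/(g_iso μB), so a positive A_iso puts
  the m_I = −1 line at high field.  g-dispersion across a 12 mT sweep
  (~0.1%) is neglected in this linear mapping.
* The m_I = (+1, 0, −1) lines are reported low-field → high-field; the
  asymmetry quotient h(0)/h(−1) compares the central and high-field
  lines.

## Direct propagation: numerical choices

* Per-frame propagators by batched scaling-and-squaring Taylor
  (‖Hδ‖ ≈ 0.06 at δ = 1 ps; truncation ~1e-16, unitary to 1e-14), with
  eigendecomposition as the general fallback.  No Trotter splitting is
  needed since H is held constant within a frame.
* The FID is sampled once per decimation block (default 32–64 ps —
  offsets span < ±250 MHz after demodulation, so this is far above
  Nyquist); block propagators accumulate every 1 ps frame.
* Window stride defaults to 1 ns.  Windows overlap; the average stays
  unbiased and the effective number of independent phase realizations is
  roughly trajectory length / FID span.  This Monte-Carlo character
  matters: the residual spectral noise of the direct engine scales as
  the inverse square root of that number (see "What passing tests
  show").
* σ hermiticity and trace conservation are asserted every 1000 lags
  (tolerance 1e-9); FID(0) must equal Tr{S₊Sx} exactly.
* No apodization is applied; if the FID has not decayed below 1% of
  FID(0) a truncation warning is raised instead, keeping lineshapes
  unbiased.
* Broadening follows the experimental calibration chain: the FID is
  multiplied by exp(−τ/T₂^O2) (Lorentzian oxygen term, default 0.83 μs
  for air-equilibrated samples), and the spectrum is convolved with a
  unit-area Gaussian of 126 μT FWHM (field inhomogeneity plus unresolved
  couplings).  Both default to "off" in the library and are set
  explicitly or via `BroadeningModel.air_equilibrated()`.

## Redfield engine: numerical choices

* Channels: 3 Zeeman (S_j paired with the z-column of the lab Zeeman
  anisotropy) and 9 hyperfine (S_j I_k paired with lab tensor elements).
  This plain Cartesian channel set is complete and makes the
  cross-correlation toggle a simple mask.
* The static Hamiltonian used for the eigenoperator decomposition is
  ω₀Sz + A_iso S·I plus the trajectory-mean anisotropy, so second-order
  hyperfine shifts present in the exact engine are reproduced.
* Correlation functions are estimated with FFTs and lag-dependent
  normalization; the decay beyond the sampled lag range is extrapolated
  by a single exponential fitted to the correlation trace, and J(ω) is a
  trapezoid transform plus the analytic tail.  Non-decaying correlations
  flag the set invalid.
* The supermatrix is assembled without the strict secular approximation
  and then filtered in coherence space: couplings between coherences
  whose static frequencies differ by more than 10× the largest
  relaxation rate are zeroed.  The block structure therefore follows the
  actual degeneracy pattern of H₀ — including the hyperfine splitting —
  rather than an assumed NMR-style kite.
* Dynamic frequency shifts (imaginary parts of J) are kept by default
  and toggleable.  Cross terms are checked against the Cauchy–Schwarz
  bound |J_gA| ≤ √(J_gg·J_AA).
* Eigenvector-basis FIDs; a near-defective Liouvillian (condition
  > 1e10) falls back to a Schur evaluation with a warning.
* A closed-form motional-narrowing oracle (golden-rule rates with
  analytic isotropic-diffusion correlation amplitudes, independent of
  the supermatrix assembly) provides the A + B·m_I + C·m_I² linewidths
  used for cross-checking; engine and oracle agree to ~0.3% in the fast
  regime.

## Tumbling decomposition and λ-rescaling

`decompose` superimposes per-frame fit-atom coordinates onto a reference
(least-squares rotation, SVD with determinant guard) to obtain the
global part Q(t); the internal part is r(t) = Q⁻¹∘R.  `rescale_tumbling`
takes the molecular-frame elementary rotations q_k = Q(t_k)⁻¹∘Q(t_{k+1}),
scales their rotation angles by λ via the axis-angle logarithm, and
re-accumulates from Q(0).  Because only angles change and the
molecular-frame axis distribution is untouched, tumbling anisotropy is
preserved exactly, and a Brownian tumbling time scales as λ⁻²
(λ = 0.5 → 4× slower).  Re-accumulation is anchored at the first frame.

τ_rot is estimated from the rank-2 orientational correlation function
averaged over the three molecular axes (equivalent to the ℓ = 2
rotation-matrix trace correlation), fitted with a single exponential
over lags [0, 5τ] with a log-linear initialization and residuals
weighted by the expected decay exp(−τ/τ_guess).  The weighting is an
inverse-variance approximation — the sampled correlation function
carries roughly lag-independent absolute noise while the signal decays —
and reduces the estimator's sampling spread about threefold on
microsecond trajectories.  S² plateaus are
reported as the mean of C(τ) over the final 10% of the lag range.

## Synthetic motion: what it emulates, what it does not

The generators reproduce the motional regimes of a spin-labeled globular
protein: isotropic or axially anisotropic Brownian tumbling (τ_rot of a
few ns, D∥/D⊥ ≈ 1.4), fast internal label dynamics (diffusion in a cone
with the closed-form order parameter S = cosβ(1+cosβ)/2, discrete
rotameric jumps as continuous-time Markov chains with 0.1–10 ns
correlation times), and slow μs-lifetime switching between environments
(e.g. mobile vs immobilized).  Increments are Gaussian axis-angle steps
in the molecular frame, valid for 6D·δ < 0.01 (asserted).  All
generators are exactly reproducible from (seed, parameters) via a
counter-based RNG stream.

They do **not** emulate: rotamer energetics or concerted χ-jump
compensation, orientational potentials coupling internal motion to the
protein surface, memory effects beyond Markovian switching, or any
solvent physics.  Consequently, passing tests demonstrate that the spin
dynamics, rescaling algebra and fitting machinery are correct for
motions with known statistics — not that any particular protein's
spectrum is predicted; that requires real MD input through the same
interfaces.

## Lineshape fitting

Voigt profiles are evaluated through the Faddeeva function with an
analytic first derivative (finite differences are too unstable for
narrow lines); the pure-Lorentzian limit is evaluated analytically
because wofz loses relative precision as the Gaussian width → 0.  Each
line is fitted over the 80% window — from the leftmost point at 80% of
the raw maximum to the rightmost point at 80% of the raw minimum — by
unweighted least squares (the experimental noise model is not specified
further).  Because Gaussian and Lorentzian widths trade off inside that
narrow window, the fit multi-starts from both pure limits and a mixed
seed and keeps the lowest residual.  Peak-to-peak widths Δ(i) and
amplitudes h(i) are measured on the best-fit function (dense evaluation
with parabolic extremum refinement), not on raw samples.  The collective
air/degassed fit shares one Gaussian G and per-line Lorentzians L(i),
with L_O2 added only to the air spectrum; with the calibration values
(G = 126 μT, L_O2 = 13.5 μT) both recover to better than 1% on noiseless
input.  Width ↔ T₂ conversion: T₂ = h/(π g μB ΔB_FWHM); 13.5 μT at
g ≈ 2.006 gives 0.84 μs.

## Problem sizes and tolerances in the test-suite

Desk-scale study conditions used by the acceptance tests, chosen once:

* λ-rescaling law: τ_rot = 3 ns, 1 μs trajectory, δ = 1 ps; ratio
  asserted within ±15% (sampling tolerance of the τ fits).
* Rigid-limit check: 128-orientation Fibonacci grid, 16.4 ns FIDs,
  engine vs stick-sum oracle on the same grid within 1e-6 of peak.
* Engine cross-validation: τ_c = 0.1 ns, 8 μs trajectory, 65.5 ns FID
  (1024 × 64 ps), 1 ns window stride — about 120 independent phase
  realizations, which puts the direct engine's Monte-Carlo noise near
  1% of peak, inside the 2% agreement band with margin.  Deviation is
  then shown to grow monotonically through τ_c = 1 and 3 ns, where the
  Redfield validity condition degrades (measured ~12% at 1 ns).
* Motional narrowing: engine rates vs closed-form oracle within 3%
  (measured ~0.3%).

## Known limitations

* The direct engine's ensemble average is Monte-Carlo over windows; very
  slow motions (τ_c approaching the trajectory length / FID span) leave
  visible spectral noise unless trajectories are long.
* No stochastic-Liouville solver: the rigid and near-rigid regimes are
  handled by direct propagation only.
* ¹³C satellites and minor isotopologue signals are not simulated;
  saturation, rapid passage and multifrequency presets are out of scope.
* Multicomponent (two-population) spectral decomposition is not
  provided; the descriptors assume resolvable single-component lines.
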