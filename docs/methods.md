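# Methods

## Rotational correlation functions

For every labelled site the P2 autocorrelation
C(t) = ⟨P₂(u(t′)·u(t′+t))⟩ is averaged over **all** available time
origins t′ (no subsampling). The implementation expands P₂ of the dot
product into the six component-product autocorrelations
⟨u_a u_b (t′) · u_a u_b (t′+t)⟩ and evaluates them with FFTs; this is
algebraically identical to the direct double loop (the test suite checks
agreement to 1e-10) and makes multi-million-frame series cheap.

Lag range. Correlation values at lags approaching the trajectory length
are statistically meaningless, so lags are truncated at a fraction of the
total length: 1/100 by default for a single-molecule site, 1/20 when many
chemically equivalent sites (e.g. the same SDS carbon in every detergent
molecule of a micelle) are averaged into one group function. Both are
statistical-quality heuristics, not laws, and are overridable. Group
averaging is the plain arithmetic mean of the member functions; averaging
replicate simulations is exposed (`average_correlations`) and the
averaging-versus-separate-fits policy is left to the user.

If C(dt) < 0.95 the saving interval is too coarse to resolve the fastest
motion present and a warning is emitted; detergent C–H work typically
needs saving intervals around 0.01 ps, backbone amides are far less
demanding.

## Timescale grids and the NNLS fit

C(t) is fitted by Σ αᵢ exp(−t/τᵢ) with αᵢ ≥ 0 on a *fixed* logarithmic
grid, by non-negative least squares over all lag points with unit
weights. There is no other regularization; the grid spacing is the
effective resolution. Presets: "NH" (N = 100, 1 ps–100 ns) for backbone
amides and "CH" (N = 500, 1 fs–1 μs) for detergent C–H. Neighbouring
grid columns are nearly collinear, so individual weights are only
determined up to local trade-offs; everything downstream
(C_fit, J(ω), τ_eff, cluster weights per decade) is solver-independent,
and tests only ever assert those quantities, never single αᵢ.

Artificial slow weight. A correlation function that has not decayed to
its plateau within the fitted window pushes a small weight onto the
slowest grid point. `filter_artificial_slow` zeroes that weight when it
is below a threshold (default 1%), records a flag, and does **not**
renormalize; a larger slow weight is kept with a warning since it may be
real. An option extends the filter to the k slowest points.

A constant plateau C(t) ≡ c < 1 is fitted as-is, giving Σα ≈ c — the
order-parameter interpretation — with no renormalization.

## Spectral density and relaxation

J(ω) = 2 Σ αᵢτᵢ/(1+ω²τᵢ²) follows analytically from the fit, and
τ_eff = Σαᵢτᵢ is evaluated as J(0)/2 so that identity is exact in
floating point.

Normalization. With the C(0) = 1 convention used here, J is five times
the Lipari–Szabo spectral density; the reduced density j(ω) = J(ω)/5
enters the Redfield expressions. This factor lives in
`NucleusConstants.j_normalization` and is validated end-to-end by the
rigid-rotor oracle tests (a wrong factor shifts T₁ by a factor ~5 and
cannot hide).

¹⁵N (dipolar ¹H–¹⁵N + CSA, no cross-correlation):

    d  = (μ₀/4π) ħ γ_H |γ_N| / r³,   c = ω_N Δσ/√3
    R₁ = (d²/4)[j(ω_H−ω_N) + 3j(ω_N) + 6j(ω_H+ω_N)] + c² j(ω_N)
    R₂ = (d²/8)[4j(0) + j(ω_H−ω_N) + 3j(ω_N) + 6j(ω_H) + 6j(ω_H+ω_N)]
         + (c²/6)[4j(0) + 3j(ω_N)]
    NOE = 1 + (γ_H/γ_N)(d²/4)[6j(ω_H+ω_N) − j(ω_H−ω_N)] T₁

γ_N < 0 is kept explicit: the extreme-narrowing NOE is
1 + γ_H/(2γ_N) ≈ −3.93 (dipolar mechanism), and slow tumbling approaches
1 from below, matching the 0.4–1 range seen for micelle-bound peptides.
Note the CSA mechanism alone has the textbook extreme-narrowing ratio
R₂/R₁ = 7/6, so "T₁ = T₂ at fast motion" is a dipolar-only statement.

²H (quadrupolar, axially symmetric field gradient, asymmetry 0):

    R₁ = (3π²/10) χ² [j(ω_D) + 4j(2ω_D)]
    R₂ = (3π²/20) χ² [3j(0) + 5j(ω_D) + 2j(2ω_D)]

Default constants (all overridable): r_NH = 1.02 Å, Δσ = −170 ppm,
χ(C–D) = 167 kHz, γ_H = 2.6752218744e8, γ_N = −2.7126e7,
γ_D = 4.10663e7 rad s⁻¹ T⁻¹. These are community-standard backbone /
methylene values; predictions scale as r⁻⁶ through d², so the bond-length
choice matters at the few-percent level and is deliberately exposed.

## Dynamic landscapes

Per-site weight vectors are stacked into a sites × timescales matrix.
For presentation, weights of k (default 5) consecutive grid points are
summed; the merged bin is represented by the geometric mean of its
members (preserving log-symmetry) and a trailing partial group is kept
as its own bin, so per-site total weight is conserved exactly.
`dominant_timescale` reports the weight-maximizing merged bin (ties
break deterministically toward the slowest bin) and the total weight
within ±¼ decade of it. No attempt is made to label a timescale as
"overall" versus "internal" motion: for disordered peptides in micelles
that dichotomy is exactly what should not be assumed.

## Geometry

Micelle membership is any-atom distance ≤ cutoff from any peptide atom,
minimum-imaged in orthorhombic boxes; the 1.8 nm default suits SDS
micelles but the right value is system-specific (1.4–1.8 nm typical) and
should be sanity-checked against the membership time series. The micelle
radius proxy is the mass-weighted radius of gyration of members plus
peptide, computed per frame and time-averaged by the caller.

Stokes–Einstein. D_r = k_B T/(8π η r³) for a rigid sphere. Two timescale
conventions are provided: the package default τ = 1/(6π D_r) — the
convention under which a 6 ns timescale at 310 K in water
(η = 0.69 mPa s) inverts to r = 3.0 nm — and the textbook P2 correlation
time τ = 1/(6 D_r), a factor π longer. Inversions for r and η solve the
same identity exactly.

Principal-axis angles use the dominant gyration-tensor eigenvector,
folded into [0°, 90°]; shapes whose two largest eigenvalues are
degenerate (spheres, coincident points) have no unique axis and are
rejected. Rotation removal is mass-weighted Kabsch superposition (proper
rotations only) of every frame onto the first frame's reference
selection, applied to all atoms about the reference centre of mass —
meaningful only for internally rigid references.

## Helicity correlation

Helicity of a residue is the frame fraction with DSSP code in {H, G, I}
(α, 3₁₀, π); the set is a parameter because conventions differ. Local
environment helicity averages the residue with its existing neighbours
(3-point interior, 2-point termini); it is deliberately non-idempotent
and should be applied once. Pearson r with a two-sided t-distribution
p-value (n−2 df) is computed per (helicity, observable) pairing; pooling
across systems versus per-simulation correlation is the caller's choice.

## Synthetic ground truth

The isotropic rotor propagates a unit vector by Gaussian tangent-plane
steps with angular variance 4 D_r dt (two rotational degrees of freedom)
followed by renormalization; its exact P2 autocorrelation is
exp(−6 D_r t). The scheme needs 6 D_r dt ≪ 1 (warning above 0.01); a
100-site ensemble test confirms that halving dt moves the fitted τ_eff
by < 1%. The two-mode rotor adds wobble-in-a-cone internal motion as
Poisson-timed uniform resampling within a cone co-rotating with the
director; with cone semi-angle chosen from S = cosθ(1+cosθ)/2 this has
the exact target C(t) = [S² + (1−S²)e^(−t/τ_int)]·e^(−6 D_r t). One
seeded generator per trajectory makes every dataset bit-reproducible.

What the generator does *not* emulate: anisotropic diffusion tensors,
correlated motions between sites, exchange between environments, and the
rugged conformational dynamics of real peptides. Passing recovery tests
therefore demonstrates the correctness of the correlation → NNLS →
Redfield machinery, not force-field accuracy or conformational sampling.

## Problem sizes, statistics, and known limitations

The reference recovery runs use a single 2 μs trajectory (2×10⁶ frames,
1 ps spacing) for τ_c = 5 ns, i.e. T/τ_c = 400. At that ratio the
sampling error of a single-site correlation function propagates into
roughly ±5–10% (1σ) scatter of τ_eff and T₁ across seeds, dominated by
correlated noise at lags beyond ~3τ_c that the NNLS maps onto spurious
slow/fast weight; the artificial-slow filter removes only the part that
lands on the very slowest grid point. Group averaging over many
equivalent sites, longer trajectories, or replicate averaging reduce the
scatter as 1/√N — the pipeline test at T/τ_c = 2000 recovers T₁ within
3%. Tests freeze one seed per dataset so that the suite is deterministic;
the corresponding single-seed results should be read with the above
scatter in mind.

Other limitations: Redfield theory itself (no slow-exchange or R₁ρ/CPMG
contributions, no dipole–CSA cross-correlation); orthorhombic boxes only
in the geometry distance code; the DSSP assignment is consumed, not
computed; and the Stokes–Einstein viscosity inversion inherits whatever
convention its input timescale was measured in — both conventions are
exposed for that reason.
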