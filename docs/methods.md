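# Methods

This note documents the models, estimators, numerical choices and known
limitations of `memdiel`, in the order the pipeline runs.

## Scope and data model

The pipeline consumes an equilibrated membrane–water system: a structure
(GRO, parsed in-package with line-numbered errors, or PDB via MDAnalysis), a
trajectory with **velocities** (TRR via MDAnalysis, or the package's HDF5
dialect with `/time`, `/box`, `/positions`, `/velocities` datasets), and a
sidecar CSV of partial charges and masses keyed by `(residue, atom)` —
coordinate formats carry neither. Units at the I/O boundary are the MD
conventions (nm, ps, nm/ps, e, u); everything spectral is converted to SI
once. A positions-only trajectory is rejected rather than differentiated
numerically: finite-difference velocities change the spectral noise floor
and must never happen silently. The frame interval is taken from the stored
times and verified uniform to 1 part in 10⁶; it sets the Nyquist limit
1/(2Δt), while the run length T sets the resolution 2/T, so the reliable
frequency grid is f ∈ [2/T, 1/(2Δt)] in steps of 2/T, zero excluded.

## Layering

Frames are re-centred so the lipid centre of mass sits at z = 0 (default on;
removes slow drift along the normal, toggleable for pre-centred data). Each
atom gets the **time mean** of its z coordinate, and the assignment to slabs
is *static* — one slab per atom for the whole run. Per-frame reassignment
would make the slab current J_L(t) discontinuous whenever an atom crossed an
edge, polluting the high-frequency spectrum with spurious steps.

The head/tail dividing line of each leaflet is the midpoint between the
innermost head-group atom and the outermost chain atom (by mean |z|); the
tail span is measured from the midplane, so monolayer thickness = head span
+ tail span. The lipid region is cut into ceil(span/spacing) slabs of equal
width (0.2 nm default), with the overhang of the last slab split evenly so
that a symmetric system gets slabs mirror-symmetric about the midplane.
Slabs are half-open [lo, hi), ties to the upper slab. Water continues
outward with the same spacing (configurable to one slab per side) and is
extended if atoms lie beyond the nominal margin, so the partition is always
exhaustive. Hydrogens follow their bonded heavy atom when bonds are known,
otherwise the nearest heavy atom of the same residue by mean z; water
molecules follow their oxygen. Slab volume is box_x × box_y × spacing.

Layering is defined on heavy atoms (the ordinal numbering 1..46 shipped for
DMPC is one documented head-to-tail ordering, exposed as configuration), but
the current sums run over **all** atoms assigned to the slab, including any
waters inside the lipid span.

## Green–Kubo spectra

For slab L, J_L(t) = Σ_{j∈L} q_j v_j(t) in SI (C·m/s). The estimator:

- autocorrelation C(k) = ⟨J(0)·J(kΔt)⟩ over all time origins with the
  biased 1/n normalization (keeps the implied spectral window
  positive-definite), computed by FFT; the direct O(n·lag) sum is the test
  oracle.
- default truncation max_lag = n/2. The canonical evaluation grid of an
  m-lag correlation, f_j = j/(mΔt), then coincides exactly with the
  reliable grid above, and the cosine series
  Δt·(C₀ + 2Σ C_k cos ωkΔt) is a single real FFT per slab.
- ε″(ω) = [1/(6 ε₀ V k_B T ω)] × that transform. No taper is applied by
  default: the correlation of thermal oscillators decays well inside the
  truncation window, and the plain transform is what the analytic oracle
  normalizes.

The 1/6 prefactor was validated, not assumed: against the exactly Lorentzian
response of the Langevin oscillator gas the seed-averaged estimate is
unbiased (in-band ratio 0.99 over 6 seeds in development runs), and the
f-sum rule ∫₀^∞ ω ε″ dω = (π/2)·Nq²/(ε₀Vm) closes to ~1%. Cross-slab dipole
correlations are neglected — each slab is treated as an independent medium —
a stated limitation of the layered picture, not of the code.

Smoothing is a centred moving average in frequency with shrinking edge
windows; the raw spectrum is always retained alongside. The window should
stay below the linewidth of interest: a flat window of width w reduces a
Lorentzian peak by ≈ w²/(3·FWHM²).

## Kramers–Kronig

Forward (ε″ → ε′): Maclaurin's alternating-point rule — the integrand
ω′ε″(ω′)/(ω′²−ω²) is sampled only at grid points of parity opposite to the
evaluation point, weight 2h, so the singular sample is never touched. On a
4096-point grid the analytic Lorentzian pair is reconstructed to 0.33% max
relative error away from ±γ of resonance. A plain trapezoid rule that skips
the singular point is kept as an independent cross-check; its PV
cancellation is O(h) and poor near sharp features, so tests compare the two
rules only on smooth spectra.

Truncation: the integral runs over the computed grid only. With the default
`zero-pad` policy the omitted high-frequency contribution is absorbed into
ε_∞ — precisely the role of the optical dielectric constant. For spectra
with a slowly decaying tail (Debye-like, ε″ ~ 1/ω) the `power-law` policy
fits B·f^(−p) to the top decade in log–log and integrates the extrapolated
tail to 1000·f_max; that brings the Debye pair to 0.18% except within the
outermost 1% of the grid, where a finite-band transform is undefined at its
own boundary (the accuracy assertions in the tests exclude that trim). These policies were chosen from the tail asymptotics, not tuned.

Inverse (ε′ → ε″): the numerator ε′−ε_∞ does **not** vanish towards zero
frequency, so the plain rule fails near the low edge. The implementation
uses the subtractive PV scheme: since ε′ is even and smooth,
(y(ω′)−y(ω))/(ω′²−ω²) is regular and integrates accurately with either
rule, and the removed piece y(ω)·PV∫dω′/(ω′²−ω²) has a closed form over the
finite band, plus a rectangle estimate of the [0, f_min) gap. The roundtrip
ε″ → ε′ → ε″ is exposed as a data-quality diagnostic (max and L2 deviation
relative to the input's scale): causal, well-resolved spectra score below a
percent, noise-dominated ones score large.

ε_∞ handling is exact by construction: linearity and the ε_∞ shift
equivariance of the transform hold to machine precision and are tested as
identities.

## Optical calibration

Group contributions (Vogel): molar refractions of the chemical units at
468.3/589.3/653.3 nm are additive. The DMPC head moiety is 3×CH₃ + 5×CH₂ +
2×COO + C + H + PO₄ + N (M = 325.255 g/mol from standard atomic masses);
the tail is 2×CH₃ + 23×CH₂ (M = 352.691 g/mol). Lorentz–Lorenz is
implemented in its standard solved form n = √((M+2ρR)/(M−ρR)), which has
the correct vacuum limit n → 1; an un-rooted ratio variant exists behind a
flag for comparison only. The Cauchy model is solved exactly through the
three (λ, n) points — no least squares, three points determine A, B, C —
and ε_∞ = n(c/f)² at the 300 THz anchor, where the moieties are transparent
(κ = 0).

The moiety mass densities are genuine configuration: group contributions do
not provide them. Defaults are ρ_head = 1.40 g/cm³ and ρ_tail = 0.85 g/cm³,
literature-typical for the hydrated phosphocholine headgroup region (which
X-ray electron-density profiles place well above water) and for liquid
tetradecane-like chains. With these defaults head ε_∞ (2.25) > tail ε_∞
(2.16), the ordering expected from the polarizability of the two regions;
because the head's R/M is smaller than the tail's, a head density below
about 1.33 g/cm³ would invert the ordering — one reason the density is
exposed, and every calibration record stores the ρ and M actually used.

## Synthetic data: what it emulates and what it does not

The generator builds a stratified slab of independent charged oscillators:
head and tail strata mirrored about the midplane (spans 0.8 and 1.2 nm per
monolayer, 64 lipid-analogues per leaflet at 0.606 nm², 310 K — the
geometry of a hydrated DMPC patch), plus an overdamped low-frequency water
analogue beyond the lipid extremes. Dynamics are BAOAB Langevin steps with
the exact Ornstein–Uhlenbeck solution in the O-step; stability is enforced
(Δt·ω₀ < 0.1, Δt·γ < 0.1) rather than assumed, and per-atom counter-based
Philox streams make runs bit-reproducible and insensitive to atom-count
changes. Initial conditions are drawn from the exact Gibbs marginals
followed by a short burn-in; temperature 0 with an explicit initial
displacement gives the deterministic ringdown at √(ω₀²−γ²/4) used to test
the integrator.

Each stratum's permittivity is exactly Lorentzian with strength
S = Nq²/(ε₀Vm) — an exact KK pair — so layering, spectra, KK and band scan
can all be judged against closed forms. Default resonances sit at 8 THz
(head), 14 THz (tail) and 1 THz overdamped (water): the stability bound at
a practical 1 fs step caps resonances near 15 THz, and the *location* of
the synthetic waveguide window is construction-dependent anyway — the tests
verify the criteria mechanism, peak recovery and ordering, not any
particular band edge. What the toy does **not** emulate: chemical bond
vibrations (C–H stretch bands), cross-slab dipole correlations,
polarizability (stratum ε_∞ ≡ 1), undulations, or the crowded many-band
spectra of real force fields; passing tests therefore demonstrate estimator
correctness, not force-field realism.

Charges alternate ±q within a stratum (neutral by construction), and the
alternating atoms carry distinct names (OH1/OH2, ...) so the
(residue, atom)-keyed charge CSV can round-trip the system through the same
readers real data uses.

## Problem sizes used by tests and the acceptance script

Oracle runs use 64-oscillator gases at 10⁵ 1-fs steps and 8 seeds; the
end-to-end toy membrane uses 1792 atoms, 25 ps of frames at 2 fs (12 500
frames), 8 seeds, with a 1500-frame profile pass, truncation at n/2 lags
and a 0.4 THz smoothing window. These sizes were chosen so the stochastic
checks sit comfortably inside their tolerances (peak noise after seed
averaging ≈ 3–5%) while a full run stays at desk scale; they are package
defaults of the validation suite, not physical claims.

## Known limitations

- Classical correlation functions only; no quantum correction factors.
- Scalar (isotropic) permittivity per slab; no tensor components or
  frequency-dependent local-field corrections.
- The band scan applies threshold criteria to ε′/ε″ profiles; it does not
  solve electromagnetic waveguide modes or compute attenuation lengths.
- The packaged DMPC fixture is a generated extended geometry with a
  simplified CHARMM36-like, group-neutral charge table — adequate for
  format, counting and neutrality checks, not an equilibrated structure.
- Edge bins of any finite-band KK transform (the outermost ~1% of the grid)
  are unreliable; downstream consumers should trim or widen the grid.
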