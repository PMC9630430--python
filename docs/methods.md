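# Methods

`nickfret` implements a hybrid single-molecule-FRET / computational
workflow for quantifying how sharply double-stranded DNA is kinked at a
single-strand break (nick).  The experimental idea it models: a 62-nt
DNA strand folds into a dumbbell — two B-form stems capped by
tetraloops, whose 5′/3′ termini juxtapose into one ligatable nick — and
carries an acceptor dye at T18 and a donor dye at T37, one on each stem.
The measured FRET efficiency between the dyes reports the inter-stem
distance; a structural ensemble plus a photophysically explicit forward
simulation turns that single distance into a distribution of allowed
kink angles.  A synthetic photon-stream generator stands in for raw
confocal data so that the photon-level analyses (burst selection,
corrections, dynamics diagnostics, filtered FCS) can be validated
against known ground truth.

## Coarse-grained DNA model

Each nucleotide is reduced to three pseudo-atoms — phosphate, sugar and
base centroid — placed on an idealized fiber B-form helix: rise 3.4 Å,
twist 36°/bp, phosphates at radius 9.4 Å, sugars at 6.9 Å, base
centroids at 2.5 Å with the two bases of a pair diametrically opposed so
that base-pair centers lie exactly on the helix axis.  Helical phase is
continuous across the stem junction, so the intact strand (nt 16–42)
has uninterrupted backbone geometry while the nick (between nt 62 and
nt 1) is a pure juxtaposition.  Tetraloops are compact 4-residue arcs
capping each stem.  The secondary structure is derived from the
sequence by a brute-force self-complementarity scan (11-bp stem + GTAA
loop; 16-bp stem + CTTG loop) and is user-overridable.

The conformational ensemble keeps both stems internally rigid and
re-orients the whole 5′ half about the linker phosphate (the P of the
first 3′-stem nucleotide) by rotations drawn from the Haar measure on
SO(3), rejecting members in which any 5′-half pseudo-atom comes within
the clash radius (default 4.0 Å) of a 3′-half pseudo-atom.  Cross-pairs
among the four junction nucleotides (linker neighbors nt 26/27 and the
base-stacked nick termini nt 1/62) are native contacts in the straight
model (≈3.7 Å) and are excluded from the clash test.  This rigid-body
sampler is a deliberate simplification of torsion-space randomization of
the five rotatable linker dihedrals: both aim at uniform coverage of the
sterically allowed relative orientations, and only that coverage — not
linker energetics — enters the downstream analysis.

## Accessible volumes

Dyes are modeled as single spheres on flexible linkers (AV1-type).  A
grid node belongs to the accessible volume (AV) if a geodesic path of
unblocked nodes no longer than the linker length connects it to the
attachment point; traversal requires linker-half-width clearance and the
end point additionally dye-radius clearance from every obstacle
pseudo-atom (obstacle radii 3.0 Å for phosphate/sugar, 3.5 Å for base
centroids).  The labeled nucleotide and its two sequence neighbors
anchor the linker and are excluded from the obstacle set — at this
resolution their 3–3.5 Å envelopes would otherwise bury the attachment
entirely.  The geodesic metric uses lattice steps up to Chebyshev
radius 3 (coprime offsets); the cruder 26-neighbor metric overestimates
path lengths by up to ~8% and truncates AV volumes by several percent.
An unobstructed AV reproduces the analytic sphere volume to ~2.5% at
spacing L/20.

Dye parameters are deliberately plain configuration: the true linker
and dye dimensions of the two C2-linked fluorophores are not derivable
from sequence, so the defaults (linker length 14 Å, width 4.5 Å, dye
radius 3.5 Å, grid 1.0 Å) were calibrated once so that the straight
model reproduces the measured free-DNA efficiency operating point
(E ≈ 0.5 at R_iso = 70 Å) and were not revisited afterwards.  They are
a coarse-grain effective parameterization, not measured chemistry.

## FRET forward simulation

For each structure, 50,000 excitations (default) are simulated.  Per
excitation both dye centers start uniformly in their AVs with dipoles
uniform in a cone about the AV principal axis; during the donor excited
state the dyes translate by a reflected random walk inside the AVs
(D = 10 Å²/ns) and rotate diffusively inside their cones
(D_rot = 1/(6ρ), ρ = 0.5 ns default), and each time step (0.05 ns)
competes donor decay (rate 1/τ, τ = 3.5 ns default) against transfer

    k_T = (3 κ² / 2) (1/τ) (R_iso / R)⁶

with κ² from the instantaneous dipole orientations.  The efficiency is
the transferred fraction; its SD is binomial.  The cone semi-angle
follows the wobbling-in-cone relation r∞/r0 = [cos α (1+cos α)/2]²
(default r∞/r0 = 0.25 → α ≈ 51.8°).  Static-κ² and isotropic-κ² (2/3)
modes exist for comparison; the isotropic mode raises the straight-model
efficiency from ≈0.51 to ≈0.60, i.e. the restricted-rotation treatment
carries real signal and is the default.

The dominant systematic uncertainty is the isotropic Förster radius:
ΔR_iso = 2 Å at R_iso = 70 Å propagates to ΔE ≈ 6·E(1−E)·ΔR₀/R₀ ≈ 0.04
at the operating point (also available by re-simulation at R₀ ± ΔR₀).
Monte-Carlo noise is negligible in comparison: the SD of the mean over
independent repeats is binomial-limited, ≈1.6–1.7% at 1,000 excitations
and ≈0.22% at 50,000.

## Structure selection and kink-angle statistics

A structure is accepted for a measured efficiency E_exp when
|E_sim − E_exp| ≤ √(ΔE_exp² + ΔE_sim²) = √(0.03² + 0.04²) = 0.05.
Each stem's axis is the largest principal component of its pseudo-atoms,
omitting the tetraloop and the loop-adjacent base pair (both
nucleotides), oriented nick → loop; the kink angle θ is the angle
between the two axes (180° = straight).  Pseudo-atoms are weighted by
the number of heavy atoms each group represents (phosphate 5, sugar 6,
base 10) so the PCA mimics an all-atom "all atoms of the stem"
computation; with equal weights the spiral of the heavy phosphate shell
tilts the axes ~2° further.  Even so the straight model reads ≈174°,
not 180°: with only 10 and 15 usable base pairs the discrete helical
spiral does not average out of the PCA.  This finite-stem tilt is a
property of the convention, and it sets the 8° pole band inside which
the azimuth φ about the 3′ axis is reported as undefined.

Because one donor–acceptor distance fixes only θ, selected structures
form rings about the 3′ axis.  Kink-angle histograms (5° bins) are
therefore corrected for the ring surface on the unit sphere using the
exact per-bin area 2π(cos θ_lo − cos θ_hi) (regular at the poles), and
means/SDs are computed from the corrected histogram.  Two axially
symmetric scenarios are supported: *cone* (mean axis = normalized vector
sum; SD about it) and *sector* (axially degenerate ring; mean polar
angle about the 3′ axis).  The sector scenario is suggested
automatically when the vector-sum direction lies within 10° of the 3′
axis.

At the study's conditions (1,000-member ensemble, ≥10⁴ excitations per
member, R_iso = 70 Å) the ensemble's simulated efficiencies cover
roughly 0.44–1, and selections at E_exp = 0.50 / 0.69 / 0.86 produce
well-separated angle regimes near 165–175° / ~125–130° / ~90°,
decreasing strictly with the target efficiency.

## Synthetic photon streams

The generator emulates pulsed-interleaved-excitation (PIE) confocal
acquisition: 20 MHz repetition rate, green pulse at the cycle start and
red pulse shifted 20 ns, macrotimes on a 12.5 ns clock, microtimes at
16 ps.  Two transit models exist:

* **Envelope mode** (`simulate_stream`): molecules arrive as a Poisson
  process (default 4 s⁻¹, well under the 13 s⁻¹ multi-molecule
  guideline) and each transit has a Gaussian intensity envelope with
  SD = τ_D/2.  Cheap and adequate for burst-level statistics,
  corrections round-trips and qualitative dynamics.
* **Dynamic 3D mode** (`simulate_stream_dynamic_3d`): molecules perform
  Brownian motion in a periodic box through a 3D Gaussian detection
  volume (lateral waist w, axial/lateral ratio p; the axial box half
  defaults to 3× the axial waist, since tighter boxes let wrap-around
  decorrelate the signal).  Its ensemble correlation follows the
  standard diffusion model exactly, so all quantitative FCS/fFCS
  recovery uses this mode.  The Gaussian-envelope ACF of the cheap mode
  is *not* hyperbolic and would bias relaxation-time fits.

Within a transit the FRET state follows a continuous-time Markov chain
(arbitrary state count and rates; stationary or user-given initial
weights).  Detection implements γ (acceptor/donor detection-probability
ratio), β and the target stoichiometry (red-excitation scaling),
crosstalk as an *additional* independent FRET-channel detection of donor
emission (probability α per detected-donor-photon, matching the
correction convention F_DA′ = F_DA − αF_DD), direct acceptor excitation
(δ relative to the red-excited rate), acceptor dark states (telegraph
with ~6–7 µs relaxation available), polarization splitting from a
steady-state anisotropy with a G-factor, and per-channel Poisson
background (defaults 0.1–0.9 kHz range).  DD microtimes decay with
τ(1−E) for the current state; DA/AA with the acceptor lifetime.  Ground
truth (per-burst state occupancies, true E/S) accompanies every stream.

What the generator does *not* emulate: IRF convolution, detector
afterpulsing and dead time (beyond a one-photon-per-pulse cap),
spectral shapes, and real linker/dye photophysics beyond the explicit
dark-state telegraph.  Passing recovery tests therefore demonstrates
the correctness of the analysis chain, not robustness to every
instrument artifact of real data.

## Burst analysis

All-photon sliding-window burst search (≥10 photons in a centered
500 µs window, >50 photons total), with candidate runs additionally
split at inter-photon gaps wider than the window.  Corrections follow
the standard convention written in the module docstring; events are
filtered by stoichiometry (0.3 < S < 0.75), ≥100 photons, ≤20 ms
duration, corrected E in [0, 1] and an ALEX-2CDE score ≤ 10 (KDE time
constant 100 µs; the exact kernel-density formula is pinned in the
docstring).  Efficiency histograms are fitted with 1–3 Gaussians
(Poisson-weighted least squares; reduced-χ² model choice when the count
is not given).  Per-burst donor lifetimes come from a mono-exponential +
uniform-background MLE without IRF deconvolution (synthetic microtimes
are IRF-free; flagged for real data).  The error budget of the
corrected efficiency propagates 10% relative errors on α, β, γ, an
absolute Δδ = 0.1·δ, and ±1 background photon per burst at a mean
photon number F = 75, giving ΔE ≈ 0.01–0.03 over the relevant E range —
the origin of the ΔE_exp = 0.03 used in structure selection.
Dynamics diagnostics: signed deviation from the static FRET line
E = 1 − τ_DA/τ_D, burst variance analysis against the √(E(1−E)/n)
shot-noise curve (n = 5 photons per sub-burst), and time-window
histograms (0.2–5 ms).

## Correlation analysis

Correlations are computed directly from (optionally weighted) photon
timestamps with a two-pointer pair-sum algorithm on a quasi-logarithmic
lag grid (16 points per octave), using the symmetric normalization
G(τ)+1 = S·(T−τ)⁻¹-corrected pair density; the implementation is tested
pointwise (1e-10) against an O(N²) oracle.  Curves are fitted with

    G(τ) = G_diff(τ)[1 + Σ A_i exp(−τ/τ_R,i)] + offset,
    G_diff = 1/(N√8) (1+τ/τ_D)⁻¹ (1+τ/(p²τ_D))^(−1/2)

— the 1/√8 prefactor is part of this model definition and differs from
the common 1/N normalization by a constant.  Per-point uncertainties
come from contiguous record segments.

Filtered FCS: species-pure TCSPC reference patterns are accumulated from
bursts inside per-species FRET-efficiency windows (stacked over
donor-parallel, donor-perpendicular and FRET channels × 64 microtime
bins); filters are the Poisson-weighted pseudo-inverse of the pattern
matrix (filterᵢ · patternₖ = δᵢₖ by construction; near-collinear
patterns, cosine > 0.99, raise a singularity error).  Photons outside
±50 ms padded burst windows carry zero weight (burst-wise fFCS).  The four
species auto/cross correlations are fitted globally with τ_D and a
photophysics term fixed, one linked relaxation time τ_R, and free —
possibly negative — cross amplitudes; the τ_R uncertainty is the SEM
over 5–8 contiguous record segments re-analyzed end-to-end.  On
synthetic two-state streams with k₁₂ = k₂₁ = 2000 s⁻¹ the analysis
recovers τ_R = 1/(k₁₂+k₂₁) = 250 µs within its SEM.

## Problem sizes and numerical choices

The shipped analyses use a 1,000-member ensemble at 10⁴ excitations per
member for the selection-to-angle mapping, 100 × {10³, 5·10⁴}
excitations for the convergence series, and 30–90 s synthetic records
(envelope mode ~10⁵–10⁶ photons; 3D mode ~2·10⁶ photons, ~6 × 10³
bursts) for the photon-level validations — sizes chosen so the full
pipeline re-runs from scratch on a laptop-class single core in minutes
while every recovered quantity remains statistically resolved.  Numba
JIT kernels (AV Dijkstra, MC photophysics, photon-pair correlator) keep
the inner loops at C speed.  Seeds thread through every stochastic
component; fixed seeds give bitwise-identical ensembles, streams and
transfer counts.

## Known limitations

* The coarse-grained model cannot reproduce sequence-dependent
  fine structure (groove widths, base-step variability, tetraloop
  geometry); the stem-axis convention mitigates but does not remove the
  resulting few-degree ambiguity in absolute angles.
* The rigid-body nick sampler explores relative stem orientation only;
  intra-stem bending and linker-conformation energetics are out of
  scope, so selected sub-ensembles are "sterically allowed and
  FRET-consistent", not Boltzmann-weighted.
* Dye parameters are effective, calibrated values (see above), so
  absolute simulated efficiencies inherit that calibration; selections
  relative to the same calibration (the angle regimes) are the robust
  output.
* Envelope-mode correlation amplitudes/shapes are approximate by
  construction; use the 3D mode for quantitative FCS.
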