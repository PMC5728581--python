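# Methods

This note records the models implemented by `nucleoslide`, the
parameter conventions, the design choices made where the problem was
genuinely open, and what the synthetic fixtures do and do not
demonstrate.

## Units and conventions

Internally everything is in Angstrom, degrees, and k_BT at the
simulation temperature (default 300 K; k_BT(300 K) ≈ 0.5961 kcal/mol,
exposed in `nucleoslide.units`). Residue indices are 1-based within
each chain; base-pair indices are 0-based at the first base pair of
strand 1, with strand 2 paired antiparallel (its residue n_bp − b pairs
with base pair b). Protein chains contain only CA beads, DNA chains
only P/S/B beads; 5′-terminal nucleotides carry no phosphate.

## The sliding-invariant hydrogen-bond potential

Histone–DNA hydrogen bonds form between a set of structured histone
residues and the backbone phosphates at the half-integer superhelical
locations (SHLs), where the DNA minor groove faces the octamer. A
conventional Go-type contact pins each donor to one specific phosphate
and is therefore not invariant when the DNA slides. Here each native
bond i (donor Cα with reference geometry r₀, θ₀, φ₀ measured in a
reference structure) is instead scored against **every** phosphate j of
both strands:

    V_hb = −ε Σ_i Σ_j f(r_ij − r_i,0) g(θ_ij − θ_i,0) g(φ_ij − φ_i,0)

* r_ij — distance from the donor Cα to phosphate j;
* θ_ij — angle between the donor→phosphate vector and the chain
  direction Cα_{i−1}→Cα_{i+1} (the direction, not its reverse, is a
  documented convention; the angle magnitude is unaffected);
* φ_ij — angle at the phosphate between the donor Cα and the sugar
  bead of the same nucleotide;
* f(x) = exp(−x²/σ²), σ = 1 Å;
* g(x) = 1 for |x| ≤ Δφ; 1 − cos²(πx/2Δφ) for Δφ < |x| ≤ 2Δφ; 0
  beyond — continuous, with compact support; Δφ = 10°.

The narrow widths make each bond specific to a single phosphate
(occupancy contributed by non-native phosphates on the ideal fixture is
< 0.01), so there is no double counting; the compact support also
permits a hard neighbour cutoff at r₀ + 6σ per donor (truncation error
< 1e-15). Under a rotation-coupled advance by one base pair every
bound phosphate is replaced by its neighbour at identical relative
geometry, so V_hb is invariant — the property the test suite asserts to
< 1e-6 relative on the ideal fixture.

**Sign convention.** The double sum as written is non-negative, yet
the bonds stabilize the nucleosome and ε is calibrated as the smallest
strength that keeps the wrap stable; we therefore apply the attractive
sign (−ε per perfectly formed bond) and expose the raw non-negative sum
as the bond's *occupancy*. Default ε = 1.2 k_BT, with ≈1.2–2.4 k_BT the
range compatible with stability at moderate salt and disassembly at
high salt; all three parameters are configurable.

**Native-parameter extraction** averages (r₀, θ₀, φ₀) arithmetically
over the available copies of a bond — up to two reference structures
and the two C2-symmetric halves of each (`symmetrize=True` groups
donors through the structure's symmetric-pair table). Bonds present in
only some copies keep the available-copy mean. Angle means are plain
arithmetic means; native bond angles sit far from the 0°/360° wrap.
Flexible-tail donors are rejected: the geometry factors assume a stable
near-native protein conformation.

## Non-bonded terms

Excluded volume is a pure r⁻¹² repulsion over protein–DNA pairs,
σ_ij = 1.1·(R_i + R_j)/2; the 1.1 rescaling keeps tails from threading
between strands. The per-kind radii and the prefactor (default
0.2 kcal/mol, converted to k_BT) are generic, documented defaults —
forcefield-specific values come from whatever parameterization the user
works with and can be supplied per bead.

Electrostatics uses the Debye–Hückel form, E = l_B Σ q_i q_j
exp(−r/λ_D)/r in k_BT, with the Bjerrum and Debye lengths computed from
scipy's physical constants. The default permittivity is the empirical
solvent model used by three-site-per-nucleotide DNA forcefields,
ε(T, C) = (249.4 − 0.788 T + 7.2·10⁻⁴ T²)(1 − 0.2551 C + 5.151·10⁻² C²
− 6.889·10⁻³ C³); a constant-ε fallback (78.0) exists for analytic
tests. Phosphates carry −0.6e against other DNA charges (Oosawa–
Manning condensation) but −1.0e against protein charges; the two
interaction classes are evaluated separately rather than by mutating
bead state, which keeps the evaluation order-independent. Tail residues
take unit charges (+1 K/R, −1 D/E annotations supplied with the input);
globular charges are read from a user table.

The unwrapping observable counts phosphates within 12 Å (1.2 nm) of any
non-tail histone bead; linker phosphates that fall inside the shell are
counted, deliberately.

## Analysis coordinates

**DNA axis.** Ten contour splines (natural cubics, chord-length
parameterized) connect strand-1 phosphates of equal index mod 10. Each
segment is subdivided into ten equal parameter steps; for every
phosphate the nearest subdivision point of each contour is collected,
and the ten-point ring is plane-projected and circle-fitted (algebraic
Kåsa fit — exact on noiseless circles). The fitted center is the axis
point; tangents are normalized central differences. Two numerical
guards: the nearest-point search is restricted to candidates within
±7 bp of the phosphate's own position along the DNA (on a strongly bent
wrap the globally nearest point of an opposite-side contour can lie a
turn away across the tube), and ten base pairs at each end are excluded
from the valid window because the shortened end contours extrapolate
poorly.

**Symmetry axis.** Total-least-squares line through the midpoints of
the symmetric histone pairs (default pairing: protein chains with
identical residue layout are paired in order of appearance and matched
residue-by-residue; user-overridable). The direction sign points
toward the dyad side.

**Sliding coordinate ζ.** The angle between the symmetry-axis
direction and the vector from the histone-core centroid to the tracked
base-pair center (centroid of all available beads of the pair, both
strands), signed by the sense of rotation about the oriented superhelix
normal. The normal is the areal vector of the wrapped path (sum of
cross products of consecutive radius vectors over the central 147 bp),
oriented so the base-pair index increases counter-clockwise; a
least-squares plane normal would be tilted several degrees by the
superhelical pitch, the areal vector is not. With this convention ζ is
a rotational order parameter: its sign is preserved, not flipped, under
a mirror image whose reference normal is re-derived from the mirrored
geometry (the index direction is mirror-covariant); it flips when the
normal is transported covariantly.

ζ is converted to slid base pairs through a table of ζ(bp) computed
from the initial frame, restricted to the maximal strictly monotone run
around the tracked base pair, with linear interpolation inside and
warned linear extrapolation outside. Per-SHL sliding series use the
same machinery with a local zero (the tracked base pair's own initial
direction) because the global signed ζ wraps at ±180° inside a
~680° wrap; SHL k maps to bp offset round(10.17·k) by default
(10.0 on the ideal fixture).

**Rotation coordinate η.** The angle, right-handed about the local DNA
tangent, from the direction axis→histone-core-centroid to the direction
axis→strand-1-phosphate of the tracked base pair, unwrapped over the
trajectory by minimizing frame-to-frame jumps. Both vectors are
projected onto the plane normal to the local tangent; in addition the
centroid vector is measured in the plane of the wrap (its component
along the superhelix normal is removed). Without that de-pitching the
reference direction rotates by ≈0.46°/bp as the tracked base pair
advances — the centroid sits off the local disc plane by the
superhelical pitch — which would bias the rotation-coupling slope by
≈1.3%. Whether and how to project is not dictated by the coordinate's
verbal definition; this choice makes η purely rotational and is the
package's documented convention.

**RMSD.** Least-squares (Kabsch) superposition on the non-tail histone
core, RMSD over the DNA beads of the central 20 base pairs around the
dyad (cross-checked against MDAnalysis in the tests).

**Loop size ΔR.** The increase, relative to a reference frame, of the
distance between a base-pair center and the histone-core centroid;
ΔR ≳ 1 Å at an SHL indicates extra base pairs stored locally as a
bulge.

## Free-energy estimation and reweighting

Surfaces are plain histograms, F = −ln P in k_BT, minimum shifted to
zero; empty bins are masked rather than pseudocounted (pseudocounts
would fabricate free energies in unvisited regions). Default bins
0.25 bp × 9°. Because V_hb is exactly linear in ε and no other term
depends on it, an ensemble sampled at ε can be reweighted to ε′ with
per-frame weights w ∝ exp[−(ε′/ε − 1)·V_hb]; the effective sample size
(Σw)²/Σw² is reported and equals the frame count only at ε′ = ε. This
single-reference estimator degrades as |ε′ − ε| grows — the package
reports ESS precisely so users can judge that. Per-bin errors, when
requested, come from a seeded block bootstrap over independent
trajectories. Burn-in removal drops a fixed number of leading frames
per trajectory (ensembles relaxing from a prepared state carry an
initial-configuration bias on the order of 3·10⁷ MD steps in the
motivating simulations).

## Repositioning kinetics

Each repositioning route is a 3-state continuous-time Markov chain
from the crystal configuration through one intermediate (5-bp-shifted,
5-bp-rotated, or end-loop) to the 10-bp-shifted state. Rates that
cannot be measured directly are completed from detailed balance,
k_fwd = k_rev·e^(−ΔF), with ΔF the intermediate's free energy relative
to the origin state. MFPTs are exact solutions of the first-step
linear system; a seeded Gillespie simulator provides an independent
stochastic check (agreement within 3 SEM is asserted in the tests).
The shipped loop-route parameters are the measured inverse rates
(dissipation 8·10⁴ steps, cross-wrap diffusion 7·10⁶ steps) and a loop
formation cost of 15 k_BT, which give a crystal→10-bp MFPT of
≈2.3·10¹³ MD steps — orders of magnitude slower than the observed
rotation-uncoupled route. Times stay in MD steps throughout; no
mapping to physical seconds is attempted.

## The ideal-nucleosome fixture

The synthetic module builds a kinematic idealization with closed-form
ground truth, not a physical simulation — no forces, no dynamics:

* DNA beads on a superhelical path: radius 41.9 Å, pitch 25.9 Å per
  superhelical turn, rise 3.4 Å/bp, 147 wrapped bp (≈1.89 turns),
  straight tangent linkers (default 38 bp) and a 15-slot register
  margin at each end. The DNA twist is exactly 10.0 bp/turn so the
  rotation-coupling slope has the closed form 36°/bp (the physical
  ~10.17 is available by configuration).
* Strand-2 beads sit diametrically opposite strand-1 on the tube
  cross-section and the strand-1 phase at the dyad is 90°; with these
  two choices the 180° rotation about the dyad axis maps the bead set
  onto itself exactly, swapping the strands — grooves are deliberately
  not modelled.
* Pseudo-histone: one donor Cα triplet 5 Å inward of the bonded
  phosphate at every half-integer SHL (±0.5…±6.5 → 14 donors;
  positive SHLs bond strand 1, negative SHLs their C2-image phosphates
  on strand 2), plus a scaffold chain tracing the wrapped DNA
  centerline, plus azimuthally mirrored copies of both sets (180°
  about the superhelix axis). The mirrored copies place the core
  centroid exactly on the superhelix axis; without them the ~1.9-turn
  wrap has an unbalanced centroid that would wobble the rotation
  coordinate by a few degrees across a ±10 bp window. The scaffold
  beads trace the DNA centerline (not a physical octamer surface) so
  that every wrapped phosphate lies within the 12 Å contact shell, the
  geometry the contact-count observable is tested against on the
  linker-free fixture.
* Trajectories: `screw` advances the base-pair register along the
  fixed spatial path with the twist phase tied to the path slot
  (exactly rotation-coupled); `jump` advances the register while
  holding every base pair's phase (η constant by construction);
  `loop` propagates a bulge of 10 extra bp stage by stage from the
  high-index end, with a Gaussian radial bulge (3 Å, 3 bp width) at
  the moving boundary; `static` does nothing. Gaussian positional
  noise is added independently per bead and frame; all generators are
  deterministic under their seed.

**What passing tests on the fixture do and do not show.** The fixture
validates the machinery: exact sliding invariance of V_hb, the
360°/10 bp coupling of a screw trajectory, η constancy of jumps,
sequential SHL stepping of loop propagation, and contact-count
geometry. It does not validate any thermodynamics or kinetics of real
nucleosomes: there is no bending energy, no sequence dependence, no
thermal sampling, and its trajectories visit only the states they were
constructed to visit. Conclusions about real systems require CG or
atomistic trajectories produced elsewhere and fed through the same
analyses.

## Numerical choices and limitations

* Spline ends are handled by shortened contours and a trimmed valid
  window — no phantom extrapolation.
* ζ tables are strictly monotone by construction; conversion is exact
  on table entries (asserted to 1e-9).
* The η unwrap assumes < 180° of rotation between consecutive frames;
  sparsely saved trajectories can alias.
* The single-reference ε-reweighting cannot create samples where none
  were taken; masked bins stay masked.
* `coarse_grain` maps sugar/base beads to heavy-atom centroids; it is
  a geometric reduction, not a forcefield-specific site placement, and
  only inter-bead geometry feeds the terms implemented here.
* The acceptance script's problem sizes (21-frame sweep for the
  coupling slope; 3-state analytic kinetics) are the smallest at which
  the quantities are exact or deterministic; larger sweeps change the
  slope by < 0.1%.
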