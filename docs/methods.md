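# Methods

This note records the models behind each analysis, the defaults that
matter, the choices made where the design was genuinely open, and what the
synthetic generator does and does not emulate.

## Geometry and units

All coordinates are nm, times ps, charges e, potentials V. Boxes are
orthorhombic only, with z the membrane normal; triclinic inputs are
rejected because every analysis here (slicing, leaflet assignment, surface
binning) presumes a planar bilayer perpendicular to z. GRO files are read
as nm, PDB as Å and converted on input. Minimum-image displacements are
used wherever distances cross the box.

## Lipid registry and force-field detection

A lipid definition names the phosphorus atom, a headgroup reference atom,
the ordered tail chains, per-carbon hydrogens (atomistic), per-atom
charges and the all-trans tail extension. POPC/POPE/POPG/DPPC ship in
three flavour variants; a YAML/JSON config overrides or extends them.
When the all-trans extension is not given it defaults to 0.127 nm per C–C
bond along the chain axis — the per-carbon advance of an all-trans acyl
chain — times the number of bonds (0.47 nm per bond for Martini beads).

Flavour detection is structural: lipid residues with ≤ 15 particles are
coarse-grained (Martini maps ~4 heavy atoms per bead, so even a
two-tail lipid stays near a dozen beads, while even a united-atom lipid
carries tens of carbons); otherwise the presence of the definition's tail
hydrogens separates atomistic from united-atom. The 15-particle threshold
is a package choice; no standard value exists.

## Leaflets, flip-flops, symmetry

The bilayer centre is the geometric mean z of *all* atoms of the
bilayer's lipids (not only phosphorus): with asymmetric leaflet
populations a phosphorus-only centre would drift toward the heavier
leaflet and misclassify borderline lipids. A lipid is in the upper leaflet
iff its phosphorus sits above the per-frame centre (minimum image in z).

Flip-flop detection is hysteretic: an assignment changes only once the
phosphorus has crossed the centre by more than δ = 0.5 nm (default).
Without hysteresis, thermal jitter of lipids near the midplane — or
mid-translocation — would register as trains of spurious events; 0.5 nm
is well above per-frame z jitter and well below a leaflet half-thickness
(~2 nm), so real translocations are never missed.

Single vs double bilayers: sort phosphorus z and count gaps larger than
1 nm — one gap means two leaflet bands (single), three mean four bands
(stacked double); anything else is reported as ambiguous rather than
guessed. This is deterministic, seed-free, and assumes bilayers do not
straddle the periodic z boundary. In double bilayers the leaflets facing
the inner water compartment are labelled *anodic* when the inner
compartment's net ion charge is negative (the compartment cations were
moved out of); with no ions, positional inner/outer labels are used.
Leaflet symmetry per lipid type is the anodic-minus-cathodic (or
upper-minus-lower) count difference; one translocation steps it by ±2.

## Order parameters

- Atomistic: every individual C–H bond contributes one sample of
  (3cos²θ−1)/2; samples are pooled over bonds, lipids and frames before
  averaging (the alternative — per-lipid means first — weights lipids
  equally rather than bonds; pooling matches the ensemble-average
  definition).
- United-atom: for interior carbon C_i, molecular z along
  C_(i−1)→C_(i+1), y in the carbon plane ⊥ z, x completing the triad;
  S_xx and S_yy from the atomistic formula applied to the x/y axes, then
  S_CD = (2/3)S_xx + (1/3)S_yy. Terminal carbons are skipped. Collinear
  triplets (perfectly straight chain segments, where y is undefined) are
  skipped and tallied on the profile. Unsaturated carbons get no special
  case: the same axis construction is applied knowingly across double
  bonds.
- Coarse-grained: P₂ = ½(3cos²⟨θ⟩−1) with the *mean angle inside the
  cosine* — deliberately a different averaging order from the atomistic
  formula, implemented as stated for this representation and covered by a
  test that distinguishes the two on a bimodal angle distribution. Bond
  angles are folded to [0°, 90°] via |cos θ| before averaging; otherwise
  the antiparallel tails of the two leaflets average to ⟨θ⟩ ≈ 90° and P₂
  collapses to −0.5 regardless of order. Histograms use the unfolded
  angle in [0°, 180°), one sample per bond instance, 1° bins.

Carbon indexing is 1-based from the carbonyl end, the lipid-NMR
convention.

## Headgroup orientation

The headgroup vector runs from the phosphorus to the reference atom
(choline/ethanolamine N for PC/PE, a glycerol oxygen for PG). The lateral
angle is arcsin of the normalized component along the *outward* leaflet
normal (+z upper, −z lower), so "pointing away from the membrane" is
positive in both leaflets and the distribution is mirror-symmetric for a
symmetric bilayer. Means are arithmetic means of the lateral angle (the
distribution lives on (−90°, 90°), far from the wrap-around that would
warrant a circular mean). The axial angle is atan2(y, x) of the in-plane
projection mapped to [0, 2π); vanishing projections are recorded missing.

## Surface and thickness maps

Per leaflet, atom heights (outward-signed, relative to the bilayer
centre) are binned into a periodic lattice; each cell keeps its outermost
atom. In-place row-major Gauss–Seidel sweeps of

    φ[i,j] ← ¼·(A[i,j] + φ[i−1,j] + φ[i+1,j] + φ[i,j−1] + φ[i,j+1])

treat the height field A as the source of a discrete Poisson problem, so
iterating spreads each occupied cell into a smooth bump — simultaneously a
contour and a density map. Numerical choices: A is de-meaned over
non-hole cells before sweeping (a periodic Poisson source must be
zero-mean; a flat leaflet then correctly yields a uniform map instead of
amplified sweep noise); hole cells (zero occupancy) are never updated,
contribute nothing to neighbour sums, and render black; 50 sweeps and
0.1 nm cells by default; after sweeping, φ is min-max normalised over
non-hole cells to [0,1] and mapped blue→green→red. Sweeps are
single-threaded and deterministic; symmetry and translation equivariance
hold at convergence (and after normalisation), not mid-transient.
Thickness maps bin a reference atom per leaflet and take per-cell mean
upper minus mean lower height through the same pipeline; cells lacking
either leaflet are holes.

## Thickness, APL, gel fraction

Membrane thickness is the difference of mean reference-atom heights of
opposing leaflets; leaflet thickness is the distance of a leaflet's mean
reference height from the bilayer centre, so the two leaflet values sum
to the membrane value by construction. APL is lateral box area over
lipids per leaflet, recomputed each frame, so flip-flops and asymmetric
bilayers automatically produce distinct per-leaflet series. A lipid is
gel when **every** tail's first-to-last-atom distance reaches the
tolerance (default 0.9) times its all-trans extension — the all-tails
rule matches the hexagonally packed, fully extended picture of the gel
phase, where a single extended tail does not make a gel lipid. Gel
percentage is emitted both per leaflet and overall.

## Annular shell

A lipid is in the shell when any of its atoms is within the cutoff
radius of any molecule atom (minimum image in x, y, z). The production
path uses a periodic k-d tree; an O(N·M) all-pairs scan is kept in the
test suite as the oracle and must agree exactly. Control groups draw
without replacement from non-shell lipids with the shell's per-leaflet
composition (largest-remainder apportioning for fixed-n mode),
optionally excluding gel lipids; draws are reproducible under a seed.
Occupancy is per-frame membership with no temporal smoothing; type
ratios are time-averaged per-frame counts.

## Electrostatics and TMV

The box is cut into n slices (default 200) along z; per-slice charge is
averaged over the frame window and divided by slice volume to give
ρ(z) in e nm⁻³. The potential is the double cumulative trapezoid
Ψ(z) = −(1/ε₀)∫₀ᶻdz′∫₀^{z′}ρ, converted to volts and anchored to
Ψ(0) = 0 at the box bottom. Every atom must resolve to a charge through
the registry or an explicit charge map; anything unresolvable is a hard
error, because a silently dropped charge biases the integral. On a
plate-capacitor configuration the numerical ΔΨ converges first-order in
slice width (the only error is smearing the sheet charge over one
slice), within 1% of σd/ε₀ at 200 slices for typical geometries.

TMV (double bilayers only): the trajectory is cut into consecutive
windows (default 10 frames); each window's Ψ profile yields one TMV
value, the mean Ψ over the central 50% of the inner water compartment
minus the same for the outer (wrapped) compartment, time-stamped at the
window centre. Compartment bounds come from the mean phosphorus heights
of the four leaflets. Plateau averaging over the central half is a
package choice — the extraction point inside the compartments is not
standardised — and is exact whenever the compartments are field-free.
Positive TMV means the inner compartment is at higher potential;
conjugating all charges flips the sign exactly.

## Mixing entropy

Within each leaflet, every lipid's single nearest neighbour is found by
phosphorus–phosphorus minimum-image distance (k-d tree candidates,
re-scored with the same arithmetic as the brute-force oracle; squared
distances within 1e-9 nm² count as ties, broken by lowest index —
without a tolerance, last-ulp coordinate noise makes tie-breaking on
perfect lattices arbitrary). The (type, neighbour-type) pairs form the
joint matrix p(x, nb), normalised to 1; S = −Σ p(x,nb) ln p(x|nb) in
nats per lipid. The sign makes S_max = −Σ ρ ln ρ (natural log; the base
cancels in S/S_max) the attainable supremum: conditioning cannot exceed
the marginal entropy, so S ≤ S_max holds even in finite samples. A
leading system-size factor would cancel in the scaled value and is
dropped; raw S is reported per lipid. Leaflet results combine as
lipid-count-weighted means of S and S_max, scaled as their ratio.
Single-type compositions have S_max = 0 and raise a degenerate-
composition error rather than returning 0/0.

## Synthetic generator

The generator emulates the *geometry* of planar bilayers, not their
energetics: lipids sit on per-leaflet square lattices (near-square
divisor pairs of the per-leaflet count) at 0.64 nm² per site with
Gaussian lateral jitter (σ = 0.05 nm default — a small fraction of the
0.8 nm spacing, enough to break lattice degeneracy without disturbing
the arrangement), minimal 4-atom headgroup/backbone stacks, and two
registry-driven tails. All-trans (gel) tails are planar zig-zags
advancing 0.127 nm per bond so their end-to-end length equals the
registry's all-trans extension exactly; fluid tails advance half a step
with a lateral zig, reaching ≈ 50% extension. Atomistic hydrogens are
placed ideally tetrahedrally in the molecular frame, which makes the
atomistic and united-atom order-parameter routes agree analytically —
sin²(½·109.47°) = 2/3 is precisely the weight in the tensor relation.
Headgroup vectors realise a requested lateral angle (default 23°, a
typical fluid-phase PC value) at per-lipid random azimuth.

Double layouts stack two bilayers with 3 nm water gaps; an ion
imbalance of q places q/2 anions in the inner compartment and q/2
cations in the outer one — the charge separation produced by moving q/2
cations across, so the inner compartment is anodic. Scripted events
animate a flip-flop across the centre over 3 frames, swap random
cross-type lipid pairs (mixing schedules), or move cations back to the
inner compartment (imbalance decay). All randomness flows from the
fixture's seed field; identical fixture parameters are
bitwise-reproducible.

What passing tests on these fixtures do **not** show: behaviour under
thermal disorder (no Boltzmann sampling, no waters — ions are point
charges), curved or undulating membranes, realistic tail dihedral
statistics, or force-field-specific atom naming beyond the registry's
generic scheme. The fixtures validate the estimators' correctness and
conventions, not their statistical behaviour on real trajectories.

## Problem sizes in the test and acceptance runs

Analytic-limit checks use single hand-built lipids; oracle-equivalence
suites use 50 random 20-lipid frames; calibration fixtures use the full
2016-lipid (1008 per leaflet) demixed/random lattices over 10 seeds;
double-bilayer/TMV fixtures use 16 lipids per leaflet with 200 slices.
These sizes keep the whole suite under a minute while leaving sampling
error far below every asserted tolerance.

## Known limitations

- Leaflet assignment is z-height-based: vesicles, buckled membranes and
  pore-lining lipids mid-translocation are outside the model (hysteresis
  merely delays the call for the latter).
- The Gauss–Seidel transient is sweep-order dependent; only the
  converged field (and anything after min-max normalisation) is
  reference-frame honest.
- Charge density ignores polarisation and uses fixed point charges; the
  potential is the bare double integral, not a PME-consistent field.
- Gel classification by end-to-end extension cannot distinguish tilted
  gel (L_β′) from untilted gel; it sees only linearity.
- United-atom reconstruction applies the standard axis construction
  across unsaturated carbons, where it is known to be approximate.
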