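# Methods

`metadkit` re-implements, at desk scale, the free-energy and structural
analysis workflow used to study how the second β-hairpin (residues 60–66)
of the class II hydrophobin HFBI controls its multimerization: a
well-tempered metadynamics bias over two collective variables, surface and
profile reconstruction from the deposited hills with block-based
convergence and uncertainty analysis, density-contour definitions of the
closed (*c*) and open (*o*) hairpin states, and the per-structure
analytics (hydrogen-bond persistence, solvent-accessible surface area and
interfaces, nonpolar solvation, electrostatic sub-region averages, RMSF).
The all-atom molecular dynamics that produced the original data is out of
scope; every stage is instead exercised end-to-end on a synthetic system
whose ground truth is known analytically.

## Collective variables and the model landscape

The conformational transition is described by a distance-like CV δ (nm; in
the protein, the CA30–CA65 distance) and a torsion-like CV τ (degrees,
periodic; the C59–N60–CA60–C60 backbone dihedral).  The synthetic
stand-in for the molecular free-energy landscape is an analytic two-basin
potential on the (δ, τ) plane (`metadkit.potentials.hairpin_double_well`):
attractive Gaussian basins at (0.47 nm, −150°) and (0.81 nm, −60°) — the
closed- and open-state minima of the real system — with depths 14 and
10 kJ/mol and widths 0.10 nm / 40°, plus a soft quadratic confinement of δ
below 0.3 nm.  Depths and widths were fixed once to give a clear
two-state landscape with a thermally rare (≈5 kBT) barrier at 300 K; the
analytic form supplies exact energies, gradients, and — by Boltzmann
quadrature — exact reference free-energy profiles.

## Sampling and the well-tempered bias

Dynamics is overdamped Langevin (Euler–Maruyama) directly in CV space.
The bias schedule is the production schedule of the original study:
initial hill height ω = 1.2·T/T₀ kJ/mol, hill widths σ_δ = 0.1 nm and
σ_τ = 0.1 rad (5.73°), bias factor γ = 10, and a one-sided upper wall on δ
at 1.3 nm with κ = 2000 kJ/mol/nm² in the PLUMED convention κ(δ−a)²
(no ½).  Hills decay as h = ω·exp(−V/(kB·ΔT)) with ΔT = (γ−1)·T, V being
the bias already accumulated at the deposition point (computed exactly
from the stored hills).  The per-step bias force is read from a fine
auxiliary gradient grid (spacing σ/5, τ periodic) updated locally at each
deposition — the standard grid-buffered scheme of metadynamics engines.

Parameters with no counterpart in the original study are the Langevin ones:
D_δ = 2·10⁻³ nm²/ps, D_τ = 300 deg²/ps, timestep 0.2 ps, hills every
40 ps, runs of 100 ns.  The deposition interval matters: depositing much
faster than the basin-exchange time violates the quasi-equilibrium
assumption of well-tempered metadynamics and biases the recovered basin
free-energy difference low; 40 ps was chosen so that hills accumulate on
a near-equilibrated walker, verified with the convergence diagnostic
below.  Runs are bit-reproducible for a fixed seed, which is mandatory
and echoed in the output headers.

## Free-energy surfaces and profiles

`sum_hills` rebuilds V(δ, τ) on a grid (δ spacing 0.035 nm; the τ axis
defaults to the same node count — a 0.035° τ spacing would give ~10⁴
bins and is treated as a unit slip, configurable via `tau_bins`) and
applies the well-tempered estimator F = −γ/(γ−1)·V, min-shifted to zero;
a flag yields the raw summation instead.  Profiles over one CV are
Boltzmann-weighted marginalizations at 300 K via log-sum-exp
(min-projection available).  Convergence and uncertainty follow the
original block construction: profiles on cumulative [0, i·10 ns]
intervals, the mean/SEM (σ/√5) and CI95 (±1.96·SEM) over the last five,
and, as the convergence verdict, the absolute change of the profile value
at a chosen position (default the outer minimum, 1.25 nm) between
consecutive blocks, required below 1 kJ/mol for the last three blocks.

For validating recovery against the analytic reference, `metadkit.recover`
additionally averages five independent seeded replicas and reports the
across-replica SEM: cumulative blocks within one run are strongly
correlated and understate the uncertainty of a single trajectory.  Under
the defaults the recovered basin-to-basin ΔG of the model landscape
(analytic value ≈ 3.44 kJ/mol) carries a single-run standard error of
≈ 0.5 kJ/mol and a replica-mean error of ≈ 0.2–0.3 kJ/mol.  The pointwise
2D surface carries, in addition, a corrugation floor of ≈ 1.1–1.3 kJ/mol
RMS set by the 0.1-rad τ hill granularity; it does not decay with run
length and averages out in the marginal profiles.  Recovery comparisons
align the free additive constant by the mean offset over the compared
region (free energy is defined up to a constant; aligning at the global
minimum anchors the comparison to the noisiest single point).

## State regions from density contours

Joint densities f(δ, τ) come from unbiased sampling, binned on the FES
grid (histogram by default, Gaussian KDE with Scott bandwidth optionally;
τ is binned periodically).  A state region at coverage χ (default 0.9)
is the contour-volume set: cells sorted by density descending, cumulative
sum C, and the region is {cells with C ≤ χ·Z}, Z = Σf — kept verbatim, so
the enclosed mass is ≤ χ when a cell straddles the threshold.  Ties are
broken by stable (row-major) order.  Samples are then labelled c / o /
both / neither by cell membership.

## Structural analytics

Hydrogen bonds use the geometric criterion of GROMACS's tool (its
defaults, since the original work names the tool, not thresholds):
donor–acceptor distance ≤ 0.35 nm and H–donor–acceptor angle ≤ 30°, both
boundaries closed (a 10⁻⁹ slack absorbs float rounding at exact
boundaries); donors are N/O with a covalently attached hydrogen, acceptors
N/O, same-residue pairs excluded (a coordinate file carries no topology
for finer bonded exclusions).  Persistence is the bonded-frame fraction;
pairs at ≤ 5% are dropped.  Bonds are decomposed into intra-hairpin,
intra-chain, inter-chain and hairpin–solvent groups around the hairpin
residues 60–66; the solvent group is reported as mean H-bonds per frame
per residue rather than per-pair persistence.

SASA is Shrake–Rupley with 960 deterministic golden-spiral test points
per atom, probe 0.14 nm and Bondi radii (single-atom closed form
4π(r+r_p)² reproduced to <0.5%; exactly duplicated atoms keep surface
only on the first-listed copy, a deterministic tie-break for degenerate
fixtures).  The interface area of a chain pair is SASA_i + SASA_j −
SASA_{i,j} with the isolated-chain terms computed with all other chains
removed; no ½ factor is applied.  Distance maps take per-frame minimum
heavy-atom distances per residue pair, averaged over frames; contacts are
pairs at ≤ 0.45 nm.  Nonpolar solvation is G = γ·SASA + b with
γ = 0.0226778 kJ/mol/Å² and b = 3.84982 kJ/mol (the polar
Poisson–Boltzmann term is out of scope).  Welch's t-test (scipy,
Welch–Satterthwaite df) compares per-frame energies between states.
RMSF splits a trajectory into 5 disjoint blocks, superposes each frame on
the block's first frame by a CA-only least-squares fit, and reports the
residue-averaged positional standard deviation as mean ± SEM over blocks.

## Potential grids

Electrostatic potential maps are consumed as OpenDX scalar grids (APBS
dialect, via gridData); the Poisson–Boltzmann solve itself is external.
For testing, an analytic Debye–Hückel generator produces screened-Coulomb
grids, φ = f/ε_r·Σ q_i·e^{−κr}/r with κ from the ionic strength (150 mM →
λ_D ≈ 0.79 nm at 300 K).  The owned computation is the cuboid sub-region
average (default sides 2.0 × 2.0 × 1.0 nm, user-supplied orthonormal
axes): trilinear interpolation at a regular 21³ lattice inside the box,
mean per frame, mean ± s.e.m. across frames.  Interpolated lattice
sampling, rather than voxel counting, keeps the average
resolution-robust.

## Synthetic fixtures and what passing tests show

`metadkit.fixtures` builds multi-model PDB fixtures from minimal
five-atom backbone residues placed analytically, with designed
donor→acceptor H-bonds present in stated fractions of frames (the
acceptor carbonyl O is steered onto the donor's N–H axis at the requested
distance/angle) and tunable inter-chain gaps.  These fixtures make the
expected output of every analytic exact by construction.  They emulate
geometry only: no realistic side chains, no solvent boxes, no force-field
energetics, no thermal noise in the coordinates.  Likewise the Langevin
system emulates the free-energy landscape and bias schedule, not the
molecular kinetics.  Passing tests therefore demonstrate that the
estimators and algorithms are implemented correctly and behave as theory
predicts on known ground truth — not that the biological conclusions of
any particular protein system are reproduced.

## Numerical choices and limitations

- kB = 0.008314462618 kJ/mol/K; energies kJ/mol, lengths nm at the CV
  level and Å at the PDB level, angles degrees externally.
- log-sum-exp guards all Boltzmann marginalizations; T → 0 reduces to
  min-projection (verified at T = 1 K).
- Minima are located on a 3-point moving-average smoothing of the
  profile, snapped to grid nodes, ties toward smaller coordinate; an
  expected position with no local minimum within the search window is
  flagged missing, never substituted.
- HILLS/COLVAR numbers are written with 12 significant digits; write∘read
  is the identity at that precision.  PDB coordinates round-trip at the
  format's 3 decimals.
- The walker aborts (rather than silently clamps) if δ leaves its sanity
  domain or energies go non-finite.
- Known limitations: single-walker bias only (no multiple-walkers, no
  reweighting estimators); no mmCIF/XTC/DCD; no polar solvation; no
  automated β-sheet plane detection for the cuboid (axes are supplied by
  the caller); crystal-structure checks require a PDB file the user
  provides.
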