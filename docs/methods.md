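# Methods

`contrast_screen` locates dynamically fluctuating domains in a large
C6-symmetric protein assembly by screening rigid-body models against two
solution-scattering channels: SAXS, which constrains the overall shape, and
inverse contrast-matching SANS (iCM-SANS), which sees only the hydrogenated
component of a selectively deuterated complex and therefore constrains where
that component sits.  This note records the models, the numerical choices
and the limitations.

## Scattering model

Profiles are computed at residue resolution with the Debye formula

    I(Q) = Σᵢ Σⱼ bᵢ(Q) bⱼ(Q) sin(Q dᵢⱼ)/(Q dᵢⱼ),

one bead per residue at the residue's mass-weighted centroid (Cα placement
is available for speed).  Excess scattering lengths are

* X-ray: residue electron count − solvent electron density (0.334 e/Å³)
  × residue volume;
* neutron: Σ of atomic coherent scattering lengths, with non-exchangeable
  hydrogens mixed as (1−d)·b_H + d·b_D for biosynthetic deuteration d, and
  exchangeable hydrogens (backbone amide plus side-chain O-H/N-H/S-H of the
  neutral form) mixed according to the solvent D₂O fraction (exchange
  fraction default 1.0), minus solvent scattering-length density × volume.

Residue volumes are Jacrot's solution volumes (Rep. Prog. Phys. 39, 911,
1976), the standard table for contrast-variation work.  With them, 75 %
deuteration in 100 % D₂O leaves a mean residue excess of ~0.9 % of the
hydrogenated magnitude — the quantitative content of inverse contrast
matching, and the reason the deuterated components vanish from the SANS
channel.  No explicit hydration shell is modeled (CRYSOL-style shells are a
different tool); absolute χ² values against real data are therefore
comparable in rank and order of magnitude, not digit for digit.

Each bead optionally carries a Gaussian form factor exp(−(Q R_b)²/2) with
R_b the equivalent-sphere radius of its residue volume (the default;
`point` turns it off).  Two evaluation paths exist: an exact O(N²·n_Q)
kernel for models up to ~3000 beads, and a weighted pair-distance histogram
(bin 0.25 Å, first-moment bin centers) for larger point-bead models; the
histogram path reproduces the exact sum to ≲0.2 % on smooth profiles.
Screening exploits the exact C6 symmetry of candidates: the core–core pair
sum is precomputed once and mobile-domain terms reduce to four cross sums
over one asymmetric unit, reproducing the full Debye sum to ~1e-13 relative
at ~5 % of the cost (asserted by a dual-route test).

## Fits and scores

* **Guinier.** ln I is fitted linearly against Q²; the window grows from
  the low-Q end (minimum 5 points) for as long as the window's own fit
  satisfies Q_max·R_g ≤ 1.3, and the last valid window is kept.  Growing
  from the low end matters: profiles with flat high-Q tails otherwise admit
  a spuriously "valid" full-range window with a badly biased R_g.
  Intrinsic limitation: for a uniform sphere the Guinier approximation
  itself overestimates R_g by ~1.5–2 % at the 1.3 limit (verified on the
  analytic form factor); this is a property of the estimator, not of the
  implementation, and is inherited by any tool that fits ln I linearly.
* **χ².** Reduced χ² = (1/(N−1)) Σ[(c·I_calc − I_exp)/σ]² with the scale c
  minimizing χ² in closed form; an additive background term is available
  behind a flag (off by default).  Computed curves are interpolated onto
  the experimental grid linearly in (Q, log I).
* **Smearing.** Gaussian resolution smearing with σ = ΔQ(Q), a scalar or a
  callable; ΔQ = 0 is the identity.
* **Forward-scattering contributions.** For an AUC-characterized mixture,
  component i contributes t_i = r_i·M_i / Σ r_j·M_j of I(0) (weight
  fraction × molar mass), which is how minor heavy species dominate
  scattering.

## Candidate generation and screening

The rigid core is assembled by proper-rotation (Kabsch) superposition:
six copies of a ternary subcomplex are placed on the hexamer through their
shared anchor domain, then full-length dimers are superposed through their
C-terminal domains.  The second step deliberately does not resolve steric
overlap — detecting that the crystal arrangement of the N-terminal domains
collides with the B ring is what motivates the pose search.

Mobile-domain poses are enumerated on a cylindrical grid (r, θ, z around
the core, quasi-uniform seeded orientations), the same asymmetric-unit pose
replicated to all six dimers.  Clash rejection uses a KD-tree with a 3.5 Å
inter-body bead cutoff (residue-resolution surrogate for heavy-atom
exclusion).  Screening is staged: SAXS χ² first (default ceiling 10.0),
iCM-SANS χ² only for survivors (ceiling 3.0), with refined (6.0, 1.5) and
post-linker (5.0, 1.5) stages when linkers are present.

Linkers (default 20 residues, the length of the canonical inter-domain
linker) are first tested for feasibility — anchor distance ≤ n_res × 3.8 Å,
boundary inclusive — then built as guided self-avoiding random walks with
exact 3.8 Å virtual bonds; the distance-to-target after each step is
cone-sampled within the band still reachable by the remaining beads, which
guarantees closure (final bead 3.0–4.5 Å from the far anchor) whenever the
anchors are feasible.  Default 100 conformers per model; the conformer with
the smallest SAXS χ² is kept.  This replaces fragment-based loop modeling,
which is out of scope.

## Classification

The complex frame puts the origin at the core COM; the symmetry axis is the
unique eigenvalue's eigenvector of the gyration tensor (the two radial
eigenvalues of a C6 assembly are degenerate), oriented toward the B ring;
the azimuth origin is the first B protomer.  The reference plane z₀ is the
top of the B ring (maximum z of B-component beads).  Candidates are typed
by where the two mobile-domain COMs fall: both strictly below z₀ (Type 1),
one below (Type 2), neither (Type 3).

Cells are half-open boxes in (r, θ folded into one 60° sector, z): rings U
(above z₀) and L (below), each θ-split into cells 1 and 2.  Cell geometry
is explicit and overridable; a data-driven constructor derives ring extents
from survivor COMs with the θ-split at the sector midline.  Group labels
combine the cell pair with linker connectivity through a configurable
sector-offset table; the shipped default maps (U1,L1) offsets 0/1/2 to
groups I/II/III and (U1,L2) offsets 0/1 to IV/V, (U2,L2) to VI, with
swapped-role patterns yielding the primed groups III′ and V′ only.  The
offset table is a best-effort default — the published grouping's exact
offsets are not recoverable from the primary text — and is expected to be
overridden when calibrating against a specific system.

## Trajectory verification

Multi-frame models (MD output or synthetic trajectories) are analyzed
with: COM-RMSF per domain after least-squares alignment on the rigid core;
dynamical cross-correlation maps c_ij/√(c_ii c_jj) with
c_ij = ⟨(r_i−⟨r_i⟩)·(r_j−⟨r_j⟩)⟩, computed after per-dimer alignment so the
six dimers are directly comparable (zero-variance beads are masked with a
warning, not NaN-propagated); per-frame χ²(t) for both channels; and the
ensemble-averaged profile (unweighted mean intensity over frames) whose χ²
and time-averaged Guinier R_g feed the asterisk grading: for χ², 0/1/2
asterisks at χ² ≤ χ₀², ≤ 1.2 χ₀², beyond (χ₀² = 5.0 SAXS, 1.5 SANS); for
R_g, at |ΔR_g| ≤ Error, ≤ 2×Error, beyond.

## Synthetic data

The generator builds the study architecture at desk scale: two stacked
hexameric rings (the double-doughnut core, 30 beads per domain), a B ring
whose top defines z₀, a twelve-domain collar, and twelve mobile N-domains
(two per dimer, 20 beads each) at configurable ground-truth poses — one
above the reference plane, one below, echoing the U/L pairing of screened
survivors.  Domains are deterministic Fibonacci-shell bead clusters with
residues drawn (seeded) from typical amino-acid abundances, so contrasts
behave like protein.  One asymmetric unit is built and replicated by exact
60° rotations, so the core is C6-symmetric to machine precision.

Simulated experiments apply relative Gaussian noise growing linearly from
2 % at low Q to 10 % at Q_max over Q ∈ [0.006, 0.12] Å⁻¹ (60 points),
echoing typical SEC-SAXS counting statistics; the reported σ is the
generating width.  Decoy sets perturb the truth poses cylindrically (up to
±20 Å in r, ±50° in θ, ±30 Å in z, minimum displacement 8 Å, clash-free,
orientation randomized).  Jiggle trajectories hold the core fixed and move
each mobile domain's COM on a stationary AR(1) process (decay 0.9, per-axis
variance a²/3 for target 3-D RMS amplitude a) with small random
re-orientations; trajectory estimators recover the generating amplitude to
a few percent at 10⁴ frames.

What the synthetic data does *not* emulate: real folds and sequences,
inter-particle effects, hydration, instrument-specific smearing, and the
conformational coupling of a physical force field.  Passing tests therefore
demonstrate the correctness of the screening and analysis machinery, not
the biological conclusions reachable only with measured profiles and
deposited structures.

## Problem sizes

Defaults are chosen for a single workstation core: the toy complex carries
834 beads (594 core), decoy-recovery runs use 500 decoys + truth, and
trajectory analyses use tens to hundreds of frames (10⁴ for statistical
calibrations of RMSF/DCCM).  All generators and the screen are
deterministic given seeds.
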