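# Methods

## Scope and model of the data

`detscreen` analyses time-ordered coordinate frames of an annotated molecular
system in an orthorhombic periodic box. Internally everything is in nm and
ps; Å enter only at the PDB boundary. A *molecule* is a contiguous run of
atoms sharing a molecule id — no bond perception is attempted, which is
sufficient because every statistic in the package is defined on whole
molecules or residues. Atoms carry a molecule class (protein / lipid /
detergent / solvent / ion), detergent atoms may carry a head or tail role,
and the heavy-atom test is element ∉ {H, D}, falling back to the first
alphabetic character of the atom name when the element column is absent.
Triclinic cells are rejected explicitly: the screening systems of interest
are cubic, and supporting only orthorhombic boxes keeps the minimum-image
kernel exact and trivial to verify.

## Periodic geometry

Minimum-image displacement uses the component-wise `d − L·round(d/L)` form,
valid for arbitrary separations in an orthorhombic box. Fixed-cutoff contact
queries go through a cell list whose cell edge is at least the cutoff
(`n_c = floor(L/c)` cells per axis, minimum one), so a query only visits the
27 wrapped neighbour cells; axes with fewer than three cells degrade
gracefully by deduplicating the neighbour set. Cutoffs must be below half
the smallest box extent, otherwise minimum-image contacts are ambiguous and
the call raises.

The contact boundary is **closed** (distance ≤ cutoff counts). The 6 Å
criterion in the screening literature is stated without a boundary
convention; the closed choice makes exact-boundary fixtures deterministic.
Both the detergent side and the lipid side of the contact test use heavy
atoms only by default (configurable), since the criterion is stated for
non-hydrogen atoms on the lipid side and hydrogen positions add noise
without information.

## Invasion statistics

A detergent molecule is *in contact* in a frame iff any of its heavy atoms
is within the cutoff (default 0.6 nm) of any lipid heavy atom. Two framings
are computed side by side because both are used when screening:

* per-system: `100 × contacting / total` detergent molecules, per frame,
  averaged over the analysis window (default: the second half of the
  trajectory, since screening runs report a production average without an
  explicit window);
* per-lipid: for each lipid, the time-averaged percentage of detergent
  molecules in contact with that lipid, ranked descending, summarised by
  the mean over lipids with the SD across lipids as the error bar.

Contacts are counted per *molecule*, not per atom (an atom-counting variant
is a config option without a literature anchor), and assignment is not
exclusive — a detergent touching two lipids counts toward both, the
simplest reading of "detergent around each lipid".

Equilibration is assessed the way long screening runs are checked: the
metric is averaged in windows `(t_{k−1}, t_k]` between user-supplied
checkpoint times (e.g. 1000/1500/2000 ns in the real protocol), and the
system counts as equilibrated iff the max pairwise difference among the
last k (default 3) checkpoint values is within tolerance. Checkpoint times
are taken as input rather than hard-coded, because sensible values depend
entirely on the run length.

## RMSF and ΔRMSF

Each frame is superposed onto a reference by least-squares rigid-body
fitting (Kabsch via SVD with the determinant correction; improper rotations
are never returned, and collinear point sets raise because the optimum is
ambiguous). RMSF_i is the root-mean-square deviation of residue *i*'s
representative atom from its post-fit time mean. The representative atom is
the Cα when present, else the centroid of the residue's heavy atoms; the
fitting selection defaults to protein heavy atoms (Cα-only available). The
default fluctuation reference is the iterated mean structure (fit →
recompute mean → refit to a 10⁻⁶ nm mean shift, max 10 iterations);
first-frame and external references are provided, the latter because a
membrane-equilibrated structure is the natural ΔRMSF baseline.

ΔRMSF subtracts a reference RMSF *profile* residue-wise (the scalar
"average ΔRMSF" is its mean). Residue-wise subtraction is the richer
interpretation; the residue masks used in averaging are configurable so
TM-only summaries can be produced when region definitions are available.

One numerical property worth knowing: rigid-body fitting absorbs six degrees
of freedom, so on a drift-free synthetic protein fitted RMSF is biased low
by ≈ √(1 − 2/N) for N residues. Parameter-recovery tests therefore disable
fitting (the OU generator has no global motion by construction); analyses of
real trajectories should keep fitting on, and ΔRMSF is unaffected to first
order because the bias cancels between the two profiles.

## Regioselectivity

Per residue, head (tail) occupancy is the fraction of frames in which at
least one head-role (tail-role) detergent heavy atom lies within the cutoff
of any of the residue's heavy atoms. Occupancy was chosen over raw contact
counts because it is robust to detergent copy number. The same 0.6 nm
cutoff as the invasion statistic is used by default (no separate
protein-contact cutoff is established in the literature), independently
configurable. Region summaries (named residue ranges from a flat TOML file)
report mean head/tail occupancy and the head:tail ratio, which is NaN when
the tail occupancy is zero. The occupancy statistic is this package's
operationalization of published head/tail interaction imagery and is
labelled as such in outputs.

## Synthetic generators and what they do (not) show

The generators reproduce the *statistical structure* the analyses assume,
each with a closed form usable as an exact oracle; they are not physical
simulations (no force field, no electrostatics, no micelle formation) and do
not attempt to reproduce published per-detergent percentages, which come
from microsecond all-atom MD of ~40k-atom systems.

* **Slab Monte Carlo** — non-interacting detergent particles in a square
  well U = −ε inside a slab of width h (the "bilayer"), periodic in all
  axes; single-particle Metropolis moves (uniform in a cube of edge
  2·step) satisfy detailed balance, so the stationary slab occupancy is
  exactly f_eq = h·e^ε / (h·e^ε + (L_z − h)). Defaults mirror the real
  screening composition: 12 nm cubic box, 80 lipids on two leaflet grids at
  z_c ± h/4 (placement is arbitrary and irrelevant to the closed form),
  240 detergents (3:1 detergent:lipid), step 0.5 nm. ε is the only
  per-species dial and maps monotonically onto invasion.
* **OU protein** — each residue's each coordinate follows
  x ← x̄ + a(x − x̄) + σᵢ√(1−a²)ξ with a = e^(−1/τ), started in
  stationarity, so RMSF_i = σᵢ√3 exactly and the lag-1 autocorrelation is
  e^(−1/τ). Default τ = 5 frames, σ ≈ 0.05 nm — the scale of well-folded
  per-residue fluctuations.
* **Regio placement** — per frame each labelled particle draws a uniform
  residue and makes contact with the propensity of that residue's range
  (placed uniformly inside the contact sphere), else goes to bulk (> 1.5×
  the contact distance from every residue); the expected occupancy of
  residue i with k same-role particles is 1 − (1 − pᵢ/n)^k. Residue
  pseudo-atoms are placed ≥ 2 nm apart so contact spheres do not overlap.

Statistical-error estimates for the Monte-Carlo occupancy use block
averaging (10 blocks by default) to absorb autocorrelation.

Passing tests on these toys show the *estimators* are correct and the
pipeline is deterministic; they say nothing about force-field accuracy,
sampling convergence of real MD, or detergent chemistry beyond the two
planted axes.

## Screen orchestration and ranking

`run_screen` characterises each candidate by (ε, σ-scale), simulates both
toy systems per candidate from deterministically split sub-seeds of one
global seed, and analyses them. The screen's membrane geometry deliberately
differs from the generator default: the slab (halfwidth 1 nm) is tiled with
lipids on a 0.6 nm grid so that any point inside the slab is within the
cutoff of a lipid and the invasion percentage tracks 100·f_eq — this makes
ε interpretable in invasion percent and lets one config straddle the 45 % /
25 % reporting thresholds. Desk-scale default sizes (20 000 MC steps
sampled every 40; 4 000 OU frames over 27 residues) keep a full 8-candidate
screen around two minutes while holding the statistical error of the mean
invasion below ~1 % and of average ΔRMSF below ~1 mnm.

The two axes are combined by rank aggregation: invasion rank (1 = highest
%) plus stability rank (1 = lowest average ΔRMSF; exact ties share
mid-ranks), lower sum better, ties broken by better stability rank then
lexicographic name. Rank-sum was chosen over any metric scalarization
because the two axes have incommensurable units and because it reproduces
the published screen's stated top-2 from the published orderings alone; it
depends only on ranks, hence is invariant under monotone transforms of the
raw metrics. Classification uses invasion % > 45 (the published grouping
boundary) for invaders and stability rank ≤ ⌈n/2⌉ for stabilizers; the 25 %
boundary annotates notably weak invaders in reports but is not a second
gate. Alternative scalarizations (e.g. z-score sums) are deliberately not
defaults.

A corner case worth noting: with a *tied* mid-rank exactly at the median
boundary (e.g. 4.5 with n = 8), the ≤ ⌈n/2⌉ rule excludes the tied pair
from the stabilizer half. The published-screen classification therefore
uses the untied ordering of the comparable pair (MEGA-9 listed before
LMNG), which is also what raw ΔRMSF values would produce; the combined
*ranking* keeps the tie, where it is harmless.

## Degenerate inputs and errors

Empty atom groups, missing metrics, cutoffs ≥ half-box, windows without
frames, sub-2-frame RMSF windows, mismatched residue sets (reported with
the symmetric difference), overlapping or out-of-bounds regions, checkpoint
times beyond the series, and trajectories without role-labelled detergent
atoms all raise `ValueError` with a message naming the offender. The
zero-particle regio generator is valid (a protein-only trajectory), but
feeding its output to the contact map raises, since an occupancy map
without any labelled detergent atoms is meaningless rather than zero.

## File formats

PDB (read/write, multi-model via MODEL/ENDMDL, CRYST1 box) and GRO (read)
go through biotite. The extended-XYZ dialect is this package's
trajectory-exchange format: atom count, a `time=<ps> box=<Lx>,<Ly>,<Lz>
units=nm` header, then `name x y z` lines with four-decimal nm coordinates;
writer output is deterministic, so write→read→write is byte-identical. The
name field written by this package is a compound
`species:class:molecule_id:residue_index:atom_name[:role]` token, making
files self-describing; plain third-party names are accepted with an
annotation mapping. Reports are plain CSV/JSON/text, and the run manifest
contains the full config so any report can be replayed bit-exactly.

## Known limitations

* Orthorhombic boxes only; no XTC/DCD readers in v1.
* Molecule identity relies on input annotation, not bond perception.
* The toy generators have single-site detergents for invasion (the contact
  statistic is per-molecule, so multi-site realism adds nothing to
  correctness testing) and a static protein in the regio generator.
* Neither axis predicts retention of enzymatic activity — selecting for
  both axes nominates candidates, it does not replace activity assays.
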