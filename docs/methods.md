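# Methods

This note documents the models and procedures implemented in confwire, the
assumptions behind them, the parameters that matter, and what the synthetic
validation does and does not establish.

## Coordinate conventions

All coordinates are in Å. Structures are assumed membrane-aligned: the
membrane normal is z and the membrane center is z = 0. This frame is what
gives the intracellular-bulk criterion (water oxygen z < −15 Å) its
meaning; inputs in other frames must be pre-transformed. Atom indices are
0-based internally; author residue numbering is preserved everywhere a
residue is named. The PDB reader is fixed-column, takes only the first
MODEL, drops alternate locations other than blank/'A', and rejects
insertion codes outright (they do not occur in the transmembrane regions
this package targets, and silently renumbering them would corrupt
selections).

## Water-wire detection

**Hydrogen-bond criterion.** Two waters are connected when any hydrogen of
either lies within `d_hb` = 2.5 Å of the other's oxygen. This pure
distance criterion is deliberately minimal: it is cheap, symmetric, and at
2.5 Å the H···O distance is only satisfiable in genuinely hydrogen-bonded
geometries, so an angular term adds little. Whether a donor-H–acceptor or
an O–O reading of a single-distance criterion is intended can be ambiguous
in the literature; both are implemented (`hbond_definition` of
`H-acceptor` or `O-O`, the latter with a 3.5 Å cutoff), the H-acceptor
form is the default — 2.5 Å is a plausible H···O bond length but far too
short for O···O — and the choice is recorded in every run manifest.
Waters lacking hydrogens automatically fall back to the O–O form.

**Graph construction.** One node per water (keyed by oxygen atom index),
edges from a KD-tree neighbor search that provably equals the all-pairs
definition (property-tested against brute force up to 500 waters). Seed
attachment — oxygen within `d_seed` = 3.5 Å of any seed atom — is a
separate rule from water-water bonding, and protein-water H-bonds are
never graph edges. Periodic boundaries are ignored by default since the
pathways of interest sit in the protein interior; a minimum-image option
exists for synthetic boxes.

**Search.** Breadth-first search from a virtual seed node through the
seed-adjacent waters, stopping at the first water below the bulk plane.
Path length is counted in water molecules (N_w); the seed→water and
water→bulk attachments are not counted. BFS guarantees minimal N_w;
expansion in ascending oxygen-index order makes the tie-break among
equal-length pathways deterministic. A seed-adjacent water that is already
in the bulk set is a valid single-water pathway.

**Statistics.** `f_path` is frames-with-pathway over frames-analyzed. The
N_w histogram is reported descriptively (mean, SD); no distributional form
is assumed or enforced. Route classification labels each pathway by the
marker residue (e.g. the Q113-lined inner route vs the E202-lined
interfacial route) whose atoms come nearest any path-water oxygen, with a
6 Å ceiling beyond which the label is `other`; because route percentages
can be quoted per pathway or per frame, both denominators are reported.
Occupancy maps count, per voxel, the fraction of frames with at least one
water oxygen inside (presence mode — a voxel saturates at one count per
frame), and export as OpenDX text with a default display isovalue of 0.35.

## Rotamer clustering

χ angles are signed dihedrals (IUPAC convention, degrees in (−180, 180]),
computed from the standard side-chain atom quadruples. Clustering uses
k-means on the (sin χᵢ, cos χᵢ) embedding: the embedding is continuous
across the ±180° seam, so a single angular mode is never split by
wraparound — verified by property test. K defaults to 5 (the number of
side-chain states the internal-glutamine analysis distinguishes) but is
user-set; the method itself is a package choice, so reproduction of any
particular published cluster boundary is not claimed. Ten restarts with a
fixed, logged seed make results deterministic; labels are renumbered by
descending population and centers are circular means. A frame mask derived
from cluster labels can condition both the trajectory scan and the
occupancy map, giving per-rotamer water maps.

## Conformational comparison

Difference distance matrices ΔD = D_A − D_B over Cα pairs are computed
without any superposition and are invariant to independent rigid motions
of either structure (verified to 1e-9 Å over random transforms) — that
invariance is the reason to prefer them when two refinement pipelines or
crystal forms are compared. Signed values are retained; exports can be
restricted to helix residues via the packaged annotation table.

Rigid superposition is the Kabsch SVD solution with the proper-rotation
sign correction (reflections are never returned). The default alignment
subset is the helix B/F/G/I core (35–47, 153–164, 174–190, 215–223),
segments that hold their internal geometry across the conformations of
interest; per-residue displacement is then read over all common residues.
Fewer than three or collinear alignment points raise a degenerate-fit
error.

Inverted-repeat RMSD compares Repeat 1 (helices B–I) and Repeat 2
(helices J–Q) within and across structures. The residue-level pairing
between repeats is not uniquely defined by sequence; the packaged
correspondence table is a curated default pairing equal-length helix-core
segments, is user-editable, and repeat-RMSD outputs should be read as
correspondence-dependent.

## DEER modeling

**Kernel.** K(t, r) = ∫₀¹ cos[ω_dd(1 − 3x²)t] dx with ω_dd = 2π·52.04
MHz·nm³/r³ (free-electron g, the standard nitroxide constant). Evaluated
via Fresnel integrals; a direct Simpson quadrature of the defining
integral serves as an independent oracle (agreement to 1e-8 over the full
(t, r) range of interest).

**Signal models.** Four-pulse: V(t) = exp(−k_bg|t|)·[1 − λ + λ·∫P(r)K(t,r)dr]
with a 3-D homogeneous-background exponential (one rate per signal) and a
single-Gaussian P(r) truncated to r > 0 and renormalized. Five-pulse: the
artifact echo is modeled as an amplitude-scaled (η), time-shifted
(t_shift) copy of the four-pulse forward model sharing (r₀, σ), the whole
renormalized to V(0) = 1. The ∫P(r)K dr integral is discretized on a
201-point grid spanning r₀ ± 6σ for simulation (91 points during
fitting), with weights normalized to sum to one.

**Fitting.** Trust-region nonlinear least squares over both traces
simultaneously; (r₀, σ) shared, per-signal λ and k_bg, five-pulse η and
t_shift, and a free amplitude scale per signal. The scale parameters make
the fit exactly invariant to uniform rescaling of V and absorb the small
error made when a sampled trace has no point exactly at t = 0. Bounds
follow the parameter domains (λ, η ∈ (0,1); t_shift ≥ 0 — the artifact
trails the main echo); multi-start (default 5, seeded) guards against
local minima. The parameter covariance is s²(JᵀJ)⁻¹ from the Jacobian at
the optimum and the unbiased residual variance; a singular JᵀJ falls back
to the pseudo-inverse with a logged warning.

**Confidence bands.** For each r, Var[P(r)] = ∇P·Cov(r₀,σ)·∇Pᵀ with a
central-difference gradient; bands are point ± z(0.95)·SE floored at zero,
which is why they can look non-Gaussian even for a Gaussian P(r). These
are first-order (delta-method) pointwise bands: they slightly undercover
exactly at the distribution peak, where ∂P/∂r₀ vanishes and the curvature
of P in σ is strongest — Monte-Carlo checks over noise replicates place
realized coverage of the 95% bands around 93–95%, within the intended
90–99% envelope, but users should not read the peak-point band as exact.

## Synthetic data and what passing means

The wire generator plants a geometrically exact chain: O–O spacing 2.7 Å,
bridging hydrogens placed along the O→O vectors (O–H 0.96 Å, so the
H···O distance is 1.74 Å, 0.76 Å inside the cutoff), first oxygen 3.0 Å
from the seed amide, last oxygen 0.5 Å below the bulk plane. Broken
frames park one chain water far outside every cutoff. Noise waters keep
≥5 Å from everything (jitter ±0.2 Å preserves every margin by
construction), so they can never bridge and the per-frame truth is exact
rather than probabilistic. Defaults (300 frames, p_connect 0.5, chain
length 5, 20 noise waters) mirror the scale on which per-frame detection
statistics are meaningful at desk scale. What this shows: the detector's
geometry, graph, and search are correct against planted truth. What it
does not show: robustness to thermal H-bond geometry fluctuations,
near-cutoff ambiguity, or PBC effects of real MD water — real
trajectories live near the criterion boundary in a way this generator
deliberately avoids.

The structure-pair generator uses an idealized α-helical Cα trace
(2.3 Å radius, 100°/residue, 1.5 Å rise) with a rigid subset displacement
and an optional random global pose; it exercises superposition and DDM
logic, not real packing. The DEER generator adds i.i.d. Gaussian noise to
the forward model — correlated noise, background mis-specification, and
multi-component P(r) are outside its scope, and fits to real data
inherit the single-Gaussian and exponential-background assumptions.

Headline simulation statistics from the original 600-ns trajectory (the
36.5% occurrence fraction, the 5–6-water mode, the 89%/96% route shares)
depend on that specific unpublished trajectory and are not reproduced
here; the package reproduces the *methods* and validates them on planted
truth.

## Validation problem sizes

The recomputation script (`scripts/acceptance.py`) uses: 200 random
graphs ≤12 waters against exhaustive enumeration and 200 graphs ≤500
waters against an independent reference; a 12-condition planted-wire grid
(p ∈ {0, 0.2, 0.5, 1} × chain length ∈ {3, 5, 8}) at 300 frames each;
100 random rigid transforms for DDM/Kabsch checks; 50 noise replicates
for DEER bias and 200 for band coverage; and a 50×50 (t, r) kernel grid.
These sizes give stable statistics (binomial SE on the coverage estimate
≈ 1.6%) while keeping the full recomputation at a few minutes on one CPU.

## Known limitations

- One pathway (the shortest) is recorded per frame; flux or multi-path
  statistics are out of scope.
- No energetic or orientational H-bond scoring; no explicit proton
  (Grotthuss) modeling.
- mmCIF, symmetry expansion, occupancy/B-factor logic are unsupported.
- The DEER module fits a single Gaussian only; model-free (Tikhonov)
  P(r) and multi-component mixtures are out of scope, as is raw
  spectrometer data handling (inputs must be real, pre-phased traces).
- Helix annotation and repeat correspondence tables are curated defaults
  for CLC-ec1 numbering, not derived quantities.
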