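# Methods

`rasdyn` scores conformational ensembles of a nucleotide-regulated GTPase
(the motivating system is KRAS 1–169 cycling between GDP- and GTP-bound
states) and classifies variants by how their dynamics deviate from wild
type.  This note documents the models, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the known
limitations.

## Ensemble representation and superposition

An ensemble is a dense array of replicate trajectory frames
`(n_replicates, n_frames, n_atoms, 3)` with a pandas atom table (1-based
author residue numbering, gap-aware).  Files are read and written through
MDAnalysis: PDB for topologies and references, DCD/XTC/multi-model PDB for
trajectories; multi-chain references keep chain A by default.

Frames are superposed to a reference by a least-squares (Kabsch/SVD) rigid
fit computed on Cα atoms **outside** the mobile Switch loops and applied to
all atoms.  The default region map is p-loop 10–17, Switch 1 25–40,
Switch 2 57–75, allosteric lobe 87–166; all ranges are configurable.  The
Switch exclusion matters: those loops carry the conformational signal being
measured, so including them in the fit would absorb part of it into the
rigid-body transform.  Fit correctness is verified against an independent
quaternion-method (Horn) superposition oracle to 1e-8 Å.

## Mobility and RMSD metrics

* **RMSF** per residue is computed per replicate about that replicate's own
  mean Cα position, then aggregated across replicates by the arithmetic mean
  (median available).  In the isotropic-noise limit with per-axis SD *s*,
  RMSF → *s*·√3; the suite checks this within 2% at 10⁴ frames.
* **SSR** between two RMSF profiles is Σ_residues (ΔRMSF)² (Å²).  The
  default reference profile is the across-variant mean per nucleotide
  state, with the WT profile available as an alternative reference.  A
  variant counts as "similar" when |SSR − SSR_WT| < 0.5 Å² (configurable);
  the threshold units are taken as Å² since SSR is a sum of squared
  Ångström residuals.
* **RMSD to reference poses** (e.g. GAP-/GEF-bound conformations supplied as
  PDB files) uses evenly strided frames (default 100 per replicate, first
  frame included), a Switch-excluded fit on shared Cα, and evaluates the
  deviation over all shared Cα by default (a switches-only selection is an
  option).  Residue matching is by index intersection, so references with
  unresolved loops work.

## PC landscapes, wells and occupancy

PCA is run on pooled, superposed, flattened Cα coordinates (thin SVD, so
frame-deficient problems are handled).  The default scope fits a separate
basis per nucleotide state; a pooled fit across states is available.
Component signs are fixed so each component's largest-magnitude loading is
positive, making scores reproducible.

The free-energy landscape over a 2D PC subspace is the Boltzmann inversion
of the observed density, F = −kT·ln(ρ/ρ_max), kT = 0.0019872·T kcal/mol at
T = 300 K, on a 50×50 grid padded 5% beyond the data extent.  Empty bins
are NaN (unknown, not infinite).  Against an isotropic Gaussian cloud the
radially averaged landscape matches (r²/2σ²)·kT within 0.1 kT out to 2σ.

Two-well analysis along PC1 uses a Gaussian KDE with Silverman bandwidth,
evaluated on a 512-point grid; the boundary is the density minimum between
the two highest local maxima.  Maxima below 5% of the peak density (height
or prominence) are treated as sampling ripple, so genuinely unimodal data
are flagged instead of producing a spurious boundary.  Well II is by
convention the side opposite the WT modal well.  A variant's occupancy
ratio is its fraction of frames on the well-II side (0 = never samples
well II, 1 = never samples well I); per-replicate counts are retained and
the pooled ratio is exactly the count-weighted replicate mean.

Per-variant PC sampling is standardized as z = (mean_mut − mean_WT)/SD_WT
per component (top 3 by default), with the WT spread taken from pooled WT
frames rather than replicate means (configurable).

## Distance monitors and interaction energy

The shipped monitor set is ten literature-derived residue pairs in four
themes: Switch-2/helix-3 coupling (Q61–D92, E62–H95), p-loop→Switch-2
opening (A11–Q61, G12–Q61), Switch-1/Switch-2 coordination (I36–A59,
Y32–Y40, Y32–A59) and the nucleotide/Mg²⁺ network around T35 (G12–T35,
Q61–T35, S17–T35).  The representative point of each residue is the
centroid of its side-chain heavy atoms, falling back to Cα for glycine (and
for Cα-only ensembles); named-atom overrides are supported per monitor.
Monitor scores are (median_mut − median_WT)/SD_WT with the WT per-frame SD —
the deliberate median-center/SD-scale mix mirrors how such scores are
reported in practice.  Monitor–PC relationships are Pearson correlations of
per-frame distance against the top-3 projections; constant series yield NaN.

Ligand–protein interaction energy is a direct pairwise nonbonded sum per
frame: Coulomb (C = 332.0716 kcal·Å/mol/e²) plus Lennard-Jones with
CHARMM-style combining rules (ε geometric mean, Rmin as the sum of Rmin/2)
and the CHARMM switching polynomial between r_on = 10 Å and r_off = 12 Å
applied to both terms.  This is a pair-interaction approximation — no
lattice sums — and is continuous at both switching radii to < 1e-8
kcal/mol.  Mg²⁺ is counted with the nucleotide by default (configurable).
Parameters come from a per-atom CSV (charge, Rmin/2, ε) with wildcard
residue entries allowed.

## Classification and grouping

Every metric is standardized against a WT reference distribution and split
low / wt-like / high with inclusive 1σ boundaries (≥ +1σ is high, ≤ −1σ is
low).  Interaction energies are classified jointly in the two nucleotide
states into a 3×3 Stable/Neutral/Unstable grid (9 labels; more-negative
energy = Stable).  RMSD metrics are split two-way per state (|z| < 1σ
"closed", else "deviated") and reported as combined labels such as
"RMSD refI GTP Closed GDP Deviated".  Well-occupancy ratios are classified
against the WT replicate mean ± SD (with a 1/n floor on the replicate SD)
and labelled "Plus SD"/"Minus SD".

Each (metric, state, category) becomes one binary meta-class column.  The
column count is an emergent function of the configured score list — nothing
is hard-coded — and columns a dataset never populates stay present as
all-zero.  k-means (default k = 6 per state, 50 restarts, seeded) runs on
the z-standardized metric matrix, with the binary matrix as an alternative
input.  Group signatures rank meta-classes by within-group occupancy
fraction, ties broken by global occupancy and then name for full
determinism; the retained meta-class set is the union of each group's
top-10 nonzero classes.  The 2D embedding backend is UMAP when available
with an exact-PCA fallback; missing metric columns are dropped by default
(mean imputation optional).

## Thermostability

Tm is the temperature of the first-derivative peak of the 350/330 nm
fluorescence ratio.  The derivative is a Savitzky–Golay filter (21-point
cubic window — 10 °C on the instrument's 0.5 °C grid, wide enough to
suppress shot noise on broad transitions yet narrower than the transitions
themselves) and the peak is refined sub-grid by a least-squares quadratic
over ±3 points.  Flat or amplitude-starved traces (amplitude below 10× the
residual noise) raise a no-transition error rather than returning a junk
peak; the call is invariant to affine rescaling of the ratio axis.  On
synthetic curves with noise SD 0.01 on a unit-amplitude transition the
called Tm is within 0.5 °C of truth in ≥ 95/100 curves.

Derived statistics per variant: ΔTm per state vs WT, ΔΔTm(GDP−PNP) within a
protein, and the activation stability change ΔΔTm* = ΔTm(PNP) − ΔTm(GDP),
which satisfies ΔΔTm* = (GDP−PNP)_WT − (GDP−PNP)_mut identically (checked
on every record).  Negative ΔΔTm* means the active state is destabilized
more than the inactive one.

## Synthetic generators

The generators plant ground truth so every stage is testable without MD
output:

* **Ensembles** — a smooth helix-like Cα chain (2.3 Å radius, 1.5 Å rise,
  100° twist ⇒ 3.8 Å spacing), mutually orthonormal Gaussian collective
  modes, an optional two-state collective coordinate implemented as a
  two-state Markov chain (stationary occupancy exactly controllable, mean
  state-II dwell in frames, stationary start), and isotropic per-residue
  noise.  All randomness flows from one integer seed through a spawned
  stream per replicate, so replicate blocks are individually deterministic.
* **Energy series** — AR(1) with exact stationary mean/SD and configurable
  lag-1 autocorrelation.
* **Melting curves** — logistic transitions between (optionally sloped)
  baselines over 20–95 °C at 0.5 °C steps plus Gaussian noise; with flat
  baselines and no noise the derivative peaks exactly at the planted Tm.
* **Score tables** — variants drawn with unit WT-SD noise around group
  centroids placed on mutually orthogonal directions scaled to the effect
  size, plus a WT row at the reference centroid.

What they do **not** emulate: force-field physics, solvent, side chains,
anharmonic coupling between modes, frame-to-frame kinetics beyond the
two-state chain, or the correlated baseline drift of real fluorimetry.
Passing tests therefore demonstrate that the estimators recover what they
claim to measure under controlled conditions, not that any particular
biological conclusion about real trajectories is correct.

## Problem sizes and numerical choices

The shipped test and acceptance runs use deliberately compact problems —
12–169 residues, 1–3 replicates, 80–10,000 frames, 6,000-frame chains for
occupancy recovery, 100 melting curves — chosen as the smallest sizes at
which the statistical tolerances above are meaningful.  Tie-breaks and
degenerate inputs are handled explicitly: zero-variance PCA input, single
occupied landscape bins, unimodal densities, constant monitor series, zero
WT SDs, single-frame replicates and flat melting curves all raise typed
errors or NaN flags rather than propagating silence.

## Known limitations

* The pair-interaction energy approximates, but will not bit-for-bit match,
  a simulation engine's switched nonbonded energy (no PME, no 1-4 scaling,
  no polarizability).
* Occupancy estimates inherit the autocorrelation of the underlying
  dynamics; at dwell length L frames the effective sample size is reduced
  by ~2L, which the tolerances account for.
* Well detection assumes at most two dominant wells along PC1; landscapes
  with three or more basins report only the boundary between the two
  highest density modes.
* Tm calling reports the global derivative maximum for double-transition
  curves and flags nothing about the secondary peak unless its prominence
  is configured.
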