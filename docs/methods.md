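# Methods

## Solvent-accessible surface area

The engine is a Shrake–Rupley style numerical integrator. Every heavy atom
carries a van der Waals radius from an element-keyed table (bundled
default: C 1.76, N 1.65, O 1.40, S 1.85 Å after Chothia 1976, P/Se after
Bondi; swappable via `RadiiSet`). Radius lookup is total over filtered
atoms: an element absent from the table is an error unless an explicit
fallback radius is configured — silent defaulting would bias areas for
selenium-substituted structures.

Each atom's accessible sphere (radius r + 1.4 Å probe) is sampled on a
golden-spiral (Fibonacci) lattice, offset so no point sits on a pole. The
lattice is purely deterministic; each point carries area weight 4π/n. A
sample point is occluded when it lies **strictly** inside a neighbouring
atom's expanded sphere; a point exactly on the boundary counts accessible.
This tie-break is a declared convention — classic program descriptions do
not specify it, and it only matters for exactly-touching spheres.

Neighbour candidates come from a KD-tree with the exact cutoff
r_i + r_j + 2·probe; a brute-force all-pairs path is retained and asserted
bit-identical in tests (identical accessible point counts, hence identical
areas).

**Point count.** Default n = 960. On tripeptide fixtures the total SASA at
960 points is within 2% of the value at 4000, while an isolated sphere is
reproduced essentially exactly (the lattice fraction is 1); 960 is the
speed/accuracy knee and is exposed as configuration.

**Relative accessibility.** The reference state for residue X is the
central residue of an extended Gly-X-Gly tripeptide (φ = −120°, ψ = 120°,
ω = 180°) built with ideal geometry and evaluated with the *same* engine,
radii, probe and point count, then cached. Computing the reference
internally keeps relative values self-consistent under any change of radii
or lattice density, rather than inheriting a literature table computed
under unknown conventions. The resulting scale (Gly 87.2, Ala 111.6,
Trp 256.4 Å²) sits within a few percent of published Gly-X-Gly maxima.
Relative values above 100% (distorted conformations) are reported as-is,
never clipped. A residue is buried when relative SASA < 5% (strict);
5.0% exactly is exposed.

**Disordered residues** are never assigned 0%: positions missing from the
coordinates (REMARK 465 or internal numbering gaps) carry an explicit
`disordered` sentinel and are excluded from statistics.

## Structure handling

PDB parsing and writing go through gemmi. Filtering policy: hydrogens and
waters always removed; HETATM removed by default, with an opt-in that
keeps modified residues (MSE→MET etc.) mapped to their parents; for
alternate locations the highest-occupancy conformer wins, first-in-file on
ties. Author numbering (chain, number, insertion code) is preserved
verbatim; all numbering conversion happens in the variant layer.

## Conservation grades

Per-column rates are empirical-Bayes posterior means under a discrete
gamma prior, the approach of the Rate4Site/ConSurf family. Column
likelihoods use Felsenstein pruning with per-node rescaling; gaps are
missing data (partial-likelihood vector of ones), never a 21st state.
All-gap columns get an undefined-rate sentinel and grade 0 (ungradable).

The default substitution process is the 20-state equal-exchangeability
(Poisson) model with uniform frequencies. Grading is rank-based and
largely insensitive to the exchangeability matrix, and the Poisson model
has a closed-form transition probability
P(same) = 1/20 + (19/20)·e^(−20/19·t); any reversible matrix (e.g. a
JTT-style table) can be plugged in through `GeneralReversibleModel`.

Prior: gamma with shape α = 1.0, mean 1, discretized into 8
equal-probability categories represented by their conditional means
(Yang 1994). Both are configurable; α = 1 is a neutral default when the
true rate dispersion is unknown.

**Grading scheme.** Rates are binned into grades 9 → 1 by an equal-width
partition of the rate range after trimming 2.5% at each end (outlier
guard); out-of-range rates clamp into the end bins, and a zero-width range
(all columns equal) maps everything to grade 9. Grades 1–4 are labelled
variable, 5–6 intermediate, 7–9 conserved. This scheme is declared and
recorded in output metadata; the binning used by public conservation
servers is not published, so grade values are comparable in rank, not
guaranteed digit-by-digit. Consequently the published grade cells in the
bundled tables are carried as annotations, not recomputed targets.

The tree is an input (or generated); tree inference is out of scope.

## Variant annotation

Substitution tokens (`Leu33Pro`, `L33P`, `Lys611del`) are parsed into
(wild type, position, mutant); the single-residue deletion is profiled at
the deleted residue's position. A curated numbering map carries per-gene
signal-peptide offsets (mature ↔ precursor), per-structure chain/offset
mappings, and the position→alignment-column offset. Every successful
structure mapping **must** pass the wild-type identity check (structure
residue name equals the recorded wild type; deletions check the deleted
residue); a mismatch raises rather than warns, because silent misnumbering
is the classic failure mode of variant-to-structure joins. The offsets in
the bundled map reflect mature-protein author numbering in the platelet
receptor crystal structures and are validated by that check at run time,
not trusted.

When a variant is resolved in several structures, the arithmetic mean of
its defined relative-SASA values enters the statistics; variants with no
defined value (disordered everywhere, or no structure) are excluded,
never imputed — hence accessibility n = 14 of 17 alloantigens while the
conservation n stays 17.

Interface proximity is available as a distance query (minimum heavy-atom
distance to a named chain set, 4.0 Å contact convention); narrative
structural claims are not auto-asserted.

## Group statistics

Kruskal–Wallis H with midranks and the standard tie correction
1 − Σ(t³−t)/(N³−N); the correction factor is reported. The omnibus p uses
the chi-square approximation on k−1 df (the default of common statistics
packages), with a Monte-Carlo permutation alternative for small samples.
Pairwise follow-ups are two-sided rank-sum tests: full enumeration of all
C(n₁+n₂, n₁) assignments when both groups have n ≤ 8 (exact under ties),
otherwise the tie-corrected normal approximation; unadjusted by default
(the historical analysis reported unadjusted pairwise marks), with an
optional Holm flag, and the method is recorded per pair. Summaries are
mean ± sample (n−1) SD; a singleton group's SD is NaN, not 0.

Under the null with group sizes (17, 13, 8) the chi-square approximation
rejects at 0.043 over 2000 simulations (tested bound [0.035, 0.065]).

## Synthetic data

Generators are pure functions of spec + seed (SeedSequence substreams per
component).

*Peptides.* Backbones are built by NeRF internal-coordinate chaining
(N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å, standard angles) at chosen φ/ψ;
residues are completed by rigidly superimposing the Chemical Component
Dictionary ideal heavy-atom coordinates (bundled with biotite) onto each
N/Cα/C frame. Side chains therefore sit in one ideal rotamer — adequate
for surface-area work; no chemistry beyond that is claimed.

*Toy folds.* `compact-shell` buries residue 1 at the origin inside one or
two concentric Fibonacci shells (5.6 / 8.4 Å) of radially oriented
glycines: every shell atom within ~4–6 Å of the centre occludes a wide
(≳ 36° half-angle) cone of the central residue's test sphere, so the
centre's relative SASA is driven to ~0 by construction while shell
residues keep > 50% free outward surface. Geometry is jittered per seed
and regenerated (bounded retries) until no heavy-atom pair of distinct,
non-adjacent residues is closer than 2.0 Å. Burial labels come from the
construction geometry, not from the engine, so engine agreement is a real
test.

*Alignments.* Root states from the stationary distribution, edge-by-edge
sampling with the model's transition probabilities at branch length ×
site rate; true rates recorded. These simulations share the engine's
substitution model family but none of its inference code.

*Benchmark.* The default study mirrors the published design: groups of
17 surface/fast ("hpa"-like), 13 buried/slow ("disease"-like, planted
rate 0.1) and 8 mixed ("neutral") variants, positions spread over 17 toy
folds, conservation columns simulated along a 32-leaf balanced tree
(branch length 0.25) with planted rates 3.0 / 0.1 against a background of
1.0. What these fixtures do **not** emulate: real side-chain packing,
domain architecture, alignment gaps/indels, rate autocorrelation along the
sequence, and realistic tree shapes — so passing the benchmark shows the
pipeline recovers planted signal through every stage, not that it
reproduces any particular protein's values.

## Problem sizes and numerics

Default run conditions: 960 lattice points, 8 gamma categories, 32-leaf
simulation trees, 200-site recovery alignments, 2000-draw null
calibration; these sizes make the full suite and the acceptance script
complete in well under a minute each while leaving all statistical checks
comfortably powered. Likelihood pruning rescales partials per internal
node, so deep trees cannot underflow. Ranking uses midranks throughout;
the degenerate all-values-identical comparison returns H = 0, p = 1.

## Known limitations

- Element-keyed radii (no atom-name-specific radii); the published SURFV
  radii set behind the original percentages is unrecoverable, so numeric
  agreement on real structures is expected within a few percentage points,
  not exactly.
- No molecular (Connolly) surface, no secondary-structure assignment
  (accepted as annotation input only), no homology modelling, no tree or
  alignment inference, no database searches.
- Grade values depend on the declared binning; only ranks are comparable
  across tools.
- mmCIF input is not supported in v1 (PDB format only).
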