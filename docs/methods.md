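# Methods

## Problem setting

Two paralogous proteins that are nearly identical in sequence can be
modified differently after translation, either because a variant residue
abolishes the chemistry outright (T→A cannot be phosphorylated) or because
the local structural neighbourhood around a conserved site differs. The
package quantifies this on a single 3-D model in the reference paralog's
numbering: all positions are 1-based, and the second paralog's sites are
assumed to map through an ungapped pairwise alignment onto the same
coordinates, so every variant is written `X{pos}Y` (reference residue,
shared position, other-paralog residue). Pairs whose alignment contains
internal indels over the modelled region are out of scope.

## Solvent accessibility

Shrake–Rupley with a deterministic golden-section spiral: each heavy atom's
test sphere of radius (vdW + probe) carries `n_points` quasi-uniform points
(default 960, minimum 92); a point is accessible iff it lies outside every
neighbouring atom's expanded sphere, and the atom's SASA is the accessible
fraction times the sphere area. Residue SASA is exactly the sum over its
atoms. The spiral replaces the classic random point set so results are
bit-reproducible run to run; no randomness exists anywhere in the geometry
modules.

* van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80 Å (Bondi-style);
  hydrogens are not modelled; any other element is a hard error.
* Probe radius 1.4 Å (water).
* Accuracy at 960 points: ≤ 0.5% against the closed-form isolated-sphere
  area and ≤ 2% against the analytic two-sphere spherical-cap solution,
  converging as the point count grows (92 → 960 → 4000). Neighbour search
  uses a KD-tree, which is exact (every atom pair within reach is
  enumerated).

## Exposure classes

Relative SASA is absolute residue SASA over the residue type's theoretical
maximum (extended Gly-X-Gly values; Tien et al. 2013). A residue is
**buried** when relative SASA < 5%, otherwise **exposed** — the threshold is
the common "completely buried" convention and is a config knob
(`buried_below`), since exposure calls near the boundary are
threshold-sensitive. Relative values are capped at 1.0 for reporting (a
lone residue with no neighbours exceeds the tripeptide reference slightly);
the cap cannot affect the class.

## Proximity

All residue-to-residue distances are minimum heavy-atom-to-heavy-atom
Euclidean distances — what a fixed-radius sphere probe around a residue
measures in a molecular viewer. No centroid or Cβ shortcut is used anywhere.
The default probe radius is 5.0 Å. The KD-tree sparse query is exactly
equivalent to the brute-force all-pairs scan (asserted against one in the
test suite); self-pairs are excluded.

## Face partition

The structure is split into two hemispheres by one plane through the
all-atom centroid. The axis points from that centroid toward the centroid of
the side-chain atoms of surface-exposed variant residues (side-chain
centroid falls back to Cα for glycine); a residue is on the **variable
face** iff its side-chain centroid projects positively on the axis, ties
going to the conserved face. This is a deliberate operationalisation of a
partition that published figures define visually; it is rigid-motion
invariant (the axis co-rotates) and fails loudly when no exposed variant
exists, since the faces are then undefined.

## Chemical compatibility and altered capability

A data-driven table maps each modification type to the side chains that
support it: phosphorylation {S,T,Y}; acetylation {K}; methylation {K,R};
ubiquitination {K}; S-nitrosylation {C}; S-glutathionylation {C};
O-glucosylation {S}; ethanolamination {E}; carbonylation {K,R,P,T}
(standard metal-catalysed-oxidation targets; editable, like the whole
table). N-terminal acetylation is deliberately excluded — only side-chain
chemistry is modelled. At a variant position with any observed PTM, a
modification is "only possible in" one isoform iff it is compatible with
that allele and not the other; a K→R variant therefore loses acetylation and
ubiquitination but *retains* methylation capability, which is the reading
adopted here for shared-chemistry substitutions. Table rows whose
(residue, modification) pair violates the table are flagged and retained at
load time, never silently dropped: input = valid + flagged holds on every
load.

## Evidence tiers, mapping, merging

A record is high-confidence iff it is confirmed by a targeted experiment
(`site_specific`) or carries ≥ `min_citations` (default 5)
mass-spectrometry citations. Accounting is by **position**: observations of
the same (position, modification) in different species or isoforms merge
into one site, and a position is "multiply modified" when ≥ 2 distinct
modification types are observed there. Positions beyond the modelled
C-terminal boundary (default: the last resolved residue; configurable when
the disorder call differs from the model end) are counted as the disordered
tail and excluded from the geometric analyses.

## Permutation enrichment

Statistic: the number of observed modified positions satisfying a hit
predicate (variant-proximal by default). Null: the same number of positions
drawn uniformly without replacement from the candidate pool. The pool
defaults to surface-exposed residues — modifying enzymes can only reach the
surface — with an all-residues option. The p-value uses the +1 small-sample
correction, `p = (1 + #{T* ≥ T})/(n_perm + 1)`, so it is never exactly zero;
when C(|pool|, |observed|) ≤ 10⁵ the null is enumerated exhaustively and the
p-value is the exact hypergeometric tail (no correction needed — the
enumeration is complete). Default `n_perm` 10,000; the seed is mandatory
whenever permutations run (no wall-clock seeding). Draws are vectorised and
deterministic given the seed.

The reported fold is observed hit fraction over pool hit fraction. Note an
estimand subtlety: when sites are generated with per-residue probabilities
`p_near`/`p_far = f`, the marginal fold of this estimator is `f/(1 + (f−1)π)`
where π is the pool's hit fraction — slightly below `f` for π > 0. The
residue-count face ratio (variable/conserved) is reported alongside; neither
is privileged as "the" enrichment normalisation, and face areas are not used
to normalise densities.

## Synthetic data: what it emulates and what it does not

The generator produces a compact self-avoiding chain on a jittered cubic
lattice (3.8 Å Cα spacing, ±0.08 Å jitter per coordinate, so the minimum Cα
separation stays above 3.5 Å) at pseudo-atom resolution: one Cα plus one
outward-pointing side-chain sphere per residue (none for glycine; a larger
sulfur-radius sphere for bulky types). Residues whose 26 lattice neighbours
are all occupied form the designated interior — fully enclosed, so the SASA
engine must call them buried (recall 1.0 is asserted). Variant clusters
(≤ 2) are grown from seeds on one hemisphere as spatially contiguous shell
patches; allele pairs mix capability-changing (S→A, C→T, K→R, T→A) and
charge-changing (D→A, D→Q, Q→E, T→E) substitutions. PTM sites are sampled
per compatible surface residue with probability `p_near` within the probe
radius of a variant and `p_far` elsewhere (defaults 0.5 / 0.25 — a planted
two-fold enrichment at roughly the site density of a well-studied protein);
citation counts come from a two-component geometric mixture (means 12 and
1.5, high-evidence weight 0.6) so the reliability filter has real work to
do, and `site_specific` is true with probability 0.08.

This emulates exactly what the pipeline consumes — buried/exposed ground
truth, clustered surface variation, near-variant site enrichment, mixed
evidence — and nothing else: no secondary structure, no rotamers, no
realistic packing density, no phylogenetic correlation in the alignment
generator (i.i.d. substitutions, with planted substitutions confined to the
designated distant row). Passing tests therefore validate the *method's
correctness and calibration*, not its conclusions on any real protein, whose
exposure and face counts remain sensitive to the model build and the
threshold choices above.

## Validation sizes and numerical choices

The acceptance suite checks: SASA against closed forms (two-sphere ≤ 2% at
960 points); proximity against brute force on 20 random 50-residue
globules; exact hypergeometric agreement on enumerable instances; type-I
error within 0.05 ± 0.02 over 1000 uniform-null datasets (pool 300, 100
hits, 60 sites, 999 permutations each — chosen so the discrete null keeps
the achievable level near 0.05); and ≥ 80% rejection power with fold
recovery against the planted two-fold enrichment over 200 replicates on a
1000-residue globule (two 12-variant clusters, ~95 sites per replicate, a
scale picked by a pre-hoc power analysis targeting ≥ 90% analytic power).
The whole suite runs in well under a minute on one CPU.

Degenerate inputs fail loudly by design: empty models, missing max-ASA
references, non-positive radii, faces without exposed variants, permutation
pools smaller than the observed set, insertion codes in PDB input (homology
models never carry them), unknown elements, and unknown modification names
all raise with the offending value named. Ties in the face projection go to
the conserved face; alternate PDB conformers resolve to the first; duplicate
(isoform, position, modification) records deduplicate at load.

## Known limitations

* Pseudo-atom synthetic residues mean synthetic SASA magnitudes are not
  protein-realistic; only classifications and comparisons are meaningful.
* The hemispheric face partition is a plane cut; a protein whose variant
  clusters wrap around the molecule would be poorly described by any single
  plane.
* The charge-environment annotation counts D/E/K/R within a radius; it is
  not an electrostatics calculation (no continuum solvent, no pKa).
* One hypothesis at a time: no multiple-testing control is applied, as the
  intended use is a single enrichment question per protein pair.
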