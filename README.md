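# ptmsurf

Structure-based analysis of post-translational modification (PTM) sites on
paralogous proteins.

Highly similar paralog pairs — the motivating case is the vertebrate
translation elongation factor isoforms eEF1A1 and eEF1A2, 92% identical yet
expressed in mutually exclusive tissues — can differ sharply in how they are
post-translationally modified. `ptmsurf` takes a 3-D model of the protein, a
curated PTM table (PhosphoSitePlus-style: positions, modification types,
citation counts, targeted-experiment flags), the list of positions at which
the two paralogs differ, and a multiple sequence alignment, and answers:

* which modified positions fall on the modelled structure vs the disordered
  C-terminal tail, and which of those are surface-exposed vs buried
  (Shrake–Rupley solvent accessibility, relative-SASA threshold);
* how modified residues distribute between the **variable face** (the
  hemisphere carrying the surface clusters of paralog sequence variation)
  and the opposite **conserved face**;
* which PTM sites lie structurally proximal to a variant residue under a
  fixed-radius probe (default 5 Å minimum heavy-atom distance);
* which variants change what chemistry is possible — e.g. a T→A change
  abolishes phosphorylation in one isoform, a K→R change abolishes
  acetylation and ubiquitination but retains methylation;
* which sites survive an evidence filter (targeted experiment, or ≥ 5
  mass-spectrometry citations);
* whether the concentration of PTM sites near the variant clusters is larger
  than chance, via a permutation test.

## The statistic

Given a candidate pool *P* of surface-exposed residues, observed modified
positions *S ⊆ P* and a hit predicate *h* (variant-proximal, or
variable-face), the test statistic is

> T = |{s ∈ S : h(s)}|

Under the null, |S| positions are drawn uniformly without replacement from
*P*; the one-sided p-value is `p = (1 + #{T* ≥ T}) / (n_perm + 1)` for
`n_perm` Monte-Carlo draws, or the exact hypergeometric tail when
C(|P|, |S|) ≤ 10⁵ (enumerated exhaustively). The fold enrichment is the
observed hit fraction over the pool hit fraction. Conditioning on the number
of modified residues and permuting their locations over the *surface* pool
reflects that modifying enzymes can only reach exposed residues.

## Worked example

Everything runs on synthetic data with planted ground truth — no downloads.
Generate a 150-residue compact globule with two variant clusters planted on
one hemisphere and a PTM table sampled with doubled site probability within
5 Å of a variant, then analyse it:

```bash
ptmsurf simulate --n-residues 150 --seed 42 --out demo_bundle
ptmsurf run \
    --structure demo_bundle/structure.pdb \
    --ptm-table demo_bundle/ptms.tsv \
    --variants demo_bundle/variants.tsv \
    --alignment demo_bundle/alignment.fasta \
    --n-perm 10000 --seed 7 --out demo_out
cat demo_out/summary.txt
```

```
PTM-to-structure analysis summary
=================================
modified positions total:        20
  mapped onto the model:         20
  in the C-terminal tail:        0
  surface-exposed:               19
  buried:                        1
  modified by >1 type:           0

variable face: 12 residues, 12 modifications
conserved face: 7 residues, 7 modifications
variant-proximal sites: 8 / 20 (40.0%)

permutation enrichment: fold = 1.42, p = 0.18 (10000 permutations)
```

Twenty sites were sampled; nineteen are surface-exposed and one is buried.
Twelve modified residues fall on the variable face against seven on the
conserved face, and 8/20 sites sit within 5 Å of a planted variant — a
1.42-fold excess over the surface pool that, at this small table size, is
not yet distinguishable from chance (p = 0.18); the test's power to detect
the planted two-fold enrichment at larger site counts is quantified in the
acceptance suite. `demo_out/` also contains `ledger.json` (every count as
machine-readable JSON), `sites.tsv` (one row per site with SASA, face,
proximity, evidence tier), and `annotated.pdb` + `annotated.pml` (category
codes in the B-factor column plus a PyMOL coloring script).

The same steps are available as library calls (`ptmsurf.run_pipeline`,
`ptmsurf.compute_sasa`, `ptmsurf.permutation_enrichment`, …); see
`docs/methods.md` for the model and parameter choices.

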