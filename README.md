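# clonalniche

Quantitative analysis of the clonal architecture and spatial organisation of
CD4 T cells in the neonatal liver.

In the first postnatal weeks the liver hosts a wave of clonally expanding
regulatory (Foxp3⁺, Treg) and conventional (Foxp3⁻, Tconv) CD4 T cells that
assemble with dendritic cells (DCs) into compact tolerogenic microclusters in
the tissue parenchyma. `clonalniche` implements the statistics that quantify
this picture, for anyone working with single-cell VDJ clonotype tables and
targeted in-situ spatial transcriptomics (e.g. 10x Xenium) cell maps:

- **R20 clonality score** — rank clones by descending size; R20 = k/C where
  k is the smallest number of top clones whose cells account for ≥ 20 % of
  the sequenced repertoire and C is the number of unique clones.  Low values
  mean oligoclonal expansion; C singleton clones give ⌈0.2·C⌉/C.
- **Expanded and shared clone fractions** — a clone is *expanded* when > 1
  cell carries the clonotype, and *shared* when it contains both Foxp3⁺ and
  Foxp3⁻ cells (evidence of peripheral Treg induction from a common
  precursor).
- **DC–T microniche detection** — DBSCAN-style density clustering of the
  typed cell point pattern (core point: ≥ `min_samples` cells within `eps`
  µm), with a deterministic nearest-core-point rule for ambiguous border
  cells and a composition filter (≥ `min_dc` DCs and ≥ `min_t` T cells).
- **Whole-slide statistics** — mean per-T-cell distance to the nearest DC,
  niche (focus) density per mm², and the fraction of niches in parenchyma,
  defined by the absence of any vessel feature within a proximity radius
  (default 50 µm) of the niche centroid.
- **Inside- vs. outside-niche differential expression** — per-gene two-sided
  Wilcoxon rank-sum tests on library-size-normalised (log1p, counts per
  10,000) expression, Benjamini–Hochberg adjusted across the tested genes.
- **Synthetic data generators** — seeded repertoire and tissue simulators
  with full ground truth (clone records, planted niche memberships,
  niche-conditional gene effects), so every stage is testable end to end.

## Worked example

```python
from clonalniche.simulate import (RepertoireSimParams, TissueSimParams,
                                  simulate_repertoire, simulate_tissue)
from clonalniche import repertoire as rep, spatial, de
from clonalniche.types import NicheParams

# a PND7-like repertoire: geometric clone sizes (mean ~1.8 cells),
# 30% of expanded clones forced to contain both lineages
table, truth = simulate_repertoire(RepertoireSimParams(
    n_cells=800, clone_size_law="GEOMETRIC", p=0.55, sharing_rate=0.30,
    subject_id="pnd7_m1", seed=7))
s = rep.summarize_subject(table, "pnd7_m1")
print(s.r20, s.expanded_fraction, s.shared_clone_count)
# 0.0782 0.4690 61   -> 7.8% of the 435 clones cover 20% of cells;
#                       47% of clones are expanded, 61 are Treg/Tconv-shared

# a tissue with 6 planted DC-T niches and a 4-fold DC effect on gene g000
cells, counts, vessels, planted = simulate_tissue(TissueSimParams(
    n_niches=6, niche_mean_dc=5.0, niche_mean_t=12.0,
    niche_effects={("DC", "g000"): 4.0}, seed=7))
niches = spatial.detect_microclusters(cells, NicheParams(eps=30, min_samples=5))
stats = spatial.slide_stats(cells, niches, vessels=vessels)
print(len(niches), stats.mean_nearest_dc_distance, stats.foci_density)
# 6 71.0 1.54   -> all 6 niches recovered; mean T-cell-to-DC distance 71 µm;
#                  1.54 foci per mm² of (hull-estimated) tissue

labels = spatial.assign_niche_membership(cells, niches)
print(de.de_inside_outside(cells, counts, labels, "DC").table.head(1))
#  gene  n_inside  n_outside  log2_fold_change      p_value      q_value
#  g000        40        135          0.946873 7.851776e-16 2.355533e-14
# -> the planted DC effect ranks first, strongly significant after BH
```

The same pipeline is available from the shell:

```sh
clonalniche simulate fixtures --out-dir fix --seed 7
clonalniche repertoire summarize --input fix/repertoire_pnd7.tsv --out summary.tsv
clonalniche niche detect --cells fix/tissue_neonatal_cells.csv \
    --vessels fix/tissue_neonatal_vessels.json \
    --out-niches niches.json --out-membership membership.csv --out-stats stats.tsv
clonalniche niche de --cells fix/tissue_neonatal_cells.csv \
    --counts-mtx fix/tissue_neonatal_counts.mtx \
    --genes fix/tissue_neonatal_genes.txt \
    --cell-names fix/tissue_neonatal_cellnames.txt \
    --membership membership.csv --cell-type DC --out de_dc.tsv
```

Each command writes a `run_manifest.json` with the tool version, resolved
parameters, input checksums and seed; seeded runs are byte-reproducible
(the manifest timestamp aside).

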