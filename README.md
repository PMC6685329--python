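# cloneatlas

Quantitative tools for studying how **resident cardiac endothelial cells (EC)
rebuild the coronary vasculature after myocardial infarction (MI)**, combining
two complementary assays in one package:

1. **Multispectral (Brainbow2.1 / "Confetti") lineage tracing.** A tamoxifen
   pulse stochastically and heritably labels each Cre-expressing EC with one of
   four fluorophores (YFP, RFP, nGFP, mCFP). Three weeks later, a *clone* —
   two or more adjacent cells sharing one fluorophore — is read as the progeny
   of a single labelled founder. The package ships a calibrated tissue
   simulator and a clone-statistics engine: connected-component clone calling,
   founder-event accounting, monoclonal vs polychromatic vessel classification,
   EdU S-phase indices, and a merger-vs-expansion permutation test.
2. **Single-cell RNA-seq of the EC compartment.** A negative-binomial count
   simulator with ten transcriptional EC archetypes (one exclusive to the
   infarcted heart) plus a haematopoietic contaminant drives a standard
   pipeline: QC (< 400 detected genes, > 20 % mitochondrial reads), PCA +
   Leiden clustering (3D t-SNE for display only), Ptprc⁺Pecam1⁻Kdr⁻ contaminant
   removal, one-vs-rest marker detection with Benjamini–Hochberg correction,
   per-cluster group-composition tests, per-gene queries (e.g. *Plvap*), and
   gene-signature (EndMT) scoring against expression-matched control genes.

## The statistics at the core

**Clone calling.** Labelled cells form a graph with edges between 6-adjacent
lattice neighbours of the same fluorophore; maximal connected components of
size ≥ 2 are clones, size-1 components are singletons, and
`founder events = clones + singletons` counts recombination events.

**Merger null.** If patches arose by merging *k* independent adjacent
founders, they appear monochromatic with probability Σ_c p_c^k (the colour
*collision* probability; 4^(1−k) for unbiased labelling), which is dominated
by the common colours — so merged "clones" of common colours would be larger.
`merger_test` permutes colour labels over clones and tests the Spearman trend
between clone size and colour frequency (one-sided, add-one rule), with a
Kruskal–Wallis test across colours reported alongside.

**Signature scoring.** A per-cell module score is the mean log-normalized
expression of the panel genes minus that of control genes sampled from
matching expression bins, so a score near zero means the panel behaves like
background even when individual members move.

## Worked example

```python
import cloneatlas as ca

params = ca.tissue_preset("mi", seed=1, n_sections=30)   # infarct-border preset
tissue = ca.simulate_tissue(params)
clones = ca.call_clones(tissue)                          # connected components
stats  = ca.clonal_stats(clones, tissue)
print(stats.mean_clone_size, stats.founder_events_per_section_mean)
```

Running `python examples/01_clonal_statistics.py` prints, for the two presets:

```
=== healthy LV (30 sections, 3270 labelled EC) ===
clones: 370, singletons: 1792 -> 72.1 founder events/section
cells per clone: 3.99 +- 2.03
labelled cells still single: 54.8%
monoclonal vessels: 73.5% of classified
Confetti+ EdU+ (S-phase) fraction: 27.3%
recovered Cre-recombination efficiency: 46.5%

=== infarct border (30 sections, 2953 labelled EC) ===
clones: 104, singletons: 1923 -> 67.6 founder events/section
cells per clone: 9.90 +- 9.44
...
```

Larger clones and a higher EdU index in the infarct border, with an
*unchanged* founder-event count and mostly monoclonal vessels, is the
quantitative signature of neovascularization by clonal expansion of resident
EC rather than recruitment of outside cells. The other example scripts cover
merger-vs-expansion inference (`02`), the EC state atlas with contaminant
removal, composition tests and *Plvap* queries (`03`), and the
"EndMT signature flat while individual markers rise" analysis (`04`).

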