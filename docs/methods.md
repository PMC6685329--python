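# Methods

## 1. The Confetti tissue simulator

### What it emulates

A multispectral lineage-tracing experiment in the adult mouse heart: an
endothelial-specific, tamoxifen-inducible Cre recombines the Brainbow2.1
cassette in a fraction ε of eligible EC, fixing one of four heritable
fluorophores per cell; labelled founders then clonally expand (or not) over a
three-week chase, read out in 100 µm wholemount sections. The simulator
produces a table of EC on an integer 3D lattice — position, fluorophore,
vessel id, EdU status, region, section and ground-truth founder id — the same
shape a segmented wholemount would take.

### Geometry

Sections are disjoint z-slabs. Vessel segments run along x, one per private
3×3 (y,z) corridor, with empty lattice rows between corridors so patches from
different vessels can never touch under 6-adjacency (the package-wide
adjacency rule: simplest 3D contiguity, and it makes the brute-force
flood-fill oracle exact). Eligible cells ("anchors") sit along each vessel
with a ≥ 3-site forward gap after the previous patch, so in the default
regime *independent founders never produce touching patches* and founder
events are exactly recoverable by the clone caller. A clone grows from its
anchor as a +x-biased Eden process (constrained random walk) inside the
corridor, giving the elongated patches seen along vessels. If the requested
founders and clone sizes cannot fit the configured lattice the simulator
raises a capacity error; it never truncates silently.

With `merger_regime` on, a configurable fraction of anchors is planted as
pairs of adjacent independent founders; pairs sharing a fluorophore merge
into one apparent clone, which is the process the merger test is designed to
detect.

### Calibration: published summary constants → simulator knobs

The presets (healthy left ventricle; infarct border at 7 days post-MI) encode
the experiment's published summary statistics. Every derived knob is obtained
analytically, once, from those constants — none is fitted to test outcomes:

| observable (preset constant) | healthy | infarct border | derived knob |
|---|---|---|---|
| Cre-recombination efficiency ε | 46.6 % | 46.6 % | per-anchor labelling probability |
| founder events / section | 72.3 | 67.3 | anchors/section = events / ε |
| fluorophore bias (YFP,RFP,nGFP,mCFP) | 51.9/25.7/11.3/11.8 % | 52.9/18.8/26.5/8.8 % | renormalized to probability vectors (published means do not sum to 100 %) |
| cells per clone (mean ± SD, clones ≥ 2 cells) | 4.0 ± 2.1 | 10.3 ± 10.6 | shifted negative binomial S = 2 + NB, moment-matched; the NB accommodates the over-dispersed (SD > mean) infarct case |
| labelled cells still single | 54.6 % | 63.4 % | founder non-division probability q0 = s·m/(1−s+s·m) — the published fraction is *cell*-level, so the founder-level probability must be much larger (0.83 healthy, 0.95 MI) |
| Confetti⁺EdU⁺ fraction | 28.5 % | 58.5 % | per-labelled-cell Bernoulli EdU rate. EdU marks S phase in a 1 h terminal window; because the MI target exceeds the fraction of labelled cells inside clones, singletons entering their first division must also be at risk, so the rate applies to all labelled cells |
| total-cell EdU fraction | 0.09 % | 1.9 % | the denominator is *all cardiac cells*, not EC; a per-section non-endothelial background compartment (counts only, 40 000 cells/section) carries a derived background EdU rate |
| monoclonal vessels (of classified) | 74.5 % | 90.7 % | mixed-founder vessel seeding rate: vessels carry 1 or 2 anchors; the two-anchor fraction solves M = (w1·c1 + w2·m2)/(w1·c1 + w2·c2) in closed form, where c1 = εd, c2 = ε² + 2ε(1−ε)d, m2 = ε²Σp² + 2ε(1−ε)d; the per-section two-anchor count is stochastically rounded so the realized fraction is unbiased |

A single `numpy` generator seeded from the mandatory `seed` drives the whole
run; identical parameters and seed give byte-identical outputs.

### What the simulator does not capture

Real wholemounts have curved, branching vessels, optical truncation of clones
at section boundaries, segmentation errors, and founders that are genuinely
adjacent at induction. The default regime deliberately separates founders so
that founder accounting is exact; consequently a *passing* calibration test
shows the analysis pipeline is unbiased under the published summary
statistics, not that merger events are absent in real tissue — that question
is delegated to `merger_test`. Bone marrow is not simulated: reporter
expression there is ~0.04 % and is treated as negligible leakage.

## 2. Clone statistics and merger inference

* **Clone calling** builds edges between same-colour 6-adjacent labelled cells
  and takes connected components (scipy sparse graph); a metric-radius
  adjacency is available for imported, non-lattice segmentations. Components
  of size ≥ 2 are clones; singletons are excluded from clone-size statistics
  but counted in founder events and in the singleton fraction (a labelled
  cell or a clone each count as one recombination event).
* **Vessel classification**: a vessel with ≥ 2 labelled cells (default) is
  monoclonal if they share one fluorophore, else polychromatic; vessels below
  the threshold are excluded. A clone touching several vessels counts once in
  clone statistics but contributes to each touched vessel's classification.
* **Merger test.** Statistic: Spearman correlation between clone size and the
  frequency of the clone's colour, one-sided (merging inflates common-colour
  clones). Null: permutation of colour labels over clones, p with the add-one
  rule (1+#{null ≥ obs})/(1+R), R = 1000 by default; degenerate inputs (all
  sizes equal) return p = 1. Kruskal–Wallis across colours is reported
  alongside with its asymptotic p. Expected per-colour sizes under merging
  can be attached by simulating paired founders at a matched planting rate.
* **Group comparisons** on per-section metrics use Mann–Whitney U by default
  (Welch's t optional); p-values are reported raw, uncorrected.

## 3. The count simulator and the state-atlas pipeline

Counts are Gamma–Poisson (negative binomial, variance µ + µ²/θ, θ = 10 by
default) over a lognormal gene-weight baseline. Ten EC archetypes carry their
published top marker genes at fold-change 8 plus ten synthetic "program"
genes at fold 3, so clustering rests on multi-gene programs while the named
markers stay top-ranked; archetype 7 occurs only in the MI group. Endothelial
identity genes (Pecam1, Kdr, Cdh5) are pinned high; the haematopoietic
contaminant (3 % of cells) expresses Ptprc at fold 300 with endothelial genes
at 1 % of baseline; 0.29 % of MI cells are Ptprc⁺Pecam1⁺ double positives.
Group mean depths follow the published per-group UMI means (2232 healthy,
5041 MI). Per-cell mitochondrial fractions follow a Beta(2, 31) capped at
0.15 plus a 4 % uniform tail on (0.22, 0.5); 2 % of cells are low-depth
(300 UMIs, hence < 400 detected genes by construction). Signature-panel genes
share a common baseline so group-shift scenarios compose additively.

Pipeline choices (the underlying study names no clustering algorithm or
normalization): median-depth scaling + log1p; optional highly-variable-gene
selection (2000 genes; disable to use the whole transcriptome); PCA (30
components); 15-NN graph; Leiden community detection. Default resolution 0.5
was fixed by a scan on synthetic data — a homogeneous population must remain
one community while fold-8 programs must separate — and `n_clusters_hint`
bisects log-resolution when an exact state count is requested. The 3D t-SNE
is computed for display only; assignments never depend on it.

* **QC boundaries**: removal is strict — `< 400` detected genes, `> 20 %`
  mitochondrial — so cells exactly at either threshold are retained. Removal
  reasons (low_genes / high_mito / both) partition the removed cells; if no
  mitochondrial genes match the rule (default prefix `mt-`, mouse
  nomenclature) the mito filter is skipped with a warning.
* **Contaminant rule**: a cluster is removed when its mean expression of every
  positive marker (Ptprc) exceeds the global per-cell upper decile while every
  endothelial marker (Pecam1, Kdr) mean falls below the global lower quartile.
  The rule assumes contamination is a minority population; retained
  double-positive cells are reported as a fraction, not removed.
* **Markers**: one-vs-rest Wilcoxon per gene per cluster, BH within cluster
  across genes, sorted by log-fold-change; "specific" flags genes qualifying
  in exactly one cluster; clusters under 3 cells are skipped and flagged.
* **Composition**: exact two-sided binomial test of each cluster's MI count
  against the global MI fraction — conservative for small clusters, flagged
  `underpowered` below 10 cells, `exclusive` when single-group.
* **Signature scoring**: genes are ranked by mean expression into 25 bins; for
  each panel gene, 50 controls are drawn from its bin, always excluding the
  panel. Per-cell score = mean(panel) − mean(controls). Group comparison uses
  Mann–Whitney plus Cohen's d; a per-gene breakdown (BH-adjusted) makes the
  "signature flat, individual genes up" pattern visible. The shipped EndMT
  panel is a reconstruction: the five markers named in the primary report
  plus canonical early (Snai1/2, Twist1, Zeb1/2, Cdh2, Icam1, Vcam1, Vim) and
  late (S100a4, Acta2, Tagln, Cnn1, Fn1, Col1a1/3a1, Postn, Smtn) EndMT genes.

## 4. Problem sizes and numerical conventions

The calibration experiments use 30 sections × 10 replicate seeds per preset
(~3 000 labelled EC per run); cluster-recovery experiments use 3 000 cells ×
2 000 genes; merger-test calibration uses 500 replicates of 200 clones with
999 permutations. These sizes put Monte-Carlo standard errors well inside the
published SDs while keeping any experiment in the minutes range on one core.
Ties in permutation p-values use the add-one rule; all seeds are explicit and
mandatory; coordinates are 0-based integers; CSV booleans are 0/1; MTX files
follow the 10x triplet convention (genes as rows).

## 5. Known limitations

* The simulator's founder separation makes founder recovery exact by design;
  it cannot quantify how often real adjacent same-colour founders are fused
  by the clone caller (the colour-collision analytics bound that effect).
* Sections are independent; there is no animal-level hierarchy, so
  between-animal variance components of the published means are not modelled.
* The composition test conditions on cluster sizes and ignores biological
  replicates, matching the per-cell reporting of the source data.
* EndMT is modelled only as an expression signature, not as a lineage
  process; the reconstructed panel is a stand-in for an unavailable original.
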