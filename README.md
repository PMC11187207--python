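# embryort

Single-cell DNA replication-timing and genome-fragility analysis for
early embryos, from shallow whole-genome-sequencing read counts.

## The problem

In cleavage-stage embryos, each S-phase blastomere has replicated part
of its genome: a replicated 100 kb bin carries twice the sequencing
signal of an unreplicated one. Reading this 2x/1x contrast out across
many single cells gives the embryo's replication-timing (RT) program —
which regions replicate early, which late — without any synchronisation
or labelling. The same copy-number readout, applied to non-replicating
cells, reveals whole-chromosome and segmental aneuploidies; the
boundary of a segmental event marks a chromosome break site. Late
replicating, origin-poor, lamina-associated regions are the fragile
territory where such breaks concentrate.

`embryort` implements this analysis end to end for users working with
per-cell binned count tables (and for method development via a bundled
truth-carrying simulator):

* **cell QC** — normalisation to an external non-replicating (G1)
  reference, GC/amplification-trend correction, MAD (median absolute
  deviation) scoring, G1/S phase classification;
* **RT inference** — per-cell binarisation into replicated/unreplicated
  states, cell ordering by percent genome replicated, the per-bin
  *replication percentage* (fraction of informative S cells replicated),
  and early (> 50 %) / late (< 50 %) region classification;
* **copy number & break sites** — exact penalized changepoint
  segmentation of per-cell copy ratios, absolute copy-number calling,
  and break-site annotation at transitions with copy-number change
  strictly greater than 1;
* **enrichment statistics** — site values against length-matched random
  regions avoiding masked territory, lamina-association
  observed/expected (OE) ratios, A/B compartment assignment, long-gene /
  long-intergenic region sets, Mann-Whitney and one-way ANOVA tests;
* **DNA-fiber arithmetic** — track-length conversion at 2.59 kb/µm,
  fork speed (kb/min), inter-origin distances and group comparisons;
* **synthetic data** — a generator producing binned counts from a known
  smooth RT program with coupled LAD/compartment/origin/gene tracks,
  negative-binomial counting noise, amplification noise, GC bias and
  injectable copy-number events, with full ground truth retained.

## The model in brief

For cell *c* with counts *n<sub>cb</sub>* over bins *b* and a G1
reference profile *r<sub>b</sub>*, the copy ratio is

> x<sub>cb</sub> = (n<sub>cb</sub> / Σ<sub>b</sub> n<sub>cb</sub>) / (r<sub>b</sub> / Σ<sub>b</sub> r<sub>b</sub>),

≈ 1 at the unreplicated baseline and ≈ 2 in replicated bins. S-phase
binarisation fits log x with a two-component mixture whose components
are constrained exactly log 2 apart (the 1x/2x structure) and calls
each bin by posterior; the per-bin replication percentage is the
fraction of informative S cells called replicated. Copy-number
segmentation minimises Σ segment SSE + λ·log(n)·σ̂² per changepoint on
log ratios (exact dynamic program), scales segment means so the
length-weighted median is the baseline copy number, and annotates a
`BreakSite` wherever adjacent segments differ by more than one copy.

## Worked example

```python
import numpy as np, pandas as pd
import embryort as ert
from embryort.qc import qc_cells

# 1. synthetic embryo cohort with a known replication-timing program
bins = ert.default_genome(seed=7)                      # 2 x 100 Mb, 100 kb bins
truth = ert.make_rt_truth(bins, coupling=2.0, seed=7)  # t, LADs, A/B, origins, genes
cells = ert.simulate_cells(truth, n_g1=30, n_s=150, flip_rate=0.02, seed=8)
cells = ert.inject_cn_event(cells, "G1_004", ("chr1", 30_000_000, 34_000_000), +2)
g1_ref = ert.simulate_cells(truth, n_g1=30, n_s=0, seed=9)  # external G1 reference

# 2. QC: normalise to the G1 reference, MAD score, phase call
profiles = qc_cells(cells.counts, cells.cell_ids, bins,
                    reference_counts=g1_ref.counts)

# 3. replication timing over the S cells
s_ratios = {p.cell_id: p.copy_ratio for p in profiles if p.phase == "S"}
rt = ert.ReplicationTimingModel(s_ratios, bins).fit()
print(rt.summary())

# 4. copy-number segmentation and break sites over the G1 cells
g1_ratios = {p.cell_id: p.copy_ratio for p in profiles if p.phase == "G1"}
cn = ert.CopyNumberModel(g1_ratios, bins).fit()
breaks = cn.breakpoints()
print(breaks[breaks.cell_id == "G1_004"].round(2).to_string(index=False))
```

prints

```
Replication timing summary
==========================
informative S cells : 141
non-informative     : 0
bins (unmasked)     : 2000
early bins          : 1224
late bins           : 776
boundary bins       : 0
percent replicated  : median 0.617 (range 0.027-1.000)
cell_id chrom  position  delta_cn  left_cn  right_cn
 G1_004  chr1  30000000      1.83     2.08      3.91
 G1_004  chr1  34000000     -1.89     3.91      2.02
```

141 of the 150 simulated S cells pass QC (the few earliest/latest cells
are indistinguishable from G1 and are excluded, as intended); both
edges of the injected 4 Mb gain are annotated at the exact bin, with a
continuous copy-number jump of ≈ ±2. The enrichment layer then ties
the RT profile to the genome annotation:

```python
from embryort.enrich import lamina_oe, enrichment_test
from embryort.genome import IntervalTrack, bin_track

late = (rt.aggregate.classes == "late") & bins.unmasked
late_sites = IntervalTrack(pd.DataFrame({
    "chrom": [bins.chrom_names[bins.chrom_index[i]] for i in np.flatnonzero(late)],
    "start": bins.starts[late], "end": bins.ends[late]}))
print("lamina OE of late bins:", round(lamina_oe(late_sites, truth.lad_track(), bins), 2))

gene_density = bin_track(truth.genes, bins, mode="count").astype(float)
early = (rt.aggregate.classes == "early") & bins.unmasked
res = enrichment_test(gene_density[early], gene_density[late])
print(f"genes per 100 kb: early {gene_density[early].mean():.3f} "
      f"vs late {gene_density[late].mean():.3f} (Mann-Whitney p = {res.p_two_sided:.1e})")
```

```
lamina OE of late bins: 1.76
genes per 100 kb: early 0.229 vs late 0.057 (Mann-Whitney p = 5.3e-20)
```

Late replicating regions are lamina-associated 1.8x more than random
and markedly gene-poor — the couplings the generator encodes, recovered
from counts alone. Fork-speed arithmetic is one call away:
`ert.fork_speed(2.9, pulse_min=30)` → `0.2504` kb/min, and
`ert.inter_origin_distances([[0, 13.127, 26.254]])` → median `34.0` kb.

## Command line

```bash
embryort all --seed 7 --out-dir out/          # simulate → qc → rt → breaks → enrich
embryort simulate --seed 7 --out-dir out/     # stages are independently rerunnable
embryort qc --out-dir out/
embryort fiber measurements.tsv --metric fork_speed --test mann_whitney
```

All outputs are plain TSV/BED/bedGraph plus a `manifest.json` with
checksums; a rerun with the same config is byte-identical.

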