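# wgdkit

Analysis toolkit for **whole-genome duplication (WGD) in fragmented polyploid
genome assemblies** — the situation faced by allotetraploid plants such as
*Panax ginseng*, where a recent WGD (and an older one) shaped a large,
repeat-rich genome that assembles into thousands of scaffolds.

It is aimed at genome-evolution analysts who need to:

* **detect and date WGDs** from the distribution of synonymous divergences
  (Ks) between paralogous gene pairs, converting modal Ks to absolute time
  with a molecular clock, `T = Ks / (2r)`;
* estimate **Ka/Ks** per gene pair with the Nei–Gojobori (1986) counting
  method under a Jukes–Cantor correction, and **K2P** nucleotide distances
  (used to date LTR-retrotransposon insertions from their terminal-repeat
  divergence);
* chain homologous gene pairs into **collinear blocks** between scaffolds and
  classify blocks as recent-WGD (median Ks below a threshold, default 0.2)
  versus older;
* order scaffolds by the **zigzag** argument: when one scaffold carries two
  recent-WGD blocks to two *different* scaffolds back-to-back, those two
  scaffolds were adjacent in the homeologous copy.  Edges are chained into
  superscaffolds (AGP output), iterating the pass until a fixpoint;
* build **reference-guided, homeolog-separated superscaffolds** against an
  outgroup gene order, 2-colouring the recent-block graph so each reference
  chromosome yields its two subgenome copies;
* quantify genomes **without an assembly**, from low-coverage WGS reads:
  genome size from the 23-mer frequency spectrum (`G = k-mer total / peak
  depth`), repeat **genome proportion** per family
  (`GP(%) = masked read bp / total read bp × 100`, absolute amount `GP × G`),
  and gene **presence/absence** from breadth of read coverage over each CDS.

Because real tetraploid data sets are enormous, the package ships a
first-class **simulator** (`wgdkit.simgenome`): an ancestral gene-dense
genome, a codon-aware WGD at a chosen Ks (calibrated so NG86+JC is unbiased),
scaffold fragmentation with a recorded truth adjacency table, repeat
insertion at chosen genome proportions, and error-bearing uniform-coverage
reads.  Every inference stage can therefore be scored against known truth.

## Worked example

```python
from wgdkit import simgenome as sg
from wgdkit.pipeline import ks_for_pairs
from wgdkit.dating import KsDistribution, detect_peaks, ks_to_time
import numpy as np

# a 220-gene ancestor, duplicated at Ks 0.05 with full retention
g = sg.simulate_ancestral_genome(1, 220, seed=42)
tet, truth = sg.apply_wgd(g, target_ks=0.05, ka_ks_ratio=0.3, retention=1.0, seed=43)

results, _ = ks_for_pairs(tet, [(a, b) for a, b, _ in truth.duplicate_pairs])
ks = np.array([r.Ks for r in results if r.status == "ok" and r.Ks > 0])
peak = max(detect_peaks(KsDistribution(ks, np.ones(len(ks))), seed=1),
           key=lambda p: p.mass)
print(f"modal Ks = {peak.modal_ks:.4f}")
print(f"T = {ks_to_time(peak.modal_ks):.2f} MYA")
print(f"printed-example check: Ks 0.035 -> {ks_to_time(0.035, 6.68e-9):.2f} MYA")
```

Output:

```
modal Ks = 0.0506
T = 3.79 MYA
printed-example check: Ks 0.035 -> 2.62 MYA
```

The fitted modal Ks recovers the simulated divergence (0.05) to a few
percent; `ks_to_time` divides by twice the synonymous substitution rate
(default `r = 6.68e-9` substitutions/site/year, overridable everywhere), so a
modal ortholog Ks of 0.035 corresponds to a 2.62-million-year-old divergence.

A command-line layer exists for the simulator:
`wgdkit simulate config.yaml --outdir sim/` writes FASTA, GFF3, FASTQ and
truth tables from one YAML config, and `wgdkit date-peak 0.035` prints the
clock conversion.

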