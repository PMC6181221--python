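# Methods

This note documents the models behind `wgdkit`, the defaults that matter,
what the simulator does and does not emulate, and the package's known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic tetraploid genomes (`simgenome`)

The simulator produces the study system end to end: ancestral genome → WGD →
fragmentation → repeat insertion → WGS reads, with truth tables
(`duplicate_pairs`, `adjacency`, `repeat_gp`, genome size) recorded at each
step.

**Ancestral genome.** Each chromosome carries `genes_per_chromosome`
stop-codon-free CDSs (ATG followed by random sense codons; length normal
around `mean_gene_len`, default 1120 bp — a typical plant mean CDS length)
separated by geometric intergenic spacers (default mean 500 bp, a deliberate
desk-scale compression of real plant intergenic distances).  Strands are
random.  All randomness flows from one `numpy` generator per operation call,
so outputs are byte-identical per seed.

**WGD divergence model.** `apply_wgd` duplicates every chromosome and
mutates *both* copies codon-aware so the expected pairwise NG86 Ks equals
`target_ks`.  At each codon position, the codons reachable by a synonymous
change form a complete graph on `c+1` states (all synonymous codon variants
at that position are single-nucleotide neighbours of one another).  A
symmetric random walk on that graph with Poisson(μ) total events over both
lineages leaves the two tips different with probability

    P_diff = c/(c+1) · (1 − exp(−μ(c+1)/c)).

We choose μ per position so that `P_diff = (c/3) · D`, where
`D = 3/4·(1 − exp(−4/3·Ks))` is the Jukes–Cantor expectation for the target
divergence.  Then NG86's `pS = Sd/S` has expectation `D` regardless of the
mix of 2-, 3- and 4-fold degenerate sites, and the JC-corrected estimator is
unbiased for any `Ks < 3` (the saturation guard refuses larger targets).  A
plain per-site Poisson without this calibration underestimates by several
percent at Ks ≈ 0.5 because 2-fold sites saturate at `pS = 1/2`, not `3/4`.
Nonsynonymous events are plain Poisson at `ka_ks_ratio` times the synonymous
rate on nonsynonymous sites, never creating stops.  Second-order
interactions (a nonsynonymous hit re-classifying a neighbouring site, and
pathway averaging across double-hit codons) leave a residual bias of a few
percent at high Ks with `ka_ks_ratio = 0.3`, measured and within all stated
tolerances; with `ka_ks_ratio = 0` the estimator is unbiased to Monte-Carlo
precision.

A fraction `1 − retention` of duplicated genes is deleted *from the new
copy*, with the flanking intergenic segment excised alongside, and retained
pairs are recorded as truth.

**Fragmentation.** Breakpoints are sampled only at midpoints of intergenic
gaps (genes are never split; anchors stay clean), rejecting draws that
violate `min_fragment`, and each break is recorded as a truth adjacency with
head-to-tail orientation.  Sequence length is conserved exactly.

**Repeats.** `insert_repeats` fills intergenic space with copies of each
family consensus mutated at `copy_divergence` (default 1%, modelling young,
recently amplified LTR families whose copies are near-identical to their
consensus) until the family's share of the *final* genome matches the target
within ±0.5 percentage points; the realized fraction is the truth value.

**Reads.** Uniform start positions weighted by scaffold length, random
strand, i.i.d. substitution errors, read count `round(coverage·G/L)` (per
mate when paired).  No indels, GC bias, heterozygosity or duplication
artefacts — by design; estimators downstream are tested against exactly the
noise they model.

## 2. Homology (`homology`)

All-vs-all protein comparison uses an exact affine-gap global alignment with
free end gaps (BLOSUM62, open −11, extend −1) — a deterministic surrogate
for a heuristic sequence search, exact at desk scale.  An amino-acid k-mer
prefilter (pairs must share ≥3 4-mers) skips hopeless pairs; disable it with
`prefilter_min_shared=0`.  Hits are thresholded at identity ≥ 0.4 and
coverage ≥ 0.5 on both sequences, and each query keeps its top 5 subjects by
score (gene-id tiebreak).  Families are connected components of the
reciprocal-hit graph: single linkage is the simplest reproducible clustering
rule, and the tests verify permutation invariance.  Externally computed hits
can be imported from 12-column tabular search output.

## 3. Ka/Ks and nucleotide distances (`kaks`)

NG86 with the classic conventions: fractional site counts per codon
(mutations to stop codons count as nonsynonymous sites, so S+N = 3 per
codon); differences averaged with equal weights over all shortest mutational
pathways, excluding pathways through stop codons and renormalising (if every
pathway crosses a stop — possible only for 2–3 differences — all pathways
are used with stop-crossing steps counted as nonsynonymous); Jukes–Cantor
correction `Ks = −3/4·ln(1 − 4/3·pS)`, flagged `saturated` when the argument
is non-positive.  A brute-force pathway-enumeration oracle in the tests
checks all six outputs to 1e−9 on random codon pairs.  NG86 is a documented
substitution for likelihood codon models: self-contained, deterministic, and
adequate for the Ks < 0.3 regime where the recent-WGD filters operate; an
import path accepts externally computed Ks tables.  Pairs whose codon
alignment covers < 50% of the shorter CDS are flagged and excluded from
distributions.

K2P separates transition (P) and transversion (Q) proportions,
`d = −1/2·ln(1−2P−Q) − 1/4·ln(1−2Q)`, ambiguity codes and gaps excluded
column-wise, saturation flagged rather than extrapolated.

## 4. Collinear blocks (`synteny`)

Anchors (homolog pairs with Ks) are chained per scaffold pair and
orientation by a longest-chain dynamic programme: ranks must advance
strictly on both scaffolds (decreasing on the second for '−' chains) with
gaps ≤ `max_gap` (default 25 genes).  The score is the anchor count (no gap
penalty inside `max_gap`), ties broken toward the smaller start rank; chains
are extracted greedily, so no anchor joins two blocks.  Tandem arrays
(consecutive homologs on one scaffold) collapse to their first member before
anchoring.  `min_anchors` defaults to 5 — the conventional "more than five
shared paralogs" filter read inclusively — with a `strict_gt` switch for the
literal ">5" reading.  Classification is strict: `median_ks < 0.2` → recent;
exactly 0.2 → ancient; blocks with no finite anchor Ks are reported
unclassified.

## 5. Zigzag scaffold ordering (`zigzag`)

If scaffold W (one homeologous copy) carries recent-WGD blocks to scaffolds
B then C (the other copy) back-to-back, B and C were adjacent.  Per witness,
blocks are ordered by span midpoint; consecutive pairs hitting distinct
counterparts with ≤ `max_junction_gap` (default 10) unanchored witness genes
between them emit a signed edge.  Blocks overlapping by more than one gene
on the witness are homeologous duplicates of the same region, not
neighbours, and emit nothing.  Sign convention: an edge (x, sx, y, sy) means
laying x then y left-to-right with the signs applied reconstructs a
consistent strand; edges are canonical up to simultaneous reversal and sign
flip.

Edges are resolved greedily by descending witness evidence (ties: larger
combined scaffold length, then lexical ids); an edge is kept only when both
scaffold ends are free and no cycle would close, so the output is always a
set of vertex-disjoint signed paths.  `iterative_zigzag` repeats the whole
pass with the chained units as new coordinate systems until a fixpoint: a
longer unit can witness junctions no single scaffold spans.

**Structural recall bound.** A junction is only ever witnessable when the
spanning counterpart scaffold has ≥ `min_anchors` retained anchors on *both*
sides of it.  At the simulated toy density (60-gene chromosomes, 8 breaks
per tetraploid chromosome, retention 0.8 → a breakpoint roughly every 3.5
genes once both copies are pooled), that bound evaluates to ≈ 0.45 even with
`min_anchors = 2`, and iteration cannot pass it because the blocked
junctions pair up into mutual deadlocks across the two copies.  The
acceptance battery therefore measures precision ≈ 0.95 and recall ≈ 0.45 at
these settings; recall rises with scaffold gene content (real assemblies
carry tens of genes per scaffold) rather than with any tuning knob.

**Reference-guided ordering.** Scaffolds are assigned to the reference
chromosome holding the majority of their anchors (ties → unplaced); per
reference chromosome the recent-block graph is 2-coloured to separate the
two homeologous subgenomes (an odd cycle drops its lowest-anchor-count
scaffold to unplaced; persistent non-bipartiteness raises an error listing
the cycle); groups are ordered by median anchor rank and oriented by the
sign of the rank-versus-position trend.  Output serialises as AGP v2.1 with
100-bp `U` gaps of type `scaffold`, evidence `align_genus`.

## 6. Ks distributions and dating (`dating`)

Distributions exclude non-`ok` rows and values above the cap (default 3.0,
the NG86 saturation regime); family-average weighting gives each gene family
one unit of weight split over its pairs.  Peaks are located by Gaussian
mixtures on ln(Ks), components 1..max chosen by BIC, modal Ks =
exp(component mean); non-uniform weights are honoured by seeded weighted
resampling, and a degenerate fit falls back to kernel-density local maxima
(Silverman bandwidth), flagged by `method="kde"`.  Zero Ks values cannot
enter a log-scale fit and are dropped there (they remain in the
distribution object).

The clock `T = Ks/(2r)` uses `r = 6.68e-9` synonymous substitutions per site
per year by default — a value inside the usual dicot range that reproduces
the worked conversion 0.035 → 2.62 MYA — and is overridable in every entry
point and echoed in every result object.  LTR insertion ages apply the same
clock to the K2P distance between an element's 5′ and 3′ terminal repeats,
which are identical at insertion time.

## 7. Read-based quantification (`wgsquant`)

**Genome size.** Canonical k-mers (k odd, default 23) are counted exactly;
depths at or below the error cutoff (auto = first local minimum of the depth
spectrum) are excluded; the homozygous peak is the argmax of lightly
smoothed `c·count(c)` (snapped to the raw maximum among its neighbours, so a
sharp spectrum is not shifted by the smoothing window); `G = retained k-mer
total / peak depth`.

**Repeat genome proportion.** Alignment-based repeat masking is replaced by
exact canonical k-mer run matching: a read base is masked for a family when
it lies in a run of ≥ `min_run` (default 2) consecutive `match_k`-mers
(default 17) shared with the family consensus; overlapping family claims go
to the longer run, ties to the lexically smaller family id.  This surrogate
is deterministic and dependency-free and quantifies high-identity (young)
families well: an isolated 1% divergence leaves only the mutated base
unmasked, so the measured GP tracks truth to well under a percentage point
at 10× coverage; it *underestimates* old, highly diverged families and is
documented as such.  `GP(%) = masked bp / total bp × 100` exactly.

**Repeat amount.** Implemented as `GP × G` (bp).  The verbally stated
"masked length × total length × (genome size / data amount)" form is
dimensionally inconsistent (bp²); `GP × G` is the only reading with units of
bp and is what the per-family bar heights represent.

**Presence/absence.** Breadth = union of aligned read intervals over CDS
length, primary alignments with MAPQ ≥ 1 when reading SAM; a gene is
`present` iff breadth ≥ threshold (default 0.5, a flagged configuration
value — fractional-coverage bars, not a published cutoff).  The built-in
mapper (exact 31-mer seeds, ungapped interval placement, both strands) is
for synthetic experiments only; real data should arrive as SAM.

## 8. Problem sizes in the reproduction script

`scripts/acceptance.py` uses: 100 random 30-codon pairs for the NG86 oracle
check; 220-gene, 1120-bp-CDS simulations × 20 seeds per target (Ks 0.05 and
0.5) for modal-Ks recovery; 2×60-gene tetraploids with 8 breaks/chromosome ×
20 seeds for zigzag recovery (5 of them re-used for homeolog 2-colouring);
a ~125-kbp genome with 20%/10% repeat families at 10× for GP recovery; a
~110-kbp genome at 30× for k-mer genome size; and 150 genes (50 deleted) at
10× for presence/absence.  These sizes were chosen as the smallest at which
the estimators' sampling noise is comfortably inside the stated tolerances;
the whole battery runs in about a minute on one CPU.

## 9. Known limitations

* NG86 is not a maximum-likelihood codon model: no transition/transversion
  bias, no codon-frequency correction, no rate variation.  Agreement with
  `codeml` is therefore approximate and intentionally out of scope.
* The zigzag conflict policy is greedy, not a global optimisation; at
  realistic fragmentation (tens of genes per scaffold) this is adequate,
  and the structural recall bound above dominates any policy choice at toy
  densities.
* The k-mer masking surrogate undercounts diverged repeat families; the GP
  machinery accepts externally masked totals when alignment-based masking is
  preferred.
* The simulator omits indel errors, GC bias, heterozygosity and TE
  transposition dynamics, so passing tests demonstrate estimator
  correctness under the stated noise model, not robustness to every real
  sequencing artefact.
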