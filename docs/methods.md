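# Methods

## Problem setting

A human tumor engrafted in an immunodeficient mouse produces a mixed RNA
sample: transcripts of the cancer cells are human, transcripts of the
recruited stroma (fibroblasts, endothelium, residual immune cells) are
mouse. Because human and mouse exons differ by roughly 15 % at the sequence
level, bulk RNA-seq of the graft can be deconvolved *by alignment*: a read
pair is attributed to the species whose transcript it matches best.
xenolink turns the two per-species expression profiles into a quantitative
map of cancer–stroma signalling over a curated ligand–receptor database.

## Read assignment

Pairs are aligned to the combined human+mouse transcript set (both mates on
the same transcript, at most one mismatch per mate). The assignment rule is
deterministic best-hit: among all candidate placements, those with the
minimum total pair mismatches are kept; if they name exactly one gene of one
species the pair is assigned there, and any tie across species or across
genes excludes the pair. Splice variants of one gene are a single candidate.
This is intentionally conservative — excluded pairs cost depth but
essentially never produce cross-species contamination (the misassignment
rate on the package's error-free disjoint simulations is exactly 0, and a
probabilistic EM-style reassignment is deliberately out of scope).

Counts are kept per gene on the representative (longest) transcript,
indexed by distance from the poly-A tail, because the library chemistry is
poly-A primed: position j = 1 is the 3′-terminal nucleotide. Two vectors
are maintained: fragment coverage `c_ij` and read starts `c'_ij` (the
3′-proximal fragment end), the latter being the natural "event" count for
copy-number estimation.

## Mappability

Regions shared verbatim (or within one mismatch) between species, or
between genes, cannot yield assignable reads. The per-nucleotide
mappability `m_ij` counts the 50 bp windows covering position j that occur
nowhere else in the combined database outside the gene itself. The
implementation hashes 2-bit-encoded k-mers; the one-mismatch tolerance uses
a pigeonhole split into two half-window seeds with explicit verification.
Reverse-complement hits count by default (reads align to either strand of a
transcript database in practice); hits on splice variants of the same gene
do not break uniqueness, since the model is gene-level. The index is exact:
on small databases it reproduces an exhaustive window-vs-window Hamming
scan bit for bit (this equivalence is asserted in the test suite and
recomputed by the acceptance script).

## Coverage bias model

Within a gene, coverage is not uniform: it decays with distance from the
poly-A tail (fragmented RNA is recovered preferentially near the priming
site) and varies mildly with local GC content. Coverage at position j of
gene i is modelled as Poisson with log link,

    log E[c_ij] = log( m_ij / Σ_k m_ik ) + log v_i + α g_ij + β d_ij

with `g_ij` the GC fraction of the 50 nt window centred on j, `d_ij = j`
the distance from the poly-A tail in nucleotides, `v_i` the gene's
expression, and α, β shared across all genes of both species in a sample
(one sequencing process, one pair of bias coefficients). The
mappability-normalised offset makes v a *mappable-length* quantity rather
than a transcript-length quantity.

Fitting is block-coordinate ascent: a Poisson GLM (statsmodels IRLS)
updates (α, β) with log(m_ij/Σm · v_i) as offset, then each v_i is updated
in closed form as the Poisson MLE of a per-gene multiplier. The GLM carries
an intercept, redundant with the v block and folded into it after each
update; without it a common scale error in the current v iterate would leak
into α and β, since (g, d) span no constant. Convergence is declared when
the relative change of (α, β) drops below 1e-6 (50 iterations maximum;
non-convergence is flagged, not raised). Training positions may be thinned
to every s-th nucleotide to bound the design matrix; the default uses all
mappable positions.

Training transcripts are restricted to genes that constrain the positional
coefficients well: no splice variant, length above 8 kb, more than 80 %
of positions covered. These thresholds are configuration; when nothing
passes (small synthetic transcriptomes, shallow samples) the fit falls back
to relaxed thresholds (2 kb, 50 %) with a warning. The initial value of v_i
is the mappability-weighted coverage sum over the 3′-most
N′ = min(N_i, 3000) positions — restricting initialization to the poly-A
proximal window keeps it away from the strongly decayed 5′ tail and speeds
convergence.

## Copy-number estimation and normalisation

The final estimate uses read starts, which are not smeared over fragment
spans:

    ṽ_i = Σ_k c'_ik / Σ_{k: m_ik > 0} exp(α g_ik + β d_ik)

The denominator sums the bias weight over *mappable* positions only. This
is what makes the estimate robust to homologous-block masking: if a block
of a uniformly covered gene is unmappable, numerator and denominator shrink
proportionally and ṽ is unchanged — the mappable-length rationale, asserted
as a test invariant.

Per species separately (the cancer:stroma ratio varies by sample, so
library-size normalisation cannot be shared), a constant Z scales ṽ so that
the genes at or below the species' 95th percentile of ṽ (linear
interpolation over genes with ṽ > 0, boundary gene included) sum to
300,000 normalised copies — roughly the mRNA complement of an average
mammalian cell, so ṽ′ reads as "mRNA molecules per average cell". Genes
above the percentile are scaled by the same Z but excluded from the sum, so
a handful of extreme genes (mitochondrial, ribosomal) cannot compress the
scale of everything else.

## Interaction indices and zones

For ligand i and receptor j with normalised expression L_C, L_S, R_C, R_S
(C = cancer/human, S = stroma/mouse; mouse values first collapsed onto
human symbols through the homolog map, summing many-to-one mappings):

    C→S:  X = L_C/(L_C+L_S)   Y = R_S/(R_C+R_S)   Z = √(L_C·R_S)
    S→C:  X = L_S/(L_C+L_S)   Y = R_C/(R_C+R_S)   Z = √(L_S·R_C)

X and Y are complementary across directions (X_CS + X_SC = 1, likewise Y)
and Z satisfies Z_CS·Z_SC = √(L_C·L_S·R_C·R_S); both identities are
enforced as property tests. The (X, Y) unit square is partitioned at 0.5
(boundary inclusive on the "strong" side) into zones 1–4 per direction;
zone 1 (both strong) holds the mutually dependent interactions — signal
made by one compartment and received by the other — which are the natural
drug-target candidates. A zero denominator leaves the index undefined
rather than pinned to 0 or 0.5; undefined scores carry no zone and are
excluded from zone counts and plots, since 0/0 has no privileged value.

Summaries follow the conventions of the figures they feed: zone counts at
signal-strength thresholds use strict inequalities (Z > 10, Z > 50), as
does the mutually-dependent extraction rule (X > 0.75, Y > 0.75, Z > 50);
the zone *boundaries* are inclusive (≥ 0.5). Multi-sample averaging takes
the pairwise-available mean of each index (samples where it is defined)
and reclassifies the zone from the averaged X, Y — recomputation, not
majority vote, which the output metadata records. Averages are computed
order-independently (values are sorted before summation), so permuting
samples is bit-identical.

## GO module enrichment

An interaction belongs to a GO category when its ligand or receptor is a
member; all categories are used as given, with no DAG propagation. For a
target zone set (the figure panels use {1,2} and {1,3} per direction), the
null hypothesis is that category members land in the target zones at the
background rate p0 of all classified interactions of that direction; the
alternative is enrichment, and p = P(Bin(n, p0) ≥ k) (one-sided, upper
tail). Whether both directions should be pooled into the background is not
determinable from the figures; per-direction backgrounds are used and
recorded. P-values become q-values either by Storey's method — π0
estimated on a λ grid with a cubic-polynomial smoother evaluated at the
largest λ, a stand-in for the spline smoother of the reference
implementation — or plain Benjamini–Hochberg (π0 = 1). Categories are
ranked by target-zone fraction, ties broken by mean member signal
strength, and categories averaging below signal strength 10 are dropped as
uninterpretable. Representative genes are those appearing in at least two
ranked categories with at least one interaction above signal strength 10.

## Synthetic data: what it emulates and what it does not

The generator produces a complete two-species study with known truth:
random transcripts (2–4 kb, typical mammalian mRNA) whose GC composition
varies in ~750 nt blocks so the GC covariate is informative within genes;
a configurable fraction of human/mouse gene pairs sharing a verbatim
homologous block (default 10 % of genes, 300 nt); lognormal true copy
numbers; 50 bp paired-end fragments of ~200 nt sampled with 3′-end weight
exp(α·g + β·d) and per-gene pair counts proportional to v_i and the
species mixing fraction. Default coefficients are α = −2 per unit GC
fraction (mild) and β = −1e−3 per nucleotide (strong 3′ decay, e-folding
1 kb). Reads are emitted as already-placed alignments; pairs falling
entirely inside a shared block also receive the homologous placement with
equal mismatch count, which the assignment stage must exclude as a
cross-species tie. Base-call errors (optional) respect the one-per-mate
alignment contract.

Two generator modes exist deliberately:

* **Read-level** (`simulate_reads`): full physical pipeline — placements,
  ties, fragment-span coverage. Used for assignment, misassignment and
  end-to-end expression recovery (Pearson r > 0.99 at 200 genes per
  species and 2×10⁵ pairs).
* **Count-level** (`simulate_counts`): positional Poisson draws taken
  exactly from the model above. Used for coefficient recovery, where α̂
  and β̂ land within a fraction of a percent of truth.

The distinction matters because physical coverage aggregates fragments
over ~200 nt, while the model's covariates are position-local; fitting the
model to fragment-smeared coverage attenuates α̂ (and mildly β̂) by tens of
percent. This is a property of the model applied to real reads, not of the
implementation — the same attenuation will be present on real libraries,
where the fitted coefficients should be read as *effective* bias slopes.
The count-level mode demonstrates that the estimator itself is unbiased
when the model holds exactly.

Other simplifications of the generator: substitution errors only (no
indels), no PCR duplicates, no strand-specific protocol, homology as
identical blocks rather than diffuse ~85 % similarity, and no
error-induced spurious alignments. Passing tests therefore validate the
statistical machinery and the bookkeeping, not aligner behaviour on real
genomes.

## Numerical and format choices

* Coordinates are 0-based half-open internally; distances from the poly-A
  tail are reported 1-based. All per-position vectors (counts, m, g, d)
  share the poly-A-distance orientation, index 0 = 3′-terminal nucleotide.
* Counts from any splice variant are projected onto the representative
  (longest) transcript by poly-A distance; positions beyond its length are
  dropped with a warning.
* v is floored at machine-tiny during iteration so a transiently empty
  gene cannot produce -inf offsets.
* Numeric outputs are written with 6 significant digits; deterministic
  stages are bit-identical across reruns and every CLI stage writes its
  resolved configuration next to its outputs.
* Problem sizes in the test suite and acceptance script (24–200 genes per
  species, 2×10⁴–2×10⁵ pairs) were chosen as the smallest sizes at which
  the recovery statistics are stable; the statistical contracts they check
  are size-free.

## Known limitations

Quantification is gene-level only (no isoform deconvolution); multi-mapped
pairs are discarded rather than probabilistically reassigned; interactions
involving lymphocyte biology are undercalled in xenografts on
immunodeficient hosts regardless of method; and cross-species
ligand–receptor reactivity differences are not modelled — a strong mouse
ligand scored against a human receptor assumes the interaction crosses
species at face value.
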