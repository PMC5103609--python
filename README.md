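# xenolink

Cancer–stromal interactome profiling from xenograft RNA-seq.

A human tumor grown in an immunodeficient mouse contains two transcriptomes
at once: the cancer cells contribute human mRNA, the recruited stroma
(fibroblasts, endothelium, immune cells) contributes mouse mRNA. Because
the two species differ by roughly 15 % in exon sequence, bulk RNA-seq of
the graft can be split by alignment into a cancer profile and a stroma
profile from a single sample. xenolink implements the full analysis chain
for researchers studying tumor–microenvironment signalling:

1. **Read assignment** — each aligned pair goes to human or mouse and to a
   single gene by a deterministic best-hit rule; equal-mismatch ties are
   excluded rather than guessed.
2. **Mappability** — per-nucleotide 50 bp uniqueness across the combined
   two-species transcript set, so homologous regions cannot distort
   expression estimates.
3. **Bias-corrected quantification** — a Poisson model of positional
   coverage, `log E[c_ij] = log(m_ij/Σ_k m_ik) + log v_i + α·g_ij + β·d_ij`,
   removes GC bias (α) and the 3′ decay with distance from the poly-A tail
   (β); normalised copy numbers ṽ′ are scaled so an average cell holds
   300,000 transcripts.
4. **Interactome scoring** — every curated ligand–receptor pair gets three
   indices per signalling direction (cancer→stroma and stroma→cancer):
   ligand dependency `X = L_C/(L_C+L_S)`, receptor dependency
   `Y = R_S/(R_C+R_S)`, signal strength `Z = √(L_C·R_S)` (and the mirrored
   forms for stroma→cancer). The (X, Y) unit square splits at 0.5 into four
   zones; zone 1 — both strong — holds the "mutually dependent"
   interactions that only exist when both compartments are present, the
   natural drug-target candidates.
5. **GO module enrichment** — one-sided binomial tests of zone composition
   per GO category, with Storey or Benjamini–Hochberg q-values.

A seeded synthetic-data module generates complete two-species studies
(transcriptomes with shared homologous blocks, biased reads with known α,
β, v) so every stage is testable against ground truth without any
downloads. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from xenolink import synthetic
from xenolink.assignment import assign_pair, accumulate_counts, summarize_sample
from xenolink.mappability import compute_mappability
from xenolink.quantify import (build_gene_data, fit_bias_model,
                               estimate_copy_numbers, TrainingFilter)
from xenolink.lrdb import collapse_mouse_homologs
from xenolink.interactome import (score_profile, count_strong_by_zone,
                                  extract_mutually_dependent)

cfg = synthetic.SimulationConfig(seed=42, n_genes=40, n_pairs=50000)
tx = synthetic.simulate_transcriptomes(cfg)
reads = synthetic.simulate_reads(cfg, tx)

assignments = [assign_pair(p) for p in reads.pairs]
counts = accumulate_counts(assignments, tx.transcripts)
summary = summarize_sample(counts)
print(f"assigned: human={summary.assigned_human} mouse={summary.assigned_mouse} "
      f"excluded={summary.excluded} (mouse {summary.mouse_percent}%)")

tracks = compute_mappability(tx.transcripts)
gene_data = build_gene_data(counts, tracks, tx.transcripts)
model = fit_bias_model(gene_data, filters=TrainingFilter(min_length=2000,
                                                         min_covered_fraction=0.5))
print(f"bias fit: alpha={model.alpha:.3f} beta={model.beta:.2e}")

profiles = estimate_copy_numbers(gene_data, model)
mouse_on_human, _ = collapse_mouse_homologs(profiles["mouse"].normalized,
                                            tx.homolog_map)
scores = score_profile(synthetic.make_interaction_db(tx),
                       profiles["human"].normalized, mouse_on_human)
print(f"mutually dependent with Z>10: "
      f"C-S={count_strong_by_zone(scores, {1}, 10, 'C-S')} "
      f"S-C={count_strong_by_zone(scores, {1}, 10, 'S-C')}")
```

prints

```
assigned: human=25581 mouse=24648 excluded=54 (mouse 49.07%)
bias fit: alpha=-1.202 beta=-8.55e-04
mutually dependent with Z>10: C-S=7 S-C=18
```

Reading the output: of 50,283 simulated pairs, 54 fell in cross-species
homologous blocks and were excluded as ties (never misassigned); the
1:1 mixture is recovered as 49.07 % mouse. The fitted 3′-decay coefficient
β ≈ −8.6×10⁻⁴/nt recovers the simulated decay (−1×10⁻³; coverage is
fragment-smeared, so read-level coefficients are effective slopes — see the
methods note), and 7 cancer→stroma plus 18 stroma→cancer interactions land
in zone 1 with strong signal. `extract_mutually_dependent(scores)` returns
the ranked candidate table.

The same pipeline runs from the shell:

```sh
xenolink all --seed 42 --n-genes 40 --n-pairs 50000 --outdir run/
```

which writes per-stage outputs (counts, mappability, model JSON,
expression tables, interaction scores, viewer JSON, GO rankings), each with
its resolved configuration alongside. Real data enter through
`xenolink assign --sam aligned.sam --fasta transcripts.fasta` (references
named `hs|GENE|TX` / `mm|GENE|TX`), your own interaction TSV
(`ligand`/`receptor` columns; a curated-style core set ships with the
package), a Homologene-style `mouse_gene`/`human_gene` map, and a
two-column GO membership table.

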