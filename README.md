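# methylselex

Analysis of HT-SELEX / Methyl-SELEX experiments that probe how cytosine
methylation reshapes a transcription factor's DNA-binding specificity —
in particular the balance between monomeric and homodimeric binding and,
within homodimers, the preferred half-site orientation and spacing.

Plant transcription factors of the WOX family recognize a short half-site
(here `YAATYA`, Y = C/T); two half-sites combine into dimeric
cis-regulatory elements classified as direct repeats (DR, same
orientation), inverted repeats (IR, head-to-head) and everted repeats (ER,
tail-to-tail), named by orientation plus the gap in bases between the
half-site spans — ER0, ER1, DR3, ... . Because methylation chemistry in a
Methyl-SELEX library converts every cytosine to 5mC on both strands,
methylation is a library-level state, and its effect on binding can be
position-dependent and, notably, spacing-dependent: the preferred
homodimeric configuration can switch (e.g. from ER1 to ER0) when the
library is methylated.

The package provides:

* **I/O** — FASTA/FASTQ ligand libraries, MEME minimal motif format,
  narrowPeak peak sets, FASTA+GFF3 genome annotation;
* **k-mer statistics** — per-cycle enrichment trajectories, log-linearity
  fits, cross-library comparison of 8-mers/12-mers, and E-MI
  (enrichment-based mutual information between 3-mers at position pairs);
* **motif construction** — seed-driven multinomial PWM building with
  shuffled-background correction, exact DP score-distribution p-value
  thresholds, both-strand matching, motif enrichment;
* **dimer grammar** — half-site scanning, DR/IR/ER + spacing
  classification of probes, enumeration of gapped dimeric seeds;
* **genome analysis** — TSS-proximity motif density, promoter target
  assignment, peak-set overlap with Fisher tests, top-peak motif
  containment, peak-intensity comparisons;
* **a SELEX simulator** with an explicit ground-truth binding model
  (monomer energies, spacing-dependent cooperativity, methylation deltas,
  methylation-dependent cooperativity), plus toy genome/peak generators, so
  every stage is testable against known truth.

See `docs/methods.md` for the models, estimators and numerical choices.

## Worked example

Classify the EMSA probe whose core reads `GATTG·CAATCA·ATG`:

```python
>>> from methylselex import classify_probe
>>> probe = "ATGCTAGCTCCATCTGTGATTGCAATCAATGGCGGTGACGTACT"
>>> classify_probe(probe, half_site="YAATYA")
DimerAssignment(orientation='ER', spacing=0, name='ER0')
```

The scanner finds a − strand half-site (`TGATTG`, the reverse complement
of `CAATCA`) immediately followed by a + strand half-site — a tail-to-tail
pair with a 0-base gap, i.e. an everted repeat, ER0. Inserting one base
between the half-sites (`GATTG·A·CAATCA`) yields `ER1`.

Simulate a paired SELEX / Methyl-SELEX experiment from the reference
ground truth and name the top-enriched configuration of each series:

```bash
$ methylselex all config.yaml      # config: out_dir, seed, simulate block
```

with `config.yaml` containing, say, `{out_dir: out, seed: 1}`. The summary
printed at the end contains, among other fields:

```json
"libraries": {
  "methyl": {
    "cycles": 5, "reads": 10000, "methylated": true,
    "top_dimer": "ER0", "top_dimer_enrichment": 416.8293, "max_emi": 0.5467
  },
  "normal": {
    "cycles": 5, "reads": 10000, "methylated": false,
    "top_dimer": "ER1", "top_dimer_enrichment": 262.1091, "max_emi": 0.7972
  }
}
```

The reference ground truth has cooperativity peaked at ER1 for unmodified
DNA and at ER0 for methylated DNA, with methyl deltas repressing the
monomeric path — and the pipeline recovers exactly that switch from the
simulated reads: ER1 tops the normal series and ER0 the methylated one,
each far above its shuffled background (the enrichment values), while the
large E-MI maxima confirm strong position-pair dependence in both selected
pools. The per-configuration ranking tables, k-mer trajectories, E-MI
matrices, MEME motif files and the position-wise methyl-vs-normal
comparison are written under `out_dir`.

The same stages run on real data: per-cycle FASTQ/FASTA files in the
config's `normal:`/`methyl:` blocks, a genome FASTA + GFF3 for the `tss`
subcommand, and MACS-style narrowPeak files for the `peaks` subcommand.

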