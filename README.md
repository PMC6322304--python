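# pepdegradome

Analysis toolkit for **endogenous peptidomics**: comparing the pools of
native peptides that proteolysis releases from functional proteins, between
cellular compartments (cell vs. secretome) and between treatment conditions
(e.g. control vs. a stress-hormone pulse such as methyl jasmonate).

It is written for proteomics researchers who have label-free peptide
identification tables (MaxQuant `peptides.txt`-style TSV), a precursor
proteome FASTA, and optionally membrane-topology predictions and external
antimicrobial-predictor scores — and who want the standard battery of
degradome analyses as tested, reusable code rather than one-off scripts.

## What it computes

* **Replicate filtering and set algebra.** A peptide counts as identified in
  a condition when seen in ≥ 2 biological repeats. Filtered sets are
  compared as Venn partitions; for treatment-unique peptides the fraction
  arising from *new precursors* (proteins with no peptide at all in the
  control) is reported.
* **Quantification.** Per-peptide log₂ fold change of mean XIC intensity
  between conditions, and the Pearson correlation of log₁₀ intensities over
  peptides quantified in both.
* **Protein degradation patterns (PDP).** Each precursor is split into 10
  equal relative-length windows and peptide start positions are counted per
  window, giving a precursor × window matrix; the 10 % window deliberately
  absorbs peptide ladders. Patterns are compared between conditions by
  cosine similarity of unit-normalised rows.
* **Composition.** Pooled amino-acid frequencies (with a background set
  sampled from protein regions *not* covered by any observed peptide),
  per-residue Fisher tests with Benjamini–Hochberg correction, and
  position-frequency matrices of the five N- and C-terminal residues with
  per-position information content in bits.
* **Physicochemical screen.** For every complete AAindex scale the
  per-peptide mean descriptor is computed; a two-sided Mann–Whitney test per
  index compares compartments, with significance tiers at
  p < 10⁻⁵ ("sig"), 10⁻¹⁵ ("sigAA") and 10⁻²⁵ ("top"); Ward hierarchical
  clustering groups the indexes into six clusters and Fisher tests ask which
  cluster is enriched among the significant indexes (the cluster holding the
  canonical hydrophobicity scales is labelled as such).
* **Membrane-topology localisation.** Each mapped peptide is assigned the
  topology class (inside / outside / TMhelix) covering the strict majority
  of its residues; compartment × location over-representation is tested with
  two-sided Fisher exact tests.
* **Antimicrobial triage.** CAMP and iAMPpred probabilities (threshold 0.5)
  and the ADAM SVM score (strictly > 0) are combined by conjunction into a
  consensus call; candidates are ranked by consensus, probability product
  and fold change, with a log₂FC > 1 up-regulation flag.
* **Simulation.** An in-silico proteolysis simulator generates proteomes,
  topology architectures and peptide tables with configurable C-terminal
  start bias, hydrophobicity and topology sampling biases, peptide ladders,
  treatment-induced extra peptides and new precursors, Bernoulli per-repeat
  detection and log-normal intensities — together with ground truth for
  every emitted row, so the whole pipeline is testable closed-loop.

## Worked example

Simulate a full study (1,000 proteins, 2,000 peptides per compartment,
3 repeats) and analyse it:

```python
from pepdegradome import RunConfig, SimulationConfig, run_synthetic

results, inputs = run_synthetic(RunConfig(rng_seed=1), SimulationConfig(rng_seed=1))

v = results.venns["cell"]
print(v.unique_a, v.shared, v.unique_b)      # 56 2471 210
print(results.new_precursors["cell"])        # (66, 0.3142857142857143)
print(results.correlations["cell"][0])       # 0.9453794167411395
print(results.truth_report["cell"]["log2fc_bias"])  # -0.005001047060575328
```

Reading the output: of the 2,737 distinct cell peptides passing the
two-repeat filter, 210 are unique to the treated condition and 31 % of those
come from precursors never seen in the control — the simulator's
treatment model (extra proteolysis plus held-out new precursor proteins)
read back through the analysis. Control and treated intensities correlate at
r ≈ 0.95 over the 2,471 shared quantified peptides, and the injected log₂
fold changes are recovered with negligible bias (−0.005). The property
screen on the same run flags the hydrophobicity scales in the secretome
direction (the simulator samples secretome peptides from hydrophobic
regions), and the hydrophobicity cluster is the enriched one
(Fisher p ≈ 3 × 10⁻⁷).

The same pipeline runs from the shell:

```bash
pepdegradome simulate --seed 1 --out-dir run1/        # synthetic study + report bundle
pepdegradome run --peptides peps.tsv --fasta prot.fasta \
    --topology tmhmm.txt --aaindex aaindex1 --out-dir out/   # real inputs
```

Every bundle contains TSV matrices plus `manifest.json` with the config
snapshot, seed and SHA-256 checksums of all outputs; identical seeds
reproduce the bundle byte-for-byte.

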