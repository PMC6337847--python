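# snipchip

Same-species spike-in normalization for ChIP-seq. Cells from a second
strain of the same species are mixed into every sample as spike-in
material; sequencing reads are assigned to their genome of origin through
the SNPs that distinguish the two strains, and the ratio of spike-in to
test signal yields a normalization factor that places all conditions on a
common quantitative scale.

## How it works

1. **Hybrid reference & SNP map** (`snipchip.snpmap`): the two strain
   assemblies are concatenated into one hybrid reference with contigs named
   `<strain>_<chrom>`. For colinear synthetic pairs the SNP map is derived
   by positionwise comparison; for real assemblies it is loaded from a VCF
   (REF = test allele, ALT = spike-in allele).
2. **Read classification** (`snipchip.classify`): reads are placed under
   perfect-match conditions — a read is assigned only when its sequence
   occurs at exactly one location in the hybrid (both strands searched).
   Reads matching both genomes (no SNP spanned) are ambiguous and
   discarded; the counts of test- and spike-assigned reads are `C_endo`
   and `C_spike`.
3. **Quotients and the normalization factor** (`snipchip.normalize`): per
   sample, `Q = C_spike / C_endo`. The input sample's Q measures the
   spike-in cell fraction (`percent = 100·Q/(1+Q)`); the ChIP sample's Q
   additionally reflects target abundance. Per condition,
   `Nf = Q_input / Q_chip`, and dividing by the reference condition's Nf
   gives the relative target level. Four estimators are available:
   `read_count` (default) and three mean-pileup variants (all positions,
   SNP positions, SNPs within peaks).
4. **Tracks** (`snipchip.tracks`): coverage pileups, SPMR depth scaling,
   Nf scaling, bedGraph/BED I/O, and a naive threshold peak caller for
   fixtures.
5. **Robustness** (`snipchip.robustness`): read-subsampling grids
   (depth invariance of the normalization factor) and spike-in titration
   series (linearity of input vs ChIP spike read proportions).
6. **Simulation** (`snipchip.simulate`): synthetic colinear genome pairs
   at configurable divergence, peaked binding profiles, and ChIP/input
   read sets for cell mixtures with known ground truth, plus closed-form
   expected values (`Q_input = s·L_s/((1-s)·L_t)`,
   `Q_chip = s·W_s/((1-s)·A·W_t)`, `Nf = A` for matched genomes/profiles)
   against which every estimator is tested.

## CLI

```sh
# SNP map (TSV) + hybrid reference from two FASTAs
snipchip snpmap --test sk1.fa --spike s288c.fa --out map.tsv --hybrid-out hybrid.fa

# classify reads against the hybrid
snipchip classify --hybrid hybrid.fa --reads chip.fq --out assign.tsv --counts-out counts.json

# full pipeline from a YAML run config (see below)
snipchip normalize --config run.yaml --out results/

# scale an existing bedGraph by a normalization factor
snipchip tracks --bedgraph cov.bedgraph --nf 0.288 --out scaled.bedgraph

# synthetic experiment fixture with ground truth
snipchip simulate --config sim.yaml --out fixtures/

# robustness analyses on simulated data
snipchip robustness subsample --sizes 50000,100000,150000 --seed 7 --out grid.tsv
snipchip robustness titration --fractions 0.05,0.1,0.15,0.2,0.25,0.3 --out titration.tsv
```

Run config for `snipchip normalize`:

```yaml
test_fasta: sk1.fa
spike_fasta: s288c.fa
# snp_vcf: snps.vcf        # optional; otherwise derived positionwise
reference: wt
method: read_count          # or pileup_all / pileup_snp / pileup_snp_peaks
conditions:
  wt:
    chip_fastq: wt_chip.fq
    input_fastq: wt_input.fq
  mutant:
    chip_fastq: mut_chip.fq
    input_fastq: mut_input.fq
    # or count tables from an external aligner (samtools idxstats layout):
    # chip_table: mut_chip_idxstats.tsv
    # input_table: mut_input_idxstats.tsv
```

The output directory receives `report.json` (per condition: C_endo/C_spike
per sample, Q_input, Q_chip, spike-in percent, Nf, level vs reference,
warnings) and spike-in-scaled SPMR bedGraph tracks.

## Notes and limitations

- Alignment is strict exact matching (end to end, zero mismatches) on an
  internal index; external alignments enter only through per-contig count
  tables.
- Internal pileups use raw read-length coverage without fragment-size
  extension; a constant extension cancels in the Q ratio.
- Indels and structural variants are out of scope for the positionwise
  SNP derivation; supply a VCF for real divergent assemblies.
- A warning is emitted when the estimated spike-in percentage falls below
  15%, where the normalization factor becomes noisy.
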