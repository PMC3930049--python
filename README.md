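# mhcpop

Pooled-amplicon MHC class IIB genotyping and local-adaptation statistics for
population samples.

## The problem

Genes of the major histocompatibility complex (MHC) are prime candidates for
pathogen-mediated local adaptation: class IIB exon 2 encodes the
peptide-binding region (PBR), the codons that contact pathogen-derived
antigens and the expected hotspot of balancing/diversifying selection. A
common and economical design genotypes MHC by pooling 18–20 individuals per
population, amplifying exon 2 of each gene duplicate with 5-bp
population-tagged primers, and sequencing the pools together — at the cost of
heavy PCR/sequencing artifacts (substitution errors, homopolymer indels,
chimeras) and the loss of individual genotypes. `mhcpop` implements the full
analysis chain for such designs:

1. **Variant calling** (`mhcpop.amplicon`) — demultiplex tagged reads,
   truncate to a fixed length, collapse exact variants, remove singleton and
   single-population artifacts, screen frameshifts by reference-anchored
   alignment, and emit a population × variant presence–absence matrix of
   true variants (TV).
2. **Selection statistics** (`mhcpop.selection`) — per-codon amino-acid
   diversity D = 1/(20·Σpᵢ²), percent polymorphic codons by PBR partition,
   Nei–Gojobori d_N/d_S with Jukes–Cantor correction, and a codon-bootstrap
   Z-test of the null d_N = d_S; Welch t-tests for partition contrasts.
3. **Differentiation** (`mhcpop.differentiation`) — Euclidean
   presence–absence distances standardized to (d−d_min)/(d_max−d_min),
   Mantel and partial Mantel permutation tests of isolation by distance
   (IBD), outlier-pair masking, Hardy–Weinberg dominant-marker (AFLP-style)
   F_ST, and a resampled neutral envelope of IBD regression slopes.
4. **Community ecology** (`mhcpop.community`) — QC filtering of classified
   16S records, pathogen flagging, species richness S, PERMANOVA.
5. **Association** (`mhcpop.association`) — OLS regressions of percent
   polymorphic codons on bacterial richness with ANOVA F-tests on (1, n−2)
   degrees of freedom.
6. **Synthetic data** (`mhcpop.simulate`) — generates all of the above
   inputs with known ground truth (true alleles per pool, artifact reads,
   realized IBD slope, programmed association effect), so every stage is
   testable against truth.

## Worked example

```python
from mhcpop import simulate, amplicon, selection

cfg = simulate.SimConfig(seed=1)                      # 9 pools, 24 alleles
alleles = simulate.simulate_allele_pool(cfg)
pools = simulate.assign_pool_alleles(cfg, alleles)
tags = simulate.default_tag_map(cfg)
reads, truth = simulate.simulate_pool_reads(cfg, pools, alleles, tags)

specs = [amplicon.PoolSpec(p, tags[p], simulate._FWD_PRIMER, simulate._REV_PRIMER)
         for p in cfg.pop_labels]
result = amplicon.run_filter(reads, specs, reference=alleles["A001"])
print(result.stats)

mask = selection.PbrMask("DAB1", cfg.pbr_mask, cfg.n_codons)
print(selection.locus_summary(result.alignment, mask, n_boot=1000, seed=1).round(3))
```

prints

```
{'n_assigned': 10800, 'n_unassigned': 0, 'n_discarded_short': 0,
 'n_variants': 5222, 'n_retained': 177, 'removed_frameshift': 212,
 'removed_single_population': 293, 'removed_singleton': 4540}
  locus partition  n_codons     dN     dS  dN_dS      Z      P
0  DAB1   non-PBR        45  0.044  0.073  0.601 -1.919  0.972
1  DAB1       PBR        10  0.219  0.092  2.398  2.345  0.010
2  DAB1       all        55  0.071  0.074  0.953 -0.223  0.588
```

Reading the output: of 10 800 simulated reads, 5 222 distinct sequence
variants were observed; the singleton / two-population / frameshift rules
removed the overwhelming majority as artifacts, leaving 177 retained TV
(every true allele present in ≥ 2 pools is among them — the surplus over the
24 simulated alleles is recurrent substitution artifacts, which no
count-based filter can separate from rare alleles). The selection table then
shows the signature the generator programmed: d_N/d_S ≈ 2.4 with a one-tailed
P = 0.010 at the 10 PBR codons (positive selection detected), purifying-like
d_N/d_S ≈ 0.6 and P ≈ 1 at the 45 non-PBR codons.

A single YAML-configured run of all six stages, with per-stage outputs and a
checksummed manifest:

```sh
mhcpop run --config run.yaml          # or: mhcpop simulate / filter / selstats /
                                      #     ibd / community / assoc, standalone
```

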