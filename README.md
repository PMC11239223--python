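# phosreport

Site-level and peptide-level quantitative reporting for DIA-MS
phosphoproteomics.

## The problem

Data-independent acquisition (DIA) search engines such as Spectronaut and
DIA-NN export phosphoproteomics results as long-format tables of fragment
(or precursor) intensities per run — one row per ion observation. Turning
that into the table biologists actually analyse, one row per
**phosphosite**, is not a simple pivot: several peptides can carry
evidence for one site, one peptide can carry several phospho groups, a
peptide can occur at multiple positions of a protein or in multiple
protein isoforms, and every observation must first pass identification
and site-localization confidence filters. `phosreport` implements this
collapse for both engines' dialects, with a proper label-free
quantification method (MaxLFQ) rather than naive intensity summing.

## What it does

1. **Optional median normalization** — per run *r*, intensities are
   scaled by `f_r = exp(m − m_r)` where `m_r` is the run's median log
   intensity and `m` the mean of the `m_r`, equalizing medians across
   runs without touching within-run ratios.
2. **Class-I filtering** — keep rows with peptide q-value `< 0.01` and
   site localization confidence `≥ 0.75` (Spectronaut score) or `≥ 0.01`
   (DIA-NN score); the localization filter is optional at peptide level.
3. **Key construction** — phosphosite identifiers
   `<accessions>_<sites>_M<multiplicity>` built from the protein
   group, the mapped residue position(s) and the multiplicity class
   (1, 2, or 3 = three or more phospho groups on the evidencing
   peptide), covering single-site, repeated-peptide (ambiguous,
   position alternatives enumerated), multi-phospho and multi-isoform
   mapping scenarios; or phosphopeptide identifiers
   `<sequence>_<modification>x<count>…` that append per-modification
   counts to the stripped sequence.
4. **Quantification** — each key's ions × samples intensity matrix is
   summarized per sample by `sum`, `max`, or `maxlfq`. MaxLFQ estimates
   per-sample log2 abundances `w_s` from the median pairwise log ratios
   `r_ij = median_f (log2 x_fj − log2 x_fi)` over shared ions by least
   squares, `min Σ (w_j − w_i − r_ij)²`, solved per connected component
   of the sample-sharing graph with the overall scale anchored to the
   mean observed log2 intensity.

A DIA-NN main report is first converted: semicolon-packed fragment
intensities are unrolled into one row per positive fragment, and protein
groups are recomputed by locating each stripped peptide in the search
FASTA so isoform membership is explicit.

A synthetic-data module generates complete mixed-species spike-in
experiments (FASTA, report, ground truth) in either dialect, with a
known multiplicative ion × sample intensity model, for validation and
benchmarking.

## Worked example

Simulate a two-species spike-in experiment (five conditions in which the
"yeast" species is spiked at 25/50/100/150/200 units against a constant
background, three replicates each) and build both reports:

```sh
$ phosreport simulate --out demo --seed 42 --replicates 3
wrote fixture with 33976 report rows, 806 true sites to demo

$ phosreport demo/report.tsv -tool sn --fasta demo/proteome.fasta
sites: 806 keys x 15 samples -> demo/report-sites.tsv
peptides: 628 keys x 15 samples -> demo/report-peptides.tsv
```

`report-sites.tsv` holds one row per phosphosite key and one column of
log2 abundance per run:

```
key            protein_group  positions  multiplicity  n_ions  yeast25_rep1 ...
H0040_S276_M2  H0040          S276       2             3       18.633752    ...
```

Here `H0040_S276_M2` is serine 276 of background protein H0040, observed
on doubly phosphorylated peptides (`M2`), quantified by MaxLFQ from 3
fragment ions. For spiked-species sites the between-condition differences
of these log2 values recover the designed mixing ratios (see below);
background sites stay flat.

Useful flags: `--method {maxlfq,sum,max}`, `--mode {site,peptide,both}`,
`--qvalue`, `--loc-threshold`, `--no-normalize`,
`--quant-level {ms1,ms2,both}`, `--out`. For DIA-NN output, first run
`phosreport convert report.tsv --fasta proteome.fasta -o long.tsv`, then
process `long.tsv` with `-tool diann`.

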