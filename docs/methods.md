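# Methods

## Input model

The pipeline consumes a long-format report: one row per fragment-ion (or
precursor) observation per run, carrying the run label, the modified
peptide sequence, the protein group, a peptide identification q-value, a
site-localization confidence, and a raw intensity. Two dialects are
supported. The Spectronaut dialect reads engine column names directly
(`R.FileName`, `EG.ModifiedSequence`, `PG.ProteinGroups`, `EG.Qvalue`,
`EG.PTMAssayProbability`, `F.FrgIon`, `F.PeakArea`,
`PEP.StrippedSequence`, `EG.PrecursorId`; every mapping is overridable)
with bracket-style modification tokens (`S[Phospho (STY)]`). The DIA-NN
dialect is the output of the package's own converter and uses UniMod
tokens (`S(UniMod:21)`; UniMod 21/35/4/1 are canonicalized to
Phospho (STY), Oxidation (M), Carbamidomethyl (C) and
Acetyl (Protein N-term); other numbers keep their literal token).
Protein-N-terminal acetylation is stored at peptide position 0: it never
creates a site key but is counted in peptide keys.

The DIA-NN converter reads the main-report TSV (default columns of the
1.8 convention: `Run`, `Modified.Sequence`, `Stripped.Sequence`,
`Precursor.Id`, `Q.Value`, `PTM.Site.Confidence`, `Fragment.Quant.Raw`;
all configurable because column names drift across versions), unrolls
each semicolon-packed fragment field into one row per fragment with
positive intensity (`fragment_id = <precursor>#<ordinal>`, ordinal =
position in the packed field), drops zero entries (they encode "not
quantified" — keeping missingness explicit for MaxLFQ), and recomputes
the protein group as all proteome accessions containing the stripped
sequence, sorted lexicographically for deterministic keys. Peptides
found nowhere in the proteome are dropped and counted in the log.

## Normalization

Median normalization (optional, on by default) multiplies every
intensity of run *r* by `f_r = exp(m − m_r)`, `m_r` the median natural-log
intensity over the run's positive fragment-level rows and `m` the mean of
the `m_r`. The common target — the geometric mean of the per-run
medians — is a free choice (any common target preserves within-run
ratios); this one is scale-stable. MS1 rows are scaled by the same
per-run factor as the fragment rows. Normalization precedes filtering;
a run with no positive intensity is an error.

## Filtering

Class-I filtering keeps rows with `q_value < q_max` (strict inequality,
default 0.01) and, in site mode, `localization ≥ loc_min` (default 0.75
for the Spectronaut assay probability, 0.01 for the DIA-NN site
confidence — the two scores are on different scales and these defaults
are the accepted equivalent operating points). Missing scores fail the
corresponding criterion. At peptide level the localization filter is off
by default. The operation is idempotent and logs per-criterion removal
counts.

## Site and peptide keys

Site keys render as `<acc[;acc…]>_<site[,site…][;…]>_M<multiplicity>`,
e.g. `P1_S12_M1`, `P2_S4,S10_M1`, `P3;P4_S3;S5_M2`. The separators are a
package convention; the binding property is that rendering is injective
over valid keys. Multiplicity is `min(#phospho groups, 3)`. Mapping
scenarios:

- one occurrence in one protein: one key per phospho group at the mapped
  position (`protein_position = peptide_start + site_position − 1`);
- peptide repeated within a protein: one key whose site list enumerates
  all alternative positions, flagged ambiguous — the peptide is a single
  piece of evidence and must not be double-counted as independent sites
  (a per-alternative-key emission was considered and rejected for that
  reason; the enumeration still surfaces sites that naive reporting
  misses when peptides repeat in a sequence);
- multiple phospho groups: one key per group, all sharing the peptide's
  multiplicity class and its quantitative evidence;
- multiple isoforms in the group: a single key listing every matching
  isoform with its per-isoform position, in group order.

Accessions missing from the proteome or not containing the peptide are
skipped with a warning; a peptide matching nothing yields no keys and is
counted. Leu/Ile are distinct in matching, and a phospho position must
land on the same S/T/Y letter in the proteome, else the key is rejected
as internally inconsistent.

Peptide keys render as `<stripped>[_<mod>x<count>…]` with counts in a
fixed order (Phospho (STY), Acetyl (Protein N-term),
Carbamidomethyl (C), Oxidation (M), then others alphabetically); zero
counts are omitted, so an unmodified peptide renders as its bare
sequence. Positional phospho-isomers with equal counts collapse to the
same peptide key while keeping distinct site keys.

## Quantification

Per key, observations form an ions × samples matrix (ion identity =
fragment id qualified by its precursor, because engine fragment labels
such as `y3` repeat across precursors; MS1 rows use the precursor id).
Duplicate (ion, sample) observations are reduced by maximum — a
deterministic rule robust to re-integration duplicates — and counted.
Evidence level is selectable: MS2 fragments (default), MS1 precursor
traces, or both.

`sum` and `max` are per-sample reductions of observed intensities,
reported as log2. `maxlfq` computes, for every unordered sample pair
with at least one shared ion (configurable minimum; 1 by default since
phosphosites often rest on a single peptide), the median log2 ratio over
shared ions, and solves `min Σ_pairs (w_j − w_i − r_ij)²` on each
connected component of the pair graph via the minimum-norm least-squares
solution of the edge-incidence system; since the null space on a
connected component is the constant vector, the remaining gauge is fixed
by the anchoring constraint `Σ w_s = Σ mean_observed(log2 x[:, s])`,
which preserves the overall intensity scale. Single-sample components
get their mean observed log2 intensity; samples with no observation stay
missing. The estimate is permutation-equivariant in samples, invariant
to ion order, and exact on noise-free multiplicative data. Output is
log2 by default (`QuantResult.linear_abundance()` converts), matching
downstream ratio analysis. Large-ratio stabilization variants and
imputation are out of scope.

## Synthetic experiments

The generator emulates a mixed-species spike-in: random protein
sequences (uniform over the 20 amino acids) for a "spike" species and a
background species, digested fully tryptically (cleave after K/R except
before P, no missed cleavages, lengths 7–25). Peptides shared between
species are discarded (no single ground truth). Each S/T/Y is
phosphorylated independently (default rate 0.25, giving a realistic
multiplicity mix); cysteines are carbamidomethylated, methionines
oxidized at rate 0.2. Log2 intensity of fragment *f* in sample *s* is

    a_f + b_s + e(species, condition(s)) + ε,   ε ~ N(0, noise_sd)

with `a_f` = peptide base N(20, 2) plus fragment offset N(0, 1), `b_s` a
per-sample loading effect N(0, 0.05), and `e` = log2 of the condition
multiplier for spike-species peptides (0 for background). Defaults
follow the classic five-condition design (spike amounts
25/50/100/150/200 against the 100 reference, i.e. ratios
0.25/0.5/1/1.5/2), six replicates per condition, noise_sd 0.3 (~23%
fragment CV) and 20% missing-completely-at-random cells — typical DIA
phosphoproteomics magnitudes. Genuine rows draw q-values in [0, 0.009]
and localization above the dialect threshold; an optional decoy fraction
violates exactly one filter per decoy unit. Everything derives from one
seeded generator, so a fixed seed reproduces FASTA, report and ground
truth byte for byte. Ground truth records each site key's species and
true per-sample log2 profile (`b_s + e`) plus the design ratios and the
sample effects.

What the generator does **not** emulate: intensity-dependent missingness
(an MCAR-only simplification; an intensity-dependent mode would be the
natural extension), interference/co-fragmentation, retention-time
structure, charge states, realistic FDR behaviour beyond
threshold-violating decoys, or shared peptides between species. Passing
the recovery benchmarks therefore shows the collapse and quantification
machinery is correct under the stated model, not that any search
engine's error control is.

## Benchmark evaluation choices

The spike-in benchmark (`phosreport.benchmark.evaluate_spike_in`,
driven by `scripts/acceptance.py`) runs the site pipeline with MaxLFQ
and **without** median normalization: in a spike-in design a large
fraction of peptides truly changes between conditions, so the
equal-median assumption is violated and normalization would compress the
very ratios being validated (with the spike species at a sizeable share
of rows, the per-run median shifts by roughly that share times the log
effect). The generator's small loading effects (sd 0.05 log2) make
normalization genuinely optional there. Per-site condition ratios are
means of linear abundances across replicates, divided by the reference
condition; medians across sites summarize each species. Problem size:
five conditions × 3 replicates, ~60 proteins per species yielding
400+ spiked and ~400 background sites, ~40 000 report rows — a scale at
which the whole evaluation runs in seconds while keeping the median
estimates tight.

## Numerical notes and limitations

- Text I/O is UTF-8, tab-separated, `.` decimal, no quoting; wide
  reports round log2 abundances to 6 decimals and render missing cells
  as empty strings, so write→read round-trips are bit-exact as text.
- Median ratios use `numpy.median` (mean of the two central order
  statistics for even counts).
- The normalization equal-median contract is enforced to 1e-9 on the log
  scale; MaxLFQ agrees with an explicit pseudoinverse solver to 1e-8.
- The pipeline trusts upstream localization: ambiguous evidence is
  enumerated, never probability-weighted or split; flanking-sequence
  windows for motif analysis are not produced.
- Spectronaut protein groups are used as given; no protein-group
  re-inference is attempted on that path.
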