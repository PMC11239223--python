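"""Synthetic DIA-MS phosphoproteomics experiments with known ground truth.

The generator emulates a two-species spike-in benchmark: peptides of a
"spike" species change abundance across conditions by known multipliers
while a background species stays constant, so the true between-condition
ratios of every phosphosite are known by design (the classic mixed-species
validation of label-free quantification).

The model, on the log2 scale, for fragment ion *f* of a peptide observed
in sample *s*::

    log2 I(f, s) = a_f + b_s + e(species, condition(s)) + N(0, noise_sd)

where ``a_f`` combines a peptide base abundance and a per-fragment
ionization/fragmentation offset, ``b_s`` is a per-sample loading effect,
and ``e`` is log2 of the species' condition multiplier (0 for the
background species).  Cells go missing completely at random at
``missing_rate``.  Identification metadata (q-value, localization
confidence) is drawn so that genuine rows pass the class-I filters of the
chosen dialect, while an optional fraction of decoy observations violates
exactly one filter each.

Everything is drawn from one seeded generator: a fixed seed reproduces
the FASTA, report and ground truth byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dialects import LOGICAL_FIELDS, get_dialect
from .io import PROTEIN_GROUP_SEP, Proteome
from .keys import build_site_keys
from .modseq import (
    CARBAMIDOMETHYL,
    OXIDATION,
    PHOSPHO,
    ModifiedPeptide,
    render_modified_sequence,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Condition names and spike-species multipliers of the mixed-species
#: benchmark: the spiked amount is 25/50/100/150/200 units, quantified
#: relative to the 100-unit reference.
DEFAULT_CONDITIONS = (
    ("yeast25", 0.25),
    ("yeast50", 0.5),
    ("yeast100", 1.0),
    ("yeast150", 1.5),
    ("yeast200", 2.0),
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic experiment.

    Defaults describe a desk-scale phospho-enriched spike-in: ~60 proteins
    per species, six replicates per condition, fragment-level noise of
    0.3 log2 units (~23% CV) and 20% missing values, both typical of
    DIA phosphoproteomics data.
    """

    n_proteins_spike: int = 60
    n_proteins_background: int = 60
    seq_length_range: tuple[int, int] = (240, 400)
    phospho_site_rate: float = 0.25
    conditions: tuple[tuple[str, float], ...] = DEFAULT_CONDITIONS
    reference_condition: str = "yeast100"
    replicates: int = 6
    peptide_abundance_sd: float = 2.0
    ion_effect_sd: float = 1.0
    sample_effect_sd: float = 0.05
    noise_sd: float = 0.3
    missing_rate: float = 0.2
    decoy_fraction: float = 0.0
    oxidation_rate: float = 0.2
    include_unmodified_fraction: float = 0.0
    dialect: str = "spectronaut"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("phospho_site_rate", "missing_rate", "decoy_fraction",
                     "oxidation_rate", "include_unmodified_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.reference_condition not in {c for c, _ in self.conditions}:
            raise ValueError("reference_condition must be one of the conditions")


@dataclass
class GroundTruth:
    """Per-site truth and the design ratios of the experiment."""

    sites: pd.DataFrame  # key, species, ambiguous + one column per sample
    design_ratios: dict[str, float]  # condition -> spike ratio vs reference
    reference_condition: str
    sample_conditions: dict[str, str]  # run id -> condition name
    sample_effects: dict[str, float]  # run id -> loading effect b_s (log2)


@dataclass
class SynthExperiment:
    config: SynthConfig
    proteome: Proteome
    report: pd.DataFrame  # canonical long format + truth_is_decoy column
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, dialect-formatted report TSV, ground-truth TSV and
        the configuration as JSON; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteome.fasta",
            "report": outdir / "report.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
            "config": outdir / "config.json",
        }
        with paths["fasta"].open("w", encoding="utf-8", newline="\n") as fh:
            for accession in self.proteome.entries:
                fh.write(f">{accession}\n")
                seq = self.proteome.entries[accession]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_dialect_report(self.report, self.config.dialect, paths["report"])
        self.ground_truth.sites.to_csv(
            paths["ground_truth"], sep="\t", index=False, float_format="%.9f"
        )
        cfg = dataclasses.asdict(self.config)
        paths["config"].write_text(json.dumps(cfg, indent=2) + "\n", encoding="utf-8")
        return paths


def write_dialect_report(report: pd.DataFrame, dialect_name: str, path: Path) -> None:
    """Render a canonical frame as a TSV in the dialect's column names
    (extra ``truth_*`` columns are carried through for inspection)."""
    dialect = get_dialect(dialect_name)
    out = pd.DataFrame()
    for logical in LOGICAL_FIELDS:
        source = dialect.column_map.get(logical, logical)
        if logical == "protein_group":
            out[source] = [PROTEIN_GROUP_SEP.join(g) for g in report[logical]]
        else:
            out[source] = report[logical]
    for col in report.columns:
        if col.startswith("truth_"):
            out[col] = report[col]
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def digest_tryptic(sequence: str, min_len: int = 7, max_len: int = 25) -> list[str]:
    """Fully tryptic digestion (cleave after K/R except before P), no
    missed cleavages; peptides outside [min_len, max_len] are discarded."""
    peptides: list[str] = []
    start = 0
    for i, residue in enumerate(sequence):
        at_end = i == len(sequence) - 1
        cleave = residue in "KR" and (at_end or sequence[i + 1] != "P")
        if cleave or at_end:
            peptides.append(sequence[start : i + 1])
            start = i + 1
    return [p for p in peptides if min_len <= len(p) <= max_len]


def generate_experiment(cfg: SynthConfig) -> SynthExperiment:
    """Generate a complete synthetic experiment from a configuration.

    Returns the proteome, the long-format report (canonical columns plus
    a ``truth_is_decoy`` flag) and the ground truth covering every site
    key derivable from the report.
    """
    rng = np.random.default_rng(cfg.seed)
    dialect = get_dialect(cfg.dialect)
    loc_threshold = dialect.default_loc_threshold

    # --- proteome -----------------------------------------------------
    proteome = Proteome()
    species_of: dict[str, str] = {}
    lo, hi = cfg.seq_length_range
    for prefix, count, species in (
        ("Y", cfg.n_proteins_spike, "spike"),
        ("H", cfg.n_proteins_background, "background"),
    ):
        for k in range(count):
            accession = f"{prefix}{k + 1:04d}"
            proteome.entries[accession] = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            species_of[accession] = species

    # --- unique tryptic peptides, assigned to a single species --------
    peptide_accessions: dict[str, set[str]] = {}
    for accession, seq in proteome.entries.items():
        for pep in digest_tryptic(seq):
            peptide_accessions.setdefault(pep, set()).add(accession)
    peptides: list[tuple[str, tuple[str, ...], str]] = []
    for pep in sorted(peptide_accessions):
        accessions = tuple(sorted(peptide_accessions[pep]))
        species = {species_of[a] for a in accessions}
        if len(species) > 1:
            continue  # a peptide shared across species has no single truth
        peptides.append((pep, accessions, species.pop()))
    if not peptides:
        raise ValueError("configuration yields zero peptides; use longer sequences")

    # --- samples ------------------------------------------------------
    sample_ids: list[str] = []
    sample_conditions: dict[str, str] = {}
    for cond, _ in cfg.conditions:
        for rep in range(1, cfg.replicates + 1):
            run = f"{cond}_rep{rep}"
            sample_ids.append(run)
            sample_conditions[run] = cond
    multipliers = dict(cfg.conditions)
    cond_effect = {c: float(np.log2(m)) for c, m in multipliers.items()}
    b_s = {run: float(rng.normal(0.0, cfg.sample_effect_sd)) for run in sample_ids}

    # --- peptide modification forms and intensities -------------------
    records: list[tuple] = []
    truth_rows: list[tuple] = []
    seen_keys: set[str] = set()

    for stripped, accessions, species in peptides:
        sty = [i + 1 for i, aa in enumerate(stripped) if aa in "STY"]
        phospho = tuple(p for p in sty if rng.random() < cfg.phospho_site_rate)
        if not phospho and rng.random() >= cfg.include_unmodified_fraction:
            continue
        mods = [(p, PHOSPHO) for p in phospho]
        mods += [(i + 1, CARBAMIDOMETHYL) for i, aa in enumerate(stripped) if aa == "C"]
        mods += [
            (i + 1, OXIDATION)
            for i, aa in enumerate(stripped)
            if aa == "M" and rng.random() < cfg.oxidation_rate
        ]
        pep = ModifiedPeptide(stripped, tuple(sorted(mods)))
        modseq = render_modified_sequence(pep, dialect.mod_grammar)
        precursor = f"{modseq}.2"

        effect = cond_effect if species == "spike" else {c: 0.0 for c in cond_effect}
        base = float(rng.normal(20.0, cfg.peptide_abundance_sd))
        n_frag = int(rng.integers(3, 7))
        frag_offsets = rng.normal(0.0, cfg.ion_effect_sd, size=n_frag)
        frag_ids = [f"y{j + 3}" for j in range(n_frag)]

        # ground truth: every site key this peptide can generate
        if phospho:
            for key in build_site_keys(pep, accessions, proteome):
                rendered = str(key)
                if rendered in seen_keys:
                    continue
                seen_keys.add(rendered)
                truth_rows.append(
                    (
                        rendered,
                        species,
                        key.ambiguous,
                        *[b_s[s] + effect[sample_conditions[s]] for s in sample_ids],
                    )
                )

        for run in sample_ids:
            unit_mean = base + b_s[run] + effect[sample_conditions[run]]
            is_decoy = phospho and cfg.decoy_fraction > 0 and rng.random() < cfg.decoy_fraction
            if is_decoy:
                if rng.random() < 0.5:  # q-value violator
                    q = float(rng.uniform(0.011, 0.3))
                    loc = float(rng.uniform(loc_threshold, 1.0))
                else:  # localization violator
                    q = float(rng.uniform(0.0, 0.009))
                    loc = float(rng.uniform(0.0, loc_threshold * 0.99))
            else:
                q = float(rng.uniform(0.0, 0.009))
                loc = float(rng.uniform(loc_threshold, 1.0))
            if not phospho:
                loc = np.nan
            for frag_id, offset in zip(frag_ids, frag_offsets):
                if rng.random() < cfg.missing_rate:
                    continue
                log2_i = unit_mean + offset + rng.normal(0.0, cfg.noise_sd)
                records.append(
                    (
                        run,
                        modseq,
                        stripped,
                        accessions,
                        precursor,
                        frag_id,
                        float(2.0 ** log2_i),
                        q,
                        loc,
                        bool(is_decoy),
                    )
                )

    report = pd.DataFrame(
        records, columns=[*LOGICAL_FIELDS, "truth_is_decoy"]
    )
    sites = pd.DataFrame(
        truth_rows, columns=["key", "species", "ambiguous", *sample_ids]
    )
    reference = cfg.reference_condition
    design_ratios = {
        cond: multipliers[cond] / multipliers[reference] for cond, _ in cfg.conditions
    }
    truth = GroundTruth(
        sites=sites,
        design_ratios=design_ratios,
        reference_condition=reference,
        sample_conditions=sample_conditions,
        sample_effects=b_s,
    )
    return SynthExperiment(cfg, proteome, report, truth)
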