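"""Phosphosite and phosphopeptide identifier construction.

A site identifier is built from the protein identifier(s), the site
position(s) in the protein, and the phosphorylation multiplicity — the
MaxQuant-style count class of phospho groups on the evidencing peptide
(1 single, 2 double, 3 = three or more).  Five mapping scenarios are
handled:

(i)   singly phosphorylated peptide, one protein, one occurrence — one
      key at the mapped position;
(ii)  the peptide occurs at several locations of one protein — a single
      key whose site list enumerates all alternative positions, flagged
      ambiguous (one peptide is one piece of evidence, not several);
(iii) doubly phosphorylated peptide — one key per site, multiplicity 2;
(iv)  three or more phospho groups — one key per site, multiplicity 3;
(v)   the peptide occurs in several protein isoforms of the group — a
      single key listing every isoform with its mapped position.

Scenarios compose, and the quantitative evidence of a peptide attaches
to every key it generates.

Peptide-level identifiers discard positions: the counts of each
modification are appended to the unmodified (stripped) sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import Proteome
from .modseq import CANONICAL_MODS, ModifiedPeptide, map_site_to_protein

log = logging.getLogger(__name__)


def multiplicity(n_phospho: int) -> int:
    """Phosphorylation multiplicity class: 1, 2, or 3 (= three or more)."""
    if n_phospho < 1:
        raise ValueError("no site key for an unphosphorylated peptide")
    return min(n_phospho, 3)


@dataclass(frozen=True)
class SiteKey:
    """One phosphosite: protein group + residue position(s) + multiplicity.

    ``sites`` holds, per accession (same order as ``accessions``), a tuple
    of ``(residue letter, 1-based protein position)``; more than one entry
    for an accession enumerates alternative positions of the same site
    when the peptide repeats within the sequence (``ambiguous`` is then
    set).
    """

    accessions: tuple[str, ...]
    sites: tuple[tuple[tuple[str, int], ...], ...]
    multiplicity: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.accessions or len(self.accessions) != len(self.sites):
            raise ValueError("accessions and sites must be parallel, non-empty")
        if any(len(s) == 0 for s in self.sites):
            raise ValueError("every accession needs at least one site position")
        for persite in self.sites:
            for residue, pos in persite:
                if residue not in "STY" or pos < 1:
                    raise ValueError(
                        f"invalid phosphosite {residue}{pos}: residue must be S/T/Y"
                    )
        if self.multiplicity not in (1, 2, 3):
            raise ValueError("multiplicity must be 1, 2 or 3")

    def __str__(self) -> str:
        accs = ";".join(self.accessions)
        sites = ";".join(
            ",".join(f"{res}{pos}" for res, pos in persite) for persite in self.sites
        )
        return f"{accs}_{sites}_M{self.multiplicity}"

    def part_names(self) -> tuple[str, ...]:
        return ("protein_group", "positions", "multiplicity")

    def parts(self) -> tuple[str, ...]:
        accs = ";".join(self.accessions)
        sites = ";".join(
            ",".join(f"{res}{pos}" for res, pos in persite) for persite in self.sites
        )
        return (accs, sites, str(self.multiplicity))


@dataclass(frozen=True)
class PeptideKey:
    """Stripped sequence + per-modification counts (positions discarded)."""

    stripped: str
    mod_counts: tuple[tuple[str, int], ...]

    def __str__(self) -> str:
        suffix = "".join(f"_{name}x{count}" for name, count in self.mod_counts)
        return f"{self.stripped}{suffix}"

    def part_names(self) -> tuple[str, ...]:
        return ("sequence", "modifications")

    def parts(self) -> tuple[str, ...]:
        return (
            self.stripped,
            ";".join(f"{name}x{count}" for name, count in self.mod_counts),
        )


def build_site_keys(
    pep: ModifiedPeptide,
    group: tuple[str, ...],
    proteome: Proteome,
) -> list[SiteKey]:
    """Construct the site keys a phosphopeptide generates.

    ``group`` is the protein group as reported (or as recomputed from the
    proteome for converted reports); accessions absent from the proteome,
    or not containing the peptide sequence, are skipped with a log entry.
    Returns one key per phospho group on the peptide (an empty list when
    the peptide maps nowhere).
    """
    if pep.n_phospho < 1:
        raise ValueError("peptide carries no phospho group")
    starts_per_acc: list[tuple[str, list[int]]] = []
    for accession in group:
        if accession not in proteome:
            log.warning("accession %r not in proteome; skipped", accession)
            continue
        seq = proteome[accession]
        starts: list[int] = []
        pos = seq.find(pep.stripped)
        while pos >= 0:
            starts.append(pos + 1)
            pos = seq.find(pep.stripped, pos + 1)
        if starts:
            starts_per_acc.append((accession, starts))
        else:
            log.warning(
                "peptide %r not found in accession %r; skipped", pep.stripped, accession
            )
    if not starts_per_acc:
        return []

    m = multiplicity(pep.n_phospho)
    ambiguous = any(len(starts) > 1 for _, starts in starts_per_acc)
    keys: list[SiteKey] = []
    for pep_pos in pep.phospho_positions:
        residue = pep.stripped[pep_pos - 1]
        accessions: list[str] = []
        sites: list[tuple[tuple[str, int], ...]] = []
        for accession, starts in starts_per_acc:
            seq = proteome[accession]
            positions = []
            for start in starts:
                prot_pos = map_site_to_protein(start, pep_pos)
                if prot_pos > len(seq) or seq[prot_pos - 1] != residue:
                    raise ValueError(
                        f"site {residue}{prot_pos} inconsistent with {accession!r}"
                    )
                positions.append((residue, prot_pos))
            accessions.append(accession)
            sites.append(tuple(positions))
        keys.append(
            SiteKey(
                accessions=tuple(accessions),
                sites=tuple(sites),
                multiplicity=m,
                ambiguous=ambiguous,
            )
        )
    return keys


def build_peptide_key(
    pep: ModifiedPeptide,
    tracked: tuple[str, ...] | None = None,
) -> PeptideKey:
    """Construct the peptide-level key: stripped sequence plus counts of
    each modification, rendered in a fixed canonical order.

    ``tracked`` restricts which modifications are counted; by default all
    observed modifications are, with the four standard ones first.
    """
    counts = pep.mod_counts()
    if tracked is not None:
        counts = {name: n for name, n in counts.items() if name in tracked}
    ordered = [name for name in CANONICAL_MODS if counts.get(name, 0) > 0]
    ordered += sorted(name for name in counts if name not in CANONICAL_MODS and counts[name] > 0)
    return PeptideKey(
        stripped=pep.stripped,
        mod_counts=tuple((name, counts[name]) for name in ordered),
    )
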