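"""Modified-sequence parsing and peptide-to-protein mapping.

Two token grammars are supported.  The bracket grammar (Spectronaut)
writes a modification as ``[Name]`` immediately after the modified
residue, with optional leading/trailing underscores:
``_AAS[Phospho (STY)]K_``.  The UniMod grammar (DIA-NN) writes
``(UniMod:N)`` after the residue: ``AAS(UniMod:21)K``.  UniMod numbers
are canonicalized to the Spectronaut-style names for the four
modifications routinely configured in phosphoproteomics searches;
unknown tokens keep their literal name.

A protein-N-terminal modification (acetylation) precedes the first
residue and is assigned position 0: it never yields a phosphosite key
but is counted for peptide-level keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import Proteome

PHOSPHO = "Phospho (STY)"
ACETYL_NTERM = "Acetyl (Protein N-term)"
CARBAMIDOMETHYL = "Carbamidomethyl (C)"
OXIDATION = "Oxidation (M)"

#: Canonical modification names, in the fixed order used when rendering
#: peptide-level keys.
CANONICAL_MODS = (PHOSPHO, ACETYL_NTERM, CARBAMIDOMETHYL, OXIDATION)

UNIMOD_NAMES = {
    1: ACETYL_NTERM,
    4: CARBAMIDOMETHYL,
    21: PHOSPHO,
    35: OXIDATION,
}

#: Modifications that attach to the protein N-terminus (position 0).
_NTERM_MODS = {ACETYL_NTERM}


class ModSeqError(ValueError):
    """Raised when a modified-sequence string cannot be parsed."""


@dataclass(frozen=True)
class ModifiedPeptide:
    """A stripped peptide plus its positioned modifications.

    ``mods`` holds ``(position, name)`` pairs with 1-based positions into
    ``stripped`` (0 for protein-N-terminal mods), sorted by position.
    """

    stripped: str
    mods: tuple[tuple[int, str], ...] = field(default=())

    @property
    def phospho_positions(self) -> tuple[int, ...]:
        return tuple(p for p, name in self.mods if name == PHOSPHO)

    @property
    def n_phospho(self) -> int:
        return len(self.phospho_positions)

    def mod_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, name in self.mods:
            counts[name] = counts.get(name, 0) + 1
        return counts


def _parse_bracket(modseq: str) -> ModifiedPeptide:
    s = modseq.strip("_")
    stripped: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "[":
            depth = 1
            j = i + 1
            while j < len(s) and depth:
                if s[j] == "[":
                    depth += 1
                elif s[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise ModSeqError(
                    f"unbalanced '[' at offset {i} in {modseq!r}"
                )
            name = s[i + 1 : j - 1]
            if not stripped:
                if name not in _NTERM_MODS:
                    raise ModSeqError(
                        f"modification token {name!r} at start of {modseq!r} "
                        "has no preceding residue and is not N-terminal"
                    )
                mods.append((0, name))
            else:
                mods.append((len(stripped), name))
            i = j
        elif c == "]":
            raise ModSeqError(f"unbalanced ']' at offset {i} in {modseq!r}")
        else:
            stripped.append(c)
            i += 1
    mods.sort(key=lambda m: m[0])
    return ModifiedPeptide("".join(stripped), tuple(mods))


def _parse_unimod(modseq: str) -> ModifiedPeptide:
    s = modseq.strip("_")
    stripped: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "(":
            j = s.find(")", i)
            if j < 0:
                raise ModSeqError(f"unbalanced '(' at offset {i} in {modseq!r}")
            token = s[i + 1 : j]
            if token.startswith("UniMod:"):
                try:
                    number = int(token.split(":", 1)[1])
                except ValueError:
                    raise ModSeqError(
                        f"bad UniMod token {token!r} at offset {i} in {modseq!r}"
                    ) from None
                name = UNIMOD_NAMES.get(number, f"UniMod:{number}")
            else:
                name = token
            if not stripped:
                if name not in _NTERM_MODS:
                    raise ModSeqError(
                        f"modification token {name!r} at start of {modseq!r} "
                        "has no preceding residue and is not N-terminal"
                    )
                mods.append((0, name))
            else:
                mods.append((len(stripped), name))
            i = j + 1
        elif c == ")":
            raise ModSeqError(f"unbalanced ')' at offset {i} in {modseq!r}")
        else:
            stripped.append(c)
            i += 1
    mods.sort(key=lambda m: m[0])
    return ModifiedPeptide("".join(stripped), tuple(mods))


def parse_modified_sequence(modseq: str, grammar: str = "bracket") -> ModifiedPeptide:
    """Parse a dialect-formatted modified sequence.

    Parameters
    ----------
    modseq
        The modified-sequence string.
    grammar
        ``"bracket"`` or ``"unimod"`` (a :class:`~phosreport.dialects.Dialect`
        object is also accepted, for convenience).
    """
    if hasattr(grammar, "mod_grammar"):
        grammar = grammar.mod_grammar
    if grammar == "bracket":
        return _parse_bracket(modseq)
    if grammar == "unimod":
        return _parse_unimod(modseq)
    raise ValueError(f"unknown modification grammar {grammar!r}")


def render_modified_sequence(pep: ModifiedPeptide, grammar: str = "bracket") -> str:
    """Inverse of :func:`parse_modified_sequence` (modulo underscore
    trimming).  Used by the synthetic generator and round-trip tests."""
    inv_unimod = {v: k for k, v in UNIMOD_NAMES.items()}
    pieces: list[str] = []
    by_pos: dict[int, list[str]] = {}
    for pos, name in pep.mods:
        by_pos.setdefault(pos, []).append(name)

    def token(name: str) -> str:
        if grammar == "bracket":
            return f"[{name}]"
        if name in inv_unimod:
            return f"(UniMod:{inv_unimod[name]})"
        return f"({name})"

    for name in by_pos.get(0, []):
        pieces.append(token(name))
    for i, residue in enumerate(pep.stripped, start=1):
        pieces.append(residue)
        for name in by_pos.get(i, []):
            pieces.append(token(name))
    body = "".join(pieces)
    return f"_{body}_" if grammar == "bracket" else body


def locate_peptide(stripped: str, proteome: Proteome) -> list[tuple[str, int]]:
    """All exact-substring occurrences of ``stripped`` in the proteome.

    Returns ``(accession, start)`` pairs with 1-based starts, including
    overlapping occurrences and multiple occurrences per accession,
    ordered by accession (lexicographic) then start (ascending).  Leu and
    Ile are distinct letters.  An empty list means the peptide maps
    nowhere.
    """
    if not stripped:
        raise ValueError("empty peptide sequence")
    hits: list[tuple[str, int]] = []
    for accession in sorted(proteome.entries):
        seq = proteome.entries[accession]
        start = seq.find(stripped)
        while start >= 0:
            hits.append((accession, start + 1))
            start = seq.find(stripped, start + 1)
    return hits


def map_site_to_protein(start: int, site_pos: int) -> int:
    """Map a 1-based peptide-local site position to a 1-based protein
    position, given the peptide's 1-based start in the protein."""
    if start < 1 or site_pos < 1:
        raise ValueError("start and site_pos must be >= 1")
    return start + site_pos - 1
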