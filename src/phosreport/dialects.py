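"""Report dialects: how each search engine names its columns and writes
modified sequences.

A *dialect* bundles three things: the mapping from the logical fields the
pipeline needs (run, modified sequence, protein group, q-value, site
localization confidence, precursor/fragment ids, intensity) to the column
names found in the source file; the grammar used for modification tokens
inside modified-sequence strings; and the default site-localization
threshold appropriate for that engine's confidence score.  The Spectronaut
localization score (``EG.PTMAssayProbability``) is conventionally cut at
0.75 for class-I sites, which is equivalent to a 0.01 cut on the DIA-NN
site-confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Logical fields every long-format report must provide.  ``fragment_id``
#: and ``localization`` may be absent in the source (MS1-only exports,
#: peptide-level work).
LOGICAL_FIELDS = (
    "run_id",
    "modified_sequence",
    "stripped_sequence",
    "protein_group",
    "precursor_id",
    "fragment_id",
    "intensity",
    "q_value",
    "localization",
)

#: Logical fields that must be present in the source file.
REQUIRED_FIELDS = (
    "run_id",
    "modified_sequence",
    "protein_group",
    "precursor_id",
    "intensity",
    "q_value",
)


@dataclass(frozen=True)
class Dialect:
    """Column naming, modification grammar and defaults for one engine.

    Parameters
    ----------
    name
        ``"spectronaut"`` or ``"diann"``.
    column_map
        logical field -> source column name.
    mod_grammar
        ``"bracket"`` for ``S[Phospho (STY)]`` style tokens,
        ``"unimod"`` for ``S(UniMod:21)`` style tokens.
    default_loc_threshold
        Default class-I site localization cut-off for this engine's score.
    """

    name: str
    column_map: dict[str, str] = field(default_factory=dict)
    mod_grammar: str = "bracket"
    default_loc_threshold: float = 0.75

    def with_columns(self, **overrides: str) -> "Dialect":
        """Return a copy with some logical->column entries replaced."""
        cmap = dict(self.column_map)
        cmap.update(overrides)
        return replace(self, column_map=cmap)


SPECTRONAUT = Dialect(
    name="spectronaut",
    column_map={
        "run_id": "R.FileName",
        "modified_sequence": "EG.ModifiedSequence",
        "stripped_sequence": "PEP.StrippedSequence",
        "protein_group": "PG.ProteinGroups",
        "precursor_id": "EG.PrecursorId",
        "fragment_id": "F.FrgIon",
        "intensity": "F.PeakArea",
        "q_value": "EG.Qvalue",
        "localization": "EG.PTMAssayProbability",
    },
    mod_grammar="bracket",
    default_loc_threshold=0.75,
)

# The converted DIA-NN long format uses the logical field names directly
# (the converter writes them); modification tokens stay in UniMod notation.
DIANN = Dialect(
    name="diann",
    column_map={f: f for f in LOGICAL_FIELDS},
    mod_grammar="unimod",
    default_loc_threshold=0.01,
)

DIALECTS = {"spectronaut": SPECTRONAUT, "sn": SPECTRONAUT, "diann": DIANN}


def get_dialect(name: str) -> Dialect:
    try:
        return DIALECTS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown dialect {name!r}; expected one of {sorted(set(DIALECTS))}"
        ) from None
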