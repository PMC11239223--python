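"""Reading and writing: FASTA proteomes, long-format reports, DIA-NN
conversion, and the wide-format output tables.

The in-memory long report is a :class:`pandas.DataFrame` with one row per
fragment (or precursor) observation per run and the logical columns of
:data:`phosreport.dialects.LOGICAL_FIELDS`.  ``protein_group`` holds a
tuple of accessions; ``intensity``, ``q_value`` and ``localization`` are
floats with ``NaN`` for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio import SeqIO

from .dialects import DIANN, LOGICAL_FIELDS, REQUIRED_FIELDS, Dialect

if TYPE_CHECKING:  # pragma: no cover
    from .quant import QuantResult

log = logging.getLogger(__name__)

PROTEIN_GROUP_SEP = ";"


@dataclass
class Proteome:
    """Accession -> amino-acid sequence map from a FASTA file."""

    entries: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __getitem__(self, accession: str) -> str:
        return self.entries[accession]


_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYXBZU")


def _accession_from_header(header: str) -> str:
    """UniProt-style ``sp|P12345|NAME ...`` -> ``P12345``; else first token."""
    first = header.split()[0]
    parts = first.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return first


def read_fasta(path: str | Path) -> Proteome:
    """Read a FASTA proteome.

    Accessions are taken from the second pipe-delimited field of
    UniProt-style headers, else from the whole first token.  Sequences are
    uppercased; wrapped lines are concatenated.

    Raises
    ------
    ValueError
        On an empty file or a duplicate accession.
    """
    proteome = Proteome()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(record.description or record.id)
        if accession in proteome.entries:
            raise ValueError(f"duplicate accession in proteome: {accession!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for accession {accession!r}")
        bad = set(seq) - _VALID_AA
        if bad:
            raise ValueError(
                f"non-amino-acid letters {sorted(bad)} in accession {accession!r}"
            )
        proteome.entries[accession] = seq
        proteome.descriptions[accession] = record.description
    if not proteome.entries:
        raise ValueError(f"empty proteome: {path}")
    return proteome


def _parse_float(value, column: str, row_number: int) -> float:
    """Empty/NA cells -> NaN; anything non-numeric is a hard error."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "filtered"):
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise ValueError(
            f"non-numeric value {value!r} in column {column!r} at data row {row_number}"
        ) from None


def read_long_report(path: str | Path, dialect: Dialect) -> pd.DataFrame:
    """Read a tab-separated long-format report into the canonical frame.

    One output row per input row, in input order.  Missing numeric cells
    become ``NaN``; the protein-group column is split on ``";"`` into a
    tuple of accessions.

    Raises
    ------
    ValueError
        If a required source column is absent, or a numeric cell cannot
        be parsed.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in REQUIRED_FIELDS:
        source = dialect.column_map.get(logical)
        if source is None or source not in raw.columns:
            raise ValueError(
                f"report is missing required column {source or logical!r} "
                f"(logical field {logical!r}, dialect {dialect.name!r})"
            )

    out: dict[str, object] = {}
    n = len(raw)
    for logical in LOGICAL_FIELDS:
        source = dialect.column_map.get(logical)
        present = source is not None and source in raw.columns
        if logical in ("intensity", "q_value", "localization"):
            if present:
                out[logical] = [
                    _parse_float(v, source, i + 1)
                    for i, v in enumerate(raw[source].tolist())
                ]
            else:
                out[logical] = [np.nan] * n
        elif logical == "protein_group":
            out[logical] = [
                tuple(a for a in v.split(PROTEIN_GROUP_SEP) if a)
                for v in raw[source].tolist()
            ]
        else:
            if present:
                out[logical] = [v.strip() for v in raw[source].tolist()]
            else:
                out[logical] = [""] * n

    frame = pd.DataFrame(out, columns=list(LOGICAL_FIELDS))
    if any(len(g) == 0 for g in frame["protein_group"]):
        raise ValueError("empty protein group in report")
    if frame["stripped_sequence"].eq("").all() and n > 0:
        # derive from modified sequence lazily; filled by the pipeline
        pass
    n_zero = int((frame["intensity"] <= 0).sum() + frame["intensity"].isna().sum())
    log.info("read %d rows from %s (%d zero/missing intensity)", n, path, n_zero)
    return frame


# ---------------------------------------------------------------------------
# DIA-NN conversion
# ---------------------------------------------------------------------------

#: Default column names of the DIA-NN 1.8 main report consumed by the
#: converter.  Report dialects drift across versions, so every entry can be
#: overridden via ``column_map`` of :func:`convert_diann_report`.
DIANN_MAIN_COLUMNS = {
    "run_id": "Run",
    "modified_sequence": "Modified.Sequence",
    "stripped_sequence": "Stripped.Sequence",
    "precursor_id": "Precursor.Id",
    "q_value": "Q.Value",
    "localization": "PTM.Site.Confidence",
    "fragment_quant": "Fragment.Quant.Raw",
}


@dataclass
class ConversionLog:
    rows_read: int = 0
    rows_written: int = 0
    precursors_dropped_unmapped: int = 0
    fragments_dropped_zero: int = 0


def convert_diann_report(
    diann_path: str | Path,
    proteome: Proteome,
    column_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, ConversionLog]:
    """Convert a DIA-NN main report into the canonical long format.

    Each precursor row carries its fragment intensities packed into one
    semicolon-separated field; it is unrolled into one output row per
    fragment with positive intensity.  ``fragment_id`` is
    ``"<precursor_id>#<ordinal>"`` where the ordinal is the fragment's
    1-based position in the packed field.  The protein group is recomputed
    by locating the stripped sequence in the proteome (all matching
    accessions, sorted lexicographically), which makes isoform membership
    explicit; precursors whose sequence is absent from every proteome entry
    are dropped and counted.
    """
    from .modseq import locate_peptide  # local import avoids a cycle

    if len(proteome) == 0:
        raise ValueError("empty proteome")
    cmap = dict(DIANN_MAIN_COLUMNS)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(diann_path, sep="\t", dtype=str, keep_default_na=False)
    for logical, source in cmap.items():
        if source not in raw.columns:
            raise ValueError(
                f"DIA-NN report is missing column {source!r} (logical field {logical!r})"
            )

    clog = ConversionLog(rows_read=len(raw))
    group_cache: dict[str, tuple[str, ...]] = {}
    records: list[tuple] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        rowd = dict(zip(raw.columns, row))
        stripped = rowd[cmap["stripped_sequence"]].strip()
        if stripped not in group_cache:
            hits = locate_peptide(stripped, proteome)
            group_cache[stripped] = tuple(sorted({acc for acc, _ in hits}))
        group = group_cache[stripped]
        if not group:
            clog.precursors_dropped_unmapped += 1
            continue
        packed = rowd[cmap["fragment_quant"]].strip().strip(";")
        try:
            intensities = [float(x) for x in packed.split(";")] if packed else []
        except ValueError:
            raise ValueError(
                f"unparsable packed fragment field {packed!r} at data row {i + 1}"
            ) from None
        precursor = rowd[cmap["precursor_id"]].strip()
        q_value = _parse_float(rowd[cmap["q_value"]], cmap["q_value"], i + 1)
        loc = _parse_float(rowd[cmap["localization"]], cmap["localization"], i + 1)
        for ordinal, intensity in enumerate(intensities, start=1):
            if intensity <= 0:
                clog.fragments_dropped_zero += 1
                continue
            records.append(
                (
                    rowd[cmap["run_id"]].strip(),
                    rowd[cmap["modified_sequence"]].strip(),
                    stripped,
                    group,
                    precursor,
                    f"{precursor}#{ordinal}",
                    intensity,
                    q_value,
                    loc,
                )
            )
    clog.rows_written = len(records)
    log.info(
        "converted %d DIA-NN rows -> %d fragment rows (%d precursors unmapped, "
        "%d zero fragments dropped)",
        clog.rows_read,
        clog.rows_written,
        clog.precursors_dropped_unmapped,
        clog.fragments_dropped_zero,
    )
    return pd.DataFrame(records, columns=list(LOGICAL_FIELDS)), clog


def write_long_report(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical long-format frame as TSV (readable back with the
    ``diann`` dialect's identity column map)."""
    out = frame.copy()
    out["protein_group"] = [PROTEIN_GROUP_SEP.join(g) for g in out["protein_group"]]
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_canonical_report(path: str | Path) -> pd.DataFrame:
    """Read back a file written by :func:`write_long_report`."""
    return read_long_report(path, DIANN)


# ---------------------------------------------------------------------------
# Wide output
# ---------------------------------------------------------------------------

def _format_number(x: float) -> str:
    return "" if x is None or np.isnan(x) else format(float(x), ".6f")


def write_wide_report(result: "QuantResult", path: str | Path) -> None:
    """Write a wide-format report: one row per key, one column per sample
    with log2 abundance; missing cells are empty.

    The first line is a ``#`` comment recording the quantification method
    so a read-back can recover it.
    """
    if len(result.keys) == 0 or len(result.sample_ids) == 0:
        raise ValueError("result must have at least one key and one sample")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# method={result.method}\n")
        part_names = result.keys[0].part_names()
        header = ["key", *part_names, "n_ions", *result.sample_ids]
        fh.write("\t".join(header) + "\n")
        for i, key in enumerate(result.keys):
            cells = [str(key), *key.parts(), str(result.n_ions[i])]
            cells.extend(_format_number(v) for v in result.log2_abundance[i])
            fh.write("\t".join(cells) + "\n")


def read_wide_report(path: str | Path) -> tuple[str, pd.DataFrame]:
    """Read back a wide report; returns ``(method, frame)`` where the frame
    is indexed by the rendered key string."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        method = first.split("=", 1)[1] if first.startswith("# method=") else ""
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return method, frame
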