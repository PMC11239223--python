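"""End-to-end report generation: normalize -> filter -> keys -> quantify.

This is the glue the command-line tool calls; each step lives in its own
module and can be used independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dialects import Dialect
from .io import Proteome
from .keys import build_peptide_key, build_site_keys
from .modseq import parse_modified_sequence
from .preprocess import DEFAULT_Q_MAX, FilterLog, filter_confident, normalize_median
from .quant import QuantResult, collate_ions, quantify

log = logging.getLogger(__name__)


@dataclass
class PipelineLog:
    rows_in: int = 0
    rows_after_filter: int = 0
    rows_quantified: int = 0
    peptides_unmapped: int = 0
    duplicates_reduced: int = 0
    n_keys: int = 0
    filter_log: FilterLog = field(default_factory=FilterLog)


def run_pipeline(
    rows: pd.DataFrame,
    dialect: Dialect,
    mode: str = "site",
    proteome: Proteome | None = None,
    method: str = "maxlfq",
    normalize: bool = True,
    q_max: float = DEFAULT_Q_MAX,
    loc_min: float | None = None,
    quant_level: str = "ms2",
    tracked_mods: tuple[str, ...] | None = None,
) -> tuple[QuantResult, PipelineLog]:
    """Run the full reporting pipeline on a canonical long-format frame.

    Parameters
    ----------
    mode
        ``"site"`` (phosphosite keys; localization filtering on, requires
        a proteome) or ``"peptide"`` (modification-count keys;
        localization filtering off).
    loc_min
        Site-localization cut-off; defaults to the dialect's threshold.
    quant_level
        ``"ms2"`` uses fragment rows, ``"ms1"`` precursor rows, ``"both"``
        all rows.
    """
    if mode not in ("site", "peptide"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "site" and proteome is None:
        raise ValueError("site mode requires a proteome to map site positions")
    if quant_level not in ("ms1", "ms2", "both"):
        raise ValueError(f"unknown quant level {quant_level!r}")
    if loc_min is None:
        loc_min = dialect.default_loc_threshold

    plog = PipelineLog(rows_in=len(rows))
    if normalize:
        rows = normalize_median(rows)
    rows, plog.filter_log = filter_confident(
        rows, q_max=q_max, loc_min=loc_min, require_loc=(mode == "site")
    )
    plog.rows_after_filter = len(rows)

    if quant_level != "both":
        is_fragment = rows["fragment_id"].astype(str).str.len() > 0
        rows = rows.loc[is_fragment if quant_level == "ms2" else ~is_fragment]
    plog.rows_quantified = len(rows)

    key_cache: dict[tuple[str, tuple[str, ...]], list] = {}
    unmapped: set[str] = set()

    def keymap(row) -> list:
        cache_key = (row.modified_sequence, row.protein_group)
        if cache_key not in key_cache:
            pep = parse_modified_sequence(row.modified_sequence, dialect.mod_grammar)
            if mode == "site":
                if pep.n_phospho < 1:
                    key_cache[cache_key] = []
                else:
                    ks = build_site_keys(pep, row.protein_group, proteome)
                    if not ks:
                        unmapped.add(pep.stripped)
                    key_cache[cache_key] = ks
            else:
                key_cache[cache_key] = [build_peptide_key(pep, tracked_mods)]
        return key_cache[cache_key]

    matrices, plog.duplicates_reduced = collate_ions(rows, keymap)
    plog.peptides_unmapped = len(unmapped)
    plog.n_keys = len(matrices)
    result = quantify(matrices, method=method)
    log.info(
        "%s-level report: %d keys x %d samples (method %s, %d unmapped peptides)",
        mode,
        plog.n_keys,
        len(result.sample_ids),
        method,
        plog.peptides_unmapped,
    )
    return result, plog
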