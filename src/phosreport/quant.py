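"""Per-key ion matrices and quantification: sum, max, and MaxLFQ.

For each site or peptide key the associated observed intensities form an
ions × samples matrix with explicit missingness (an unobserved (ion,
sample) cell is NaN; zeros never enter — they are treated as "not
quantified" upstream).  Three per-key summaries are offered:

``sum``
    log2 of the per-sample sum of observed intensities.
``max``
    log2 of the per-sample maximum.
``maxlfq``
    The MaxLFQ estimate: for every sample pair sharing at least one ion,
    the median log2 ratio over shared ions is computed; per-sample
    abundances are then the least-squares solution of the pairwise ratio
    system, solved independently on each connected component of the
    sample-sharing graph.  The remaining additive gauge freedom is fixed
    by anchoring the component's total to the sum of its per-sample mean
    observed log2 intensities, which preserves the overall intensity
    scale.  Samples with no observed ion stay missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class IonQuantMatrix:
    """Raw intensities of one key's ions across all samples (NaN = missing)."""

    key: object
    ion_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_ions, n_samples), float, NaN for missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ion_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match ion/sample ids")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] <= 0):
                raise ValueError("stored intensities must be positive (zeros are missing)")


@dataclass
class QuantResult:
    """Keys × samples log2 abundances produced by one quantification method."""

    keys: list[object]
    sample_ids: list[str]
    log2_abundance: np.ndarray
    method: str
    n_ions: list[int] = field(default_factory=list)

    def linear_abundance(self) -> np.ndarray:
        return np.power(2.0, self.log2_abundance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log2_abundance,
            index=[str(k) for k in self.keys],
            columns=self.sample_ids,
        )


def collate_ions(rows: pd.DataFrame, keymap) -> tuple[list[IonQuantMatrix], int]:
    """Group observations into one ion matrix per distinct key.

    ``keymap`` maps a row (a named tuple over the canonical columns) to
    the list of keys its evidence supports; a row contributing to k keys
    appears in all k matrices.  The ion id is the fragment id qualified
    by its precursor when present (engine fragment labels such as ``y3``
    repeat across precursors), else the precursor id alone (an MS1
    trace).  Duplicate (ion,
    sample) observations are reduced by taking the maximum intensity;
    the number of duplicates is returned alongside the matrices.
    """
    sample_ids = list(dict.fromkeys(rows["run_id"])) if len(rows) else []
    cells: dict[object, dict[tuple[str, str], float]] = {}
    key_order: list[object] = []
    n_duplicates = 0
    for row in rows.itertuples(index=False):
        intensity = float(row.intensity)
        if not np.isfinite(intensity) or intensity <= 0:
            continue
        ion = (
            f"{row.precursor_id}/{row.fragment_id}"
            if row.fragment_id
            else row.precursor_id
        )
        for key in keymap(row):
            if key not in cells:
                cells[key] = {}
                key_order.append(key)
            bucket = cells[key]
            cell = (ion, row.run_id)
            if cell in bucket:
                n_duplicates += 1
                bucket[cell] = max(bucket[cell], intensity)
            else:
                bucket[cell] = intensity

    matrices: list[IonQuantMatrix] = []
    sample_index = {s: j for j, s in enumerate(sample_ids)}
    for key in key_order:
        bucket = cells[key]
        ion_ids = list(dict.fromkeys(ion for ion, _ in bucket))
        ion_index = {f: i for i, f in enumerate(ion_ids)}
        values = np.full((len(ion_ids), len(sample_ids)), np.nan)
        for (ion, run), intensity in bucket.items():
            values[ion_index[ion], sample_index[run]] = intensity
        matrices.append(IonQuantMatrix(key, ion_ids, sample_ids, values))
    if n_duplicates:
        log.info("reduced %d duplicate (ion, sample) observations by max", n_duplicates)
    return matrices, n_duplicates


def quantify_sum(m: IonQuantMatrix) -> np.ndarray:
    """Per-sample log2 of the sum of observed intensities."""
    observed = np.isfinite(m.values)
    sums = np.where(observed, m.values, 0.0).sum(axis=0)
    out = np.full(len(m.sample_ids), np.nan)
    has = observed.any(axis=0)
    out[has] = np.log2(sums[has])
    return out


def quantify_max(m: IonQuantMatrix) -> np.ndarray:
    """Per-sample log2 of the maximum observed intensity."""
    observed = np.isfinite(m.values)
    out = np.full(len(m.sample_ids), np.nan)
    has = observed.any(axis=0)
    if has.any():
        with np.errstate(invalid="ignore"):
            maxima = np.nanmax(m.values[:, has], axis=0)
        out[has] = np.log2(maxima)
    return out


def _components(n: int, edges: list[tuple[int, int]], active: np.ndarray) -> list[list[int]]:
    """Connected components (union-find) over the active samples."""
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for s in range(n):
        if active[s]:
            groups.setdefault(find(s), []).append(s)
    return list(groups.values())


def quantify_maxlfq(m: IonQuantMatrix, min_shared_ions: int = 1) -> np.ndarray:
    """MaxLFQ per-sample log2 abundances from pairwise median log ratios.

    For each unordered sample pair (i, j) with at least ``min_shared_ions``
    ions observed in both, the median over shared ions of
    ``log2 v[:, j] - log2 v[:, i]`` enters the least-squares system
    ``w_j - w_i = r_ij``.  The system is solved per connected component of
    the pair graph; the solution's free additive constant is fixed so the
    component's total equals the sum of its samples' mean observed log2
    intensities.  A single-sample component gets the mean of its observed
    log2 intensities; a sample with no observations gets NaN.

    The result is equivariant under sample permutation and invariant to
    ion row order.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        X = np.log2(m.values)
    n_samples = X.shape[1]
    observed = np.isfinite(X)
    active = observed.any(axis=0)
    out = np.full(n_samples, np.nan)
    if not active.any():
        return out

    edges: list[tuple[int, int]] = []
    ratios: list[float] = []
    for i in range(n_samples):
        if not active[i]:
            continue
        for j in range(i + 1, n_samples):
            if not active[j]:
                continue
            shared = observed[:, i] & observed[:, j]
            if shared.sum() >= min_shared_ions and shared.any():
                edges.append((i, j))
                ratios.append(float(np.median(X[shared, j] - X[shared, i])))

    col_means = np.array(
        [X[observed[:, s], s].mean() if active[s] else np.nan for s in range(n_samples)]
    )
    for component in _components(n_samples, edges, active):
        anchor = float(col_means[component].sum())
        if len(component) == 1:
            out[component[0]] = anchor
            continue
        local = {s: k for k, s in enumerate(component)}
        comp_edges = [(local[i], local[j], r) for (i, j), r in zip(edges, ratios)
                      if i in local and j in local]
        A = np.zeros((len(comp_edges), len(component)))
        b = np.zeros(len(comp_edges))
        for row, (i, j, r) in enumerate(comp_edges):
            A[row, i] = -1.0
            A[row, j] = 1.0
            b[row] = r
        # minimum-norm least-squares solution; the null space of A on a
        # connected component is the constant vector, so shifting to the
        # anchor keeps it a minimizer
        w0 = np.linalg.lstsq(A, b, rcond=None)[0]
        w = w0 + (anchor - w0.sum()) / len(component)
        for s, k in local.items():
            out[s] = w[k]
    return out


QUANT_METHODS = {
    "sum": quantify_sum,
    "max": quantify_max,
    "maxlfq": quantify_maxlfq,
}


def quantify(matrices: list[IonQuantMatrix], method: str = "maxlfq") -> QuantResult:
    """Apply one quantification method to every key's matrix."""
    try:
        fn = QUANT_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown quantification method {method!r}; expected one of "
            f"{sorted(QUANT_METHODS)}"
        ) from None
    if not matrices:
        return QuantResult([], [], np.zeros((0, 0)), method, [])
    sample_ids = matrices[0].sample_ids
    rows = [fn(m) for m in matrices]
    return QuantResult(
        keys=[m.key for m in matrices],
        sample_ids=list(sample_ids),
        log2_abundance=np.vstack(rows),
        method=method,
        n_ions=[len(m.ion_ids) for m in matrices],
    )
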