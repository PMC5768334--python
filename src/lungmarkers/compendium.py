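"""Expression compendium container and I/O.

A compendium is a probe-by-sample matrix of log2 intensities together with a
group label per sample (``lung_tumor`` and ``lung_normal`` are reserved;
other labels name non-lung normal tissues) and optional per-probe gene and
surface-accessibility annotations.

Matrices are tab-delimited with probe ids in the first column and sample ids
in the header row; annotations are tab-delimited with ``sample_id`` and
``group`` columns (``histology`` optional).  Missing values are rejected
rather than imputed: all downstream statistics assume complete matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LUNG_TUMOR = "lung_tumor"
LUNG_NORMAL = "lung_normal"

log = logging.getLogger(__name__)


@dataclass
class ExpressionCompendium:
    """Probe x sample log2 expression matrix with sample group labels.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, probes as rows, samples as columns.
    sample_group
        Series mapping every sample id to a group label.
    probe_gene
        Optional Series mapping probe ids to gene symbols.
    surface_flag
        Optional Series of booleans marking surface-accessible probes.
    """

    values: pd.DataFrame
    sample_group: pd.Series
    probe_gene: pd.Series | None = None
    surface_flag: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at probe "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.sample_group.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    # -- convenience -----------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_group.loc[self.sample_ids]))

    def group_samples(self, group: str) -> list[str]:
        labels = self.sample_group.loc[self.sample_ids]
        return [s for s, g in labels.items() if g == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of all samples carrying ``group``."""
        cols = self.group_samples(group)
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[cols]

    def gene_of(self, probe_id: str) -> str | None:
        if self.probe_gene is None:
            return None
        return self.probe_gene.get(probe_id)


def read_compendium(matrix_path: str | Path, annotation_path: str | Path) -> ExpressionCompendium:
    """Read a TSV expression matrix plus its sample annotation table."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids in {matrix_path}: {dups}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {matrix_path} at probe {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {matrix_path} at probe {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in ann.columns:
            raise ValueError(f"annotation {annotation_path} lacks a {col!r} column")
    sample_group = ann.set_index("sample_id")["group"]
    return ExpressionCompendium(values=values, sample_group=sample_group)


def write_compendium(
    comp: ExpressionCompendium, matrix_path: str | Path, annotation_path: str | Path
) -> None:
    """Write the matrix and annotation back to the TSV formats ``read_compendium`` accepts."""
    comp.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    ann = pd.DataFrame(
        {"sample_id": comp.sample_ids,
         "group": comp.sample_group.loc[comp.sample_ids].to_numpy()}
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_probe_list(path: str | Path) -> list[str]:
    """One probe id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def filter_surface(
    comp: ExpressionCompendium, surface_list_path: str | Path
) -> ExpressionCompendium:
    """Restrict the compendium to surface-accessible probes.

    The retained probe count is the N used for Bonferroni correction in the
    screen; it is always taken from the filtered compendium, never assumed.
    List entries absent from the matrix are ignored with a warning.
    """
    wanted = set(read_probe_list(surface_list_path))
    unknown = wanted.difference(comp.values.index)
    if unknown:
        log.warning(
            "%d surface-list probe ids absent from the matrix (ignored)", len(unknown)
        )
    keep = [p for p in comp.values.index if p in wanted]
    if not keep:
        raise ValueError("surface list shares no probes with the matrix")
    out = replace(
        comp,
        values=comp.values.loc[keep],
        surface_flag=pd.Series(True, index=keep),
        probe_gene=None if comp.probe_gene is None else comp.probe_gene.reindex(keep),
    )
    log.info("surface filter retained %d of %d probes", out.n_probes, comp.n_probes)
    return out


def normalize_to_reference(
    comp: ExpressionCompendium, reference: str = "median"
) -> ExpressionCompendium:
    """Shift each sample on the log2 scale so its median matches a reference sample.

    ``reference`` is a sample id, or ``"median"`` to pick the sample whose
    total intensity is the median over samples.  This is a deliberately simple
    location adjustment: the screen's statistics depend only on relative
    per-probe group differences, and real compendia are expected to arrive
    already normalized by a full between-array method.
    """
    if comp.n_samples == 1 and reference == "median":
        log.warning("single-sample compendium: normalization is a no-op")
        return comp
    if reference == "median":
        totals = comp.values.sum(axis=0)
        order = totals.sort_values(kind="stable").index
        reference = order[(len(order) - 1) // 2]
    elif reference not in comp.values.columns:
        raise ValueError(f"reference sample {reference!r} not in compendium")
    ref_median = comp.values[reference].median()
    shifts = ref_median - comp.values.median(axis=0)
    return replace(comp, values=comp.values.add(shifts, axis=1))
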