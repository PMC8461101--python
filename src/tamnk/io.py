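"""Readers and writers for the formats the pipeline touches, plus the
built-in gene-set registry.

Supported formats: Matrix Market triplet bundles (10x-style
``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``), dense CSV
(genes × observations with a header row of observation ids), survival
TSV (``sample_id  time  event``), and GMT gene-set files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import (
    ExpressionMatrix,
    FormatError,
    GeneSet,
    LigandReceptorPair,
    SurvivalRecord,
    ValidationError,
    normalize_symbol,
)

# ---------------------------------------------------------------------------
# Built-in gene-set registry
# ---------------------------------------------------------------------------

#: 12-gene monocyte/TAM signature used by the TAM-to-NK score.
TAM_TYPE_GENES = (
    "APOE", "C1QA", "C1QB", "C1QC", "CCL12", "CCL6",
    "CCL8", "LYZ2", "PF4", "WFDC17", "CSF1R", "CXCL14",
)
#: 10-gene NK-like non-functioning cell signature used by the TAM-to-NK score.
#: AW112010 is a mouse transcript with no human ortholog symbol; it simply
#: fails to match in human cohorts and is dropped at scoring time.
NK_TYPE_GENES = (
    "AW112010", "CCL5", "CD3E", "CD52", "GZMA",
    "GZMB", "GZMC", "IL2RB", "LTB", "NKG7",
)

_PANELS = {
    "M0": ("CD74", "C1QA", "APOE"),
    "M1": ("CXCL2", "IL1B", "CXCL10"),
    "M2": ("CCL8", "CBR2", "FOLR2"),
    "MONOCYTE": ("C1QB", "C1QC", "C1QA"),
    "NK_MARK": ("NKG7", "IL2RB", "CD3E"),
}

#: Macrophage → T/NK ligand-receptor axes scored by the interaction analysis.
BUILTIN_LR_PAIRS = (
    LigandReceptorPair("CCL3", "CCR5"),
    LigandReceptorPair("CSF1", "CSF1R"),
    LigandReceptorPair("ICAM1", "ITGAL"),
    LigandReceptorPair("CCL4", "CCR5"),
)


def builtin_gene_sets() -> dict[str, GeneSet]:
    """Return the built-in registry of signatures and marker panels.

    Keys: ``TAM_TYPE`` and ``NK_TYPE`` (the two TAM-to-NK score
    signatures), the polarization panels ``M0``/``M1``/``M2``, plus
    ``MONOCYTE`` and ``NK_MARK`` population markers.
    """
    reg = {
        "TAM_TYPE": GeneSet("TAM_TYPE", TAM_TYPE_GENES),
        "NK_TYPE": GeneSet("NK_TYPE", NK_TYPE_GENES),
    }
    for name, genes in _PANELS.items():
        reg[name] = GeneSet(name, genes)
    return reg


def builtin_lr_pairs() -> tuple[LigandReceptorPair, ...]:
    return BUILTIN_LR_PAIRS


# ---------------------------------------------------------------------------
# Matrix Market bundle
# ---------------------------------------------------------------------------

def _read_sidecar(path: str | Path) -> list[str]:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # 10x sidecars may carry extra tab-separated columns; first wins
            entries.append(line.split("\t")[0])
    return entries


def read_mtx_bundle(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a 10x-style Matrix Market count bundle into an ExpressionMatrix.

    The MTX file uses 1-based coordinate indexing per the Matrix Market
    standard; sidecar files list one gene symbol / barcode per line.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    if scipy.sparse.issparse(mat):
        dense = np.asarray(mat.todense(), dtype=float)
    else:
        dense = np.asarray(mat, dtype=float)
    genes = _read_sidecar(genes_path)
    barcodes = _read_sidecar(barcodes_path)
    if len(genes) != dense.shape[0]:
        raise FormatError(
            f"gene sidecar has {len(genes)} entries but matrix header declares "
            f"{dense.shape[0]} rows"
        )
    if len(barcodes) != dense.shape[1]:
        raise FormatError(
            f"barcode sidecar has {len(barcodes)} entries but matrix header declares "
            f"{dense.shape[1]} columns"
        )
    if dense.size and not np.allclose(dense, np.round(dense)):
        raise FormatError("count matrix contains non-integer entries")
    return ExpressionMatrix(dense, genes, barcodes, layer_tag="counts")


def write_mtx_bundle(
    m: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    if m.layer_tag != "counts":
        raise FormatError("MTX bundles hold integer counts; got lognorm layer")
    sparse = scipy.sparse.coo_matrix(np.round(m.values).astype(np.int64))
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in m.gene_symbols))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in m.obs_ids))


# ---------------------------------------------------------------------------
# Dense CSV
# ---------------------------------------------------------------------------

def read_dense_csv(path: str | Path, layer_tag: str = "counts") -> ExpressionMatrix:
    """Read a genes × observations CSV with gene symbols in the first column."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return ExpressionMatrix.from_frame(frame, layer_tag=layer_tag)


def write_dense_csv(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a TSV with columns sample_id, time, event into records.

    Raises :class:`ValidationError` naming the offending row for
    non-positive times or event indicators outside {0, 1}.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"survival table must have columns {sorted(required)}; got {list(frame.columns)}"
        )
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        try:
            records.append(SurvivalRecord(str(row.sample_id), float(row.time), row.event))
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"survival table line {i}: {exc}") from exc
    return records


def write_survival_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.subject_id, r.time, r.event) for r in records],
        columns=["sample_id", "time", "event"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file (name, description, genes...) into a registry dict."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected at least name, description and one gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g.strip()]
            # silently de-duplicate: public GMT files routinely repeat symbols
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(normalize_symbol(g), None)
            sets[name] = GeneSet(name, list(seen))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")
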