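"""Core in-memory containers for expression data and gene sets.

The pipeline spans two kinds of observations — single cells and bulk
patient samples — so the central container is a genes × observations
matrix with a ``layer_tag`` recording whether it holds raw UMI counts or
log-normalized expression.  Gene symbols are uppercase-normalized on
ingest so that mouse panels (``Cd74``) and human TCGA-style symbols
(``CD74``) resolve to the same registry entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or matrix does not conform to its declared format."""


class ContractError(ValueError):
    """An operation was called on input violating its pre-conditions."""


class ValidationError(ValueError):
    """User-supplied data failed semantic validation."""


#: Typographical variants seen in the literature mapped to official symbols.
SYMBOL_ALIASES = {
    "FOLR2X": "FOLR2",
    "CAF1R": "CSF1R",
    "GSF1R": "CSF1R",
    "CSCL14": "CXCL14",
}


def normalize_symbol(symbol: str) -> str:
    """Uppercase a gene symbol and resolve known typographical aliases.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    s = str(symbol).strip().upper()
    return SYMBOL_ALIASES.get(s, s)


def normalize_symbols(symbols: Iterable[str]) -> list[str]:
    return [normalize_symbol(s) for s in symbols]


@dataclass
class ExpressionMatrix:
    """Genes × observations expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_obs)
        Non-negative expression values.  When ``layer_tag == "counts"``
        all entries must be non-negative integers.
    gene_symbols : sequence of str
        Unique gene symbols; uppercased and alias-resolved on construction.
    obs_ids : sequence of str
        Unique observation (cell or sample) identifiers.
    layer_tag : {"counts", "lognorm"}
    """

    values: np.ndarray
    gene_symbols: list[str]
    obs_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D genes × observations matrix")
        self.gene_symbols = normalize_symbols(self.gene_symbols)
        self.obs_ids = [str(o) for o in self.obs_ids]
        n_genes, n_obs = self.values.shape
        if len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} matrix rows"
            )
        if len(self.obs_ids) != n_obs:
            raise FormatError(
                f"{len(self.obs_ids)} observation ids for {n_obs} matrix columns"
            )
        if len(set(self.gene_symbols)) != n_genes:
            raise FormatError("duplicate gene symbols after normalization")
        if len(set(self.obs_ids)) != n_obs:
            raise FormatError("duplicate observation ids")
        if self.layer_tag not in ("counts", "lognorm"):
            raise FormatError(f"unknown layer_tag {self.layer_tag!r}")
        if self.values.size and self.values.min() < 0:
            raise FormatError("expression values must be non-negative")
        if self.layer_tag == "counts" and self.values.size:
            if not np.allclose(self.values, np.round(self.values)):
                raise FormatError("counts layer must contain integer values")

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    # -- subsetting ----------------------------------------------------------
    def subset_obs(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_symbols),
            [self.obs_ids[i] for i in idx],
            self.layer_tag,
        )

    def subset_genes(self, symbols: Sequence[str]) -> "ExpressionMatrix":
        gi = self.gene_index()
        keep = [gi[normalize_symbol(s)] for s in symbols if normalize_symbol(s) in gi]
        return ExpressionMatrix(
            self.values[keep, :],
            [self.gene_symbols[i] for i in keep],
            list(self.obs_ids),
            self.layer_tag,
        )

    # -- interop -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_symbols, columns=self.obs_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, layer_tag: str = "counts") -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), layer_tag)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (obs × genes orientation)."""
        import anndata as ad

        adata = ad.AnnData(X=self.values.T.copy())
        adata.obs_names = list(self.obs_ids)
        adata.var_names = list(self.gene_symbols)
        adata.uns["layer_tag"] = self.layer_tag
        return adata

    @classmethod
    def from_anndata(cls, adata, layer_tag: str | None = None) -> "ExpressionMatrix":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        tag = layer_tag or adata.uns.get("layer_tag", "counts")
        return cls(np.asarray(X).T, list(adata.var_names), list(adata.obs_names), tag)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols (signature or marker panel)."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Iterable[str]):
        norm = normalize_symbols(genes)
        if not norm:
            raise ValidationError(f"gene set {name!r} is empty")
        if len(set(norm)) != len(norm):
            raise ValidationError(f"gene set {name!r} contains duplicate symbols")
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "genes", tuple(norm))

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, symbols: Iterable[str]) -> "GeneSet | None":
        """Restrict to symbols present in ``symbols``; None if empty."""
        avail = set(normalize_symbols(symbols))
        kept = [g for g in self.genes if g in avail]
        return GeneSet(self.name, kept) if kept else None


@dataclass(frozen=True)
class LigandReceptorPair:
    """A directed ligand → receptor gene pair."""

    ligand: str
    receptor: str

    def __init__(self, ligand: str, receptor: str):
        lig, rec = normalize_symbol(ligand), normalize_symbol(receptor)
        if lig == rec:
            raise ValidationError(f"ligand and receptor are identical: {lig}")
        object.__setattr__(self, "ligand", lig)
        object.__setattr__(self, "receptor", rec)

    @property
    def name(self) -> str:
        return f"{self.ligand}-{self.receptor}"


@dataclass
class SurvivalRecord:
    """One subject's follow-up: time on study and event indicator."""

    subject_id: str
    time: float
    event: int
    score: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if not self.time > 0:
            raise ValidationError(f"subject {self.subject_id}: time must be > 0")
        self.event = int(self.event)
        if self.event not in (0, 1):
            raise ValidationError(f"subject {self.subject_id}: event must be 0 or 1")
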