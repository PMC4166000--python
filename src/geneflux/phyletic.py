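"""Gene-family copy-number matrices and pangenome summaries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["PhyleticMatrix", "PangenomeSummary", "read_matrix", "write_matrix", "read_categories", "summarize"]


@dataclass
class PhyleticMatrix:
    """Families x genomes copy-number table.

    counts[i, j] is the number of copies of family ``family_ids[i]`` in genome
    ``genome_ids[j]``. Every family must be present (count >= 1) in at least
    one genome: never-observed families are unknowable from data and are
    rejected at construction.
    """

    family_ids: list[str]
    genome_ids: list[str]
    counts: np.ndarray  # int array, shape (n_families, n_genomes)
    categories: Optional[dict[str, str]] = None  # family id -> single-letter category

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.family_ids), len(self.genome_ids)):
            raise ValueError("counts shape does not match family/genome id lists")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at family {self.family_ids[i]!r}, genome {self.genome_ids[j]!r}"
            )
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("duplicate family ids")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome ids")
        empty = np.flatnonzero(self.counts.sum(axis=1) == 0)
        if empty.size:
            raise ValueError(
                f"families absent from every genome: {[self.family_ids[i] for i in empty[:5]]}"
            )

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def presence(self) -> np.ndarray:
        return self.counts >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.family_ids, name="family_id"),
                            columns=self.genome_ids)

    def check_against_tree(self, tree) -> None:
        tree_leaves = set(tree.leaf_labels())
        here = set(self.genome_ids)
        if tree_leaves != here:
            only_tree = sorted(tree_leaves - here)
            only_matrix = sorted(here - tree_leaves)
            raise ValueError(
                f"genome ids do not match tree leaves; only in tree: {only_tree[:5]}, "
                f"only in matrix: {only_matrix[:5]}"
            )


@dataclass
class PangenomeSummary:
    F: float  # median number of gene families per genome
    P: int  # pangenome size: number of distinct families
    n_genomes: int
    n_singletons: int  # families present in exactly one genome
    mean_gene_length_nt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.F > self.P or self.n_singletons > self.P:
            raise ValueError("inconsistent pangenome summary (F <= P, singletons <= P required)")


def read_matrix(path: Union[str, Path]) -> PhyleticMatrix:
    """Read a TSV with header ``family_id<TAB>genome1<TAB>...`` and integer cells."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "family_id":
        raise ValueError(f"{path}: first column must be 'family_id', got {df.columns[0]!r}")
    family_ids = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-integer cell at family {family_ids[row]!r}, genome {col!r}"
            )
    counts = body.to_numpy(dtype=np.int64)
    return PhyleticMatrix(family_ids, list(body.columns), counts)


def write_matrix(matrix: PhyleticMatrix, path: Union[str, Path]) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_categories(path: Union[str, Path]) -> dict[str, str]:
    """Sidecar TSV ``family_id<TAB>category`` mapping families to COG letters."""
    df = pd.read_csv(path, sep="\t", header=None, names=["family_id", "category"], dtype=str)
    return dict(zip(df["family_id"], df["category"]))


def summarize(matrix: PhyleticMatrix, mean_gene_length_nt: Optional[float] = None) -> PangenomeSummary:
    """F (median families per genome, presence = copy number >= 1), P, singletons.

    The even-n median is the mean of the two central values.
    """
    per_genome = matrix.presence.sum(axis=0)
    genomes_per_family = matrix.presence.sum(axis=1)
    return PangenomeSummary(
        F=float(np.median(per_genome)),
        P=matrix.n_families,
        n_genomes=matrix.n_genomes,
        n_singletons=int((genomes_per_family == 1).sum()),
        mean_gene_length_nt=mean_gene_length_nt,
    )
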