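"""OTU table container and preprocessing.

An OTU table is a samples x taxa matrix of non-negative abundances, either
raw (library-size dependent) or relative (each row sums to 1).  Optional
per-sample binary phenotype labels and per-taxon taxonomy lineages ride
along.  All preprocessing used by the correlation-network pipeline lives
here: relative-abundance conversion, zero-sum sample removal, joint
prevalence/abundance filtering, taxonomic agglomeration and phenotype
splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered taxonomic ranks understood by :func:`agglomerate_to_rank`.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Lineage tokens treated as "unclassified at this rank".
_UNCLASSIFIED = {"", "unclassified", "unknown", "na", "none", "__"}


@dataclass
class OtuTable:
    """Samples x taxa abundance matrix with optional labels and lineages.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row.
    taxon_ids
        Unique taxon identifiers, one per column.
    abundance
        Non-negative matrix of shape ``(n_samples, n_taxa)``.  Raw counts
        (or absolute abundances) unless ``is_relative`` is set, in which
        case every row sums to 1.
    is_relative
        Whether ``abundance`` holds per-sample proportions.
    labels
        Optional binary phenotype per sample (0 = control/healthy,
        1 = case/disease).
    lineages
        Optional mapping ``taxon_id -> ordered rank strings`` (kingdom
        through genus, semicolon-joined in the on-disk format).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    abundance: np.ndarray
    is_relative: bool = False
    labels: np.ndarray | None = None
    lineages: dict[str, list[str]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 2:
            raise ValueError("abundance must be a 2-D matrix")
        n, p = self.abundance.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise ValueError(
                f"shape mismatch: {n} x {p} matrix with "
                f"{len(self.sample_ids)} sample ids, {len(self.taxon_ids)} taxon ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.taxon_ids)) != p:
            raise ValueError("taxon_ids are not unique")
        if not np.all(np.isfinite(self.abundance)):
            raise ValueError("abundance contains non-finite values")
        if np.any(self.abundance < 0):
            raise ValueError("abundance contains negative values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per sample")
        if self.is_relative and n > 0:
            sums = self.abundance.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValueError(f"relative table has row not summing to 1 (sample {bad!r})")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundance.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.sample_ids, columns=self.taxon_ids)

    def select_taxa(self, keep: np.ndarray | list) -> "OtuTable":
        """Return a copy restricted to the given taxon indices (order kept)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        taxa = [self.taxon_ids[i] for i in keep]
        lineages = None
        if self.lineages is not None:
            lineages = {t: self.lineages[t] for t in taxa if t in self.lineages}
        # dropping columns breaks the row-sum invariant of a relative table
        return replace(
            self,
            taxon_ids=taxa,
            abundance=self.abundance[:, keep].copy(),
            is_relative=False,
            lineages=lineages,
        )

    def select_samples(self, keep: np.ndarray | list) -> "OtuTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in keep],
            abundance=self.abundance[keep].copy(),
            labels=None if self.labels is None else self.labels[keep].copy(),
        )


def to_relative_abundance(table: OtuTable) -> OtuTable:
    """Normalize each sample by its library size so rows sum to 1.

    Proportionality within each row is preserved; applying twice equals
    applying once.  Raises on all-zero rows (remove them first with
    :func:`remove_zero_sum_samples`).
    """
    sums = table.abundance.sum(axis=1)
    zero = sums <= 0
    if np.any(zero):
        bad = table.sample_ids[int(np.argmax(zero))]
        raise ValueError(
            f"sample {bad!r} has zero total abundance; "
            "remove zero-sum samples before normalizing"
        )
    rel = table.abundance / sums[:, None]
    return replace(table, abundance=rel, is_relative=True)


def remove_zero_sum_samples(table: OtuTable) -> OtuTable:
    """Drop samples whose taxa abundances sum to zero, preserving order."""
    keep = table.abundance.sum(axis=1) > 0
    if not np.any(keep):
        logger.warning("all %d samples have zero total abundance", table.n_samples)
    if np.all(keep):
        return table
    return table.select_samples(keep)


def prevalence_abundance_filter(
    table: OtuTable, min_prevalence: float, min_rel_abundance: float = 1e-4
) -> OtuTable:
    """Keep taxa exceeding ``min_rel_abundance`` in >= ``min_prevalence`` of samples.

    The abundance comparison is strict (> floor), the prevalence comparison
    non-strict (>= fraction).  Requires a relative-abundance table so the
    floor is on a proportion scale.
    """
    if not table.is_relative:
        raise ValueError("prevalence filter requires a relative-abundance table")
    present = table.abundance > min_rel_abundance
    prevalence = present.mean(axis=0)
    keep = prevalence >= min_prevalence
    out = table.select_taxa(keep)
    # selecting taxa breaks the row-sum invariant; the result is no longer
    # a relative table in the strict sense
    return replace(out, is_relative=False)


def kept_taxa_mask(table: OtuTable, min_prevalence: float, min_rel_abundance: float = 1e-4) -> np.ndarray:
    """Boolean mask over taxa for the prevalence/abundance filter rule."""
    if not table.is_relative:
        raise ValueError("prevalence filter requires a relative-abundance table")
    present = table.abundance > min_rel_abundance
    return present.mean(axis=0) >= min_prevalence


def _rank_fallback_id(lineage: list[str], rank_index: int) -> str:
    """Identifier at the requested rank, falling back to the nearest
    classified higher rank when unclassified."""
    for i in range(min(rank_index, len(lineage) - 1), -1, -1):
        token = lineage[i].strip() if i < len(lineage) else ""
        if token.lower() not in _UNCLASSIFIED and not token.endswith("__"):
            return token
    raise ValueError(f"lineage has no classified rank at or above index {rank_index}: {lineage}")


def agglomerate_to_rank(table: OtuTable, rank: str = "genus") -> OtuTable:
    """Sum taxa sharing the same identifier at ``rank``.

    A taxon unclassified at ``rank`` is identified by its nearest classified
    higher rank (e.g. family), and taxa sharing that fallback identifier
    merge together.  Per-sample total abundance is conserved exactly.
    """
    if table.lineages is None:
        raise ValueError("agglomeration requires lineages")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rank_index = RANKS.index(rank)
    group_ids: list[str] = []
    for t in table.taxon_ids:
        if t not in table.lineages:
            raise ValueError(f"taxon {t!r} has no lineage")
        group_ids.append(_rank_fallback_id(table.lineages[t], rank_index))
    order: list[str] = []
    cols: dict[str, list[int]] = {}
    for j, g in enumerate(group_ids):
        if g not in cols:
            cols[g] = []
            order.append(g)
        cols[g].append(j)
    out = np.zeros((table.n_samples, len(order)))
    for k, g in enumerate(order):
        out[:, k] = table.abundance[:, cols[g]].sum(axis=1)
    return OtuTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=order,
        abundance=out,
        is_relative=table.is_relative,
        labels=table.labels,
    )


def split_by_phenotype(table: OtuTable) -> tuple[OtuTable, OtuTable]:
    """Partition samples into (label 0, label 1) sub-tables sharing the taxon set."""
    if table.labels is None:
        raise ValueError("phenotype split requires labels")
    values = np.unique(table.labels)
    if len(values) != 2:
        raise ValueError(f"binary phenotype required; found label values {values.tolist()}")
    lo, hi = sorted(values.tolist())
    return (
        table.select_samples(table.labels == lo),
        table.select_samples(table.labels == hi),
    )


# --------------------------------------------------------------------------
# I/O: tab-separated tables, first column sample ID, taxa as columns.

def read_otu_table(
    path,
    labels_path=None,
    lineage_path=None,
    is_relative: bool = False,
) -> OtuTable:
    """Read a TSV OTU table (rows = samples, columns = taxa).

    ``labels_path``: optional two-column TSV (sample ID, 0/1 label).
    ``lineage_path``: optional two-column TSV (taxon ID, semicolon-joined
    lineage kingdom..genus).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
        labels = lab.reindex(df.index).to_numpy()
        if np.any(pd.isna(labels)):
            missing = df.index[pd.isna(labels)][0]
            raise ValueError(f"no label for sample {missing!r}")
        labels = labels.astype(int)
    lineages = None
    if lineage_path is not None:
        lin = pd.read_csv(lineage_path, sep="\t", index_col=0).iloc[:, 0]
        lineages = {t: str(s).split(";") for t, s in lin.items()}
    return OtuTable(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        abundance=df.to_numpy(dtype=float),
        is_relative=is_relative,
        labels=labels,
        lineages=lineages,
    )


def write_otu_table(table: OtuTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")
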