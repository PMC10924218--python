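"""Core data containers shared by the sequencing arm.

A :class:`CountMatrix` couples a genes × samples integer count table with
per-gene lengths and per-sample metadata; an :class:`ExpressionMatrix`
holds the TPM-normalized view and keeps a provenance link back to the
counts it was derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: columns every sample-metadata table must provide
METADATA_COLUMNS = ("cell_type", "condition", "timepoint", "replicate", "female_id")

CONDITIONS = ("donor", "NT")


@dataclass
class CountMatrix:
    """Raw read counts per gene per sample with sample metadata.

    Parameters
    ----------
    counts
        genes × samples non-negative integer counts; index = gene ids,
        columns = sample ids.
    lengths
        per-gene transcript (summed exon) length in bp, indexed like
        ``counts``; strictly positive.
    metadata
        per-sample table indexed by sample id with columns
        ``cell_type``, ``condition`` (donor / NT), ``timepoint``,
        ``replicate`` and ``female_id``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        lacking = set(METADATA_COLUMNS) - set(self.metadata.columns)
        if lacking:
            raise ValueError(f"metadata lacks columns: {sorted(lacking)}")
        bad = set(self.metadata["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def select_samples(self, **filters: object) -> list[str]:
        """Sample ids matching all metadata ``column=value`` filters."""
        keep = pd.Series(True, index=self.metadata.index)
        for col, val in filters.items():
            if val is None:
                continue
            keep &= self.metadata[col] == val
        return list(self.metadata.index[keep])

    # -- plain-text round trip -------------------------------------------
    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        table = self.counts.copy()
        table.insert(0, "length", self.lengths)
        table.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, metadata_path: str | Path) -> "CountMatrix":
        table = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        if "length" not in table.columns:
            raise ValueError("count table needs a 'length' column")
        lengths = table.pop("length")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id", dtype=str)
        meta["replicate"] = meta["replicate"].astype(int)
        return cls(counts=table.astype(np.int64), lengths=lengths, metadata=meta)


@dataclass
class ExpressionMatrix:
    """genes × samples TPM values with provenance to the source counts."""

    tpm: pd.DataFrame
    source: CountMatrix = field(repr=False)

    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns

    @property
    def metadata(self) -> pd.DataFrame:
        return self.source.metadata

    def select_samples(self, **filters: object) -> list[str]:
        return self.source.select_samples(**filters)

    def group_mean(self, **filters: object) -> pd.Series:
        """Replicate-mean TPM per gene over samples matching the filters."""
        cols = self.select_samples(**filters)
        if not cols:
            raise ValueError(f"no samples match {filters}")
        return self.tpm[cols].mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.tpm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")
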