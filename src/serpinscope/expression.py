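"""Abundance metrics and the zero-TPM sex partition.

A transcript is deemed expressed in a sex iff TPM > 0 in at least one sample
of that sex (samples within a sex are OR-combined); there is no epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._util import round_half_up


@dataclass
class ExpressionTable:
    """Per-transcript counts with effective lengths and a sample→sex map."""

    counts: pd.DataFrame  # index: transcript id; columns: samples
    lengths: pd.Series  # index: transcript id; effective length (nt)
    sex_map: Mapping[str, str]  # sample -> "F" | "M"

    def __post_init__(self):
        self.counts = self.counts.astype(float)
        self.lengths = self.lengths.astype(float).reindex(self.counts.index)
        if not self.counts.index.is_unique:
            raise ValueError("duplicate transcript ids")
        if (self.lengths <= 0).any() or self.lengths.isna().any():
            raise ValueError("effective lengths must be positive for all transcripts")
        if (self.counts < 0).any().any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.sex_map)
        if missing:
            raise ValueError(f"samples without sex assignment: {sorted(missing)}")

    def samples_of(self, sex: str) -> list[str]:
        return [s for s in self.counts.columns if self.sex_map[s] == sex]

    @classmethod
    def read_tsv(cls, counts_path, sex_map: Mapping[str, str]) -> "ExpressionTable":
        df = pd.read_csv(Path(counts_path), sep="\t")
        df = df.set_index(df.columns[0])
        lengths = df.iloc[:, 0]
        counts = df.iloc[:, 1:]
        return cls(counts, lengths, dict(sex_map))

    def write_tsv(self, path) -> None:
        out = pd.concat([self.lengths.rename("length"), self.counts], axis=1)
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t")


def compute_tpm(table: ExpressionTable) -> pd.DataFrame:
    """TPM_i = 1e6 · (c_i/l_i) / Σ_j (c_j/l_j), per sample.  An all-zero
    sample yields all-zero TPM (with a warning)."""
    rate = table.counts.div(table.lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        import warnings

        warnings.warn(f"all-zero sample(s): {list(denom.index[zero])}", stacklevel=2)
        denom = denom.replace(0, np.nan)
    return (1e6 * rate.div(denom, axis=1)).fillna(0.0)


def compute_fpkm(table: ExpressionTable) -> pd.DataFrame:
    """FPKM_i = 1e9 · c_i / (l_i · N) with N the sample's total count."""
    totals = table.counts.sum(axis=0).replace(0, np.nan)
    return (1e9 * table.counts.div(table.lengths, axis=0).div(totals, axis=1)).fillna(
        0.0
    )


def compute_isopct(
    tpm: pd.DataFrame, gene_map: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Isoform percentage: 100 · TPM_i / Σ TPM over the transcript's gene
    (identity map when ``gene_map`` is None — every transcript 100 or 0)."""
    genes = pd.Series(
        {t: (gene_map or {}).get(t, t) for t in tpm.index}, name="gene"
    )
    gene_tot = tpm.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100 * tpm / gene_tot
    return pct.fillna(0.0)


@dataclass
class SexPartition:
    female_only: frozenset
    male_only: frozenset
    shared: frozenset
    total_expressed: int = field(init=False)

    def __post_init__(self):
        if self.female_only & self.male_only or self.female_only & self.shared or (
            self.male_only & self.shared
        ):
            raise ValueError("partition sets must be disjoint")
        self.total_expressed = len(self.female_only) + len(self.male_only) + len(
            self.shared
        )

    @property
    def expressed_in_male(self) -> int:
        return len(self.male_only) + len(self.shared)

    @property
    def expressed_in_female(self) -> int:
        return len(self.female_only) + len(self.shared)

    def percentages(self) -> dict:
        n = self.total_expressed
        pct = lambda k: round_half_up(100 * k / n) if n else 0.0
        return {
            "female_only": pct(len(self.female_only)),
            "male_only": pct(len(self.male_only)),
            "shared": pct(len(self.shared)),
        }

    def to_dict(self) -> dict:
        return {
            "female_only": sorted(self.female_only),
            "male_only": sorted(self.male_only),
            "shared": sorted(self.shared),
            "counts": {
                "female_only": len(self.female_only),
                "male_only": len(self.male_only),
                "shared": len(self.shared),
                "total_expressed": self.total_expressed,
                "expressed_in_male": self.expressed_in_male,
                "expressed_in_female": self.expressed_in_female,
            },
            "percentages": self.percentages(),
        }


def partition_by_sex(
    tpm: pd.DataFrame, sex_map: Mapping[str, str]
) -> SexPartition:
    """Apply the zero-TPM presence rule per sex and assemble the partition.

    Transcripts with zero TPM in every sample of both sexes are absent from
    all three sets.
    """
    f_samples = [s for s in tpm.columns if sex_map[s] == "F"]
    m_samples = [s for s in tpm.columns if sex_map[s] == "M"]
    if not f_samples or not m_samples:
        raise ValueError("need at least one sample per sex")
    in_f = (tpm[f_samples] > 0).any(axis=1)
    in_m = (tpm[m_samples] > 0).any(axis=1)
    return SexPartition(
        female_only=frozenset(tpm.index[in_f & ~in_m]),
        male_only=frozenset(tpm.index[in_m & ~in_f]),
        shared=frozenset(tpm.index[in_f & in_m]),
    )


def log2_matrix(tpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(TPM + pseudocount) heatmap matrix (zeros map to 0 at the default
    pseudocount of 1)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(tpm + pseudocount)
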