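"""Core in-memory containers for methylation data.

Beta values are per-probe methylation fractions in [0, 1] (0 = unmethylated,
1 = fully methylated). Matrices are oriented probes x samples, the convention
of array-methylation toolchains. Missing values are carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")

ANNOTATION_COLUMNS = ("probe_id", "chr", "pos", "gene", "region_group",
                      "cgi_relation", "snp_flag")


class AnnotationError(ValueError):
    """A probe required by an operation is missing from the annotation."""


@dataclass
class BetaMatrix:
    """Probes x samples beta-value matrix with missing values as NaN."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("beta values must be a 2-D probes x samples array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("observed beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index),
                   list(frame.columns))

    def subset_probes(self, probe_ids: list[str]) -> "BetaMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:10]}")
        rows = [index[p] for p in probe_ids]
        return BetaMatrix(self.values[rows, :], list(probe_ids),
                          list(self.sample_ids))

    def subset_samples(self, sample_ids: list[str]) -> "BetaMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        cols = [index[s] for s in sample_ids]
        return BetaMatrix(self.values[:, cols], list(self.probe_ids),
                          list(sample_ids))


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation (450K-manifest style).

    Columns: probe_id, chr (1..22/X/Y), pos (1-based), gene (symbol or
    empty), region_group (TSS200/TSS1500/5'UTR/1stExon/Body/3'UTR/IGR),
    cgi_relation (island/shore/shelf/open_sea), snp_flag (bool).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"]
            raise ValueError(f"duplicate probe_id in annotation: {list(dup)[:10]}")
        self.table = self.table.reset_index(drop=True)
        self._by_probe = self.table.set_index("probe_id", drop=False)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def require(self, probe_ids: list[str]) -> pd.DataFrame:
        """Annotation rows for ``probe_ids``; AnnotationError on any gap."""
        known = self._by_probe.index
        unknown = [p for p in probe_ids if p not in known]
        if unknown:
            raise AnnotationError(
                f"{len(unknown)} probe(s) missing from annotation: {unknown[:10]}"
            )
        return self._by_probe.loc[probe_ids]


@dataclass
class ReferenceProfiles:
    """Two per-probe reference methylomes used for mixture deconvolution."""

    probe_ids: list[str]
    beta_epithelial: np.ndarray
    beta_adipose: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.beta_epithelial = np.asarray(self.beta_epithelial, dtype=float)
        self.beta_adipose = np.asarray(self.beta_adipose, dtype=float)
        n = len(self.probe_ids)
        if self.beta_epithelial.shape != (n,) or self.beta_adipose.shape != (n,):
            raise ValueError("reference profiles must align with probe_ids")
        for name, arr in (("epithelial", self.beta_epithelial),
                          ("adipose", self.beta_adipose)):
            if np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} reference betas must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def abs_difference(self) -> np.ndarray:
        return np.abs(self.beta_adipose - self.beta_epithelial)

    def swapped(self) -> "ReferenceProfiles":
        """Relabel the two tissues (adipose <-> epithelial)."""
        return ReferenceProfiles(list(self.probe_ids),
                                 self.beta_adipose.copy(),
                                 self.beta_epithelial.copy())

    def subset(self, probe_ids: list[str]) -> "ReferenceProfiles":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise KeyError(f"probes absent from references: {missing[:10]}")
        rows = [index[p] for p in probe_ids]
        return ReferenceProfiles(list(probe_ids),
                                 self.beta_epithelial[rows],
                                 self.beta_adipose[rows])
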