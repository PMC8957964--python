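"""Immune and immunotherapy-response scores.

Formula-level scores computed here:

* TMB — tumor mutation burden, non-synonymous mutation count divided by the
  exome size in megabases (default 38 Mb).
* Signature scores — unweighted mean expression over a gene set. Built-in
  sets: the 6-gene interferon-gamma signature (IFNG) and the 18-gene antigen
  processing and presenting machinery set (APM, whose mean is the APS
  score). The IFNG.GS hallmark set ships as a placeholder requiring a
  user-supplied gene list, since its membership is defined externally.

Externally computed score tables (ESTIMATE, CIBERSORT, TIDE, MDSC, CAF,
TAM-M2 ...) are ingested as per-sample columns, never recomputed, and
associated with DM-BMI via Spearman correlation on the overlapping samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characterize import CorrelationRecord, correlate_features_with_score

DEFAULT_EXOME_MB = 38.0

IFNG_GENES = ("IFNG", "STAT1", "IDO1", "CXCL9", "CXCL10", "HLA-DRA")
APM_GENES = ("PSMB5", "PSMB6", "PSMB7", "PSMB8", "PSMB9", "PSMB10",
             "TAP1", "TAP2", "ERAP1", "ERAP2", "CANX", "CALR", "PDIA3",
             "TAPBP", "B2M", "HLA-A", "HLA-B", "HLA-C")


class CoverageError(ValueError):
    """No signature gene is present in the expression matrix."""


class NeedsGeneListError(ValueError):
    """The requested signature has no built-in membership."""


class AlignmentError(ValueError):
    """Score table and DM-BMI share too few samples."""


@dataclass(frozen=True)
class SignatureSet:
    """A named, ordered, duplicate-free gene set."""

    name: str
    gene_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("signature genes must be unique")


def builtin_signatures(ifng_gs_genes=None) -> list[SignatureSet]:
    """The built-in sets; pass genes to instantiate IFNG.GS.

    Without ``ifng_gs_genes`` only IFNG and APM are returned; requesting the
    hallmark set explicitly is done via :func:`get_signature`.
    """
    sigs = [SignatureSet("IFNG", IFNG_GENES), SignatureSet("APM", APM_GENES)]
    if ifng_gs_genes is not None:
        sigs.append(SignatureSet("IFNG.GS", tuple(ifng_gs_genes)))
    return sigs


def get_signature(name: str, genes=None) -> SignatureSet:
    if name == "IFNG":
        return SignatureSet("IFNG", IFNG_GENES)
    if name == "APM":
        return SignatureSet("APM", APM_GENES)
    if name == "IFNG.GS":
        if genes is None:
            raise NeedsGeneListError(
                "IFNG.GS has no built-in membership; supply the hallmark gene list"
            )
        return SignatureSet("IFNG.GS", tuple(genes))
    raise KeyError(f"unknown signature {name!r}")


def compute_tmb(mutations, exome_mb: float = DEFAULT_EXOME_MB):
    """Non-synonymous mutation count per megabase of exome.

    ``mutations`` is a per-sample count vector or Series; counts must be
    non-negative integers. Returns the same container type.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    counts = np.asarray(mutations, dtype=float)
    if (counts < 0).any():
        raise ValueError("mutation counts must be non-negative")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("mutation counts must be integers")
    tmb = counts / exome_mb
    if isinstance(mutations, pd.Series):
        return pd.Series(tmb, index=mutations.index, name="tmb")
    return tmb


def score_signature(expr: pd.DataFrame, sig: SignatureSet,
                    ) -> tuple[pd.Series, dict]:
    """Unweighted mean expression over the signature genes present.

    Returns (per-sample score, metadata). Genes missing from ``expr`` are
    listed in the metadata; if none is present a :class:`CoverageError` is
    raised.
    """
    present = [g for g in sig.gene_symbols if g in expr.index]
    missing = [g for g in sig.gene_symbols if g not in expr.index]
    if not present:
        raise CoverageError(
            f"no gene of signature {sig.name!r} present in expression matrix"
        )
    score = expr.loc[present].mean(axis=0)
    score.name = sig.name
    meta = {"signature": sig.name, "n_genes": len(sig.gene_symbols),
            "n_present": len(present), "missing_genes": missing,
            "aggregation": "unweighted mean"}
    return score, meta


def associate_scores(dmbmi: pd.Series, scores: pd.DataFrame,
                     min_overlap: int = 3) -> list[CorrelationRecord]:
    """Spearman association of each score column with DM-BMI.

    Both inputs are indexed by sample id; each column is correlated on its
    non-missing overlap with ``dmbmi``, and the overlap size is recorded.
    """
    dmbmi = pd.Series(dmbmi).astype(float)
    records = []
    for col in scores.columns:
        s = scores[col].dropna().astype(float)
        common = dmbmi.dropna().index.intersection(s.index)
        if len(common) < min_overlap:
            raise AlignmentError(
                f"column {col!r} overlaps DM-BMI on only {len(common)} samples"
            )
        rec = correlate_features_with_score(
            s.loc[common].to_numpy()[None, :], dmbmi.loc[common].to_numpy(),
            feature_ids=[col])[0]
        rec.extra["n_overlap"] = int(len(common))
        records.append(rec)
    return records


def build_score_table(expr: pd.DataFrame | None = None,
                      mutations: pd.Series | None = None,
                      external: pd.DataFrame | None = None,
                      exome_mb: float = DEFAULT_EXOME_MB,
                      ifng_gs_genes=None) -> tuple[pd.DataFrame, dict]:
    """Assemble the merged per-sample score table.

    Computes TMB from mutation counts and the built-in signature scores from
    expression, then joins any external score columns on sample id. Returns
    (table indexed by sample_id, metadata about signature coverage).
    """
    pieces, meta = [], {}
    if mutations is not None:
        pieces.append(compute_tmb(mutations, exome_mb).rename("TMB"))
    if expr is not None:
        for sig in builtin_signatures(ifng_gs_genes):
            score, m = score_signature(expr, sig)
            name = "APS" if sig.name == "APM" else sig.name
            pieces.append(score.rename(name))
            meta[name] = m
    if external is not None:
        ext = external.set_index("sample_id") if "sample_id" in external.columns \
            else external
        pieces.append(ext)
    if not pieces:
        raise ValueError("nothing to score: provide expr, mutations or external")
    table = pd.concat(pieces, axis=1)
    table.index.name = "sample_id"
    return table, meta
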