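"""Probe-level QC for beta-value matrices.

The chain mirrors standard 450K practice: drop probes with excessive
missingness (strictly more than half the samples by default), drop
sex-chromosome and SNP-overlapping probes, impute the remaining gaps with
k-nearest-neighbour imputation in probe space, and remove additive batch
effects by per-probe mean-centring of each batch onto the probe's grand mean.

The batch step is deliberately a mean-shift adjustment, not an
empirical-Bayes (ComBat-style) procedure: it exactly removes additive
per-batch offsets, which is the batch structure the synthetic generator
produces, and makes no claim about batch-specific variances.
"""

from __future__ import annotations

import numpy as np

from .containers import AnnotationError, BetaMatrix, ProbeAnnotation

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "x", "y"})


class DegenerateInputError(ValueError):
    """Input that leaves an operation with nothing valid to work on."""


def filter_probes(beta: BetaMatrix, ann: ProbeAnnotation,
                  missing_threshold: float = 0.5) -> BetaMatrix:
    """Remove probes failing QC; surviving probe order is preserved.

    A probe is removed iff its missing fraction is strictly greater than
    ``missing_threshold``, or it lies on a sex chromosome, or it carries a
    known SNP. Probes absent from ``ann`` raise :class:`AnnotationError`.
    """
    rows = ann.require(beta.probe_ids)
    missing_frac = np.isnan(beta.values).mean(axis=1)
    on_sex = rows["chr"].astype(str).isin(SEX_CHROMOSOMES).to_numpy()
    snp = rows["snp_flag"].astype(bool).to_numpy()
    keep = ~((missing_frac > missing_threshold) | on_sex | snp)
    kept = [p for p, k in zip(beta.probe_ids, keep) if k]
    return BetaMatrix(beta.values[keep, :], kept, list(beta.sample_ids))


def knn_impute(beta: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute missing entries from the k nearest probes.

    For a missing entry (probe i, sample j) the neighbours are the k probes
    closest to probe i in Euclidean distance over their co-observed samples,
    restricted to probes observed at sample j; the imputed value is the mean
    of their betas at sample j. Ties in distance break by probe order.
    Observed entries are returned bit-exactly unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = beta.values.copy()
    miss = np.isnan(X)
    if not miss.any():
        return BetaMatrix(X, list(beta.probe_ids), list(beta.sample_ids))
    if miss.all(axis=0).any():
        bad = [s for s, m in zip(beta.sample_ids, miss.all(axis=0)) if m]
        raise DegenerateInputError(f"sample(s) with no observed probes: {bad}")
    if miss.all(axis=1).any():
        bad = [p for p, m in zip(beta.probe_ids, miss.all(axis=1)) if m]
        raise DegenerateInputError(f"probe(s) with no observed values: {bad}")

    n_probes = X.shape[0]
    filled = np.nan_to_num(X, nan=0.0)
    obs = (~miss).astype(float)
    # pairwise squared Euclidean distance restricted to co-observed samples:
    # sum over j of obs_i*obs_l*(x_i - x_l)^2, expanded into matrix products
    sq = filled**2
    cross = filled @ filled.T
    a = sq @ obs.T          # sum_j x_i^2 over samples where l observed too
    co_count = obs @ obs.T
    d2 = a + a.T - 2.0 * cross
    # pairs with no co-observed samples are incomparable
    d2[co_count == 0] = np.inf
    np.fill_diagonal(d2, np.inf)

    out = X.copy()
    for i, j in zip(*np.nonzero(miss)):
        candidates = np.nonzero(~miss[:, j])[0]
        dists = d2[i, candidates]
        usable = candidates[np.isfinite(dists)]
        if usable.size == 0:
            # fall back to the probe's own mean when nothing is comparable
            out[i, j] = np.nanmean(X[i, :])
            continue
        order = np.argsort(d2[i, usable], kind="stable")
        chosen = usable[order[: min(k, usable.size)]]
        out[i, j] = X[chosen, j].mean()
    return BetaMatrix(out, list(beta.probe_ids), list(beta.sample_ids))


def adjust_batches(beta: BetaMatrix, batch_labels) -> BetaMatrix:
    """Shift each batch's per-probe mean onto the probe grand mean.

    Requires a complete matrix (impute first) and a label for every sample;
    output is clipped to [0, 1].
    """
    labels = np.asarray(batch_labels)
    if labels.shape != (beta.n_samples,):
        raise ValueError("batch_labels must give one label per sample")
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab))
           for lab in labels.tolist()):
        raise ValueError("every sample must carry a batch label")
    if np.isnan(beta.values).any():
        raise ValueError("adjust_batches requires a complete matrix")

    X = beta.values.copy()
    grand = X.mean(axis=1, keepdims=True)
    for lab in np.unique(labels):
        cols = labels == lab
        X[:, cols] += grand - X[:, cols].mean(axis=1, keepdims=True)
    np.clip(X, 0.0, 1.0, out=X)
    return BetaMatrix(X, list(beta.probe_ids), list(beta.sample_ids))


__all__ = ["filter_probes", "knn_impute", "adjust_batches",
           "AnnotationError", "DegenerateInputError"]
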