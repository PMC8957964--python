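"""Characterization of predictor CpGs.

Covers the descriptive layer around a fitted predictor: where its probes sit
in the genome (chromosome, TSS-region group, CpG-island relation), which of
them are differentially methylated between paired tumor and tumor-adjacent
tissue (exact paired t-tests with Benjamini-Hochberg adjustment), and
correlation screens — Spearman throughout, with the |r| > 0.3 flag used for
"correlated with the score" claims and a negative-correlation flag for the
methylation-vs-expression screen.

The differential-methylation caller here is a plain paired t-test + BH, not
a moderated-statistics caller: it is exact, closed-form-checkable and
sufficient for per-probe paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, ProbeAnnotation
from .model import DMBMIModel

FLAG_THRESHOLD = 0.3
CATEGORY_AXES = ("chr", "region_group", "cgi_relation")


class PairingError(ValueError):
    """A sample pair is incomplete."""


class ConfigurationError(ValueError):
    """An operation was invoked without the inputs it needs."""


@dataclass
class DistributionSummary:
    """Category counts and proportions of predictor probes per axis."""

    tables: dict[str, pd.DataFrame]
    n_probes: int
    warning: str | None = None

    def __getitem__(self, axis: str) -> pd.DataFrame:
        return self.tables[axis]


def summarize_predictor_distribution(m: DMBMIModel, ann: ProbeAnnotation,
                                     ) -> DistributionSummary:
    """Count model probes per chromosome / region group / CGI relation.

    Categories observed in the annotation but absent from the model's probes
    are reported explicitly with zero counts; proportions sum to 1 per axis.
    """
    probes = m.support
    if not probes:
        empty = {axis: pd.DataFrame(columns=["category", "count", "proportion"])
                 for axis in CATEGORY_AXES}
        return DistributionSummary(empty, 0, warning="model has no probes")
    rows = ann.require(probes)
    tables = {}
    for axis in CATEGORY_AXES:
        levels = pd.unique(ann.table[axis].astype(str))
        counts = rows[axis].astype(str).value_counts()
        counts = counts.reindex(levels, fill_value=0)
        tables[axis] = pd.DataFrame({
            "category": counts.index,
            "count": counts.to_numpy(),
            "proportion": counts.to_numpy() / len(probes),
        }).reset_index(drop=True)
    return DistributionSummary(tables, len(probes))


@dataclass
class DMPResult:
    """One probe's paired differential-methylation call."""

    probe_id: str
    mean_diff: float
    t_stat: float
    p_value: float
    q_value: float
    direction: str  # hyper / hypo / ns


def paired_dmp_test(beta_tumor: BetaMatrix, beta_adjacent: BetaMatrix,
                    pairs: dict[str, str], alpha: float = 0.05,
                    ) -> list[DMPResult]:
    """Paired t-test per probe on tumor-minus-adjacent differences.

    ``pairs`` maps tumor sample id -> adjacent sample id. p-values are BH
    adjusted across all tested probes; a probe is called hyper/hypo by the
    sign of its mean difference when q < alpha (strict), else ``ns``.
    Probes with zero-variance differences get t = NaN and are never called.
    """
    if len(pairs) < 3:
        raise PairingError("need at least 3 complete pairs")
    tumor_ids = list(pairs)
    adj_ids = [pairs[t] for t in tumor_ids]
    missing_t = [s for s in tumor_ids if s not in set(beta_tumor.sample_ids)]
    missing_a = [s for s in adj_ids if s not in set(beta_adjacent.sample_ids)]
    if missing_t or missing_a:
        raise PairingError(
            f"unmatched samples; tumor: {missing_t[:5]}, adjacent: {missing_a[:5]}"
        )
    if beta_tumor.probe_ids != beta_adjacent.probe_ids:
        adj = beta_adjacent.subset_probes(beta_tumor.probe_ids)
    else:
        adj = beta_adjacent
    T = beta_tumor.subset_samples(tumor_ids).values
    A = adj.subset_samples(adj_ids).values
    if np.isnan(T).any() or np.isnan(A).any():
        raise ValueError("paired test requires complete matrices")

    diff = T - A
    mean_diff = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    n = diff.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p_for_bh = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p_for_bh, method="fdr_bh")

    out = []
    for i, probe in enumerate(beta_tumor.probe_ids):
        if np.isnan(t[i]) or q[i] >= alpha:
            direction = "ns"
        else:
            direction = "hyper" if mean_diff[i] > 0 else "hypo"
        out.append(DMPResult(probe, float(mean_diff[i]), float(t[i]),
                             float(p[i]), float(q[i]), direction))
    return out


@dataclass
class CorrelationRecord:
    """Spearman correlation of one feature with a per-sample score."""

    feature_id: str
    r: float
    p_value: float
    flagged: bool
    note: str = ""
    extra: dict = field(default_factory=dict)


def correlate_features_with_score(features, score, feature_ids=None,
                                  flag_threshold: float = FLAG_THRESHOLD,
                                  ) -> list[CorrelationRecord]:
    """Spearman screen of each feature row against a per-sample score.

    ``features`` is feature x sample (ndarray or DataFrame with feature
    index). A record is flagged iff |r| > flag_threshold (strict). Constant
    features yield r = NaN with an explanatory note instead of being dropped.
    """
    if isinstance(features, pd.DataFrame):
        feature_ids = list(features.index)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if feature_ids is None:
            feature_ids = [f"feature_{i}" for i in range(X.shape[0])]
    score = np.asarray(score, dtype=float)
    if X.shape[1] != score.size:
        raise ValueError("features and score must share the sample axis")
    if score.size < 3:
        raise ValueError("need at least 3 samples")

    out = []
    for fid, row in zip(feature_ids, X):
        if np.ptp(row) == 0 or np.ptp(score) == 0:
            out.append(CorrelationRecord(str(fid), float("nan"), float("nan"),
                                         False, note="constant input; r undefined"))
            continue
        r, p = stats.spearmanr(row, score)
        out.append(CorrelationRecord(str(fid), float(r), float(p),
                                     bool(abs(r) > flag_threshold)))
    return out


def correlate_methylation_expression(beta: BetaMatrix, expr: pd.DataFrame,
                                     mapping: dict[str, str],
                                     alpha: float = 0.05,
                                     ) -> tuple[list[CorrelationRecord], list[str]]:
    """Spearman r between each mapped probe's beta and its gene's expression.

    ``expr`` is gene x sample with columns matching ``beta.sample_ids``.
    Returns (records, skip_log); probes without a mapping or whose gene is
    absent from ``expr`` are skipped with a log entry. A record's ``flagged``
    is the negative-correlation call: r < 0 and p < alpha.
    """
    if not mapping:
        raise ConfigurationError("probe-to-gene mapping is empty")
    expr = expr.loc[:, beta.sample_ids]
    records, skipped = [], []
    for i, probe in enumerate(beta.probe_ids):
        gene = mapping.get(probe, "")
        if not gene:
            skipped.append(f"{probe}: no gene mapping")
            continue
        if gene not in expr.index:
            skipped.append(f"{probe}: gene {gene} absent from expression")
            continue
        b = beta.values[i, :]
        e = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(b) == 0 or np.ptp(e) == 0:
            records.append(CorrelationRecord(probe, float("nan"), float("nan"),
                                             False, note="constant input",
                                             extra={"gene": gene}))
            continue
        r, p = stats.spearmanr(b, e)
        records.append(CorrelationRecord(probe, float(r), float(p),
                                         bool(r < 0 and p < alpha),
                                         extra={"gene": gene}))
    return records, skipped


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"feature_id": rec.feature_id, "r": rec.r,
               "p_value": rec.p_value, "flagged": rec.flagged, "note": rec.note}
        row.update(rec.extra)
        rows.append(row)
    return pd.DataFrame(rows)
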