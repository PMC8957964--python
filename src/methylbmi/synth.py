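"""Synthetic methylation cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in breast tissue cohorts, so every downstream stage can be tested
against truth without external data:

* each sample's baseline methylome is a two-component mixture
  ``f * beta_adipose + (1 - f) * beta_epithelial`` of reference profiles,
  with the adipose fraction ``f`` coupled to BMI through a Gaussian copula;
* a sparse set of causal CpGs additionally shifts on the beta scale by
  ``effect_scale * F(BMI)`` (the trait transform), so a lasso fitted to
  F(BMI) has a recoverable support;
* additive per-batch, per-probe offsets (sd = ``batch_shift_sd``), Gaussian
  measurement noise, clipping to [0, 1], and missing values at a fixed rate;
* a 450K-style annotation with configurable category proportions, gene
  symbols for non-intergenic probes, an expression matrix in which
  promoter-probe genes decrease with their probe's methylation, and
  per-sample non-synonymous mutation counts.

BMI is drawn log-normally (right-skewed, like reported cohorts) and
truncated to ``bmi_range``. Causal probes are placed on autosomes without a
SNP flag so that the signal survives the QC chain — a predictor can only be
learned from probes that pass filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import BetaMatrix, ProbeAnnotation, ReferenceProfiles
from .transform import TraitTransform

# default annotation category proportions (450K-like, configurable)
CHR_LEVELS = [str(c) for c in range(1, 23)] + ["X", "Y"]
CHR_PROPS = np.array([0.05] * 22 + [0.027, 0.003])
CHR_PROPS = CHR_PROPS / CHR_PROPS.sum()
REGION_PROPS = {"TSS200": 0.10, "TSS1500": 0.14, "5'UTR": 0.10,
                "1stExon": 0.05, "Body": 0.45, "3'UTR": 0.04, "IGR": 0.12}
CGI_PROPS = {"island": 0.31, "shore": 0.23, "shelf": 0.10, "open_sea": 0.36}
SNP_FLAG_RATE = 0.05

PROMOTER_GROUPS = ("TSS200", "TSS1500")


class ParameterError(ValueError):
    """A generator parameter is outside its documented domain."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a training cohort of ~221 breast tissues measured on a
    450K-style array: right-skewed BMI around a median near 28 kg/m2, a
    sparse causal CpG set, moderate measurement noise on the beta scale,
    BMI-coupled adipose content, and mild additive batch structure.
    """

    n_samples: int = 221
    n_probes: int = 5000
    n_causal: int = 30
    effect_scale: float = 0.2      # beta-units per transformed-BMI-unit
    noise_sd: float = 0.02         # beta-units
    bmi_range: tuple[float, float] = (16.0, 54.0)
    adipose_coupling: float = 0.8  # copula correlation BMI <-> adipose fraction
    missing_rate: float = 0.02
    n_batches: int = 2
    batch_shift_sd: float = 0.01   # beta-units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_probes:
            raise ParameterError("n_causal must not exceed n_probes")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.bmi_range[0] <= 0 or self.bmi_range[1] <= self.bmi_range[0]:
            raise ParameterError("bmi_range must satisfy 0 < min < max")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must lie in [0, 1)")
        if not 0 <= self.adipose_coupling <= 1:
            raise ParameterError("adipose_coupling must lie in [0, 1]")
        if self.n_batches < 1:
            raise ParameterError("n_batches must be >= 1")


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth."""

    beta: BetaMatrix
    annotation: ProbeAnnotation
    true_bmi: np.ndarray
    true_adipose_fraction: np.ndarray
    causal_probes: list[str]
    batch_labels: np.ndarray
    expression: pd.DataFrame           # gene x sample
    mutation_counts: pd.Series         # per sample
    clinical: pd.DataFrame
    probe_gene_map: dict[str, str] = field(default_factory=dict)
    config: SynthConfig | None = None


def simulate_reference_profiles(n_probes: int, n_discriminating: int,
                                delta: float, seed: int = 0,
                                ) -> ReferenceProfiles:
    """Epithelial/adipose reference methylomes with a known contrast set.

    Exactly ``n_discriminating`` probes get |beta_adipose - beta_epithelial|
    >= ``delta``; the rest differ by small amounts (< delta, and < 0.3) as
    at non-marker CpGs of related tissues.
    """
    if not 0 < delta <= 1:
        raise ParameterError("delta must lie in (0, 1]")
    if n_discriminating > n_probes:
        raise ParameterError("n_discriminating must not exceed n_probes")
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    beta_e = np.empty(n_probes)
    beta_a = np.empty(n_probes)

    disc = rng.choice(n_probes, size=n_discriminating, replace=False)
    disc_mask = np.zeros(n_probes, dtype=bool)
    disc_mask[disc] = True

    # discriminating probes: gap in [delta, 1], placed so both betas fit
    gaps = rng.uniform(delta, 1.0, size=n_discriminating)
    lo = rng.uniform(0.0, 1.0 - gaps)
    sign = rng.integers(0, 2, size=n_discriminating).astype(bool)
    beta_e[disc] = np.where(sign, lo, lo + gaps)
    beta_a[disc] = np.where(sign, lo + gaps, lo)

    # non-marker probes: small tissue difference strictly below delta
    rest = ~disc_mask
    n_rest = int(rest.sum())
    base = rng.uniform(0.0, 1.0, size=n_rest)
    spread = min(0.9 * delta, 0.3)
    lo_r = np.maximum(0.0, base - spread)
    hi_r = np.minimum(1.0, base + spread)
    beta_e[rest] = base
    beta_a[rest] = rng.uniform(lo_r, hi_r)
    return ReferenceProfiles(probe_ids, beta_e, beta_a)


def _sample_annotation(probe_ids, causal_idx, rng) -> ProbeAnnotation:
    n = len(probe_ids)
    chrom = rng.choice(CHR_LEVELS, size=n, p=CHR_PROPS)
    region = rng.choice(list(REGION_PROPS), size=n, p=list(REGION_PROPS.values()))
    cgi = rng.choice(list(CGI_PROPS), size=n, p=list(CGI_PROPS.values()))
    snp = rng.random(n) < SNP_FLAG_RATE
    # causal probes must survive QC: autosomal, no SNP flag
    autosomes = [str(c) for c in range(1, 23)]
    chrom[causal_idx] = rng.choice(autosomes, size=len(causal_idx))
    snp[causal_idx] = False
    pos = rng.integers(1, 2_000_000_00, size=n)
    genes = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    genes[region == "IGR"] = ""
    table = pd.DataFrame({
        "probe_id": probe_ids, "chr": chrom, "pos": pos, "gene": genes,
        "region_group": region, "cgi_relation": cgi, "snp_flag": snp,
    })
    return ProbeAnnotation(table)


def _draw_bmi_and_fraction(cfg: SynthConfig, rng):
    """Truncated log-normal BMI and copula-coupled adipose fraction."""
    lo, hi = cfg.bmi_range
    mu = 0.5 * (np.log(lo) + np.log(hi))   # geometric midpoint as median
    sigma = 0.22
    z_b = np.empty(cfg.n_samples)
    filled = 0
    while filled < cfg.n_samples:
        draw = rng.standard_normal(cfg.n_samples)
        bmi_try = np.exp(mu + sigma * draw)
        ok = draw[(bmi_try >= lo) & (bmi_try <= hi)]
        take = min(len(ok), cfg.n_samples - filled)
        z_b[filled:filled + take] = ok[:take]
        filled += take
    bmi = np.exp(mu + sigma * z_b)
    rho = cfg.adipose_coupling
    z_f = rho * z_b + np.sqrt(1.0 - rho**2) * rng.standard_normal(cfg.n_samples)
    # breast adipose content: map copula normal into a 10-80% band
    frac = 0.10 + 0.70 * norm.cdf(z_f)
    return bmi, frac


def simulate_cohort(config: SynthConfig, refs: ReferenceProfiles,
                    ) -> SyntheticCohort:
    """Generate one cohort under ``config`` on the probes of ``refs``."""
    if len(refs) != config.n_probes:
        raise ValueError(
            f"reference profiles cover {len(refs)} probes, "
            f"config requests {config.n_probes}"
        )
    rng = np.random.default_rng(config.seed)
    probe_ids = list(refs.probe_ids)
    sample_ids = [f"S{j:04d}" for j in range(config.n_samples)]

    bmi, frac = _draw_bmi_and_fraction(config, rng)
    t = TraitTransform()
    f_bmi = np.asarray(t.forward(bmi))

    causal_idx = np.sort(rng.choice(config.n_probes, size=config.n_causal,
                                    replace=False))
    causal_probes = [probe_ids[i] for i in causal_idx]
    ann = _sample_annotation(probe_ids, causal_idx, rng)

    # mixture baseline, then causal shift, batch shift, noise; clip once
    X = (refs.beta_adipose[:, None] * frac[None, :]
         + refs.beta_epithelial[:, None] * (1.0 - frac[None, :]))
    X[causal_idx, :] += config.effect_scale * f_bmi[None, :]

    batch_labels = np.array([f"batch{j % config.n_batches}"
                             for j in range(config.n_samples)])
    rng.shuffle(batch_labels)
    if config.batch_shift_sd > 0:
        for b in np.unique(batch_labels):
            shift = rng.normal(0.0, config.batch_shift_sd,
                               size=config.n_probes)
            X[:, batch_labels == b] += shift[:, None]
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)
    np.clip(X, 0.0, 1.0, out=X)

    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X[mask] = np.nan
    beta = BetaMatrix(X, probe_ids, sample_ids)

    # expression: promoter-probe genes decrease with their probe's beta
    mapping = {p: g for p, g in zip(ann.table["probe_id"], ann.table["gene"])
               if g}
    region_by_probe = dict(zip(ann.table["probe_id"], ann.table["region_group"]))
    beta_complete = np.where(np.isnan(X), np.nanmean(X, axis=1, keepdims=True), X)
    expr_rows, gene_ids = [], []
    for i, p in enumerate(probe_ids):
        g = mapping.get(p)
        if not g:
            continue
        base = rng.normal(8.0, 1.0)
        if region_by_probe[p] in PROMOTER_GROUPS:
            row = base - 2.0 * beta_complete[i, :] \
                + rng.normal(0.0, 0.5, size=config.n_samples)
        else:
            row = base + rng.normal(0.0, 1.0, size=config.n_samples)
        expr_rows.append(row)
        gene_ids.append(g)
    # immune/APM signature genes so the scoring stage is exercisable;
    # expressed independently of methylation
    from .scores import APM_GENES, IFNG_GENES
    for g in (*IFNG_GENES, *APM_GENES):
        expr_rows.append(rng.normal(8.0, 1.0)
                         + rng.normal(0.0, 1.0, size=config.n_samples))
        gene_ids.append(g)
    expression = pd.DataFrame(np.vstack(expr_rows), index=gene_ids,
                              columns=sample_ids)

    mutation_counts = pd.Series(rng.poisson(45, size=config.n_samples),
                                index=sample_ids, name="n_nonsynonymous")
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "bmi": bmi,
        "batch": batch_labels,
        "menopause": rng.choice(["pre", "post"], size=config.n_samples),
        "age": rng.integers(25, 80, size=config.n_samples),
    })
    return SyntheticCohort(beta=beta, annotation=ann, true_bmi=bmi,
                           true_adipose_fraction=frac,
                           causal_probes=causal_probes,
                           batch_labels=batch_labels, expression=expression,
                           mutation_counts=mutation_counts, clinical=clinical,
                           probe_gene_map=mapping, config=config)


def write_cohort(cohort: SyntheticCohort, refs: ReferenceProfiles,
                 outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the pipeline's TSV/JSON interchange files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, frame, **kw):
        path = outdir / name
        frame.to_csv(path, sep="\t", **kw)
        paths[name] = path

    _w("beta.tsv", cohort.beta.to_frame(), index_label="probe_id")
    _w("annotation.tsv", cohort.annotation.table, index=False)
    _w("clinical.tsv", cohort.clinical, index=False)
    _w("expression.tsv", cohort.expression, index_label="gene")
    _w("mutations.tsv",
       cohort.mutation_counts.rename_axis("sample_id").reset_index(),
       index=False)
    _w("references.tsv", pd.DataFrame({
        "probe_id": refs.probe_ids,
        "beta_epithelial": refs.beta_epithelial,
        "beta_adipose": refs.beta_adipose,
    }), index=False)

    truth = {
        "causal_probes": cohort.causal_probes,
        "true_bmi": dict(zip(cohort.beta.sample_ids,
                             map(float, cohort.true_bmi))),
        "true_adipose_fraction": dict(zip(cohort.beta.sample_ids,
                                          map(float, cohort.true_adipose_fraction))),
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["truth.json"] = truth_path
    return paths
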