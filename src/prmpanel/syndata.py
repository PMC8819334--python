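"""Synthetic proteomes and PRM serum cohorts with known ground truth.

The generator emulates the statistical structure of a targeted-proteomics
case/control study of intracranial aneurysm: three groups (NC healthy
controls, UR unruptured, R ruptured), peptide peak areas acquired in
batches with batch-level intensity offsets, pooled quality-control (QC)
runs per batch, and spiked heavy-isotope (SIL) reference peptides.

Generative model (log10 scale; areas are 10**x):

    x_ij = mu_j + beta_j * g(i) + b_batch(i) + s_i + eps_ij

where ``mu_j`` is the feature baseline, ``beta_j = d * residual_sd`` for
features planted in a contrast's case group (0 otherwise), ``b`` a
batch-level offset ~ N(0, batch_sd^2), ``s_i`` an optional per-sample
loading/drift term (default off), and ``eps ~ N(0, residual_sd^2)``.
Effects are additive in log10, i.e. multiplicative on areas.  Heavy-channel
reference areas share the instrument terms (batch, drift, noise) but carry
no group effect: standards are spiked after digestion, so they see the
instrument, not the biology.  QC runs are simulated pooled aliquots: their
expectation per feature is the mean of the group means.

Default cohort sizes mirror the study design the pipeline targets:
cohort I with NC=100, UR=57, R=55 (n=212) quantifying 113 peptides from
100 proteins with 18 SIL references, and an external cohort II with
NC=20, UR=6, R=6 (n=32).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .prm_quant import PeakAreaMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Rough serum-proteome residue frequencies; only used to make synthetic
# sequences look peptide-like, not to model any particular proteome.
AA_WEIGHTS = np.array(
    [8.0, 2.0, 5.5, 6.5, 4.0, 7.0, 2.5, 5.5, 6.0, 9.5,
     2.2, 4.2, 5.0, 4.0, 5.5, 7.0, 5.5, 6.5, 1.2, 3.0]
)
AA_WEIGHTS = AA_WEIGHTS / AA_WEIGHTS.sum()


@dataclass
class SynConfig:
    """Configuration of a synthetic PRM cohort.

    ``planted_ia`` / ``planted_rupture`` map feature ids to standardized
    effect sizes d (mean shift in units of residual_sd, log10 scale) for
    the IA-vs-NC and R-vs-UR contrasts respectively.
    """

    n_features: int = 113
    n_proteins: int = 100  # quantified proteins the features map onto
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 100, "UR": 57, "R": 55}
    )
    n_batches: int = 4
    planted_ia: dict[str, float] = field(default_factory=dict)
    planted_rupture: dict[str, float] = field(default_factory=dict)
    batch_sd: float = 0.2
    residual_sd: float = 0.2
    sample_drift_sd: float = 0.0
    qc_per_batch: int = 3
    n_heavy_refs: int = 18
    mu_mean: float = 5.5
    mu_sd: float = 0.8
    heavy_mu: float = 5.0
    dropout_rate: float = 0.0  # optional MCAR missingness on light areas
    seed: int = 0
    # Seed for the biological layer (feature baselines); two cohorts drawn
    # with the same biology_seed but different seeds measure the same
    # peptide panel under fresh sampling and instrument conditions.
    biology_seed: int | None = None

    def feature_ids(self) -> list[str]:
        return [f"F{j + 1:03d}" for j in range(self.n_features)]

    def reference_ids(self) -> list[str]:
        return self.feature_ids()[: self.n_heavy_refs]

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.batch_sd < 0 or self.sample_drift_sd < 0:
            raise ValueError("spread parameters must be nonnegative")
        if self.n_heavy_refs > self.n_features:
            raise ValueError("n_heavy_refs cannot exceed n_features")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        ids = set(self.feature_ids())
        for name, planted in (("planted_ia", self.planted_ia),
                              ("planted_rupture", self.planted_rupture)):
            for fid, d in planted.items():
                if fid not in ids:
                    raise ValueError(f"{name}: unknown feature id {fid}")
                if not np.isfinite(d):
                    raise ValueError(f"{name}: non-finite effect for {fid}")


def default_config(seed: int = 0) -> SynConfig:
    """Study-condition defaults: cohort-I sizes, six IA markers and eight
    rupture markers planted at d = 1.5, none among the SIL references."""
    cfg = SynConfig(seed=seed)
    feats = cfg.feature_ids()
    cfg.planted_ia = {fid: 1.5 for fid in feats[20:26]}
    cfg.planted_rupture = {fid: 1.5 for fid in feats[30:38]}
    return cfg


@dataclass
class GroundTruth:
    """What was planted: effects, baselines and batch offsets."""

    planted_ia: dict[str, float]
    planted_rupture: dict[str, float]
    feature_mu: dict[str, float]
    batch_offsets: dict[str, float]
    residual_sd: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_ia": self.planted_ia,
                    "planted_rupture": self.planted_rupture,
                    "feature_mu": self.feature_mu,
                    "batch_offsets": self.batch_offsets,
                    "residual_sd": self.residual_sd,
                },
                fh, indent=2, sort_keys=True,
            )


def _spawn(seed: int, stream: int) -> np.random.Generator:
    """Named sub-stream so each generator section is independently
    reproducible under the one master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_proteome(n_proteins: int, seed: int = 0) -> dict[str, str]:
    """Random protein sequences with tryptic sites every ~5–14 residues.

    Sequences are built from K/R-terminated segments so in-silico digestion
    yields peptides in the typical tryptic length range.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = _spawn(seed, 0)
    proteome: dict[str, str] = {}
    for i in range(n_proteins):
        target = int(rng.integers(120, 360))
        parts: list[str] = []
        length = 0
        while length < target:
            seg_len = int(rng.integers(5, 14))
            seg = "".join(rng.choice(list(AMINO_ACIDS), size=seg_len, p=AA_WEIGHTS))
            term = "K" if rng.random() < 0.5 else "R"
            parts.append(seg + term)
            length += seg_len + 1
        proteome[f"SYN{i + 1:04d}"] = "".join(parts)
    return proteome


def write_fasta(proteome: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=acc, description="synthetic protein")
        for acc, seq in proteome.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


def generate_cohort(cfg: SynConfig) -> tuple[PeakAreaMatrix, pd.DataFrame, GroundTruth]:
    """Simulate one PRM cohort under the additive log10 model.

    Returns linear-scale areas (a :class:`~prmpanel.prm_quant.PeakAreaMatrix`
    with light and heavy channels), the sample metadata table, and the
    ground truth.  Deterministic and bit-identical under a fixed config.
    """
    cfg.validate()
    features = cfg.feature_ids()
    refs = cfg.reference_ids()

    bio_seed = cfg.seed if cfg.biology_seed is None else cfg.biology_seed
    rng_mu = _spawn(bio_seed, 1)
    rng_batch = _spawn(cfg.seed, 2)
    rng_noise = _spawn(cfg.seed, 3)
    rng_drop = _spawn(cfg.seed, 4)

    mu = cfg.mu_mean + cfg.mu_sd * rng_mu.standard_normal(cfg.n_features)
    batch_ids = [f"B{b + 1}" for b in range(cfg.n_batches)]
    batch_offset = dict(zip(batch_ids, cfg.batch_sd * rng_batch.standard_normal(cfg.n_batches)))

    # Feature -> protein map: first proteins carry two peptides so that
    # n_features peptides cover n_proteins proteins (113 -> 100 by default).
    n_twin = max(cfg.n_features - cfg.n_proteins, 0)
    protein_of: dict[str, str] = {}
    for j, fid in enumerate(features):
        if j < 2 * n_twin:
            protein_of[fid] = f"PROT{j // 2 + 1:03d}"
        else:
            protein_of[fid] = f"PROT{j - n_twin + 1:03d}"

    # Sample roster: study samples round-robin over batches within group,
    # then qc_per_batch pooled-QC runs per batch.
    rows = []
    counter = 0
    for group in sorted(cfg.group_sizes):
        for k in range(cfg.group_sizes[group]):
            counter += 1
            rows.append((f"S{counter:03d}", group, batch_ids[(counter - 1) % cfg.n_batches], False))
    for b in batch_ids:
        for q in range(cfg.qc_per_batch):
            rows.append((f"QC_{b}_{q + 1}", "QC", b, True))
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "batch", "is_qc"]).set_index("sample_id")

    n_samples = len(meta)
    beta_ia = np.array([cfg.planted_ia.get(f, 0.0) for f in features]) * cfg.residual_sd
    beta_r = np.array([cfg.planted_rupture.get(f, 0.0) for f in features]) * cfg.residual_sd
    # Group means per feature: NC baseline; UR gets the IA effect; R both.
    group_shift = {
        "NC": np.zeros(cfg.n_features),
        "UR": beta_ia,
        "R": beta_ia + beta_r,
    }
    sizes = cfg.group_sizes
    n_study = sum(sizes.values())
    pooled = sum(sizes[g] * group_shift[g] for g in sizes) / max(n_study, 1)

    drift = cfg.sample_drift_sd * rng_noise.standard_normal(n_samples)
    light = np.empty((cfg.n_features, n_samples))
    heavy = np.empty((len(refs), n_samples))
    mu_heavy = cfg.heavy_mu + 0.3 * rng_mu.standard_normal(len(refs))
    for i, (sid, row) in enumerate(meta.iterrows()):
        shift = pooled if row["is_qc"] else group_shift[row["group"]]
        b = batch_offset[row["batch"]]
        light[:, i] = (
            mu + shift + b + drift[i]
            + cfg.residual_sd * rng_noise.standard_normal(cfg.n_features)
        )
        heavy[:, i] = (
            mu_heavy + b + drift[i]
            + cfg.residual_sd * rng_noise.standard_normal(len(refs))
        )

    light_lin = np.power(10.0, light)
    heavy_lin = np.power(10.0, heavy)
    if cfg.dropout_rate > 0:
        mask = rng_drop.random(light_lin.shape) < cfg.dropout_rate
        light_lin[mask] = np.nan

    feature_meta = pd.DataFrame(
        {"protein": [protein_of[f] for f in features],
         "is_reference": [f in set(refs) for f in features]},
        index=pd.Index(features, name="feature_id"),
    )
    matrix = PeakAreaMatrix(
        light=pd.DataFrame(light_lin, index=feature_meta.index, columns=meta.index),
        heavy=pd.DataFrame(heavy_lin, index=pd.Index(refs, name="feature_id"), columns=meta.index),
        sample_meta=meta,
        feature_meta=feature_meta,
        scale="linear",
    )
    matrix.check()

    truth = GroundTruth(
        planted_ia=dict(cfg.planted_ia),
        planted_rupture=dict(cfg.planted_rupture),
        feature_mu=dict(zip(features, mu.tolist())),
        batch_offsets={b: float(v) for b, v in batch_offset.items()},
        residual_sd=cfg.residual_sd,
    )
    return matrix, meta.reset_index(), truth


def generate_spectral_library(sequence: str, seed: int = 0):
    """Deterministic pseudo spectral-library entry for a peptide.

    Intensities are exponential draws seeded from the sequence itself, so
    the same peptide always receives the same library regardless of call
    order.  Stands in for a DDA-derived library; carries no real
    fragmentation propensities.
    """
    from .assay_design import LibraryFragment

    key = np.frombuffer(sequence.encode(), dtype=np.uint8)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(int(key.sum()), len(sequence))))
    frags = []
    for series in ("b", "y"):
        for ordinal in range(1, len(sequence)):
            frags.append(LibraryFragment(series, ordinal, float(rng.exponential(100.0))))
    return frags
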