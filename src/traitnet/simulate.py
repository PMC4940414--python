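"""Synthetic replicated trait panels with planted ground truth.

The generator emulates a replicated inbred trait panel: each line carries a
latent genetic value per feature, drawn from a multivariate normal whose
correlation matrix contains planted blocks (the ground-truth communities);
replicates add independent residual noise scaled so that the intraclass
correlation sigma2_g / (sigma2_g + sigma2_e) hits each feature's target
broad-sense heritability. Metabolite observations are multiplied by a
simulated per-chromatogram internal-standard intensity (so downstream
normalization must divide it back out); enzyme observations receive additive
assay-plate offsets (so plate standardization is consequential). Missing
entries are inserted completely at random.

Defaults mirror the study design the pipeline targets: 101 lines, 5
replicates, 43 metabolites + 13 enzymes, 5.7% missing cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ENZYME,
    METABOLITE,
    ReplicateProfileTable,
    annotation_frame,
)

_COMPOUND_CLASSES = [
    "amino acid",
    "organic acid",
    "sugar",
    "sugar alcohol",
    "phosphorylated intermediate",
    "N-compound",
    "specialized metabolite",
]


@dataclass
class CorrelationBlock:
    """A planted community: a set of features sharing latent correlation rho."""

    block_id: str
    members: list[str]
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"block {self.block_id}: rho must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic replicated trait panel.

    ``h2`` may be a scalar (applied to every feature), a sequence aligned
    with ``feature_ids`` order (metabolites first), or a mapping
    feature_id -> target heritability. ``phenotypic_variance`` is the total
    per-observation variance sigma2_g + sigma2_e on the trait scale;
    ``feature_mean`` is the baseline trait level (keeps CVs finite and
    positive). The internal-standard channel is lognormal with mean
    ``control_mean`` and coefficient of variation ``control_cv``.
    """

    n_lines: int = 101
    n_replicates: int = 5
    n_metabolites: int = 43
    n_enzymes: int = 13
    blocks: list[CorrelationBlock] = field(default_factory=list)
    h2: float | Sequence[float] | Mapping[str, float] = 0.4
    missing_rate: float = 0.057
    n_plates: int = 4
    control_mean: float = 1000.0
    control_cv: float = 0.2
    feature_mean: float = 10.0
    phenotypic_variance: float = 1.0
    plate_sd: float = 0.5
    seed: int = 0

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"met_{i + 1:02d}" for i in range(self.n_metabolites)]

    @property
    def enzyme_ids(self) -> list[str]:
        return [f"enz_{i + 1:02d}" for i in range(self.n_enzymes)]

    @property
    def feature_ids(self) -> list[str]:
        return self.metabolite_ids + self.enzyme_ids

    def h2_targets(self) -> dict[str, float]:
        feats = self.feature_ids
        if isinstance(self.h2, Mapping):
            targets = dict(self.h2)
            missing = set(feats) - set(targets)
            if missing:
                raise ValueError(f"h2 mapping lacks features: {sorted(missing)}")
        elif np.isscalar(self.h2):
            targets = {f: float(self.h2) for f in feats}
        else:
            vals = list(self.h2)
            if len(vals) != len(feats):
                raise ValueError(
                    f"h2 sequence has {len(vals)} entries for {len(feats)} features"
                )
            targets = dict(zip(feats, map(float, vals)))
        for f, h in targets.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"target H2 for {f} outside [0, 1]: {h}")
        return targets

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_plates < 1:
            raise ValueError("need at least 1 plate")
        feats = set(self.feature_ids)
        seen: set[str] = set()
        for b in self.blocks:
            members = set(b.members)
            if not members <= feats:
                raise ValueError(
                    f"block {b.block_id} references unknown features: "
                    f"{sorted(members - feats)}"
                )
            if members & seen:
                raise ValueError(
                    f"block {b.block_id} overlaps another block: "
                    f"{sorted(members & seen)}"
                )
            seen |= members
        self.h2_targets()


@dataclass
class PlantedTruth:
    """Ground truth behind a generated panel, for parameter-recovery tests."""

    sigma2_g: dict[str, float]
    sigma2_e: dict[str, float]
    latent_correlation: pd.DataFrame
    block_membership: dict[str, str | None]
    genetic_values: pd.DataFrame
    plate_offsets: dict[str, float]

    def h2_true(self) -> dict[str, float]:
        out = {}
        for f, sg in self.sigma2_g.items():
            se = self.sigma2_e[f]
            total = sg + se
            out[f] = sg / total if total > 0 else float("nan")
        return out


def latent_correlation_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Block-diagonal planted correlation among line-level latent values."""
    feats = config.feature_ids
    corr = pd.DataFrame(np.eye(len(feats)), index=feats, columns=feats)
    for b in config.blocks:
        for i in b.members:
            for j in b.members:
                if i != j:
                    corr.loc[i, j] = b.rho
    return corr


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Return L with L @ L.T = corr; reject non-PSD specifications."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8:
        raise ValueError(
            "planted correlation matrix is not positive semi-definite "
            f"(minimum eigenvalue {vals.min():.3g}); lower the block rho or "
            "shrink the blocks"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_panel(
    config: SimulationConfig,
) -> tuple[ReplicateProfileTable, PlantedTruth]:
    """Simulate a replicated trait panel with planted correlation blocks.

    Returns the raw long-format table (as the pipeline would ingest it) and
    the planted truth. Identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    feats = config.feature_ids
    n_feat = len(feats)
    h2 = config.h2_targets()

    corr = latent_correlation_matrix(config)
    factor = _psd_factor(corr.to_numpy())

    sigma2_g = {f: h2[f] * config.phenotypic_variance for f in feats}
    sigma2_e = {f: (1.0 - h2[f]) * config.phenotypic_variance for f in feats}
    sd_g = np.array([np.sqrt(sigma2_g[f]) for f in feats])
    sd_e = np.array([np.sqrt(sigma2_e[f]) for f in feats])

    # line-level latent genetic values with the planted correlation
    z = rng.standard_normal((config.n_lines, n_feat))
    genetic = (z @ factor.T) * sd_g
    lines = [f"line_{i + 1:03d}" for i in range(config.n_lines)]
    genetic_df = pd.DataFrame(genetic, index=lines, columns=feats)

    n_samples = config.n_lines * config.n_replicates
    residual = rng.standard_normal((n_samples, n_feat)) * sd_e

    # per-chromatogram internal standard: lognormal around control_mean
    s2 = np.log1p(config.control_cv**2)
    mu = np.log(config.control_mean) - s2 / 2.0
    controls = rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n_samples)

    plate_ids = [f"plate_{i + 1}" for i in range(config.n_plates)]
    plate_offsets = dict(
        zip(plate_ids, rng.normal(0.0, config.plate_sd, config.n_plates))
    )
    missing_mask = rng.random((n_samples, n_feat)) < config.missing_rate

    met_set = set(config.metabolite_ids)
    records = []
    sample = 0
    for li, line in enumerate(lines):
        for r in range(config.n_replicates):
            rep = f"rep_{r + 1}"
            plate = plate_ids[sample % config.n_plates]
            ctl = controls[sample]
            for fi, f in enumerate(feats):
                true_val = config.feature_mean + genetic[li, fi] + residual[sample, fi]
                if f in met_set:
                    obs, plate_id, control = true_val * ctl, None, ctl
                else:
                    obs = true_val + plate_offsets[plate]
                    plate_id, control = plate, None
                if missing_mask[sample, fi]:
                    obs = np.nan
                records.append(
                    (line, rep, plate_id, f, obs, control)
                )
            sample += 1

    data = pd.DataFrame.from_records(
        records,
        columns=[
            "line_id",
            "replicate_id",
            "plate_id",
            "feature_id",
            "value",
            "control_value",
        ],
    )
    classes = {
        f: _COMPOUND_CLASSES[i % len(_COMPOUND_CLASSES)]
        for i, f in enumerate(config.metabolite_ids)
    }
    annotations = annotation_frame(config.metabolite_ids, config.enzyme_ids, classes)
    table = ReplicateProfileTable(data, annotations)

    block_of: dict[str, str | None] = {f: None for f in feats}
    for b in config.blocks:
        for f in b.members:
            block_of[f] = b.block_id

    truth = PlantedTruth(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        latent_correlation=corr,
        block_membership=block_of,
        genetic_values=genetic_df,
        plate_offsets=plate_offsets,
    )
    return table, truth


def truth_report(truth: PlantedTruth) -> dict:
    """Serializable summary of all planted parameters."""
    blocks: dict[str, list[str]] = {}
    for f, b in truth.block_membership.items():
        if b is not None:
            blocks.setdefault(b, []).append(f)
    return {
        "n_features": len(truth.sigma2_g),
        "sigma2_g": dict(truth.sigma2_g),
        "sigma2_e": dict(truth.sigma2_e),
        "h2_true": truth.h2_true(),
        "blocks": {b: sorted(m) for b, m in sorted(blocks.items())},
        "n_blocks": len(blocks),
        "plate_offsets": dict(truth.plate_offsets),
        "latent_correlation": {
            "features": list(truth.latent_correlation.columns),
            "matrix": truth.latent_correlation.to_numpy().tolist(),
        },
    }


def truth_to_json(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_report(truth), fh, indent=1)


def study_scale_config(seed: int = 0) -> SimulationConfig:
    """Panel emulating the target study's scale and structure.

    101 lines x 5 replicates, 43 metabolites + 13 enzymes, 5.7% missing
    cells. Heritabilities are drawn once (deterministically from the seed)
    from a Beta(1.4, 2.6) — positively skewed, most features below 0.5,
    as observed for leaf metabolites and enzymes in inbred panels. Three
    correlation blocks play the role of the co-regulated communities:
    a mixed enzyme/metabolite block, an amino-acid-like block, and an
    organic-acid/sugar-like block.
    """
    cfg = SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed + 202_301)
    h2 = rng.beta(1.4, 2.6, size=len(cfg.feature_ids))
    mets, enzs = cfg.metabolite_ids, cfg.enzyme_ids
    blocks = [
        CorrelationBlock("community_1", mets[:6] + enzs[:8], 0.60),
        CorrelationBlock("community_2", mets[6:20], 0.55),
        CorrelationBlock("community_3", mets[20:32], 0.50),
    ]
    cfg.blocks = blocks
    cfg.h2 = {f: float(max(h, 0.15)) for f, h in zip(cfg.feature_ids, h2)}
    return cfg


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if isinstance(config.h2, Mapping):
        d["h2"] = dict(config.h2)
    elif not np.isscalar(config.h2):
        d["h2"] = list(map(float, config.h2))
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    blocks = [
        b if isinstance(b, CorrelationBlock) else CorrelationBlock(**b)
        for b in d.pop("blocks", [])
    ]
    return SimulationConfig(blocks=blocks, **d)
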