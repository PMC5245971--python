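"""End-to-end seeded experiments.

Each experiment re-creates the full simulation protocol: per replication
("network"), one 8-layer random tanh stack is initialized and one
prototype/distortion stimulus set is generated; every model encoder is
some portion of that shared stack.  Replications use independent,
deterministically derived sub-seeds, so whole runs are reproducible
bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding import encode_hash, init_network, model_table
from .similarity import (
    SmoothnessResult,
    pearson_similarity,
    smoothness_from_similarities,
)
from .stimuli import DegenerateInputError, generate_distortions, generate_prototype

__all__ = [
    "ExperimentConfig",
    "DistortionCurve",
    "SmoothnessByDepth",
    "run_distortion_experiment",
    "run_smoothness_by_depth",
    "run_factorial_proof",
    "run_hash_demo",
    "write_report",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol parameters; the defaults are the study conditions.

    100-dimensional stimuli, 19 distortion levels in noise-sd steps of
    0.05, 100 independently seeded networks, tanh stacks up to depth 8.
    ``aggregation`` selects the headline smoothness statistic: ``pooled``
    correlates the input/output similarity lists of all prototype-
    distortion pairs across networks at once; ``per_network_mean``
    computes one statistic per network and averages.
    """

    dim: int = 100
    n_distortions: int = 19
    sd_step: float = 0.05
    n_networks: int = 100
    max_depth: int = 8
    seed: int = 0
    n_prototypes: int = 1
    aggregation: str = "pooled"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.aggregation not in ("pooled", "per_network_mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=seed)


def _network_rngs(config: ExperimentConfig, net_index: int):
    """Deterministic per-network RNG pair (weights, stimuli) from the root seed."""
    w = np.random.default_rng(np.random.SeedSequence([config.seed, net_index, 0]))
    s = np.random.default_rng(np.random.SeedSequence([config.seed, net_index, 1]))
    return w, s


def _network_stimuli(config: ExperimentConfig, rng_s) -> list:
    sets = []
    for _ in range(config.n_prototypes):
        proto = generate_prototype(config.dim, rng_s)
        sets.append(
            generate_distortions(proto, config.n_distortions, config.sd_step, rng_s)
        )
    return sets


@dataclass(frozen=True)
class DistortionCurve:
    """Mean encoded similarity to the prototype per distortion level."""

    model_id: int
    model_name: str
    noise_sds: np.ndarray = field(repr=False)
    mean_similarity: np.ndarray = field(repr=False)
    dispersion: np.ndarray = field(repr=False)
    n_networks: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_id": self.model_id,
                "model_name": self.model_name,
                "level": np.arange(1, self.noise_sds.size + 1),
                "noise_sd": self.noise_sds,
                "mean_similarity": self.mean_similarity,
                "sd_across_networks": self.dispersion,
            }
        )


def run_distortion_experiment(config: ExperimentConfig | None = None) -> list[DistortionCurve]:
    """Similarity-to-prototype curves for all eleven models.

    For every network and level, the Pearson similarity between the
    encoded prototype and the encoded distortion is recorded; curves
    report the mean and s.d. across networks.  Degenerate (constant)
    representations are dropped pairwise and counted, never imputed.
    """
    config = config or ExperimentConfig()
    n_models = 4 + (config.max_depth - 1)
    sims = np.full((n_models, config.n_networks, config.n_distortions), np.nan)
    names: list[str] = []
    for net in range(config.n_networks):
        rng_w, rng_s = _network_rngs(config, net)
        stack = init_network(config.dim, config.max_depth, rng_w)
        models = model_table(stack)
        if net == 0:
            names = [name for _, name, _ in models]
        for sset in _network_stimuli(config, rng_s):
            proto = sset.prototype.values
            for m, (_, _, spec) in enumerate(models):
                enc = spec
                try:
                    ep = enc(proto)
                    for lvl, d in enumerate(sset.distortions):
                        sims[m, net, lvl] = pearson_similarity(ep, enc(d))
                except DegenerateInputError:
                    continue
    noise_sds = config.sd_step * np.arange(1, config.n_distortions + 1)
    curves = []
    for m in range(n_models):
        curves.append(
            DistortionCurve(
                model_id=m + 1,
                model_name=names[m],
                noise_sds=noise_sds,
                mean_similarity=np.nanmean(sims[m], axis=0),
                dispersion=np.nanstd(sims[m], axis=0),
                n_networks=config.n_networks,
            )
        )
    return curves


@dataclass(frozen=True)
class SmoothnessByDepth:
    """Functional smoothness at one network depth.

    ``statistic`` is the headline value under the configured aggregation;
    both aggregations are always stored, along with the per-network raw
    statistics they are recomputable from.
    """

    depth: int
    statistic: float
    aggregation: str
    pooled_statistic: float
    per_network_mean: float
    sd_across_networks: float
    per_network_statistics: np.ndarray = field(repr=False)
    n_excluded_pairs: int = 0


def run_smoothness_by_depth(config: ExperimentConfig | None = None) -> list[SmoothnessByDepth]:
    """The smoothness-by-depth experiment over tanh stacks of depth 1..max_depth.

    Per network, the input similarities are the 19 prototype-distortion
    Pearson similarities and the output similarities are computed on the
    layer-k representations of the shared stack; the statistic is the
    Pearson correlation between the two lists, aggregated per
    ``config.aggregation``.
    """
    config = config or ExperimentConfig()
    depths = range(1, config.max_depth + 1)
    per_net = {d: [] for d in depths}
    pooled_pairs = {d: [] for d in depths}
    excluded = {d: 0 for d in depths}
    for net in range(config.n_networks):
        rng_w, rng_s = _network_rngs(config, net)
        stack = init_network(config.dim, config.max_depth, rng_w)
        net_out = {d: [] for d in depths}
        for sset in _network_stimuli(config, rng_s):
            proto = sset.prototype.values
            reps = {0: [proto] + list(sset.distortions)}
            for d in depths:
                layer = stack.weights[d - 1]
                reps[d] = [np.tanh(r @ layer.matrix.T) for r in reps[d - 1]]
            in_sims = [pearson_similarity(proto, x) for x in sset.distortions]
            for d in depths:
                ep = reps[d][0]
                for s_in, r in zip(in_sims, reps[d][1:]):
                    try:
                        s_out = pearson_similarity(ep, r)
                    except DegenerateInputError:
                        excluded[d] += 1
                        continue
                    net_out[d].append((s_in, s_out))
        for d in depths:
            pairs = net_out[d]
            pooled_pairs[d].extend(pairs)
            if len(pairs) >= 3:
                per_net[d].append(
                    pearson_similarity([a for a, _ in pairs], [b for _, b in pairs])
                )
    results = []
    for d in depths:
        stats = np.asarray(per_net[d])
        pairs = pooled_pairs[d]
        pooled_stat = float("nan")
        if len(pairs) >= 3:
            pooled_stat = pearson_similarity(
                [a for a, _ in pairs], [b for _, b in pairs]
            )
        mean_stat = float(stats.mean()) if stats.size else float("nan")
        headline = pooled_stat if config.aggregation == "pooled" else mean_stat
        results.append(
            SmoothnessByDepth(
                depth=d,
                statistic=headline,
                aggregation=config.aggregation,
                pooled_statistic=pooled_stat,
                per_network_mean=mean_stat,
                sd_across_networks=float(stats.std(ddof=1)) if stats.size > 1 else float("nan"),
                per_network_statistics=stats,
                n_excluded_pairs=excluded[d],
            )
        )
    return results


def run_factorial_proof(n_factors: int = 3) -> dict:
    """Verify the orthogonality of full factorial design coding.

    Checks, in exact integer arithmetic, that all distinct rows (and
    columns) of the 2^n x 2^n design matrix have dot product 0, and that
    the normalized design Q satisfies Q Qᵀ = Qᵀ Q = I.
    """
    from .coding import build_factorial_design

    design = build_factorial_design(n_factors)
    m = design.matrix
    size = design.size
    gram_rows = m @ m.T
    gram_cols = m.T @ m
    off_row = gram_rows - np.diag(np.diag(gram_rows))
    off_col = gram_cols - np.diag(np.diag(gram_cols))
    q = design.normalized()
    eye = np.eye(size)
    report = {
        "n_factors": n_factors,
        "size": size,
        "n_distinct_row_pairs": size * (size - 1) // 2,
        "max_abs_row_dot": int(np.abs(off_row).max()),
        "max_abs_col_dot": int(np.abs(off_col).max()),
        "max_dev_QQt_identity": float(np.abs(q @ q.T - eye).max()),
        "max_dev_QtQ_identity": float(np.abs(q.T @ q - eye).max()),
        "rows_orthogonal": bool(np.all(off_row == 0)),
        "columns_orthogonal": bool(np.all(off_col == 0)),
    }
    report["orthogonal"] = bool(
        report["rows_orthogonal"]
        and report["columns_orthogonal"]
        and report["max_dev_QQt_identity"] < 1e-12
        and report["max_dev_QtQ_identity"] < 1e-12
    )
    return report


def run_hash_demo(config: ExperimentConfig | None = None, n_permutations: int = 1000) -> dict:
    """Push the distortion protocol through SHA-1 hash coding.

    Reports the similarity-to-prototype curve (expected flat around 0
    within the analytic 95% null band for uncorrelated representations)
    and the pooled smoothness statistic against a permutation null built
    by shuffling the output-similarity list relative to the input list.
    """
    config = config or ExperimentConfig()
    level_sims = np.empty((config.n_networks, config.n_distortions))
    in_all: list[float] = []
    out_all: list[float] = []
    rep_len = None
    for net in range(config.n_networks):
        _, rng_s = _network_rngs(config, net)
        for sset in _network_stimuli(config, rng_s):
            proto = sset.prototype.values
            hp = encode_hash(proto)
            rep_len = hp.size
            for lvl, d in enumerate(sset.distortions):
                s = pearson_similarity(hp, encode_hash(d))
                level_sims[net, lvl] = s
                in_all.append(pearson_similarity(proto, d))
                out_all.append(s)
    smooth = smoothness_from_similarities(in_all, out_all)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    out_arr = np.asarray(out_all)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = pearson_similarity(in_all, rng.permutation(out_arr))
    lo, hi = np.percentile(null, [2.5, 97.5])
    # analytic null band for the mean of n_networks independent Pearson rhos
    # between length-m uncorrelated vectors (sd ~ 1/sqrt(m-1)), made
    # simultaneous across the distortion levels by Bonferroni correction
    from scipy.stats import norm

    z = norm.ppf(1 - 0.025 / config.n_distortions)
    band = z / np.sqrt((rep_len - 1) * config.n_networks)
    mean_curve = level_sims.mean(axis=0)
    return {
        "noise_sds": (config.sd_step * np.arange(1, config.n_distortions + 1)).tolist(),
        "mean_similarity": mean_curve.tolist(),
        "similarity_null_band_95": float(band),
        "curve_within_null_band": bool(np.all(np.abs(mean_curve) <= band)),
        "smoothness_statistic": smooth.statistic,
        "null_band_95": [float(lo), float(hi)],
        "smoothness_within_null_band": bool(lo <= smooth.statistic <= hi),
        "n_permutations": n_permutations,
        "representation_length": rep_len,
    }


def _curves_frame(curves: list[DistortionCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)


def _smoothness_frame(results: list[SmoothnessByDepth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "depth": [r.depth for r in results],
            "statistic": [r.statistic for r in results],
            "aggregation": [r.aggregation for r in results],
            "pooled_statistic": [r.pooled_statistic for r in results],
            "per_network_mean": [r.per_network_mean for r in results],
            "sd_across_networks": [r.sd_across_networks for r in results],
            "n_excluded_pairs": [r.n_excluded_pairs for r in results],
        }
    )


def write_report(results: dict, output_dir, config: ExperimentConfig | None = None) -> list[str]:
    """Persist experiment results as delimited tables plus a JSON summary.

    ``results`` maps names to result objects: lists of
    :class:`DistortionCurve`, lists of :class:`SmoothnessByDepth`, dict
    reports, or :class:`~fmricode.similarity.SmoothnessResult`.  Re-running
    with the same seed reproduces byte-identical files (no timestamps).
    """
    import os

    os.makedirs(output_dir, exist_ok=True)
    written = []
    summary: dict = {"software_version": __version__}
    if config is not None:
        summary["config"] = asdict(config)
        summary["seed"] = config.seed
    for name, obj in results.items():
        if isinstance(obj, list) and obj and isinstance(obj[0], DistortionCurve):
            path = os.path.join(output_dir, f"{name}.csv")
            _curves_frame(obj).to_csv(path, index=False)
            written.append(path)
            summary[name] = {"file": os.path.basename(path), "n_models": len(obj)}
        elif isinstance(obj, list) and obj and isinstance(obj[0], SmoothnessByDepth):
            path = os.path.join(output_dir, f"{name}.csv")
            _smoothness_frame(obj).to_csv(path, index=False)
            written.append(path)
            raw = os.path.join(output_dir, f"{name}_per_network.csv")
            pd.DataFrame(
                {r.depth: pd.Series(r.per_network_statistics) for r in obj}
            ).to_csv(raw, index_label="network")
            written.append(raw)
            summary[name] = {
                "file": os.path.basename(path),
                "n_excluded_pairs": {r.depth: r.n_excluded_pairs for r in obj},
            }
        elif isinstance(obj, SmoothnessResult):
            path = os.path.join(output_dir, f"{name}.json")
            obj.to_json(path)
            written.append(path)
            summary[name] = {"file": os.path.basename(path), "statistic": obj.statistic}
        else:
            summary[name] = obj
    spath = os.path.join(output_dir, "summary.json")
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append(spath)
    return written
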