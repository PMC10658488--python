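"""End-to-end orchestration: generate -> measure -> label -> train -> report.

One master seed fans out to per-stage seeds through a fixed counter scheme
(``SeedSequence(master_seed, spawn_key=(stage_index,))``), so a single
integer reproduces every number in the run. The manifest records the config
snapshot, all derived seeds, and a content hash of every CSV the run wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence  # noqa: F401  (Mapping in annotations)

import numpy as np
import pandas as pd
import yaml

from vnqi import io as vio
from vnqi.model import (
    ChainSpec,
    architecture_comparison,
    evaluate,
    fit_chain,
    learning_curve,
    pearson_ranking,
    split_dataset,
    stability_analysis,
    FEATURES,
)
from vnqi.morphometrics import measure
from vnqi.oxygen import TransportParams, solve_oxygen, summarize
from vnqi.synthetic import DEFAULT_JITTER, GeneratorConfig, VesselMask, generate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "build_dataset",
    "run_pipeline",
    "sweep_determinant",
    "stage_seed",
]

_STAGES = ("generate", "split", "train", "stability", "learning_curve", "sweep")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the master seed."""
    k = _STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Everything a full run needs, loadable from one YAML file."""

    n_samples: int = 500
    base_generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    jitter: dict = field(default_factory=lambda: dict(DEFAULT_JITTER))
    transport: TransportParams = field(default_factory=TransportParams)
    chain_spec: ChainSpec = field(default_factory=ChainSpec)
    train_frac: float = 0.8
    spur_len_px: int = 5
    n_stability_partitions: int = 10
    learning_sizes: tuple[int, ...] = (50, 100, 200, 300, 400)
    save_masks: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "base_generator" in kwargs:
            gen = dict(kwargs["base_generator"])
            if "image_shape" in gen:
                gen["image_shape"] = tuple(gen["image_shape"])
            kwargs["base_generator"] = GeneratorConfig(**gen)
        if "transport" in kwargs:
            tp = dict(kwargs["transport"])
            if "boundary" in tp:
                tp["boundary"] = tuple(tp["boundary"])
            kwargs["transport"] = TransportParams(**tp)
        if "chain_spec" in kwargs:
            cs = dict(kwargs["chain_spec"])
            if "hidden_layer_options" in cs:
                cs["hidden_layer_options"] = tuple(cs["hidden_layer_options"])
            kwargs["chain_spec"] = ChainSpec(**cs)
        if "jitter" in kwargs:
            kwargs["jitter"] = {k: tuple(v) for k, v in kwargs["jitter"].items()}
        if "learning_sizes" in kwargs:
            kwargs["learning_sizes"] = tuple(kwargs["learning_sizes"])
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["learning_sizes"] = list(self.learning_sizes)
        return d


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    master_seed: int
    stage_seeds: dict
    output_hashes: dict
    version: str
    started: str
    finished: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_dataset(
    masks: Sequence[VesselMask],
    provenance: pd.DataFrame,
    transport: TransportParams | None = None,
    spur_len_px: int = 5,
) -> pd.DataFrame:
    """Measure morphology and solve oxygen transport for a mask cohort.

    Returns the modeling table: one row per mask with ``sample_id``, the six
    morphology metrics, and the oracle ``oxy_v`` / ``oxy_t`` labels.
    """
    if transport is None:
        transport = TransportParams()
    rows = []
    for mask, sid in zip(masks, provenance["sample_id"]):
        mm = measure(mask, spur_len_px=spur_len_px)
        summ = summarize(solve_oxygen(mask, transport), mask)
        rows.append({"sample_id": sid, **mm.as_dict(), "oxy_v": summ.oxy_v, "oxy_t": summ.oxy_t})
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig | str | Path,
    master_seed: int,
    outdir: str | Path,
) -> RunManifest:
    """Execute the full pipeline and write all reports under ``outdir``.

    Stages: cohort generation, morphometry + oxygen labeling, 80/20 split,
    five-architecture comparison, chained-model scoring of all samples with
    Pearson ranking, repartitioning stability, and the learning curve. Any
    stage failure aborts with the stage name attached.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(master_seed, s) for s in _STAGES}
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs: dict[str, str] = {}
    stage = "generate"
    try:
        masks, prov = generate_cohort(
            config.base_generator, config.n_samples, config.jitter, seeds["generate"]
        )
        prov.to_csv(outdir / "cohort_manifest.csv", index=False)
        if config.save_masks:
            (outdir / "masks").mkdir(exist_ok=True)
            for m, sid in zip(masks, prov["sample_id"]):
                vio.save_mask(m, outdir / "masks" / f"{sid}.png")
        records = build_dataset(masks, prov, config.transport, config.spur_len_px)
        records.to_csv(outdir / "dataset.csv", index=False)

        stage = "split"
        train, test = split_dataset(records, config.train_frac, seed=seeds["split"])

        stage = "train"
        spec = dataclasses.replace(config.chain_spec, rng_seed=seeds["train"])
        comparison = architecture_comparison(train, test, spec)
        comparison.to_csv(outdir / "architecture_comparison.csv", index=False)

        chain = fit_chain(train, spec)
        vio.save_chain(chain, outdir / "model")
        X_all = records[FEATURES].to_numpy(dtype=float)
        vnqi_all = chain.predict(X_all)
        scored = records[["sample_id"]].copy()
        scored["vnqi"] = vnqi_all
        scored.to_csv(outdir / "vnqi_scores.csv", index=False)
        ranking = pearson_ranking(records, vnqi_all, target="oxy_t")
        ranking.to_csv(outdir / "pearson_ranking.csv", index=False)

        stage = "stability"
        stab_spec = dataclasses.replace(spec, rng_seed=seeds["stability"])
        stability = stability_analysis(
            records, stab_spec, n_partitions=config.n_stability_partitions,
            train_frac=config.train_frac,
        )
        stability.to_csv(outdir / "stability.csv", index=False)

        stage = "learning_curve"
        pool_size = int(np.ceil(config.train_frac * len(records)))
        sizes = [s for s in config.learning_sizes if s <= pool_size]
        if not sizes:  # cohort smaller than every requested size: single point
            sizes = [pool_size]
        lc_spec = dataclasses.replace(spec, rng_seed=seeds["learning_curve"])
        lc = learning_curve(records, lc_spec, sizes=sizes, train_frac=config.train_frac,
                            split_seed=seeds["split"])
        lc.to_csv(outdir / "learning_curve.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(outdir.glob("*.csv")):
        outputs[f.name] = _sha256(f)
    manifest = RunManifest(
        config=config.snapshot(),
        master_seed=master_seed,
        stage_seeds=seeds,
        output_hashes=outputs,
        version=_pkg_version(),
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(outdir / "run_manifest.json")
    return manifest


def _pkg_version() -> str:
    from vnqi import __version__

    return __version__


def sweep_determinant(
    config: PipelineConfig,
    chain,
    knob: str,
    levels: Sequence[float],
    seeds: Sequence[int],
    n_per_level: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score cohorts generated at several levels of one generator knob.

    Emulates wet-lab sensitivity experiments (vary one determinant of
    vasculogenesis, hold the rest): for each level of ``knob``, generate
    ``n_per_level`` masks per seed with the base config pinned at that
    level, label them with the oracle, score them with a *fixed* trained
    chain, and compute the per-level (group) Pearson ranking.

    Returns ``(scores, ranking)``: per-mask VNQI + labels with a ``group``
    column, and the group-wise Pearson table (7 rows per level).
    """
    if knob not in {f.name for f in dataclasses.fields(GeneratorConfig)}:
        raise ValueError(f"{knob!r} is not a generator config field")
    if len(levels) < 2:
        raise ValueError("need at least 2 levels for a sweep")

    all_rows = []
    for level in levels:
        for s in seeds:
            base = dataclasses.replace(
                config.base_generator,
                **{knob: int(level) if knob == "n_seed_points" else level},
            )
            jitter = {k: v for k, v in config.jitter.items() if k != knob}
            masks, prov = generate_cohort(base, n_per_level, jitter, master_seed=int(s))
            records = build_dataset(masks, prov, config.transport, config.spur_len_px)
            records["vnqi"] = chain.predict(records[FEATURES].to_numpy(dtype=float))
            records["group"] = f"{knob}={level}"
            records["seed"] = s
            all_rows.append(records)
    scores = pd.concat(all_rows, ignore_index=True)
    ranking = pearson_ranking(
        scores, scores["vnqi"].to_numpy(), target="oxy_t", group="group"
    )
    return scores, ranking
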