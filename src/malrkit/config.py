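"""Run configuration and the end-to-end pipeline driver.

One YAML config drives every stage; CLI flags override config values and
both are captured in the run manifest together with the seed, a config
hash, package version and sha256 checksums of every output file, so a run
is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, phylo, structvar, timing, tint
from .formats import group_entities, family_census
from .simulate import (
    FamilyActivity,
    SpeciesTree,
    default_scenario,
    plant_structural_variants,
    simulate_succession,
    synthetic_internal_consensus,
    synthetic_ltr_consensus,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for the pipeline stages.

    ``seed`` is mandatory: every stochastic stage derives its randomness
    from it.  Thresholds default to the comparative-genomics criteria
    (SW 100 / 300 bp flanks / 200 bp aligned per side / >50 bp presence).
    """

    seed: int
    outdir: str = "malrkit_run"
    log_level: str = "INFO"
    min_sw_score: int = 100
    flank_length: int = 300
    min_flank_aligned: int = 200
    min_presence: int = 50
    tint_tolerance: int = 30
    tint_restarts: int = 12
    nest_prob: float = 0.25
    bg_length: int = 150_000
    structvar_counts: dict = field(
        default_factory=lambda: {"canonical": 20, "precursor": 1, "intermediate": 1}
    )
    structvar_subst_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic stages")
        self.seed = int(self.seed)

    def thresholds(self) -> timing.TimingThresholds:
        return timing.TimingThresholds(
            min_sw_score=self.min_sw_score,
            flank_length=self.flank_length,
            min_flank_aligned=self.min_flank_aligned,
            min_presence=self.min_presence,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("seed is mandatory for stochastic stages")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig, outdir=None) -> dict:
    """simulate -> census -> timing -> tint -> tree -> structvar, with manifest.

    Any stage failure aborts with the stage name; outputs of completed
    stages remain on disk.  Returns the manifest (also written as JSON).
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "simulate"
    try:
        tree, families = default_scenario()
        bundle = simulate_succession(
            tree, families, seed=config.seed,
            nest_prob=config.nest_prob, bg_length=config.bg_length,
        )
        written += bundle.write(out / "simulate")

        stage = "census"
        fam_names = [f.name for f in families]
        census = family_census(bundle.copies[tree.focal], fam_names, tree.focal)
        p = out / "census.tsv"
        census.to_csv(p, sep="\t", index=False)
        written.append(p)

        stage = "timing"
        entities = group_entities(bundle.copies[tree.focal])
        older, younger = sorted(tree.splits, key=tree.splits.get)
        calls = timing.run_timing(
            entities, bundle.chains, config.thresholds(), (older, younger)
        )
        p = out / "timing_calls.tsv"
        calls.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = out / "timing_summary.tsv"
        timing.timing_summary(calls).to_csv(p, sep="\t", index=False)
        written.append(p)

        stage = "tint"
        events = tint.detect_tint_events(entities, config.tint_tolerance)
        matrix = tint.build_nesting_matrix(events, fam_names)
        p = out / "tint_matrix.tsv"
        matrix.to_csv(p, sep="\t")
        written.append(p)
        ent_counts = {f: sum(1 for e in entities if e.family == f)
                      for f in fam_names}
        fit = tint.infer_activity_periods(
            matrix, copy_weights={f: max(1, n) for f, n in ent_counts.items()},
            seed=config.seed, restarts=config.tint_restarts,
        )
        p = out / "tint_periods.tsv"
        _periods_table(fit).to_csv(p, sep="\t", index=False)
        written.append(p)

        stage = "tree"
        dm = phylo.distance_matrix(bundle.consensus)
        p = out / "consensus_distances.tsv"
        dm.to_csv(p, sep="\t")
        written.append(p)
        newick = phylo.neighbor_joining(dm)
        p = out / "consensus_nj.nwk"
        p.write_text(newick + "\n")
        written.append(p)

        stage = "structvar"
        ltr = synthetic_ltr_consensus()
        internal = synthetic_internal_consensus()
        defs = {n: d for n, d in structvar.load_variant_defs().items()
                if n in structvar.THE1A_VARIANTS}
        elements, truth = plant_structural_variants(
            ltr, internal, defs, config.structvar_counts,
            seed=config.seed + 1, subst_rate=config.structvar_subst_rate,
        )
        table = structvar.scan_for_stage(elements, ltr, defs)
        p = out / "structvar_stages.tsv"
        table.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = out / "structvar_truth.tsv"
        truth.to_csv(p, sep="\t", index=False)
        written.append(p)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    cfg = config.to_dict()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _periods_table(fit: "tint.TintFit"):
    import pandas as pd

    return pd.DataFrame([
        {
            "family": p.family, "mu": p.mu, "sigma": p.sigma,
            "lo75": p.interval_75[0], "hi75": p.interval_75[1],
            "lo95": p.interval_95[0], "hi95": p.interval_95[1],
            "lo99": p.interval_99[0], "hi99": p.interval_99[1],
            "unconstrained": p.unconstrained,
        }
        for p in fit.periods
    ])
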